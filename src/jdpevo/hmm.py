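"""Profile hidden Markov models: building, scoring, decoding.

The model is a classic match/insert/delete profile over the 20-letter
alphabet, aligned *globally* over the model with free flanking inserts
(``I0`` before the first match state and ``IL`` after the last both emit at
background), so whole-domain profiles do not penalise N/C-terminal flanks.
All nine transition types (M/I/D to M/I/D) are parameterised per position.

State graph for a model of length ``L``::

    B -> {M1, I0, D1}
    Mk -> {M(k+1) | E, Ik, D(k+1)}
    Ik -> {M(k+1) | E, Ik, D(k+1)}
    Dk -> {M(k+1) | E, D(k+1), Ik}

Dynamic programming runs in log space (no underflow by construction); the
heavy recurrences are JIT-compiled with numba.  Scores are reported in bits:
``log2`` of the forward (or Viterbi) likelihood over an i.i.d. background
null.  ``X`` residues are emitted with probability one by every state and by
the null, so they contribute zero bits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .io import AA_INDEX, AMINO_ACIDS, GAP, AlignmentBlock, ProteinRecord

__all__ = [
    "ProfileHMM",
    "ProfileHit",
    "PosteriorMatrix",
    "build_profile",
    "henikoff_weights",
    "forward_score",
    "viterbi_align",
    "posterior_decode",
    "search_profile",
    "write_profile",
    "read_profile",
]

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Model container

@dataclass
class ProfileHMM:
    """A profile HMM with ``L`` match states.

    ``transitions`` holds nine per-position vectors of length ``L+1``; index
    ``k`` of the M/I rows refers to state ``Mk``/``Ik`` with ``M0 = Begin``,
    and index ``L`` transitions lead to End.  D rows use indices ``1..L``.
    """

    name: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L+1, 20)
    transitions: dict[str, np.ndarray]  # keys mm mi md im ii id dm dd di
    background: np.ndarray  # (20,)
    match_column_map: np.ndarray  # (L,) seed-alignment column of each match state

    def __post_init__(self) -> None:
        L = self.length
        if L < 1:
            raise ValueError("profile must have at least one match state")
        if np.any(np.diff(self.match_column_map) <= 0):
            raise ValueError("match_column_map must be strictly increasing")
        for k in range(L):
            if abs(self.match_emissions[k].sum() - 1.0) > 1e-9:
                raise ValueError(f"match emission row {k} does not sum to 1")
        for k in range(L + 1):
            if abs(self.insert_emissions[k].sum() - 1.0) > 1e-9:
                raise ValueError(f"insert emission row {k} does not sum to 1")
        t = self.transitions
        for k in range(L + 1):
            m_out = t["mm"][k] + t["mi"][k] + t["md"][k]
            i_out = t["im"][k] + t["ii"][k] + t["id"][k]
            if abs(m_out - 1.0) > 1e-9 or abs(i_out - 1.0) > 1e-9:
                raise ValueError(f"transition rows at {k} do not sum to 1")
            if k >= 1:
                d_out = t["dm"][k] + t["dd"][k] + t["di"][k]
                if abs(d_out - 1.0) > 1e-9:
                    raise ValueError(f"D transition row at {k} does not sum to 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    def _logs(self) -> dict[str, np.ndarray]:
        cached = getattr(self, "_log_cache", None)
        if cached is None:
            with np.errstate(divide="ignore"):
                cached = {
                    "lme": np.log(self.match_emissions),
                    "lie": np.log(self.insert_emissions),
                    "lbg": np.log(self.background),
                    **{
                        "l" + k: np.log(v) for k, v in self.transitions.items()
                    },
                }
            object.__setattr__(self, "_log_cache", cached)
        return cached


@dataclass
class ProfileHit:
    """One sequence scored and aligned against a profile."""

    record_id: str
    bit_score: float  # forward (total-likelihood) bits
    viterbi_bits: float
    viterbi_path: list[tuple[str, int]]  # (state in {M,I,D}, position index)
    aligned_span: tuple[int, int]  # half-open residue span hitting match states
    match_assignment: np.ndarray  # per residue: 0-based match index, -1 = insert


@dataclass
class PosteriorMatrix:
    """Forward-backward posteriors of one sequence against one profile.

    ``p_match[i, k]``: probability residue ``i`` (0-based) is emitted by match
    state ``k+1``; ``p_insert[i]``: total insert-state probability of residue
    ``i``; ``p_delete[k]``: probability match state ``k+1`` is deleted.
    """

    p_match: np.ndarray  # (n, L)
    p_insert: np.ndarray  # (n,)
    p_delete: np.ndarray  # (L,)
    log_likelihood: float


# ---------------------------------------------------------------------------
# Building from a seed alignment

def henikoff_weights(matrix: Sequence[str]) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994),
    normalised to sum to the number of sequences."""
    n = len(matrix)
    w = np.zeros(n)
    ncols = len(matrix[0])
    for c in range(ncols):
        col = [row[c] for row in matrix]
        residues = [a for a in col if a != GAP and a != "X"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for a in residues:
            counts[a] = counts.get(a, 0) + 1
        r = len(counts)
        for i, a in enumerate(col):
            if a in counts:
                w[i] += 1.0 / (r * counts[a])
    if w.sum() == 0:
        return np.ones(n)
    return w * n / w.sum()


def _seed_background(matrix: Sequence[str]) -> np.ndarray:
    counts = np.full(20, 0.5)  # half-count keeps unseen letters possible
    for row in matrix:
        for a in row:
            if a in AA_INDEX:
                counts[AA_INDEX[a]] += 1
    return counts / counts.sum()


def build_profile(
    seed: AlignmentBlock,
    name: str = "profile",
    match_occupancy_threshold: float = 0.5,
    pseudocount_weight: float | None = None,
    weighting: str = "henikoff",
    flank_expected_len: float | None = 200.0,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose non-gap fraction is at least ``match_occupancy_threshold``
    become match states.  Emissions are weighted counts mixed with
    ``pseudocount_weight`` x background (default 0.1 x sequence count);
    transitions come from the seed's state paths with Laplace one-count
    smoothing.

    The flanking insert states ``I0`` and ``IL`` are the N/C loops of the
    global-with-flanks alignment mode.  Seed alignments span only the
    modelled domain, so their self-loops cannot be estimated from seed
    counts; they are instead parameterised by ``flank_expected_len`` (the
    geometric mean flank length a query may carry at no emission cost),
    keeping whole-domain profiles usable on full-length sequences.  Pass
    ``None`` to keep the raw seed-count estimates.
    """
    n, ncols = seed.n_rows, seed.column_count
    if n < 2:
        raise ValueError("single-row seed: need at least 2 sequences")
    occupancy = np.array(
        [sum(1 for row in seed.matrix if row[c] != GAP) / n for c in range(ncols)]
    )
    match_cols = np.flatnonzero(occupancy >= match_occupancy_threshold)
    if match_cols.size == 0:
        if occupancy.max() == 0:
            raise ValueError("no match columns: all-gap seed")
        raise ValueError("no match columns at this occupancy threshold")
    L = match_cols.size
    is_match = np.zeros(ncols, dtype=bool)
    is_match[match_cols] = True

    if weighting == "henikoff":
        weights = henikoff_weights(seed.matrix)
    elif weighting == "none":
        weights = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    background = _seed_background(seed.matrix)
    if pseudocount_weight is None:
        pseudocount_weight = 0.1 * n

    # emissions
    counts = np.zeros((L, 20))
    for row, w in zip(seed.matrix, weights):
        for k, c in enumerate(match_cols):
            a = row[c]
            if a in AA_INDEX:
                counts[k, AA_INDEX[a]] += w
    match_em = counts + pseudocount_weight * background
    match_em /= match_em.sum(axis=1, keepdims=True)
    insert_em = np.tile(background, (L + 1, 1))

    # transitions from seed state paths (Laplace 1-count smoothing)
    tc = {key: np.zeros(L + 1) for key in ("mm", "mi", "md", "im", "ii", "id", "dm", "dd", "di")}
    for row, w in zip(seed.matrix, weights):
        prev = ("m", 0)  # Begin acts as M0
        k = 0
        for c in range(ncols):
            a = row[c]
            if is_match[c]:
                k += 1
                state = ("m", k) if a != GAP else ("d", k)
            elif a != GAP:
                state = ("i", k)
            else:
                continue
            tc[prev[0] + state[0]][prev[1]] += w
            prev = state
        tc[prev[0] + "m"][prev[1]] += w  # exit to End via the *m slot

    trans = {key: np.zeros(L + 1) for key in tc}
    for k in range(L + 1):
        legal_md = 1.0 if k < L else 0.0
        m_row = np.array([tc["mm"][k] + 1, tc["mi"][k] + 1, tc["md"][k] + legal_md])
        i_row = np.array([tc["im"][k] + 1, tc["ii"][k] + 1, tc["id"][k] + legal_md])
        trans["mm"][k], trans["mi"][k], trans["md"][k] = m_row / m_row.sum()
        trans["im"][k], trans["ii"][k], trans["id"][k] = i_row / i_row.sum()
        if k >= 1:
            d_row = np.array([tc["dm"][k] + 1, tc["dd"][k] + legal_md, tc["di"][k] + 1])
            trans["dm"][k], trans["dd"][k], trans["di"][k] = d_row / d_row.sum()

    if flank_expected_len is not None:
        eta = flank_expected_len / (flank_expected_len + 1.0)
        trans["ii"][0] = eta
        trans["im"][0] = (1 - eta) * 0.95
        trans["id"][0] = (1 - eta) * 0.05
        trans["ii"][L] = eta
        trans["im"][L] = 1 - eta
        trans["id"][L] = 0.0

    return ProfileHMM(
        name=name,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        background=background,
        match_column_map=match_cols.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Numba DP kernels

@njit(cache=True)
def _fwd(em, ei, lmm, lmi, lmd, lim, lii, lid, ldm, ldd, ldi):
    n = em.shape[0] - 1
    L = em.shape[1] - 1
    fM = np.full((n + 1, L + 1), NEG_INF)
    fI = np.full((n + 1, L + 1), NEG_INF)
    fD = np.full((n + 1, L + 1), NEG_INF)
    fM[0, 0] = 0.0
    for k in range(1, L + 1):
        fD[0, k] = np.logaddexp(fM[0, k - 1] + lmd[k - 1], fD[0, k - 1] + ldd[k - 1])
    for i in range(1, n + 1):
        for k in range(0, L + 1):
            a = fM[i - 1, k] + lmi[k]
            a = np.logaddexp(a, fI[i - 1, k] + lii[k])
            a = np.logaddexp(a, fD[i - 1, k] + ldi[k])
            fI[i, k] = ei[i, k] + a
            if k >= 1:
                b = fM[i - 1, k - 1] + lmm[k - 1]
                b = np.logaddexp(b, fI[i - 1, k - 1] + lim[k - 1])
                b = np.logaddexp(b, fD[i - 1, k - 1] + ldm[k - 1])
                fM[i, k] = em[i, k] + b
        for k in range(1, L + 1):
            d = fM[i, k - 1] + lmd[k - 1]
            d = np.logaddexp(d, fI[i, k - 1] + lid[k - 1])
            d = np.logaddexp(d, fD[i, k - 1] + ldd[k - 1])
            fD[i, k] = d
    total = np.logaddexp(fM[n, L] + lmm[L], fI[n, L] + lim[L])
    total = np.logaddexp(total, fD[n, L] + ldm[L])
    return fM, fI, fD, total


@njit(cache=True)
def _bwd(em, ei, lmm, lmi, lmd, lim, lii, lid, ldm, ldd, ldi):
    n = em.shape[0] - 1
    L = em.shape[1] - 1
    bM = np.full((n + 1, L + 1), NEG_INF)
    bI = np.full((n + 1, L + 1), NEG_INF)
    bD = np.full((n + 1, L + 1), NEG_INF)
    for i in range(n, -1, -1):
        for k in range(L, -1, -1):
            # to M(k+1) / End
            if k == L:
                toM = lmm[L] if i == n else NEG_INF
                toM_i = lim[L] if i == n else NEG_INF
                toM_d = ldm[L] if i == n else NEG_INF
            elif i < n:
                nxt = em[i + 1, k + 1] + bM[i + 1, k + 1]
                toM = lmm[k] + nxt
                toM_i = lim[k] + nxt
                toM_d = ldm[k] + nxt
            else:
                toM = toM_i = toM_d = NEG_INF
            # to I_k (emits)
            if i < n:
                nxt_i = ei[i + 1, k] + bI[i + 1, k]
                toI = lmi[k] + nxt_i
                toI_i = lii[k] + nxt_i
                toI_d = ldi[k] + nxt_i
            else:
                toI = toI_i = toI_d = NEG_INF
            # to D(k+1) (silent, same row)
            if k < L:
                toD = lmd[k] + bD[i, k + 1]
                toD_i = lid[k] + bD[i, k + 1]
                toD_d = ldd[k] + bD[i, k + 1]
            else:
                toD = toD_i = toD_d = NEG_INF
            bM[i, k] = np.logaddexp(np.logaddexp(toM, toI), toD)
            bI[i, k] = np.logaddexp(np.logaddexp(toM_i, toI_i), toD_i)
            if k >= 1:
                bD[i, k] = np.logaddexp(np.logaddexp(toM_d, toI_d), toD_d)
    return bM, bI, bD


@njit(cache=True)
def _vit(em, ei, lmm, lmi, lmd, lim, lii, lid, ldm, ldd, ldi):
    """Viterbi DP.  Pointer codes: 0=M, 1=D, 2=I (also the tie-break
    preference order), -1 = from Begin."""
    n = em.shape[0] - 1
    L = em.shape[1] - 1
    vM = np.full((n + 1, L + 1), NEG_INF)
    vI = np.full((n + 1, L + 1), NEG_INF)
    vD = np.full((n + 1, L + 1), NEG_INF)
    pM = np.full((n + 1, L + 1), -9, dtype=np.int8)
    pI = np.full((n + 1, L + 1), -9, dtype=np.int8)
    pD = np.full((n + 1, L + 1), -9, dtype=np.int8)
    vM[0, 0] = 0.0
    pM[0, 0] = -1
    for k in range(1, L + 1):
        cm = vM[0, k - 1] + lmd[k - 1]
        cd = vD[0, k - 1] + ldd[k - 1]
        if cm >= cd:
            vD[0, k] = cm
            pD[0, k] = 0
        else:
            vD[0, k] = cd
            pD[0, k] = 1
    for i in range(1, n + 1):
        for k in range(0, L + 1):
            cm = vM[i - 1, k] + lmi[k]
            cd = vD[i - 1, k] + ldi[k]
            ci = vI[i - 1, k] + lii[k]
            best, ptr = cm, 0
            if cd > best:
                best, ptr = cd, 1
            if ci > best:
                best, ptr = ci, 2
            vI[i, k] = ei[i, k] + best
            pI[i, k] = ptr
            if k >= 1:
                cm = vM[i - 1, k - 1] + lmm[k - 1]
                cd = vD[i - 1, k - 1] + ldm[k - 1]
                ci = vI[i - 1, k - 1] + lim[k - 1]
                best, ptr = cm, 0
                if cd > best:
                    best, ptr = cd, 1
                if ci > best:
                    best, ptr = ci, 2
                vM[i, k] = em[i, k] + best
                pM[i, k] = ptr
        for k in range(1, L + 1):
            cm = vM[i, k - 1] + lmd[k - 1]
            cd = vD[i, k - 1] + ldd[k - 1]
            ci = vI[i, k - 1] + lid[k - 1]
            best, ptr = cm, 0
            if cd > best:
                best, ptr = cd, 1
            if ci > best:
                best, ptr = ci, 2
            vD[i, k] = best
            pD[i, k] = ptr
    cm = vM[n, L] + lmm[L]
    cd = vD[n, L] + ldm[L]
    ci = vI[n, L] + lim[L]
    best, ptr = cm, 0
    if cd > best:
        best, ptr = cd, 1
    if ci > best:
        best, ptr = ci, 2
    return vM, vI, vD, pM, pI, pD, best, ptr


# ---------------------------------------------------------------------------
# Scoring API

def _encode(record: ProteinRecord) -> np.ndarray:
    return np.array([AA_INDEX.get(a, -1) for a in record.residues], dtype=np.int64)


def _emission_tables(model: ProfileHMM, x: np.ndarray):
    """Per-(residue, state) log emission lookups; X (code -1) emits with
    probability one everywhere so that it cancels against the null."""
    n, L = x.size, model.length
    logs = model._logs()
    em = np.full((n + 1, L + 1), NEG_INF)
    ei = np.full((n + 1, L + 1), NEG_INF)
    for i in range(1, n + 1):
        if x[i - 1] >= 0:
            em[i, 1:] = logs["lme"][:, x[i - 1]]
            ei[i, :] = logs["lie"][:, x[i - 1]]
        else:
            em[i, 1:] = 0.0
            ei[i, :] = 0.0
    return em, ei


def _null_logprob(model: ProfileHMM, x: np.ndarray) -> float:
    logs = model._logs()
    return float(sum(logs["lbg"][a] for a in x if a >= 0))


def _kernel_args(model: ProfileHMM, record: ProteinRecord):
    if not record.residues:
        raise ValueError("empty sequence")
    x = _encode(record)
    em, ei = _emission_tables(model, x)
    logs = model._logs()
    t = tuple(logs["l" + k] for k in ("mm", "mi", "md", "im", "ii", "id", "dm", "dd", "di"))
    return x, em, ei, t


def forward_log_likelihood(model: ProfileHMM, record: ProteinRecord) -> float:
    x, em, ei, t = _kernel_args(model, record)
    _, _, _, total = _fwd(em, ei, *t)
    return float(total)


def forward_score(model: ProfileHMM, record: ProteinRecord) -> float:
    """Forward bit score: log2 of total model likelihood over the iid null."""
    x = _encode(record)
    ll = forward_log_likelihood(model, record)
    return (ll - _null_logprob(model, x)) / np.log(2.0)


def viterbi_align(model: ProfileHMM, record: ProteinRecord) -> ProfileHit:
    """Maximum-probability alignment; ties prefer M over D over I."""
    x, em, ei, t = _kernel_args(model, record)
    vM, vI, vD, pM, pI, pD, best, end_ptr = _vit(em, ei, *t)
    n, L = x.size, model.length
    # traceback
    path: list[tuple[str, int]] = []
    state = "MDI"[end_ptr]
    i, k = n, L
    assignment = np.full(n, -1, dtype=np.int64)
    while True:
        path.append((state, k))
        if state == "M":
            if k == 0:
                break
            assignment[i - 1] = k - 1
            ptr = pM[i, k]
            i, k = i - 1, k - 1
        elif state == "I":
            ptr = pI[i, k]
            i = i - 1
        else:  # D
            ptr = pD[i, k]
            k = k - 1
        state = "MDI"[ptr]
    path.reverse()
    matched = np.flatnonzero(assignment >= 0)
    span = (int(matched[0]), int(matched[-1]) + 1) if matched.size else (0, 0)
    fwd_bits = forward_score(model, record)
    vit_bits = (float(best) - _null_logprob(model, x)) / np.log(2.0)
    return ProfileHit(
        record_id=record.id,
        bit_score=fwd_bits,
        viterbi_bits=vit_bits,
        viterbi_path=path[1:],  # drop the Begin entry
        aligned_span=span,
        match_assignment=assignment,
    )


def posterior_decode(model: ProfileHMM, record: ProteinRecord) -> PosteriorMatrix:
    """Forward-backward posterior state occupancies for every residue."""
    x, em, ei, t = _kernel_args(model, record)
    fM, fI, fD, total = _fwd(em, ei, *t)
    bM, bI, bD = _bwd(em, ei, *t)
    n, L = x.size, model.length
    if not np.isfinite(total):
        raise FloatingPointError("sequence has zero likelihood under the model")
    p_match = np.exp(fM[1:, 1:] + bM[1:, 1:] - total)
    p_ins = np.exp(fI[1:, :] + bI[1:, :] - total).sum(axis=1)
    p_del = np.exp(fD[:, 1:] + bD[:, 1:] - total).sum(axis=0)
    return PosteriorMatrix(
        p_match=np.clip(p_match, 0.0, 1.0),
        p_insert=np.clip(p_ins, 0.0, 1.0),
        p_delete=np.clip(p_del, 0.0, 1.0),
        log_likelihood=float(total),
    )


def backward_log_likelihood(model: ProfileHMM, record: ProteinRecord) -> float:
    """Total likelihood recomputed from the backward pass (consistency check)."""
    x, em, ei, t = _kernel_args(model, record)
    bM, bI, bD = _bwd(em, ei, *t)
    return float(bM[0, 0])


def search_profile(
    model: ProfileHMM,
    records: Sequence[ProteinRecord],
    bit_threshold: float = 15.0,
) -> list[ProfileHit]:
    """All records whose forward bit score reaches ``bit_threshold``,
    sorted by descending score, ties broken by record id."""
    if not np.isfinite(bit_threshold) and bit_threshold > 0:
        return []
    hits = []
    for rec in records:
        bits = forward_score(model, rec)
        if bits >= bit_threshold:
            hit = viterbi_align(model, rec)
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.record_id))
    return hits


# ---------------------------------------------------------------------------
# Flat-text serialization

def write_profile(model: ProfileHMM, path: str | Path) -> None:
    def row(v):
        return " ".join(f"{x:.6g}" for x in v)

    with open(path, "w") as fh:
        fh.write("# jdpevo profile v1\n")
        fh.write(f"NAME {model.name}\n")
        fh.write(f"LENG {model.length}\n")
        fh.write(f"ALPH {AMINO_ACIDS}\n")
        fh.write(f"BG   {row(model.background)}\n")
        fh.write(f"MAP  {' '.join(str(c) for c in model.match_column_map)}\n")
        for k in range(model.length):
            fh.write(f"MATCH {k + 1} {row(model.match_emissions[k])}\n")
        for k in range(model.length + 1):
            fh.write(f"INSERT {k} {row(model.insert_emissions[k])}\n")
        keys = ("mm", "mi", "md", "im", "ii", "id", "dm", "dd", "di")
        for k in range(model.length + 1):
            vals = row(model.transitions[key][k] for key in keys)
            fh.write(f"TRANS {k} {vals}\n")


def read_profile(path: str | Path) -> ProfileHMM:
    name, L, bg, cmap = None, None, None, None
    match_rows: dict[int, np.ndarray] = {}
    ins_rows: dict[int, np.ndarray] = {}
    trans_rows: dict[int, np.ndarray] = {}
    for line in open(path):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        tag = parts[0]
        if tag == "NAME":
            name = parts[1] if len(parts) > 1 else "profile"
        elif tag == "LENG":
            L = int(parts[1])
        elif tag == "BG":
            bg = np.array([float(v) for v in parts[1:]])
        elif tag == "MAP":
            cmap = np.array([int(v) for v in parts[1:]], dtype=np.int64)
        elif tag == "MATCH":
            match_rows[int(parts[1])] = np.array([float(v) for v in parts[2:]])
        elif tag == "INSERT":
            ins_rows[int(parts[1])] = np.array([float(v) for v in parts[2:]])
        elif tag == "TRANS":
            trans_rows[int(parts[1])] = np.array([float(v) for v in parts[2:]])
    if L is None or bg is None or cmap is None:
        raise ValueError(f"{path}: incomplete profile file")
    me = np.stack([match_rows[k + 1] for k in range(L)])
    ie = np.stack([ins_rows[k] for k in range(L + 1)])
    me /= me.sum(axis=1, keepdims=True)
    ie /= ie.sum(axis=1, keepdims=True)
    keys = ("mm", "mi", "md", "im", "ii", "id", "dm", "dd", "di")
    trans = {key: np.zeros(L + 1) for key in keys}
    for k in range(L + 1):
        vals = trans_rows[k]
        for j, key in enumerate(keys):
            trans[key][k] = vals[j]
    # renormalise rounding error from the 6-digit format
    for k in range(L + 1):
        s = trans["mm"][k] + trans["mi"][k] + trans["md"][k]
        trans["mm"][k], trans["mi"][k], trans["md"][k] = (
            trans["mm"][k] / s, trans["mi"][k] / s, trans["md"][k] / s)
        s = trans["im"][k] + trans["ii"][k] + trans["id"][k]
        trans["im"][k], trans["ii"][k], trans["id"][k] = (
            trans["im"][k] / s, trans["ii"][k] / s, trans["id"][k] / s)
        if k >= 1:
            s = trans["dm"][k] + trans["dd"][k] + trans["di"][k]
            trans["dm"][k], trans["dd"][k], trans["di"][k] = (
                trans["dm"][k] / s, trans["dd"][k] / s, trans["di"][k] / s)
    return ProfileHMM(name or "profile", me, ie, trans, bg / bg.sum(), cmap)
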