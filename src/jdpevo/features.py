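"""Diagnostic molecular features of J-domain proteins.

Three features drive classification and the family summaries: the status of
the cysteine-rich zinc finger (full / truncated / absent), the residue length
of the glycine/phenylalanine-rich (G/F) region, and the presence of the
autoinhibitory helix V inside the G/F region.  Features are measured on the
query sequence after mapping named column blocks of a master profile onto
query residues through a profile alignment.

The zinc-finger criterion — eight cysteines positioned to coordinate two
zinc ions — is operationalised as four copies of the canonical DnaJ repeat
C-x-x-C-x-G-x-G.  By default only the C spacing is enforced (the glycines
drift in real families); a strict flag restores the full spelling.  A
truncated finger is exactly two repeats (four cysteines); anything else
that still contains cysteine structure is reported as ambiguous rather
than silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import ProfileHit
from .io import ProteinRecord

__all__ = [
    "ReferenceBlockMap",
    "ZnFCall",
    "HelixVCall",
    "DomainAnnotation",
    "map_reference_blocks",
    "anchored_feature_spans",
    "detect_znf",
    "measure_gf_length",
    "detect_helix_v",
    "annotate_architecture",
]

MOTIF_LEN = 8  # C-x-x-C-x-G-x-G


@dataclass(frozen=True)
class ReferenceBlockMap:
    """Named half-open *match-state column* spans on a master profile.

    ``helix_v_columns`` is a set of columns inside ``gf_region``.  Spans are
    config data tied to one profile (checked via ``profile_length``), not
    hard-coded constants.
    """

    profile_length: int
    j_domain: tuple[int, int]
    gf_region: tuple[int, int]
    znf_block: tuple[int, int] = (0, 0)
    ctd_dd_block: tuple[int, int] = (0, 0)
    helix_v_columns: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        spans = [self.j_domain, self.gf_region, self.znf_block, self.ctd_dd_block]
        for a, b in spans:
            if not (0 <= a <= b <= self.profile_length):
                raise ValueError(f"block span ({a},{b}) outside profile")
        named = [(a, b) for a, b in spans if b > a]
        for i, (a1, b1) in enumerate(named):
            for a2, b2 in named[i + 1 :]:
                if max(a1, a2) < min(b1, b2):
                    raise ValueError("reference blocks overlap")
        gf = self.gf_region
        if any(not gf[0] <= c < gf[1] for c in self.helix_v_columns):
            raise ValueError("helix V columns must lie inside the G/F block")


@dataclass
class ZnFCall:
    status: str  # full | truncated | absent | ambiguous
    n_cys: int
    block_residue_count: int
    motif_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class HelixVCall:
    present: bool | None  # None = secondary structure unavailable
    helix_span: tuple[int, int] | None = None
    overlap_fraction: float = 0.0


@dataclass
class DomainAnnotation:
    record_id: str
    j_domain_span: tuple[int, int]
    gf_span: tuple[int, int]
    gf_length: int
    znf: ZnFCall
    has_ctd_dd: bool
    has_st_bd: bool
    helix_v: HelixVCall


# ---------------------------------------------------------------------------

def map_reference_blocks(
    hit: ProfileHit, blocks: ReferenceBlockMap
) -> dict[str, tuple[int, int]]:
    """Transfer profile-column blocks onto query-residue spans.

    For each block, the minimal residue span covering all query residues
    whose Viterbi match assignment falls inside the block's columns; an
    empty ``(x, x)`` span if the block is fully deleted in the query.
    """
    assignment = hit.match_assignment
    if assignment.size and assignment.max() >= blocks.profile_length:
        raise ValueError(
            "block map defined on a different profile "
            f"(length {blocks.profile_length}, assignment up to {assignment.max()})"
        )
    out: dict[str, tuple[int, int]] = {}
    for name in ("j_domain", "gf_region", "znf_block", "ctd_dd_block"):
        a, b = getattr(blocks, name)
        idx = np.flatnonzero((assignment >= a) & (assignment < b))
        out[name] = (int(idx[0]), int(idx[-1]) + 1) if idx.size else (0, 0)
    return out


def map_columns_to_residues(hit: ProfileHit, columns: frozenset[int]) -> set[int]:
    """Query residue positions assigned to the given profile columns."""
    return {
        int(i) for i in np.flatnonzero(np.isin(hit.match_assignment, list(columns)))
    }


def _max_motif_tiling(
    seq: str, start: int, end: int, strict_g: bool
) -> list[tuple[int, int]]:
    """Maximum set of non-overlapping C-x-x-C(-x-G-x-G) repeats in a span,
    by dynamic programming (robust to stray cysteines)."""
    n = end - start

    def is_motif(p: int) -> bool:
        if p + MOTIF_LEN > end:
            return False
        if seq[p] != "C" or seq[p + 3] != "C":
            return False
        if strict_g and (seq[p + 5] != "G" or seq[p + 7] != "G"):
            return False
        return True

    best = [0] * (n + 1)  # best[i]: max motifs in seq[start+i:end]
    for i in range(n - 1, -1, -1):
        best[i] = best[i + 1]
        if is_motif(start + i):
            best[i] = max(best[i], 1 + best[min(i + MOTIF_LEN, n)])
    spans = []
    i = 0
    while i < n:
        if is_motif(start + i) and best[i] == 1 + best[min(i + MOTIF_LEN, n)] and best[i] > 0:
            spans.append((start + i, start + i + MOTIF_LEN))
            i += MOTIF_LEN
        else:
            i += 1
    return spans


def detect_znf(
    record: ProteinRecord,
    znf_span: tuple[int, int],
    strict_g: bool = False,
) -> ZnFCall:
    """Classify the zinc-finger block of a query.

    ``full``: four cysteine repeats (>= 8 Cys); ``truncated``: exactly two
    repeats and exactly four Cys; ``absent``: no repeats and no cysteine
    excess; ``ambiguous`` otherwise (one or three repeats, or >= 8 stray
    cysteines without repeat structure).  An empty span is ``absent``.
    """
    a, b = znf_span
    if not (0 <= a <= b <= len(record)):
        raise ValueError(f"ZnF span ({a},{b}) outside record {record.id}")
    if b <= a:
        return ZnFCall("absent", 0, 0)
    block = record.residues[a:b]
    n_cys = block.count("C")
    spans = _max_motif_tiling(record.residues, a, b, strict_g)
    m = len(spans)
    if m >= 4 and n_cys >= 8:
        return ZnFCall("full", n_cys, b - a, spans[:4])
    if m == 2 and n_cys == 4:
        return ZnFCall("truncated", n_cys, b - a, spans)
    if m == 0 and n_cys < 8:
        return ZnFCall("absent", n_cys, b - a)
    return ZnFCall("ambiguous", n_cys, b - a, spans)


def measure_gf_length(record: ProteinRecord, gf_span: tuple[int, int]) -> int:
    """Residue count of the G/F region (residues, not alignment columns)."""
    a, b = gf_span
    if not (0 <= a <= b <= len(record)):
        raise ValueError(f"G/F span ({a},{b}) outside record {record.id}")
    return b - a


def detect_helix_v(
    ss: str | None,
    gf_span: tuple[int, int],
    helix_v_positions: set[int],
    min_run: int = 4,
    min_overlap: float = 0.5,
) -> HelixVCall:
    """Two-criteria helix V call.

    Present iff (i) some maximal run of >= ``min_run`` consecutive H lies
    inside the G/F span and (ii) that run covers >= ``min_overlap`` of the
    mapped helix V positions.  With no secondary structure available the
    call is unknown (``present=None``), never a silent negative.
    """
    if ss is None:
        return HelixVCall(present=None)
    a, b = gf_span
    best_span: tuple[int, int] | None = None
    best_frac = 0.0
    i = a
    while i < b:
        if ss[i] != "H":
            i += 1
            continue
        j = i
        while j < b and ss[j] == "H":
            j += 1
        if j - i >= min_run:
            frac = (
                len(helix_v_positions & set(range(i, j))) / len(helix_v_positions)
                if helix_v_positions else 0.0
            )
            if best_span is None or frac > best_frac:
                best_span, best_frac = (i, j), frac
        i = j
    if best_span is None:
        return HelixVCall(present=False)
    return HelixVCall(best_frac >= min_overlap, best_span, best_frac)


def _anchored_gf_span(spans: dict[str, tuple[int, int]]) -> tuple[int, int]:
    """The G/F residue span between its structured anchors.

    The G/F interior is disordered, so the alignment of its own residues to
    G/F profile columns is ambiguous and the minimal matched span can start
    far inside the region.  Its boundaries, however, are well anchored: the
    J-domain immediately precedes it and the conserved helix V block sits
    at its C-terminal end.  The regional length the summaries need is
    therefore measured from the end of the mapped J-domain to the end of
    the G/F block's own matched span.
    """
    j = spans["j_domain"]
    gf = spans["gf_region"]
    start = j[1] if j[1] > j[0] else gf[0]
    end = max(gf[1], start)
    return (start, end)


def anchored_feature_spans(
    hit: ProfileHit, blocks: ReferenceBlockMap
) -> dict[str, tuple[int, int]]:
    """Feature spans with disordered-region boundaries taken from their
    structured anchors.

    ``gf_region`` runs from the end of the mapped J-domain to the end of its
    own matched span (the helix V block anchors that end); ``znf_block``
    runs from the G/F end to the start of the mapped CTD when both anchors
    exist — the zinc finger sits between them, and its own matched span
    under-counts when the query's finger diverges from the profile (e.g. a
    truncated finger against a full-length master).
    """
    spans = dict(map_reference_blocks(hit, blocks))
    gf = _anchored_gf_span(spans)
    spans["gf_region"] = gf
    ctd = spans["ctd_dd_block"]
    if blocks.znf_block[1] > blocks.znf_block[0] and ctd[1] > ctd[0] and gf[1] <= ctd[0]:
        spans["znf_block"] = (gf[1], ctd[0])
    return spans


def annotate_architecture(
    record: ProteinRecord,
    master_hit: ProfileHit,
    blocks: ReferenceBlockMap,
    has_ctd_dd: bool,
    has_st_bd: bool,
    ss: str | None = None,
    strict_g: bool = False,
    min_run: int = 4,
    min_overlap: float = 0.5,
) -> DomainAnnotation:
    """Assemble the full per-sequence architecture call.

    ``master_hit`` is the query's alignment to the master profile the block
    map is defined on; CTD/DD and ST presence come from the dedicated
    profile searches.
    """
    spans = anchored_feature_spans(master_hit, blocks)
    j_span = spans["j_domain"]
    gf_span = spans["gf_region"]
    ctd_span = spans["ctd_dd_block"]
    if j_span[1] > j_span[0] and ctd_span[1] > ctd_span[0]:
        if max(j_span[0], ctd_span[0]) < min(j_span[1], ctd_span[1]):
            raise ValueError(
                f"{record.id}: contradictory spans J={j_span} CTD={ctd_span}"
            )
    hv_positions = map_columns_to_residues(master_hit, blocks.helix_v_columns)
    return DomainAnnotation(
        record_id=record.id,
        j_domain_span=j_span,
        gf_span=gf_span,
        gf_length=measure_gf_length(record, gf_span),
        znf=detect_znf(record, spans["znf_block"], strict_g),
        has_ctd_dd=has_ctd_dd,
        has_st_bd=has_st_bd,
        helix_v=detect_helix_v(ss, gf_span, hv_positions, min_run, min_overlap),
    )
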