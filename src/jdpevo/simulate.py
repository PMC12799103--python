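"""Synthetic J-domain protein families with known ground truth.

The generator emulates the four architecture classes of the Hsp40/DnaJ
family on which the pipeline's detectors operate:

* ``A``          — J-domain, short G/F (median 34), full zinc finger
                   (60 residues, four C-x-x-C-x-G-x-G motifs, 8 cysteines),
                   CTD1/2 + dimerisation domain.
* ``B_C_CYTO``   — cytosolic/nuclear canonical B: long G/F (median 86),
                   no zinc finger, CTD1/2 + DD.
* ``B_C_ER``     — ER-type canonical B: G/F median 36, *truncated* zinc
                   finger (30 residues, two motifs, 4 cysteines), CTD1/2 + DD.
* ``B_PRIME_ST`` — metazoan cytonuclear B': G/F median 60, no CTD, an
                   S/T-rich segment followed by a beta-sheet domain.

Structured segments (J-domain, zinc fingers, CTD block, ST and beta-domain)
come from fixed canonical templates so that sequences of different classes
are genuinely homologous and profiles built from one class retrieve the
others.  The disordered G/F filler is redrawn per record (Gly/Phe-enriched,
length from a class-specific distribution); the helix V segment sits at a
fixed offset from the G/F C-terminus so it stays alignable.

Randomness contract: one integer seed fans out to independent per-record
streams by a stable CRC32 hash of the record id, so adding a record never
perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .classify import JDPClass
from .io import AMINO_ACIDS, AlignmentBlock, ProteinRecord, TreeNode

__all__ = [
    "ArchClass",
    "ArchitectureSpec",
    "ArchitectureTruth",
    "FamilyTruth",
    "generate_architecture",
    "evolve_family",
    "simulate_gene_family",
    "reference_alignment",
    "star_tree",
    "balanced_tree",
    "clade_tree",
    "planted_column_alignment",
    "GF_MEDIANS",
]

_TEMPLATE_SEED = 77003917  # fixed: canonical segment templates are constants

J_LEN = 70
HPD_OFFSET = 31  # HPD motif position inside the J-domain
HELIX_V_LEN = 10
GF_TAIL_LEN = 4
ZNF_FULL_LEN = 60
ZNF_TRUNC_LEN = 30
CTD_LEN = 170
ST_LEN = 70
BD_LEN = 70

#: Class-specific G/F-region median lengths (residues).
GF_MEDIANS = {"A": 34, "B_C_CYTO": 86, "B_C_ER": 36, "B_PRIME_ST": 60}


class ArchClass(str, Enum):
    A = "A"
    B_C_CYTO = "B_C_CYTO"
    B_C_ER = "B_C_ER"
    B_PRIME_ST = "B_PRIME_ST"

    @property
    def expected_label(self) -> JDPClass:
        return {
            ArchClass.A: JDPClass.A,
            ArchClass.B_C_CYTO: JDPClass.B_C,
            ArchClass.B_C_ER: JDPClass.B_C,
            ArchClass.B_PRIME_ST: JDPClass.B_PRIME_ST,
        }[self]


def _rng_for(seed: int, record_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(record_id.encode())])


def _draw(rng, n, weights: dict[str, float]) -> str:
    letters = list(weights)
    p = np.array([weights[a] for a in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def _composition_exact(rng, n, enriched: dict[str, float], filler: str) -> str:
    """A segment with *guaranteed* minimum content of the enriched letters
    (counts are taken with ceil, then shuffled)."""
    out = []
    for a, frac in enriched.items():
        out.extend(a * int(np.ceil(frac * n)))
    out = out[:n]
    while len(out) < n:
        out.append(filler[rng.integers(len(filler))])
    out = np.array(out)
    rng.shuffle(out)
    return "".join(out)


_HELICAL = dict.fromkeys("AEKLQRDIM", 1.0)
_BETA = dict.fromkeys("VILFYTWAKSGE", 1.0)
_NO_CYS = AMINO_ACIDS.replace("C", "")
_DISORDER = "PSNQADERKG"


def _make_motif(rng) -> str:
    """Canonical zinc-binding repeat C-x-x-C-x-G-x-G (no stray Cys in x)."""
    x = _NO_CYS.replace("G", "")
    pick = lambda: x[rng.integers(len(x))]
    return "C" + pick() + pick() + "C" + pick() + "G" + pick() + "G"


def _make_templates() -> dict[str, str]:
    rng = np.random.default_rng(_TEMPLATE_SEED)
    j = list(_draw(rng, J_LEN, _HELICAL))
    j[HPD_OFFSET : HPD_OFFSET + 3] = "HPD"
    spacer = lambda n: _draw(rng, n, dict.fromkeys(_NO_CYS.replace("G", ""), 1.0))
    znf_full = "".join(
        _make_motif(rng) + spacer(6) for _ in range(4)
    ) + spacer(ZNF_FULL_LEN - 4 * 14)
    znf_trunc = _make_motif(rng) + spacer(6) + _make_motif(rng) + spacer(
        ZNF_TRUNC_LEN - 2 * 8 - 6
    )
    templates = {
        "J": "".join(j),
        "HV": _draw(rng, HELIX_V_LEN, _HELICAL),
        "GF_TAIL": _draw(rng, GF_TAIL_LEN, dict.fromkeys("GFSA", 1.0)),
        "ZNF_FULL": znf_full,
        "ZNF_TRUNC": znf_trunc,
        "CTD": _draw(rng, CTD_LEN, _BETA),
        "ST": _composition_exact(
            np.random.default_rng(_TEMPLATE_SEED + 1), ST_LEN,
            {"S": 0.38, "T": 0.28}, "GAPNQ"),
        "BD": _draw(rng, BD_LEN, _BETA),
    }
    assert znf_full.count("C") == 8 and len(znf_full) == ZNF_FULL_LEN
    assert znf_trunc.count("C") == 4 and len(znf_trunc) == ZNF_TRUNC_LEN
    return templates


TEMPLATES = _make_templates()


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blueprint for one synthetic class architecture."""

    class_label: ArchClass
    gf_median: int | None = None  # None -> class default
    gf_spread: float = 0.15  # +/- fractional spread of the G/F length draw
    gf_gly_frac: float = 0.28
    gf_phe_frac: float = 0.17
    znf: str | None = None  # None -> class default; override must stay legal

    def __post_init__(self) -> None:
        if self.znf is not None and self.znf != self.znf_status:
            raise ValueError(
                f"impossible spec: {self.znf} ZnF on class {self.class_label.value}"
            )

    @property
    def znf_status(self) -> str:
        return {
            ArchClass.A: "full",
            ArchClass.B_C_CYTO: "absent",
            ArchClass.B_C_ER: "truncated",
            ArchClass.B_PRIME_ST: "absent",
        }[self.class_label]

    @property
    def median(self) -> int:
        return self.gf_median if self.gf_median is not None else GF_MEDIANS[self.class_label.value]


@dataclass
class ArchitectureTruth:
    """Ground truth for one generated record (0-based half-open spans)."""

    record_id: str
    arch_class: ArchClass
    expected_label: JDPClass
    segments: dict[str, tuple[int, int]]
    gf_length: int
    znf_status: str
    helix_v_span: tuple[int, int]
    protected_spans: list[tuple[int, int]]

    def shifted(self, delta_after: int, pos: int) -> "ArchitectureTruth":
        """Spans adjusted after an indel of signed length ``delta_after``
        at residue position ``pos``."""

        def adj(span):
            a, b = span
            return (a + delta_after if a >= pos else a,
                    b + delta_after if b > pos else b)

        return replace(
            self,
            segments={k: adj(v) for k, v in self.segments.items()},
            helix_v_span=adj(self.helix_v_span),
            protected_spans=[adj(s) for s in self.protected_spans],
            gf_length=self.segments["gf_region"][1] - self.segments["gf_region"][0]
            + (delta_after if self.segments["gf_region"][0] <= pos < self.segments["gf_region"][1] else 0),
        )


@dataclass
class FamilyTruth:
    """Family-level ground truth from :func:`evolve_family` or
    :func:`simulate_gene_family`."""

    template: ProteinRecord | None = None
    tree: TreeNode | None = None
    root_residues: str | None = None
    per_record: dict[str, ArchitectureTruth] = field(default_factory=dict)
    leaf_map: dict[str, str] = field(default_factory=dict)
    event_script: list[tuple[str, int]] = field(default_factory=list)
    duplication_count: int = 0


# ---------------------------------------------------------------------------
# Architecture generation

def generate_architecture(
    spec: ArchitectureSpec, seed: int, record_id: str | None = None
) -> tuple[ProteinRecord, ArchitectureTruth]:
    """Build one synthetic sequence with its truth map.

    Deterministic in ``(spec, seed, record_id)``; diagnostic motifs (HPD,
    zinc-finger cysteine repeats) are placed exactly.
    """
    rid = record_id or f"{spec.class_label.value}_s{seed}"
    rng = _rng_for(seed, rid)

    median = spec.median
    lo = int(round(median * (1 - spec.gf_spread)))
    hi = int(round(median * (1 + spec.gf_spread)))
    gf_len = int(rng.integers(lo, hi + 1)) if hi > lo else median
    min_gf = HELIX_V_LEN + GF_TAIL_LEN + 1
    gf_len = max(gf_len, min_gf)
    filler_len = gf_len - HELIX_V_LEN - GF_TAIL_LEN
    filler = _composition_exact(
        rng, filler_len, {"G": spec.gf_gly_frac, "F": spec.gf_phe_frac}, _DISORDER
    )
    gf = filler + TEMPLATES["HV"] + TEMPLATES["GF_TAIL"]

    parts: list[tuple[str, str]] = [("j_domain", TEMPLATES["J"]), ("gf_region", gf)]
    if spec.class_label is ArchClass.A:
        parts += [("znf_block", TEMPLATES["ZNF_FULL"]), ("ctd_dd_block", TEMPLATES["CTD"])]
    elif spec.class_label is ArchClass.B_C_ER:
        parts += [("znf_block", TEMPLATES["ZNF_TRUNC"]), ("ctd_dd_block", TEMPLATES["CTD"])]
    elif spec.class_label is ArchClass.B_C_CYTO:
        parts += [("ctd_dd_block", TEMPLATES["CTD"])]
    else:  # B_PRIME_ST
        parts += [("st_bd_block", TEMPLATES["ST"] + TEMPLATES["BD"])]

    segments: dict[str, tuple[int, int]] = {}
    seq = []
    pos = 0
    for name, chunk in parts:
        segments[name] = (pos, pos + len(chunk))
        seq.append(chunk)
        pos += len(chunk)
    residues = "".join(seq)

    j0 = segments["j_domain"][0]
    protected = [(j0 + HPD_OFFSET, j0 + HPD_OFFSET + 3)]
    if "znf_block" in segments:
        z0 = segments["znf_block"][0]
        block = residues[segments["znf_block"][0] : segments["znf_block"][1]]
        protected += [(z0 + i, z0 + i + 1) for i, a in enumerate(block) if a == "C"]
    gf0 = segments["gf_region"][0]
    hv_start = gf0 + filler_len
    truth = ArchitectureTruth(
        record_id=rid,
        arch_class=spec.class_label,
        expected_label=spec.class_label.expected_label,
        segments=segments,
        gf_length=gf_len,
        znf_status=spec.znf_status,
        helix_v_span=(hv_start, hv_start + HELIX_V_LEN),
        protected_spans=protected,
    )
    return ProteinRecord(rid, residues), truth


# ---------------------------------------------------------------------------
# Sequence evolution (Poisson substitutions, optional G/F indels)

def _mutate(
    seq: str,
    expected_subs: float,
    protected: list[tuple[int, int]],
    protection: float,
    rng: np.random.Generator,
) -> str:
    """Per-site Poisson substitution events; each event jumps to one of the
    other 19 residues uniformly (the jump chain of the Poisson rate model).
    Protected sites evolve at ``expected_subs * protection``."""
    if expected_subs <= 0:
        return seq
    n = len(seq)
    rate = np.full(n, expected_subs)
    for a, b in protected:
        rate[a:b] *= protection
    events = rng.poisson(rate)
    out = list(seq)
    for i in np.flatnonzero(events):
        a = out[i]
        for _ in range(events[i]):
            j = rng.integers(19)
            alt = AMINO_ACIDS.replace(a, "") if a in AMINO_ACIDS else AMINO_ACIDS[:19]
            a = alt[j]
        out[i] = a
    return "".join(out)


def evolve_family(
    template: ProteinRecord,
    truth: ArchitectureTruth,
    tree: TreeNode,
    rate: float = 1.0,
    motif_protection: float = 0.05,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ProteinRecord], FamilyTruth]:
    """Evolve a template down a tree.

    Expected substitutions per site on an edge are ``rate x branch_length``.
    Indels (geometric length, mean 2) are confined to the disordered G/F
    filler; diagnostic motifs are protected by ``motif_protection``.
    Leaf ids are ``<template.id>|<leaf label>``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    fam = FamilyTruth(template=template, tree=tree, root_residues=template.residues)
    records: list[ProteinRecord] = []

    def descend(node: TreeNode, seq: str, tr: ArchitectureTruth) -> None:
        for child in node.children:
            bl = child.branch_length if child.branch_length is not None else 1.0
            rng = _rng_for(seed, f"{template.id}|{child.label or id(child)}")
            s = _mutate(seq, rate * bl, tr.protected_spans, motif_protection, rng)
            t = tr
            if indel_rate > 0:
                s, t = _apply_indels(s, t, indel_rate * bl, rng)
            if child.is_leaf:
                rid = f"{template.id}|{child.label}"
                records.append(ProteinRecord(rid, s))
                fam.per_record[rid] = replace(t, record_id=rid)
            else:
                descend(child, s, t)

    descend(tree, template.residues, truth)
    return records, fam


def _apply_indels(seq, truth, rate, rng):
    gf0, gf1 = truth.segments["gf_region"]
    hv0 = truth.helix_v_span[0]
    lo, hi = gf0, hv0  # indels only in the disordered filler
    if hi <= lo:
        return seq, truth
    n_events = rng.poisson(rate * (hi - lo))
    for _ in range(n_events):
        pos = int(rng.integers(lo, hi))
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:  # insertion
            ins = _draw(rng, length, dict.fromkeys(_DISORDER, 1.0))
            seq = seq[:pos] + ins + seq[pos:]
            truth = truth.shifted(length, pos)
            hi += length
        else:  # deletion, clipped to the filler
            length = min(length, hi - pos)
            seq = seq[:pos] + seq[pos + length :]
            truth = truth.shifted(-length, pos + length)
            hi -= length
    return seq, truth


# ---------------------------------------------------------------------------
# Convenience trees and reference alignments

def star_tree(n: int, branch_length: float = 1.0) -> TreeNode:
    return TreeNode(children=[
        TreeNode(label=f"r{i}", branch_length=branch_length) for i in range(n)
    ])


def clade_tree(n_clades: int = 4, leaves_per_clade: int = 4, branch_length: float = 0.2) -> TreeNode:
    """A two-level radiation: ``n_clades`` clades of ``leaves_per_clade``
    leaves, every edge ``branch_length`` long.  The default 4x4 shape is the
    family tree used for ancestral-reconstruction recovery checks."""
    clades = []
    k = 0
    for _ in range(n_clades):
        kids = [
            TreeNode(label=f"t{k + j}", branch_length=branch_length)
            for j in range(leaves_per_clade)
        ]
        k += leaves_per_clade
        clades.append(TreeNode(branch_length=branch_length, children=kids))
    return TreeNode(children=clades)


def planted_column_alignment(
    n_conserved: int = 20,
    n_planted: int = 10,
    n_rows: int = 12,
    seed: int = 0,
    sub_rate: float = 0.1,
    planted_occupancy: float = 0.3,
) -> tuple[AlignmentBlock, list[int], list[int]]:
    """A conserved-core alignment with planted unalignable insert columns.

    ``n_conserved`` well-conserved columns (per-cell substitution probability
    ``sub_rate``) are interleaved with ``n_planted`` noise columns, grouped
    into a few multi-column slots, where an exact ``planted_occupancy``
    fraction of rows carries an i.i.d. random residue and the rest are
    gapped.  Returns the alignment and the conserved / planted column
    indices — ground truth for confidence-filter checks.
    """
    rng = np.random.default_rng([seed, 0xA11])
    template = _draw(rng, n_conserved, dict.fromkeys(AMINO_ACIDS, 1.0))
    n_occ = max(1, int(round(planted_occupancy * n_rows)))
    # spread planted columns over three slots inside the conserved core
    slot_starts = [n_conserved // 4, n_conserved // 2, (3 * n_conserved) // 4]
    widths = [n_planted // 3 + (1 if i < n_planted % 3 else 0) for i in range(3)]
    inserts_after = dict(zip(slot_starts, widths))
    out: list[list[str]] = [[] for _ in range(n_rows)]
    conserved_cols: list[int] = []
    planted_cols: list[int] = []
    col = 0
    for c in range(n_conserved):
        for _ in range(inserts_after.get(c, 0)):
            carriers = rng.choice(n_rows, size=n_occ, replace=False)
            for r in range(n_rows):
                out[r].append(
                    AMINO_ACIDS[rng.integers(20)] if r in carriers else "-"
                )
            planted_cols.append(col)
            col += 1
        for r in range(n_rows):
            a = template[c]
            if rng.random() < sub_rate:
                a = AMINO_ACIDS[rng.integers(20)]
            out[r].append(a)
        conserved_cols.append(col)
        col += 1
    aln = AlignmentBlock([f"s{i}" for i in range(n_rows)], ["".join(r) for r in out])
    return aln, conserved_cols, planted_cols


def balanced_tree(depth: int, branch_length: float = 1.0) -> TreeNode:
    counter = [0]

    def build(d: int) -> TreeNode:
        if d == 0:
            counter[0] += 1
            return TreeNode(label=f"t{counter[0] - 1}", branch_length=branch_length)
        return TreeNode(branch_length=branch_length, children=[build(d - 1), build(d - 1)])

    root = build(depth)
    root.branch_length = None
    return root


def reference_alignment(
    spec: ArchitectureSpec,
    n: int,
    seed: int = 0,
    rate: float = 0.05,
    motif_protection: float = 0.05,
) -> tuple[AlignmentBlock, ArchitectureTruth]:
    """An ungapped seed alignment of ``n`` same-length family members.

    The G/F length is pinned to the class median (spread 0) so rows align
    column-to-column; row-to-row variation comes from substitutions only.
    Because the alignment is ungapped, alignment columns coincide with
    template residue positions, which makes the returned truth's segment
    spans directly usable as profile block coordinates.
    """
    pinned = replace(spec, gf_spread=0.0)
    template, truth = generate_architecture(pinned, seed, f"{spec.class_label.value}_ref")
    records, _ = evolve_family(
        template, truth, star_tree(n), rate=rate,
        motif_protection=motif_protection, seed=seed,
    )
    return AlignmentBlock([r.id for r in records], [r.residues for r in records]), truth


# ---------------------------------------------------------------------------
# Gene-family simulation with scripted duplications

def simulate_gene_family(
    species_tree: TreeNode,
    event_script: list[tuple[str, int]],
    seed: int = 0,
    loss_prob: float = 0.0,
) -> tuple[TreeNode, dict[str, str], FamilyTruth]:
    """Grow a gene tree along a species tree with scripted duplications.

    Each script entry ``(node_label, count)`` places ``count`` sequential
    duplications on the species-tree edge *above* the node with that label
    (the root label addresses the root stem).  Returns the gene tree, the
    gene-leaf -> species map, and the truth (surviving duplication count).
    """
    labels = {n.label for n in species_tree.postorder() if n.label}
    script: dict[str, int] = {}
    for edge, count in event_script:
        if edge not in labels:
            raise ValueError(f"duplication scripted on nonexistent edge {edge!r}")
        script[edge] = script.get(edge, 0) + count
    rng = np.random.default_rng([seed, 0xD0])
    leaf_map: dict[str, str] = {}
    dup_nodes: list[TreeNode] = []
    counter = [0]

    def visit(sp: TreeNode, slots: list[TreeNode]) -> None:
        # scripted duplications on the edge above sp: each event copies one
        # of the lineages currently on this edge
        for _ in range(script.get(sp.label or "", 0)):
            tgt = slots[int(rng.integers(len(slots)))]
            a, b = TreeNode(), TreeNode()
            tgt.children = [a, b]
            dup_nodes.append(tgt)
            slots.remove(tgt)
            slots.extend([a, b])
        if sp.is_leaf:
            for slot in slots:
                counter[0] += 1
                slot.label = f"{sp.label}|g{counter[0]}"
                leaf_map[slot.label] = sp.label
            return
        per_child: dict[int, list[TreeNode]] = {id(ch): [] for ch in sp.children}
        for slot in slots:
            kids = []
            for child in sp.children:
                if loss_prob > 0 and rng.random() < loss_prob:
                    continue
                sub = TreeNode()
                kids.append(sub)
                per_child[id(child)].append(sub)
            slot.children = kids
        for child in sp.children:
            if per_child[id(child)]:
                visit(child, per_child[id(child)])

    root = TreeNode()
    visit(species_tree, [root])

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return node if node.label else None
        kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = kept
        return node

    gene_tree = prune(root)
    if gene_tree is None:
        raise ValueError("all gene lineages were lost")
    surviving = sum(
        1 for d in dup_nodes
        if not d.is_leaf and len(d.children) >= 2 and _has_descendant(gene_tree, d)
    )
    truth = FamilyTruth(
        tree=species_tree,
        leaf_map=leaf_map,
        event_script=list(event_script),
        duplication_count=surviving,
    )
    return gene_tree, leaf_map, truth


def _has_descendant(tree: TreeNode, target: TreeNode) -> bool:
    return any(n is target for n in tree.postorder())
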