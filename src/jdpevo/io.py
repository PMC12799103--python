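"""Readers, writers and core containers for the formats the pipeline touches.

Sequence data travel as :class:`ProteinRecord`, alignments as
:class:`AlignmentBlock` (optionally carrying per-residue posterior-probability
codes from Stockholm ``#=GR <seq> PP`` lines), and trees as :class:`TreeNode`.
Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive only in human-readable report tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import yaml
from Bio import AlignIO, SeqIO

__all__ = [
    "AMINO_ACIDS",
    "Compartment",
    "ProteinRecord",
    "AlignmentBlock",
    "TreeNode",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "write_newick",
    "read_ss_annotation",
    "decode_pp_code",
    "encode_pp_value",
    "load_config",
    "setup_logging",
    "DEFAULTS",
]

log = logging.getLogger("jdpevo")

#: The 20 canonical residues, in the fixed index order used by every matrix
#: in the package.  'X' is accepted in sequences and scored at background.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_VALID = set(AMINO_ACIDS) | {"X"}
GAP = "-"

#: Package-wide defaults, overridable from a YAML config file.
DEFAULTS: dict = {
    "match_occupancy_threshold": 0.5,
    "pseudocount_weight": None,  # None -> 0.1 x effective sequence count
    "weighting": "henikoff",
    "bit_threshold": 15.0,
    "pp_threshold": 0.5,
    "znf_strict_g": False,
    "helix_v_min_run": 4,
    "helix_v_min_overlap": 0.5,
    "min_coverage": 0.7,
    "identity_sd_cut": 2.0,
    "support_cutoff": 50.0,
    "ancestral_gap_majority": 0.5,
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the package defaults."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a mapping")
        unknown = set(user) - set(cfg)
        if unknown:
            log.warning("unknown config keys ignored: %s", sorted(unknown))
        cfg.update({k: v for k, v in user.items() if k in cfg})
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    log.setLevel(getattr(logging, level.upper()))


class Compartment(str, Enum):
    """Subcellular (or domain-of-life) origin of a sequence."""

    MITOCHONDRIA = "mitochondria"
    PLASTID = "plastid"
    ER = "ER"
    CYTOSOL_NUCLEUS = "cytosol_nucleus"
    BACTERIAL = "bacterial"
    ARCHAEAL = "archaeal"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``residues`` is uppercase over the 20 canonical letters plus ``X``;
    gap characters are illegal here (gapped rows live in
    :class:`AlignmentBlock`).
    """

    id: str
    residues: str
    taxon: str | None = None
    compartment: Compartment | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch == GAP:
                raise ValueError(
                    f"record {self.id}: gap character at position {pos + 1}"
                )
            if ch not in _VALID:
                raise ValueError(
                    f"record {self.id}: illegal character {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentBlock:
    """A rectangular multiple alignment with optional posterior codes.

    ``pp`` rows, when present, use the Stockholm convention: digits ``0``-``9``
    and ``*`` on residues, ``.`` on gaps.
    """

    rows: list[str]
    matrix: list[str]
    pp: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.matrix:
            raise ValueError("empty alignment")
        if len(self.rows) != len(self.matrix):
            raise ValueError("rows and matrix length mismatch")
        if len(set(self.rows)) != len(self.rows):
            dup = sorted({r for r in self.rows if self.rows.count(r) > 1})
            raise ValueError(f"duplicate id {dup[0]}")
        n = len(self.matrix[0])
        for rid, row in zip(self.rows, self.matrix):
            if len(row) != n:
                raise ValueError("ragged alignment")
        if self.pp is not None:
            if len(self.pp) != len(self.matrix):
                raise ValueError("pp row count mismatch")
            for rid, row in zip(self.rows, self.pp):
                if len(row) != n:
                    raise ValueError(f"pp line length mismatch for {rid}")

    @property
    def column_count(self) -> int:
        return len(self.matrix[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, row: int | str) -> ProteinRecord:
        """The ungapped sequence of one row, as a :class:`ProteinRecord`."""
        i = self.rows.index(row) if isinstance(row, str) else row
        return ProteinRecord(self.rows[i], self.matrix[i].replace(GAP, "").replace(".", ""))

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.matrix)


@dataclass
class TreeNode:
    """A rooted tree node; leaves carry labels, internal edges may carry
    bootstrap support on the 0-100 scale."""

    label: str | None = None
    support: float | None = None
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["TreeNode"]:
        for ch in self.children:
            yield from ch.postorder()
        yield self

    def preorder(self) -> Iterable["TreeNode"]:
        yield self
        for ch in self.children:
            yield from ch.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> "TreeNode":
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(f"node {label!r} not found")

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.label,
            self.support,
            self.branch_length,
            [c.copy() for c in self.children],
        )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; uppercase, strip one terminal ``*`` stop.

    Raises on empty files, duplicate ids, gap or other illegal characters.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments (aligned FASTA / Stockholm with PP lines)

def decode_pp_code(code: str) -> float:
    """Stockholm posterior code -> numeric midpoint: ``*`` is 0.975,
    digit *d* the midpoint of its 0.1-wide bin, ``(d*0.1)+0.05``."""
    if code == "*":
        return 0.975
    if code.isdigit():
        return int(code) * 0.1 + 0.05
    raise ValueError(f"bad posterior code {code!r}")


def encode_pp_value(value: float) -> str:
    """Inverse of :func:`decode_pp_code` on bin midpoints."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"posterior {value} outside [0,1]")
    if value >= 0.9625:  # midpoint between the '9' and '*' code values
        return "*"
    return str(min(9, max(0, int(round((value - 0.05) / 0.1)))))


def read_alignment(path: str | Path, format: str = "afa") -> AlignmentBlock:
    """Read an aligned FASTA (``afa``) or Stockholm (``stockholm``) file.

    Stockholm ``#=GR <seq> PP`` annotation lines, if present, are kept as raw
    code strings on the block's ``pp`` attribute.
    """
    if format == "afa":
        aln = AlignIO.read(str(path), "fasta")
        pp = None
    elif format == "stockholm":
        aln = AlignIO.read(str(path), "stockholm")
        pp_rows: dict[str, str] = {}
        for rec in aln:
            ann = rec.letter_annotations.get("posterior_probability")
            if ann is not None:
                pp_rows[rec.id] = ann
        pp = [pp_rows.get(rec.id) for rec in aln] if pp_rows else None
        if pp is not None and any(p is None for p in pp):
            raise ValueError("PP lines present for only a subset of sequences")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    rows = [rec.id for rec in aln]
    matrix = [str(rec.seq).upper().replace(".", GAP) for rec in aln]
    lengths = {len(m) for m in matrix}
    if len(lengths) > 1:
        raise ValueError("ragged alignment")
    return AlignmentBlock(rows, matrix, pp)


def write_alignment(block: AlignmentBlock, path: str | Path, format: str = "afa") -> None:
    if format == "afa":
        with open(path, "w") as fh:
            for rid, row in zip(block.rows, block.matrix):
                fh.write(f">{rid}\n{row}\n")
    elif format == "stockholm":
        width = max(len(f"#=GR {r} PP") for r in block.rows) + 2
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for i, (rid, row) in enumerate(zip(block.rows, block.matrix)):
                fh.write(f"{rid:<{width}}{row}\n")
                if block.pp is not None:
                    tag = f"#=GR {rid} PP"
                    fh.write(f"{tag:<{width}}{block.pp[i]}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# Newick

def _from_dendropy(nd: "dendropy.Node") -> TreeNode:
    children = [_from_dendropy(c) for c in nd.child_nodes()]
    label = nd.taxon.label if nd.taxon is not None else nd.label
    support = None
    if children and label is not None:
        # internal integer labels in [0,100] are bootstrap supports
        try:
            val = float(label)
        except ValueError:
            val = None
        if val is not None and val == int(val) and 0 <= val <= 100:
            support, label = val, None
    bl = nd.edge.length
    if bl is not None and bl < 0:
        raise ValueError(f"negative branch length {bl}")
    return TreeNode(label, support, bl, children)


def parse_newick(text: str) -> TreeNode:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"unbalanced parentheses or malformed Newick: {exc}") from exc
    return _from_dendropy(tree.seed_node)


def read_newick(path: str | Path) -> TreeNode:
    """Read a single rooted Newick tree.  Integer internal-node labels in
    [0,100] become bootstrap supports; other labels are kept as names."""
    return parse_newick(Path(path).read_text())


def format_newick(node: TreeNode) -> str:
    def fmt(n: TreeNode) -> str:
        if n.is_leaf:
            out = n.label or ""
        else:
            inner = ",".join(fmt(c) for c in n.children)
            lab = ""
            if n.support is not None:
                lab = f"{n.support:g}"
            elif n.label:
                lab = n.label
            out = f"({inner}){lab}"
        if n.branch_length is not None:
            out += f":{n.branch_length:.10g}"
        return out

    return fmt(node) + ";"


def write_newick(node: TreeNode, path: str | Path) -> None:
    Path(path).write_text(format_newick(node) + "\n")


# ---------------------------------------------------------------------------
# Secondary-structure annotations

#: DSSP 8-state -> 3-state collapse: helices to H, strands to E, rest coil.
_SS_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def collapse_ss8(code: str) -> str:
    return _SS_COLLAPSE.get(code, "C")


def _read_dssp_table(path: str | Path) -> str:
    """Extract the per-residue 8-state codes from a DSSP-format output file.

    Standard fixed columns of the data section (after the ``#  RESIDUE``
    header line): amino acid at index 13, structure code at index 16.
    """
    ss8 = []
    started = False
    for line in open(path):
        if not started:
            if line.lstrip().startswith("#") and "RESIDUE" in line:
                started = True
            continue
        if len(line) < 14 or line[13] == "!":  # chain break marker
            continue
        code = line[16] if len(line) > 16 else " "
        ss8.append(code if code != " " else "C")
    if not started:
        raise ValueError(f"{path}: no DSSP residue table found")
    return "".join(ss8)


def read_ss_annotation(
    path: str | Path,
    format: str = "plain",
    record: ProteinRecord | None = None,
) -> str:
    """Per-residue H/E/C secondary-structure string.

    ``plain`` files hold one H/E/C character per residue (whitespace ignored);
    ``dssp`` files are standard DSSP output whose 8-state codes are collapsed
    (H,G,I -> H; E,B -> E; else C).  If ``record`` is given, the annotation
    length must match the record length.
    """
    if format == "plain":
        ss = "".join(Path(path).read_text().split())
        bad = set(ss) - set("HEC")
        if bad:
            raise ValueError(f"unknown secondary-structure code {sorted(bad)[0]!r}")
    elif format == "dssp":
        ss = "".join(collapse_ss8(c) for c in _read_dssp_table(path))
    else:
        raise ValueError(f"unknown ss format {format!r}")
    if record is not None and len(ss) != len(record):
        raise ValueError(
            f"annotation length {len(ss)} does not match record "
            f"{record.id} length {len(record)}"
        )
    return ss
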