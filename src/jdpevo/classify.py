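"""Class assignment, curation flags, and dataset-level summaries.

The class rules condense to a total function of four inputs: retrieval by
the J-domain/G-F profile, retrieval by the CTD-DD profile, retrieval by the
S/T-region profile, and the zinc-finger call.  Sequences retrieved by both
the JD-GF and CTD-DD profiles are class A when they carry a full-length
zinc finger and canonical B (B^C) otherwise; sequences retrieved only by
JD-GF are B', refined to B'(ST) when the S/T profile also fires; sequences
the JD-GF profile misses are not J-domain proteins at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .features import DomainAnnotation, ReferenceBlockMap, ZnFCall, annotate_architecture

__all__ = [
    "JDPClass",
    "ClassLabel",
    "CurationFlags",
    "DatasetSummary",
    "classify_sequence",
    "classify_records",
    "curate_dataset",
    "summarize_classes",
]


class JDPClass(str, Enum):
    A = "A"
    B_C = "B_C"
    B_PRIME = "B_prime"
    B_PRIME_ST = "B_prime_ST"
    NOT_JDP = "not_jdp"


@dataclass(frozen=True)
class ClassLabel:
    value: JDPClass
    rationale: str


def classify_sequence(
    hit_jdgf: bool, hit_ctd: bool, hit_st: bool, znf: ZnFCall | str
) -> ClassLabel:
    """Deterministic, total class assignment.

    ``znf`` may be a :class:`~jdpevo.features.ZnFCall` or its status string.
    Only a *full* zinc finger qualifies for class A; truncated fingers go to
    B^C (the strict class A definition).
    """
    status = znf.status if isinstance(znf, ZnFCall) else znf
    if not hit_jdgf:
        return ClassLabel(JDPClass.NOT_JDP, "no JD-GF profile hit")
    if hit_ctd:
        if status == "full":
            return ClassLabel(JDPClass.A, "JD-GF + CTD-DD hits with full ZnF")
        return ClassLabel(
            JDPClass.B_C, f"JD-GF + CTD-DD hits without full ZnF (znf={status})"
        )
    if hit_st:
        return ClassLabel(JDPClass.B_PRIME_ST, "JD-GF + ST profile hits, no CTD-DD")
    return ClassLabel(JDPClass.B_PRIME, "JD-GF hit only")


@dataclass
class CurationFlags:
    record_id: str
    incomplete: bool
    fast_evolving: bool
    profile_coverage: float
    consensus_identity: float
    warning: str | None = None


def curate_dataset(
    coverages: dict[str, float],
    identities: dict[str, float],
    min_coverage: float = 0.7,
    identity_sd_cut: float = 2.0,
) -> list[CurationFlags]:
    """Flag incomplete and unusually fast-evolving sequences.

    ``coverages``: fraction of profile match states covered by each record's
    Viterbi path; ``identities``: identity to the profile consensus over
    matched positions.  A record is incomplete below ``min_coverage`` and
    fast-evolving when its identity falls more than ``identity_sd_cut``
    standard deviations below the dataset mean.  Flags are reported;
    removal is the caller's choice.
    """
    ids = sorted(coverages)
    vals = np.array([identities[r] for r in ids])
    warning = None
    if len(ids) < 3:
        warning = "fewer than 3 sequences: fast-evolving test skipped"
        lo = -np.inf
    else:
        lo = vals.mean() - identity_sd_cut * vals.std(ddof=0)
    return [
        CurationFlags(
            record_id=r,
            incomplete=coverages[r] < min_coverage,
            fast_evolving=bool(identities[r] < lo),
            profile_coverage=coverages[r],
            consensus_identity=identities[r],
            warning=warning,
        )
        for r in ids
    ]


def coverage_and_identity(hit, model, record) -> tuple[float, float]:
    """Viterbi match-state coverage of the profile and identity of the
    record's matched residues to the profile consensus."""
    assigned = hit.match_assignment
    matched = np.flatnonzero(assigned >= 0)
    coverage = matched.size / model.length
    if matched.size == 0:
        return 0.0, 0.0
    consensus = model.consensus
    same = sum(1 for i in matched if record.residues[i] == consensus[assigned[i]])
    return coverage, same / matched.size


def classify_records(
    records,
    jdgf_model,
    ctd_model,
    st_model,
    master_model,
    blocks: ReferenceBlockMap,
    bit_threshold: float = 15.0,
    ss: dict[str, str] | None = None,
    strict_g: bool = False,
) -> tuple[list[DomainAnnotation], list[ClassLabel]]:
    """End-to-end per-record pipeline: profile retrieval, feature mapping on
    the master profile, and class assignment.  Records missed by the JD-GF
    profile are labelled ``not_jdp`` with an empty annotation."""
    from . import hmm  # deferred: keeps import graph simple for light users

    annotations: list[DomainAnnotation] = []
    labels: list[ClassLabel] = []
    for rec in records:
        hit_jdgf = hmm.forward_score(jdgf_model, rec) >= bit_threshold
        hit_ctd = hmm.forward_score(ctd_model, rec) >= bit_threshold
        hit_st = hmm.forward_score(st_model, rec) >= bit_threshold
        master_hit = hmm.viterbi_align(master_model, rec)
        ann = annotate_architecture(
            rec,
            master_hit,
            blocks,
            has_ctd_dd=hit_ctd,
            has_st_bd=hit_st,
            ss=None if ss is None else ss.get(rec.id),
            strict_g=strict_g,
        )
        annotations.append(ann)
        labels.append(classify_sequence(hit_jdgf, hit_ctd, hit_st, ann.znf))
    return annotations, labels


@dataclass
class ClassSummaryRow:
    label: JDPClass
    n: int
    gf_median: float | None
    gf_q1: float | None
    gf_q3: float | None
    znf_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class DatasetSummary:
    rows: dict[JDPClass, ClassSummaryRow]
    total: int

    def row(self, label: JDPClass) -> ClassSummaryRow:
        return self.rows[label]


def summarize_classes(
    annotations: list[DomainAnnotation], labels: list[ClassLabel]
) -> DatasetSummary:
    """Per-class counts, G/F-length quartiles (linear interpolation), and
    zinc-finger status contingency table."""
    if len(annotations) != len(labels):
        raise ValueError("annotations and labels must be parallel lists")
    rows: dict[JDPClass, ClassSummaryRow] = {}
    for cls in JDPClass:
        anns = [a for a, l in zip(annotations, labels) if l.value is cls]
        if anns:
            gf = np.array([a.gf_length for a in anns], dtype=float)
            q1, med, q3 = np.percentile(gf, [25, 50, 75])  # type-7 linear
            row = ClassSummaryRow(cls, len(anns), float(med), float(q1), float(q3))
        else:
            row = ClassSummaryRow(cls, 0, None, None, None)
        for a in anns:
            row.znf_counts[a.znf.status] = row.znf_counts.get(a.znf.status, 0) + 1
        rows[cls] = row
    return DatasetSummary(rows=rows, total=len(annotations))
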