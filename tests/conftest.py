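import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import jdpevo as J
from jdpevo.simulate import ArchClass, ArchitectureSpec


def subalignment(aln, truth, segment_names):
    """Columns of an ungapped reference alignment restricted to segments."""
    cols = []
    for name in segment_names:
        if name in truth.segments:
            a, b = truth.segments[name]
            cols.extend(range(a, b))
    mat = ["".join(row[c] for c in cols) for row in aln.matrix]
    return J.AlignmentBlock(list(aln.rows), mat)


@pytest.fixture(scope="session")
def reference_suite():
    """The four profiles plus master block map built from synthetic seeds,
    shared across classifier/feature tests."""
    specA = ArchitectureSpec(ArchClass.A)
    refA, truthA = J.reference_alignment(specA, n=8, seed=1)
    master = J.build_profile(refA, name="master")
    blocks = J.ReferenceBlockMap(
        profile_length=master.length,
        j_domain=truthA.segments["j_domain"],
        gf_region=truthA.segments["gf_region"],
        znf_block=truthA.segments["znf_block"],
        ctd_dd_block=truthA.segments["ctd_dd_block"],
        helix_v_columns=frozenset(range(*truthA.helix_v_span)),
    )
    jdgf = J.build_profile(
        subalignment(refA, truthA, ["j_domain", "gf_region"]), name="JD-GF"
    )
    ctd = J.build_profile(subalignment(refA, truthA, ["ctd_dd_block"]), name="CTD-DD")
    refST, truthST = J.reference_alignment(
        ArchitectureSpec(ArchClass.B_PRIME_ST), n=8, seed=2
    )
    st = J.build_profile(subalignment(refST, truthST, ["st_bd_block"]), name="ST")
    return {
        "master": master,
        "blocks": blocks,
        "jdgf": jdgf,
        "ctd": ctd,
        "st": st,
        "truthA": truthA,
    }


@pytest.fixture(scope="session")
def synthetic_200():
    """200 synthetic sequences, 50 per class, 0.3 expected substitutions per
    site from their templates (fixed seeds)."""
    records, truths = [], []
    for cls in ArchClass:
        spec = ArchitectureSpec(cls)
        for i in range(50):
            template, tr = J.generate_architecture(
                spec, seed=1000 + i, record_id=f"{cls.value}_{i}"
            )
            evolved, _ = J.evolve_family(
                template, tr, J.simulate.star_tree(1, 1.0), rate=0.3, seed=i
            )
            records.append(evolved[0])
            truths.append(tr)
    return records, truths


@pytest.fixture
def toy_profile():
    """A 3-state profile from three identical HPD rows (the J-domain motif)."""
    block = J.AlignmentBlock(["a", "b", "c"], ["HPD", "HPD", "HPD"])
    return J.build_profile(
        block, pseudocount_weight=0.1, weighting="none", flank_expected_len=None
    )


def random_small_model(rng, max_cols=5, max_rows=4):
    """A random tiny profile for oracle comparisons (may raise ValueError
    if the random seed alignment has no match columns)."""
    from jdpevo.io import AMINO_ACIDS

    nrow = int(rng.integers(2, max_rows + 1))
    ncol = int(rng.integers(2, max_cols + 1))
    mat = ["".join(rng.choice(list(AMINO_ACIDS + "-"), size=ncol)) for _ in range(nrow)]
    block = J.AlignmentBlock([f"s{i}" for i in range(nrow)], mat)
    return J.build_profile(
        block, pseudocount_weight=0.3, weighting="none", flank_expected_len=None
    )
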