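# Methods

This note records the models implemented in `jdpevo`, the conventions and
defaults that matter for interpreting its output, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the problem left the design open.  Every number quoted here is computed by
the test suite or by `scripts/acceptance.py`.

## Profile HMMs

`jdpevo.hmm` implements a match/insert/delete profile HMM over the
20-letter amino-acid alphabet with all nine transition types
parameterised per position.  Alignment is **global over the model with
free flanking inserts**: the insert states before the first and after the
last match state act as N/C loops.  Because seed alignments span only the
modelled domain, those two self-loops cannot be estimated from seed
counts; they are set from `flank_expected_len` (default 200 residues,
geometric), which makes a whole-domain profile usable on full-length
sequences at negligible flank cost.  Local (Smith–Waterman-style)
alignment is deliberately out of scope, with one practical consequence
noted under *Limitations*.

Estimation from a seed alignment:

* columns with non-gap fraction ≥ `match_occupancy_threshold` (default
  0.5) become match states;
* emissions are (position-weighted counts + *w*·background) normalised,
  with a single background-mixture pseudocount *w* defaulting to 0.1 ×
  the number of seed sequences — not Dirichlet mixtures, which would be
  overkill at this scale;
* transitions come from the seed rows' implied state paths with Laplace
  one-count smoothing;
* sequence weighting is position-based (Henikoff) by default, `none` for
  unit-testing determinism;
* the background is the seed's overall residue frequency (half-count
  smoothed so unseen letters stay possible).

Forward, backward, Viterbi and posterior decoding run in log space
(underflow is impossible by construction) with the recurrences
JIT-compiled by numba.  Scores are bits: log₂ of the model likelihood
over an i.i.d. background null.  `X` is emitted with probability one by
every state and by the null, contributing zero bits.  Viterbi ties are
broken M over D over I.  The whole DP core is validated against an
exhaustive path-enumeration oracle (all models with L ≤ 4, sequences of
length ≤ 5, agreement to 1e-10) and by forward/backward total-likelihood
identity on random model–sequence pairs.

Retrieval uses a forward bit-score threshold, default 15 bits per
profile.  This is an explicit, configurable operating point — the
package reports it in every search header — chosen so that clearly
homologous synthetic queries score hundreds of bits while unrelated
segments score strongly negative; it is not calibrated to E-values
(calibration against random-sequence ensembles is a non-goal).

## Feature detection

Features are measured on the query after aligning it to a full-length
master profile and transferring named column blocks (J-domain, G/F, ZnF,
CTD1/2+DD, helix V columns) onto query residues.  Block coordinates are
data (a `ReferenceBlockMap` tied to one profile), not constants.

**Block transfer.**  The generic rule maps each block to the minimal
residue span covering all residues Viterbi-assigned to match states in
the block's columns.  Disordered regions need anchored variants: the G/F
region is measured from the end of the mapped J-domain to the end of the
G/F block's own matched span (the conserved helix V block pins that
end), and the ZnF block — when both G/F and CTD anchors mapped — is
the residue stretch between them.  Without anchoring, the ambiguous
alignment of disordered G/F residues (or of a truncated finger against a
full-length master) systematically under-counts.

**Zinc finger.**  "Eight cysteines positioned to coordinate two zinc
ions" is operationalised as four copies of the canonical DnaJ repeat
C-x-x-C-x-G-x-G.  By default only the C spacing is enforced (`strict_g`
restores the glycines); repeats are found as a *maximum non-overlapping
tiling* by dynamic programming, which is robust to stray cysteines that
defeat greedy scanning.  Status: `full` = ≥4 repeats and ≥8 Cys;
`truncated` = exactly 2 repeats and exactly 4 Cys; `absent` = no repeats
and fewer than 8 Cys; anything else is `ambiguous` (displayed as "?"),
never silently coerced.  Strict 8-cysteine completeness is required for
`full`; whether natural families tolerate substitutions within the block
is a judgement call this package surfaces as `ambiguous` instead of
making.

**G/F length** is a residue count (not columns) over the anchored span.

**Helix V** requires both criteria jointly: a maximal helix run of ≥
`min_run` (default 4, one helical turn) consecutive H inside the G/F
span, covering ≥ `min_overlap` (default 0.5, a majority reading of
"corresponds to") of the mapped helix V reference positions.  Missing
secondary structure yields `present=None`, never a silent negative.
DSSP 8-state codes collapse H,G,I→H; E,B→E; else C.  The package ingests
DSSP output; it does not recompute secondary structure.

## Classification and curation

The class rules are a total function of four inputs (JD-GF hit, CTD-DD
hit, ST hit, ZnF status), tested exhaustively over all 32 combinations.
"Has a ZnF" for class A means *full*; truncated-finger ER sequences are
B^C under the strict class A definition.  Curation *flags* rather than
removes: `incomplete` = Viterbi coverage of profile match states below
`min_coverage` (default 0.7); `fast_evolving` = consensus identity more
than `identity_sd_cut` (default 2.0) standard deviations below the
dataset mean — an explicit identity-outlier stand-in for a judgement the
original workflow made manually.  Datasets of fewer than three sequences
skip the outlier test with a warning.  Summaries use type-7 (linear
interpolation) quantiles so expected values are exactly computable.

## Alignment confidence filtering

Every alignment cell gets a forward–backward posterior against the
profile the alignment maps to.  A residue in a match column carries
p(residue emitted by that column's match state); a gap cell carries the
column's delete-state posterior.  A residue in a *non-match* column
carries its total insert-state posterior divided by the width of the
insert slot: columns inside an unalignable region are mutually
non-identifiable, so per-column confidence is diluted across the slot.
Columns are dropped unless the mean over residue cells strictly exceeds
the threshold (default 0.5); gap cells are excluded from the mean by
default (`include_gap_cells` restores the alternative reading), and
whole columns are dropped rather than cells masked because tree builders
need rectangular input.  On the planted-column fixture (20 conserved
columns, 10 planted inserts at one-third occupancy, seed 0) the strict
0.5 filter keeps all conserved and removes all planted columns; the
retained-column count is monotone in the threshold by construction of
the test.

## Gene-tree reconciliation

`collapse_low_support` contracts internal edges with bootstrap support
strictly below the cutoff (default 50 on the 0–100 scale), promoting
children and dropping the contracted branch length with a log note.
`reconcile_lca` is classic LCA mapping: each gene node maps to the LCA
of its children's images; a node is a duplication iff it maps to the
same species node as one of its children; losses follow the standard
depth-difference count.  Gene trees must be binary; polytomies (e.g.
produced by support collapse) either raise or, on request, are resolved
to the duplication-minimising local arrangement (exhaustive over rooted
shapes, refused above degree 6 — silent arbitrary resolution would
corrupt counts).  Rooting is taken as given; no outgroup logic.  Losses
are reported but nothing downstream depends on them.  The implementation
is cross-checked against a naive leaf-set-LCA oracle on random instances
and against scripted simulations: `simulate_gene_family` grows a gene
tree from an event script of (species-edge, duplication-count) pairs,
and reconciliation recovers the scripted count exactly in 100/100 random
scripts — LCA reconciliation is exact for duplication–loss histories
without transfer.

The module ships the three duplication histories of the human
cytonuclear JDP repertoire encoded as (gene tree, species tree, leaf
map) triples over a five-taxon vertebrate backbone (teleost, amphibian,
reptile, human, mouse) or a three-taxon eukaryote backbone: the five
B′^(ST) paralogs (DNAJB2 basal; B6 from B2 at the vertebrate stem; B8
from B6 in the amniote ancestor; B7 from B6 and B3 from B8 in the
mammalian ancestor — four duplications), the four canonical-B paralogs
(three duplications), and the two ancestral class A duplications on the
eukaryote stem that produced the ER lineage and the sister cytosolic
A/B^C pair.  Reconciliation of these topologies yields 4, 3 and 2
duplications with the stated stem placements.  The canonical-B history
is encoded with human+mouse sampling only, which is sufficient to pin
the count (3) though not the deeper branch-order placements.

## Ancestral sequence reconstruction

Marginal ML reconstruction on a fixed rooted tree under a reversible
model Q = S·diag(π), normalised to one expected substitution per unit
branch length.  Transition matrices come from the symmetric
eigendecomposition of diag(π)^{1/2}·Q·diag(π)^{−1/2} (stable for
reversible Q).  Site likelihoods are Felsenstein pruning with gaps as
missing data (all-gap columns have likelihood 1).  Posteriors at a node
combine the below-node partial likelihood with an outside pass that
propagates the root prior π — equivalent, for a reversible model, to
rerooting at the node; root invariance of the total likelihood is
tested to 1e-8 and posteriors match brute-force enumeration over
ancestral states to 1e-10 on 4-leaf trees.

Models: a `poisson` preset (uniform exchangeabilities and frequencies)
and a PAML-dat-format loader for published exchangeability sets; the
shipped `.dat` test fixture is synthetic (made-up values exercising the
format).  Rate heterogeneity is optional discrete-gamma with four
equal-probability categories (mean category rates); the invariant-sites
class is omitted — full LG+I+G inference belongs to the external tree
tools whose output this package consumes, and this module is a
documented stand-in for dedicated ASR software, not a reimplementation
of any particular one.  Ancestral gaps are not modelled in the
likelihood; a site is gap-called when more than half of the node's
descendant leaves are gapped (a declared convention, reported alongside
the residue posteriors).  MAP ties break to the lower residue index.

## The synthetic-data generator

The generator is the test bed: it emulates the four architecture classes
with exact diagnostic motifs and known truth, so detector and classifier
claims are checkable end to end.

* **Architectures** (N→C): class A = J(70, HPD at offset 31) + G/F
  (median 34) + full ZnF (60 = 4×(motif 8 + spacer 6) + 4) + CTD block
  (170); cytosolic B^C = J + G/F(86) + CTD; ER B^C = J + G/F(36) +
  truncated ZnF (30 = motif+6+motif+8, cysteine-free spacers) + CTD;
  B′^(ST) = J + G/F(60) + ST(70, ≥60% S/T by construction) + βD(70).
  G/F medians are the class anchors; lengths draw uniformly within
  ±15% (`gf_spread`, set to 0 where tests need exact medians).
* **Homology**: structured segments come from fixed canonical templates
  (one internal constant seed), so families of different classes are
  genuinely homologous and profiles built from class A retrieve the
  others.  The G/F filler is redrawn per record (Gly+Phe ≥ 45% by exact
  counts, remainder disorder-promoting residues, no cysteines); the
  10-residue helix V template sits at a fixed offset from the G/F end so
  it stays alignable despite length variation.
* **Evolution**: per-site Poisson substitution events, each a uniform
  jump to one of the other 19 residues — exactly the jump chain of the
  normalised Poisson rate model used by the ASR module.  Sites inside
  protected motifs (HPD, ZnF cysteines) evolve at rate ×
  `motif_protection` (default 0.05; 0 makes them immutable).  Optional
  geometric indels are confined to the disordered G/F filler with truth
  spans updated per lineage.
* **Randomness contract**: one integer seed fans out to per-record
  streams via a stable CRC32 hash of the record id, so adding a record
  never perturbs the others; all outputs are byte-identical across runs.
* **Gene families**: `simulate_gene_family` copies one lineage per
  scripted duplication on the named species-tree edge, follows
  speciation to the leaves, applies optional per-edge loss, and records
  the surviving event count and leaf map.
* **Confidence-filter fixture**: `planted_column_alignment` interleaves
  well-conserved columns with noise columns grouped into multi-column
  slots at exactly one-third row occupancy (below the match threshold by
  construction).

What the generator does **not** emulate — and hence what passing tests
do not show about real proteomes: realistic amino-acid exchangeabilities
or site-rate variation in the families themselves, domain-level indels
and rearrangements, compartment targeting signals, taxon-sampling
structure of real proteome sets, alignment-error modes of real MSA
tools.  Recovery rates measured here are upper bounds for idealised
noise, not field performance estimates.

Problem sizes used throughout (tests and the acceptance script) are
desk-scale by design: reference alignments of 8 sequences, query sets of
200, families of 16 leaves, profiles of ~100–340 match states — large
enough to exercise every code path and small enough to rerun anywhere.

## Known limitations

* Global-with-flanks alignment makes skipping a long absent block (e.g.
  the 60 ZnF columns for a cytosolic B^C query against the full-length
  master) pay a per-column deletion cost; near the disordered G/F this
  can shift the Viterbi boundary at higher divergence.  The anchored
  spans absorb most of this; residual G/F-length noise at ≥0.2
  substitutions/site is visible in summaries, while class labels (which
  depend on profile hits and the ZnF call, not on G/F length) stay
  robust — 97% recovery at 0.3 substitutions/site.
* The identity-based fast-evolving flag is a stand-in for manual
  curation; branch-length-based criteria would need the trees this
  package treats as external input.
* Reconciliation is duplication/loss only (no transfers, no dating), and
  the ASR module is a stand-in for dedicated ASR software (no joint
  reconstruction, no model selection, no indel coding beyond the
  majority-rule gap call).
* Tree inference itself (ML searches, bootstrapping) and HMMER
  interoperation beyond the Stockholm PP conventions are out of scope;
  the pipeline consumes Newick and Stockholm produced by external tools.
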