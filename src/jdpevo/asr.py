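"""Marginal maximum-likelihood ancestral sequence reconstruction.

Works on a fixed rooted tree with branch lengths, under a reversible
amino-acid rate model Q = S diag(pi) (S symmetric exchangeabilities, pi
stationary frequencies), normalised to one expected substitution per unit
branch length.  Site likelihoods come from Felsenstein pruning with gaps as
missing data; marginal posteriors at an internal node combine the partial
likelihood below the node with the likelihood of the rest of the tree
propagated down from the root prior (the outside algorithm), which for a
reversible model is equivalent to rerooting at the node.

Transition matrices are computed by symmetric eigendecomposition of
``diag(pi)^1/2 Q diag(pi)^-1/2`` — stable for reversible Q.  Optional
discrete-gamma rate heterogeneity (equal-probability categories, mean
category rates) mixes posteriors with per-site category weights.

Ancestral gaps are not modelled in the likelihood; a site is called gapped
at a node when more than half of the node's descendant leaves are gapped
there (a declared convention, reported separately from the residue
posteriors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gamma as gamma_dist

from .io import AA_INDEX, AMINO_ACIDS, GAP, AlignmentBlock, TreeNode

__all__ = [
    "RateModel",
    "AncestralPosterior",
    "build_rate_model",
    "read_paml_dat",
    "site_likelihood",
    "tree_log_likelihood",
    "reconstruct_marginal",
    "discrete_gamma_rates",
]


@dataclass
class RateModel:
    """A reversible 20-state substitution model, rate-normalised."""

    exchangeabilities: np.ndarray  # (20,20) symmetric, zero diagonal
    stationary_frequencies: np.ndarray  # (20,)
    name: str = "custom"
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S = self.exchangeabilities
        pi = self.stationary_frequencies
        if S.shape != (20, 20) or not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        if np.any(pi <= 0):
            raise ValueError("stationary frequencies must be strictly positive")
        pi = pi / pi.sum()
        self.stationary_frequencies = pi
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        self.Q = Q / scale
        # symmetric eigendecomposition for stable matrix exponentials
        rpi = np.sqrt(pi)
        B = (self.Q * rpi[:, None]) / rpi[None, :]
        B = (B + B.T) / 2
        self._eigval, self._eigvec = np.linalg.eigh(B)
        self._rpi = rpi

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        ew = np.exp(self._eigval * t)
        inner = (self._eigvec * ew[None, :]) @ self._eigvec.T
        P = inner / self._rpi[:, None] * self._rpi[None, :]
        return np.clip(P, 0.0, None)


def build_rate_model(
    exchangeability_source: str | Path | np.ndarray = "poisson",
    frequencies: str | np.ndarray = "from-file",
) -> RateModel:
    """Assemble a :class:`RateModel`.

    ``exchangeability_source``: the preset ``"poisson"`` (uniform
    exchangeabilities), a PAML ``.dat``-format file path, or a matrix.
    ``frequencies``: ``"from-file"`` (dat files), ``"uniform"``, or an
    explicit 20-vector.
    """
    name = "custom"
    file_freqs = None
    if isinstance(exchangeability_source, (str, Path)) and str(exchangeability_source) == "poisson":
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        name = "poisson"
        if isinstance(frequencies, str) and frequencies == "from-file":
            frequencies = "uniform"
    elif isinstance(exchangeability_source, (str, Path)):
        S, file_freqs = read_paml_dat(exchangeability_source)
        name = Path(exchangeability_source).stem
    else:
        S = np.asarray(exchangeability_source, dtype=float)
    if isinstance(frequencies, str):
        if frequencies == "uniform":
            pi = np.full(20, 0.05)
        elif frequencies == "from-file":
            if file_freqs is None:
                raise ValueError("no frequency line available from this source")
            pi = file_freqs
        else:
            raise ValueError(f"unknown frequency source {frequencies!r}")
    else:
        pi = np.asarray(frequencies, dtype=float)
    return RateModel(S, pi, name=name)


def read_paml_dat(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-format amino-acid exchangeability file: 19 lower-triangle
    rows (190 values) followed by a 20-value stationary-frequency line."""
    values: list[float] = []
    for line in open(path):
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                break  # comment tail; skip rest of line
    if len(values) < 210:
        raise ValueError(f"{path}: expected 190 exchangeabilities + 20 frequencies")
    tri, freqs = values[:190], np.array(values[190:210])
    S = np.zeros((20, 20))
    it = iter(tri)
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return S, freqs


def discrete_gamma_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories
    (mean 1 overall)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=shape, scale=1.0 / shape)
    upper = gamma_dist.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = ncat * np.diff(upper)
    return rates / rates.mean() * 1.0


# ---------------------------------------------------------------------------
# Pruning

def _encode_column(tree: TreeNode, column: dict[str, str]) -> dict[str, int]:
    out = {}
    for leaf in tree.leaves():
        ch = column.get(leaf.label, GAP)
        out[leaf.label] = AA_INDEX.get(ch, -1)  # -1: gap/X = missing
    return out


def _up_partials(
    tree: TreeNode, model: RateModel, codes: dict[str, np.ndarray], rate: float = 1.0
) -> dict[int, np.ndarray]:
    """Conditional likelihoods below each node: (n_sites, 20) per node."""
    n_sites = next(iter(codes.values())).size if codes else 0
    up: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            x = codes[node.label]
            part = np.ones((n_sites, 20))
            obs = x >= 0
            part[obs] = 0.0
            part[obs, x[obs]] = 1.0
            up[id(node)] = part
        else:
            part = np.ones((n_sites, 20))
            for ch in node.children:
                t = ch.branch_length
                if t is None:
                    raise ValueError("missing branch length")
                P = model.transition_matrix(t * rate)
                part = part * (up[id(ch)] @ P.T)
            up[id(node)] = part
    return up


def _leaf_codes(tree: TreeNode, aln: AlignmentBlock) -> dict[str, np.ndarray]:
    rows = {rid: row for rid, row in zip(aln.rows, aln.matrix)}
    codes = {}
    for leaf in tree.leaves():
        if leaf.label not in rows:
            raise ValueError(f"leaf {leaf.label!r} missing from alignment")
        codes[leaf.label] = np.array(
            [AA_INDEX.get(c, -1) for c in rows[leaf.label]], dtype=np.int64
        )
    return codes


def site_likelihood(
    tree: TreeNode, model: RateModel, column: dict[str, str]
) -> float:
    """Felsenstein-pruning likelihood of one alignment column; gaps are
    missing data (an all-gap column has likelihood 1)."""
    codes = {k: np.array([v]) for k, v in _encode_column(tree, column).items()}
    up = _up_partials(tree, model, codes)
    pi = model.stationary_frequencies
    return float(up[id(tree)][0] @ pi)


def tree_log_likelihood(
    tree: TreeNode, model: RateModel, aln: AlignmentBlock
) -> float:
    codes = _leaf_codes(tree, aln)
    up = _up_partials(tree, model, codes)
    pi = model.stationary_frequencies
    site_l = up[id(tree)] @ pi
    return float(np.log(site_l).sum())


@dataclass
class AncestralPosterior:
    node_id: str
    posteriors: np.ndarray  # (n_sites, 20), rows sum to 1
    map_sequence: str  # '-' at gap-called sites
    mean_map_posterior: float
    gap_calls: np.ndarray  # (n_sites,) bool


def _above_partials(
    tree: TreeNode, model: RateModel, up: dict[int, np.ndarray], rate: float = 1.0
) -> dict[int, np.ndarray]:
    """Outside pass: above[v][site, x] = P(data outside v's subtree and
    state x at v), root prior included."""
    n_sites = up[id(tree)].shape[0]
    pi = model.stationary_frequencies
    above: dict[int, np.ndarray] = {id(tree): np.tile(pi, (n_sites, 1))}
    for node in tree.preorder():
        for ch in node.children:
            msg = above[id(node)].copy()
            for sib in node.children:
                if sib is ch:
                    continue
                P = model.transition_matrix(sib.branch_length * rate)
                msg = msg * (up[id(sib)] @ P.T)
            P = model.transition_matrix(ch.branch_length * rate)
            above[id(ch)] = msg @ P
    return above


def reconstruct_marginal(
    tree: TreeNode,
    model: RateModel,
    aln: AlignmentBlock,
    node_id: str,
    gamma_shape: float | None = None,
    ncat: int = 4,
    gap_majority: float = 0.5,
) -> AncestralPosterior:
    """Marginal posterior amino-acid distribution at one internal node.

    Per site, posterior(x) is proportional to the likelihood below the node
    times the likelihood of the rest of the tree with the root prior, both
    conditioned on state x at the node.  With ``gamma_shape`` set, discrete-
    gamma categories are mixed with per-site category weights.  A site is
    gap-called when more than ``gap_majority`` of the node's descendant
    leaves are gapped.
    """
    node = _find_node(tree, node_id)
    if node.is_leaf:
        raise ValueError(f"node {node_id!r} is a leaf")
    codes = _leaf_codes(tree, aln)
    n_sites = next(iter(codes.values())).size
    rates = (
        discrete_gamma_rates(gamma_shape, ncat) if gamma_shape is not None else [1.0]
    )
    weighted = np.zeros((n_sites, 20))
    site_totals = np.zeros(n_sites)
    for r in rates:
        up = _up_partials(tree, model, codes, rate=r)
        above = _above_partials(tree, model, up, rate=r)
        joint = up[id(node)] * above[id(node)]  # (sites, 20)
        weighted += joint
        site_totals += joint.sum(axis=1)
    posteriors = weighted / site_totals[:, None]

    leaf_labels = [l.label for l in node.leaves()]
    gapped = np.zeros(n_sites)
    for lab in leaf_labels:
        gapped += codes[lab] < 0
    gap_calls = gapped / len(leaf_labels) > gap_majority

    map_idx = posteriors.argmax(axis=1)
    map_seq = "".join(
        GAP if gap_calls[i] else AMINO_ACIDS[map_idx[i]] for i in range(n_sites)
    )
    per_site_max = posteriors.max(axis=1)
    mean_map = float(per_site_max[~gap_calls].mean()) if (~gap_calls).any() else 0.0
    return AncestralPosterior(
        node_id=node_id,
        posteriors=posteriors,
        map_sequence=map_seq,
        mean_map_posterior=mean_map,
        gap_calls=gap_calls,
    )


def _find_node(tree: TreeNode, node_id: str) -> TreeNode:
    for n in tree.postorder():
        if n.label == node_id:
            return n
    if node_id == "root":
        return tree
    raise KeyError(f"node {node_id!r} not found in tree")
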