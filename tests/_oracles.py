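"""Independent brute-force oracles used by the test suite.

These enumerate every legal state path (profile HMM) or every ancestral
state assignment (tree likelihood) explicitly, sharing no code with the
dynamic-programming implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from jdpevo.io import AMINO_ACIDS


def enumerate_profile_paths(model, x: np.ndarray):
    """All (probability, path) pairs of a profile HMM over a coded sequence.

    Paths are lists of (state, position) with state in {M, I, D}; Begin/End
    are implicit.  Probabilities are products of explicit transition and
    emission terms.
    """
    L = model.length
    t = model.transitions
    me, ie = model.match_emissions, model.insert_emissions
    n = len(x)
    results: list[tuple[float, list]] = []

    def emit_m(k, i):
        return 1.0 if x[i] < 0 else me[k - 1, x[i]]

    def emit_i(k, i):
        return 1.0 if x[i] < 0 else ie[k, x[i]]

    def step(state, k, i, p, path):
        if p == 0.0:
            return
        if k == L and i == n:
            out = {"M": t["mm"][L], "I": t["im"][L], "D": t["dm"][L]}[state]
            if out > 0:
                results.append((p * out, path))
        if k < L and i < n:
            out = {"M": t["mm"][k], "I": t["im"][k], "D": t["dm"][k]}[state]
            step("M", k + 1, i + 1, p * out * emit_m(k + 1, i), path + [("M", k + 1)])
        if i < n:
            out = {"M": t["mi"][k], "I": t["ii"][k], "D": t["di"][k]}[state]
            step("I", k, i + 1, p * out * emit_i(k, i), path + [("I", k)])
        if k < L:
            out = {"M": t["md"][k], "I": t["id"][k], "D": t["dd"][k]}[state]
            step("D", k + 1, i, p * out, path + [("D", k + 1)])

    step("M", 0, 0, 1.0, [])
    return results


def path_posteriors(paths, n: int, L: int):
    """Aggregate enumerated paths into match/insert/delete posteriors."""
    total = sum(p for p, _ in paths)
    pm = np.zeros((n, L))
    pi = np.zeros(n)
    pd = np.zeros(L)
    for p, path in paths:
        i = 0
        deleted = set()
        for st, k in path:
            if st == "M":
                pm[i, k - 1] += p
                i += 1
            elif st == "I":
                pi[i] += p
                i += 1
            else:
                deleted.add(k)
        for k in deleted:
            pd[k - 1] += p
    return pm / total, pi / total, pd / total, total


def enumerate_tree_likelihood(tree, model, column: dict[str, str]):
    """Site likelihood and per-node marginal posteriors by explicit
    enumeration over all internal-state assignments."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    pi = model.stationary_frequencies
    P = {}
    for node in tree.postorder():
        if node is not tree:
            P[id(node)] = model.transition_matrix(node.branch_length)
    total = 0.0
    post = {id(n): np.zeros(20) for n in internals}
    for states in itertools.product(range(20), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, states)}
        p = pi[assign[id(tree)]]
        for node in tree.postorder():
            if node is tree:
                continue
            parent_state = None
            # find parent
            for cand in tree.postorder():
                if node in cand.children:
                    parent_state = assign[id(cand)]
                    break
            if node.is_leaf:
                ch = column.get(node.label, "-")
                if ch in AMINO_ACIDS:
                    p *= P[id(node)][parent_state, AMINO_ACIDS.index(ch)]
            else:
                p *= P[id(node)][parent_state, assign[id(node)]]
        total += p
        for n in internals:
            post[id(n)][assign[id(n)]] += p
    return total, {k: v / total for k, v in post.items()}
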