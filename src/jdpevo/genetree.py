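"""Tree post-processing and duplication counting by LCA reconciliation.

``collapse_low_support`` contracts weakly supported splits into polytomies
(the bootstrap < 50 convention).  ``reconcile_lca`` maps every gene-tree
node to the lowest common ancestor of its descendants' species; a node is a
gene duplication exactly when it maps to the same species-tree node as one
of its children, and losses follow the standard depth-difference count
along each gene-tree edge.  LCA reconciliation is exact for
duplication-loss histories without transfer.

The module also encodes, as ready-made (gene tree, species tree, leaf map)
triples, the three duplication histories of the human cytonuclear JDP
repertoire: the five B'(ST) paralogs (four duplications), the four
canonical-B paralogs (three duplications), and the two ancestral class A
duplications at the base of eukaryotes that produced the ER lineage and
the sister cytosolic A and B pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .io import TreeNode, parse_newick

__all__ = [
    "Reconciliation",
    "collapse_low_support",
    "reconcile_lca",
    "place_events",
    "resolve_polytomies",
    "human_bprime_st_history",
    "human_bc_history",
    "eukaryote_class_a_history",
]

log = logging.getLogger("jdpevo")


def collapse_low_support(tree: TreeNode, cutoff: float = 50.0) -> TreeNode:
    """Contract internal edges with support strictly below ``cutoff``.

    Children of a collapsed node are promoted to its parent; the collapsed
    edge's branch length is dropped (with a log note).  Leaves are never
    touched.  Supports are on the 0-100 scale.
    """
    if not 0 <= cutoff <= 100:
        raise ValueError(f"support cutoff {cutoff} outside [0,100]")
    dropped = [0]

    def rebuild(node: TreeNode) -> TreeNode:
        new = TreeNode(node.label, node.support, node.branch_length)
        for child in node.children:
            sub = rebuild(child)
            if (
                not sub.is_leaf
                and sub.support is not None
                and sub.support < cutoff
            ):
                if sub.branch_length is not None:
                    dropped[0] += 1
                new.children.extend(sub.children)
            else:
                new.children.append(sub)
        return new

    out = rebuild(tree)
    if dropped[0]:
        log.info("collapse_low_support: dropped %d contracted branch lengths", dropped[0])
    return out


@dataclass
class Reconciliation:
    """LCA mapping of a gene tree into a species tree."""

    mapping: dict[int, TreeNode]  # id(gene node) -> species node
    events: dict[int, str]  # id(gene internal node) -> duplication|speciation
    duplication_count: int
    loss_count: int
    gene_tree: TreeNode
    species_tree: TreeNode
    duplications: list[TreeNode] = field(default_factory=list)

    def event_of(self, gene_node: TreeNode) -> str:
        return self.events[id(gene_node)]

    def species_of(self, gene_node: TreeNode) -> TreeNode:
        return self.mapping[id(gene_node)]


def _depths(tree: TreeNode) -> dict[int, int]:
    depth: dict[int, int] = {}

    def walk(node: TreeNode, d: int) -> None:
        depth[id(node)] = d
        for ch in node.children:
            walk(ch, d + 1)

    walk(tree, 0)
    return depth


def _species_index(species_tree: TreeNode):
    parent: dict[int, TreeNode | None] = {id(species_tree): None}
    for node in species_tree.preorder():
        for ch in node.children:
            parent[id(ch)] = node
    depth = _depths(species_tree)

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if depth[id(a)] < depth[id(b)]:
                b = parent[id(b)]
            else:
                a = parent[id(a)]
        return a

    return lca, parent, depth


def reconcile_lca(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_map: dict[str, str],
    resolve_gene_polytomies: bool = False,
) -> Reconciliation:
    """Classic LCA (lowest-common-ancestor) reconciliation.

    ``leaf_map`` sends every gene-tree leaf label to a species-tree leaf
    label.  The gene tree must be binary; polytomies raise unless
    ``resolve_gene_polytomies`` asks for the duplication-minimising local
    resolution (exhaustive, refused above degree 6).
    """
    if resolve_gene_polytomies:
        gene_tree = resolve_polytomies(gene_tree, species_tree, leaf_map)
    species_leaves = {n.label: n for n in species_tree.leaves()}
    lca, parent, depth = _species_index(species_tree)

    mapping: dict[int, TreeNode] = {}
    events: dict[int, str] = {}
    duplications: list[TreeNode] = []

    for node in gene_tree.postorder():
        if node.is_leaf:
            if node.label not in leaf_map:
                raise ValueError(f"unmapped gene leaf {node.label!r}")
            sp = leaf_map[node.label]
            if sp not in species_leaves:
                raise ValueError(f"species {sp!r} not in species tree")
            mapping[id(node)] = species_leaves[sp]
            continue
        if len(node.children) != 2:
            raise ValueError(
                f"gene-tree polytomy of degree {len(node.children)} "
                "(use resolve_gene_polytomies)"
            )
        m = mapping[id(node.children[0])]
        for ch in node.children[1:]:
            m = lca(m, mapping[id(ch)])
        mapping[id(node)] = m
        if any(mapping[id(ch)] is m for ch in node.children):
            events[id(node)] = "duplication"
            duplications.append(node)
        else:
            events[id(node)] = "speciation"

    # losses by the standard depth-difference formula along each gene edge
    losses = 0
    for node in gene_tree.preorder():
        for ch in node.children:
            d = depth[id(mapping[id(ch)])] - depth[id(mapping[id(node)])]
            losses += d if events[id(node)] == "duplication" else max(d - 1, 0)
    return Reconciliation(
        mapping=mapping,
        events=events,
        duplication_count=len(duplications),
        loss_count=losses,
        gene_tree=gene_tree,
        species_tree=species_tree,
        duplications=duplications,
    )


def resolve_polytomies(
    gene_tree: TreeNode, species_tree: TreeNode, leaf_map: dict[str, str]
) -> TreeNode:
    """Resolve each gene-tree polytomy to the binary arrangement minimising
    the total duplication count (exhaustive over rooted shapes, refused for
    degree > 6)."""

    def all_binary(groups: list[TreeNode]) -> list[TreeNode]:
        if len(groups) == 1:
            return [groups[0]]
        out = []
        rest = groups[1:]
        first = groups[0]
        # `first` goes left; every proper subset of the rest may join it
        for r in range(len(rest)):
            for combo in combinations(range(len(rest)), r):
                left = [first] + [rest[i] for i in combo]
                right = [rest[i] for i in range(len(rest)) if i not in combo]
                for lt in all_binary(left):
                    for rt in all_binary(right):
                        out.append(TreeNode(children=[lt, rt]))
        return out

    def rebuild(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return node.copy()
        kids = [rebuild(ch) for ch in node.children]
        if len(kids) <= 2:
            return TreeNode(node.label, node.support, node.branch_length, kids)
        if len(kids) > 6:
            raise ValueError(f"polytomy of degree {len(kids)} too large to resolve")
        best, best_dups = None, None
        for cand in all_binary(kids):
            cand.branch_length = node.branch_length
            rec = reconcile_lca(cand, species_tree, leaf_map)
            if best_dups is None or rec.duplication_count < best_dups:
                best, best_dups = cand, rec.duplication_count
        return best

    return rebuild(gene_tree)


def place_events(
    rec: Reconciliation, species_tree: TreeNode | None = None
) -> list[tuple[TreeNode, TreeNode]]:
    """Assign each duplication to the species-tree edge above its mapping.

    Returns (gene duplication node, species node below the edge) pairs; a
    duplication mapping to the species root sits on the root stem.
    """
    return [(g, rec.species_of(g)) for g in rec.duplications]


def count_events_per_edge(rec: Reconciliation) -> dict[str, int]:
    """Duplications per species-tree edge, keyed by the label of the node
    below the edge (unlabelled nodes keyed by their leaf set)."""
    out: dict[str, int] = {}
    for _, sp in place_events(rec):
        key = sp.label or "{" + ",".join(sorted(sp.leaf_labels())) + "}"
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# Encoded duplication histories of the human cytonuclear JDP repertoire.
# Species sampling is a five-taxon vertebrate backbone (teleost fish,
# amphibian, reptile, and two mammals) — enough to pin every duplication
# to its stated stem edge.

_VERT_SPECIES = (
    "(fish:1,(amphibian:1,(reptile:1,(human:1,mouse:1)Mammalia:1)"
    "Amniota:1)Tetrapoda:1)Vertebrata;"
)


def _clade(paralog: str, species: list[str]) -> str:
    """Newick for one paralog tracked through nested speciations."""
    if len(species) == 1:
        return f"{paralog}_{species[0]}"
    return f"({_clade(paralog, species[:1])},{_clade(paralog, species[1:])})"


def human_bprime_st_history() -> tuple[TreeNode, TreeNode, dict[str, str]]:
    """The five human B'(ST) paralogs: DNAJB2 basal and pan-vertebrate;
    DNAJB6 from a duplication of the B2 lineage at the vertebrate stem;
    DNAJB8 from DNAJB6 in the amniote ancestor; DNAJB7 (from B6) and
    DNAJB3 (from B8) in the mammalian ancestor.  Four duplications."""
    vert = ["fish", "amphibian", "reptile", "human", "mouse"]
    amniote = ["reptile", "human", "mouse"]
    mammal = ["human", "mouse"]
    b6_line = f"({_clade('DNAJB6', ['reptile'])},({_clade('DNAJB6', mammal)},{_clade('DNAJB7', mammal)}))"
    b8_line = f"({_clade('DNAJB8', ['reptile'])},({_clade('DNAJB8', mammal)},{_clade('DNAJB3', mammal)}))"
    b6_super = (
        f"({_clade('DNAJB6', ['fish'])},({_clade('DNAJB6', ['amphibian'])},"
        f"({b6_line},{b8_line})))"
    )
    gene = parse_newick(f"({_clade('DNAJB2', vert)},{b6_super});")
    species = parse_newick(_VERT_SPECIES)
    leaf_map = {lab: lab.rsplit("_", 1)[1] for lab in gene.leaf_labels()}
    return gene, species, leaf_map


def human_bc_history() -> tuple[TreeNode, TreeNode, dict[str, str]]:
    """Three sequential duplications producing the four human canonical-B
    paralogs DNAJB1, B4, B5 and B13 (ladderised; the count, not the branch
    order, is the reconstructed quantity)."""
    mammal = ["human", "mouse"]
    gene = parse_newick(
        f"((({_clade('DNAJB1', mammal)},{_clade('DNAJB4', mammal)}),"
        f"{_clade('DNAJB5', mammal)}),{_clade('DNAJB13', mammal)});"
    )
    species = parse_newick(_VERT_SPECIES)
    leaf_map = {lab: lab.rsplit("_", 1)[1] for lab in gene.leaf_labels()}
    return gene, species, leaf_map


_EUK_SPECIES = "((fungi:1,metazoa:1)Opisthokonta:1,plants:1)Eukaryota;"


def eukaryote_class_a_history() -> tuple[TreeNode, TreeNode, dict[str, str]]:
    """Two sequential class A duplications in the eukaryote common ancestor:
    the first separated the ER lineage from the cytosol/nucleus lineage, the
    second split the cytosolic gene into sister class A and canonical-B
    genes.  Both map to the eukaryote stem."""
    euk = ["fungi", "metazoa", "plants"]

    def clade3(par):
        return f"(({par}_fungi,{par}_metazoa),{par}_plants)"

    gene = parse_newick(f"({clade3('ER_A')},({clade3('cyto_A')},{clade3('cyto_BC')}));")
    species = parse_newick(_EUK_SPECIES)
    leaf_map = {lab: lab.rsplit("_", 1)[1] for lab in gene.leaf_labels()}
    return gene, species, leaf_map
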