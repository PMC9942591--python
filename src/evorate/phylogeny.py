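"""Tree construction and manipulation.

The rate machinery treats the tree as fixed, so all that is needed here is
a reasonable distance-based reconstruction: model-corrected pairwise
distances (Poisson correction for protein, Jukes-Cantor for nucleotide)
followed by classic neighbor joining. Trees are held as dendropy objects;
Newick reading/writing goes through dendropy.

Because the substitution models are reversible, the pruning likelihood is
invariant to the root placement; the rooting produced here is purely a
traversal convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import (
    DegenerateInputError,
    LabelMismatchError,
    ParseError,
    QueryOutsideSubtreeError,
    TooFewHomologuesError,
)
from .seq_io import Alignment

#: distance assigned to saturated pairs (p at/beyond the correction singularity)
DISTANCE_CAP = 5.0


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        assert self.d.shape == (n, n)
        assert np.allclose(self.d, self.d.T)
        assert np.allclose(np.diag(self.d), 0.0)

    def value(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])


def poisson_distance(p: float, cap: float = DISTANCE_CAP) -> float:
    """Poisson-corrected protein distance -ln(1 - p), capped."""
    if p >= 1.0 - np.exp(-cap):
        return cap
    return float(-np.log(1.0 - p))


def jukes_cantor_distance(p: float, cap: float = DISTANCE_CAP) -> float:
    """Jukes-Cantor nucleotide distance -(3/4) ln(1 - 4p/3), capped."""
    p_cap = 0.75 * (1.0 - np.exp(-4.0 * cap / 3.0))
    if p >= p_cap:
        return cap
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def pairwise_distances(alignment: Alignment, cap: float = DISTANCE_CAP) -> DistanceMatrix:
    """Model-corrected distances from pairwise mismatch fractions.

    Gaps and missing characters are excluded pairwise; pairs sharing no
    informative column get the cap.
    """
    if alignment.n_sequences < 2:
        raise DegenerateInputError("need at least 2 sequences")
    correct = (
        poisson_distance if alignment.alphabet == "protein" else jukes_cantor_distance
    )
    # integer codes; -1 = gap/missing
    from .rates import build_model, encode_alignment

    enc = encode_alignment(alignment, build_model(alignment.alphabet))
    n = alignment.n_sequences
    d = np.zeros((n, n))
    valid = enc >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                d[i, j] = d[j, i] = cap
                continue
            p = float(np.sum(enc[i, both] != enc[j, both])) / m
            d[i, j] = d[j, i] = correct(p, cap)
    return DistanceMatrix(taxa=tuple(alignment.ids), d=d)


def build_nj(D: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining.

    Ties in the Q-criterion are broken by the smallest (i, j) index pair in
    the current working order; negative branch-length estimates are clamped
    to 0. The final join point serves as the (arbitrary) root.
    """
    n = len(D.taxa)
    if n < 2:
        raise DegenerateInputError("neighbor joining needs at least 2 taxa")

    ns = dendropy.TaxonNamespace([str(t) for t in D.taxa])

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        return node

    if n == 2:
        root = dendropy.Node()
        for t in D.taxa:
            child = leaf(t)
            child.edge.length = float(D.d[0, 1]) / 2.0
            root.add_child(child)
        tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
        tree.is_rooted = False
        return tree

    nodes: list[dendropy.Node] = [leaf(t) for t in D.taxa]
    d = D.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        nodes[i].edge.length = max(0.0, float(vi))
        nodes[j].edge.length = max(0.0, float(vj))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remainder
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    root = dendropy.Node()
    if len(nodes) == 3:
        va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, v in zip(nodes, (va, vb, vc)):
            node.edge.length = max(0.0, float(v))
            root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse {path} as Newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    s = tree_to_newick(tree)
    with open(path, "w") as fh:
        fh.write(s + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def validate_tree_against_alignment(tree: dendropy.Tree, alignment: Alignment) -> None:
    """Leaf set must equal the alignment taxa exactly."""
    leaves = leaf_labels(tree)
    taxa = set(alignment.ids)
    if leaves != taxa:
        raise LabelMismatchError(
            f"tree leaves and alignment taxa differ: only-in-tree "
            f"{sorted(leaves - taxa)}, only-in-alignment {sorted(taxa - leaves)}"
        )


def extract_subtree(
    tree: dendropy.Tree,
    clade_leaves: Iterable[str],
    alignment: Alignment,
    min_homologues: int = 5,
) -> tuple[dendropy.Tree, Alignment]:
    """Induced subtree for a clade (given as its full leaf-name set) and the
    alignment restricted to it, with all-gap columns dropped.

    The clade must contain the query and at least ``min_homologues`` leaves.
    """
    wanted = set(clade_leaves)
    all_leaves = leaf_labels(tree)
    unknown = wanted - all_leaves
    if unknown:
        raise LabelMismatchError(f"clade names not in tree: {sorted(unknown)}")
    if alignment.query_id not in wanted:
        raise QueryOutsideSubtreeError(
            f"query {alignment.query_id!r} is outside the selected clade"
        )
    if len(wanted) < min_homologues:
        raise TooFewHomologuesError(
            f"subtree has {len(wanted)} leaves; minimum is {min_homologues} "
            "(including the query)"
        )

    if wanted == all_leaves:
        sub = tree.clone(depth=1)
    else:
        copy = tree.clone(depth=1)
        copy.is_rooted = True  # treat the seed node as root for MRCA lookup
        target = copy.mrca(taxon_labels=sorted(wanted))
        below = {lf.taxon.label for lf in target.leaf_iter()}
        if below != wanted:
            raise LabelMismatchError(
                "the given leaf set is not a clade of the tree "
                f"(its ancestor also spans {sorted(below - wanted)})"
            )
        if target.parent_node is not None:
            target.parent_node.remove_child(target)
        target.edge.length = None
        sub = dendropy.Tree(taxon_namespace=copy.taxon_namespace, seed_node=target)
        sub.is_rooted = False
        # drop taxa no longer referenced so namespace matches leaves
        sub.purge_taxon_namespace()
    sub_alignment = alignment.subset(wanted, drop_all_gap=True)
    return sub, sub_alignment


def reroot_on_edge(tree: dendropy.Tree, leaf_label: str) -> dendropy.Tree:
    """Copy of the tree rerooted at the midpoint of the edge above a leaf
    (used to verify root-invariance of the likelihood)."""
    copy = tree.clone(depth=1)
    leaf = None
    for lf in copy.leaf_node_iter():
        if lf.taxon.label == leaf_label:
            leaf = lf
            break
    if leaf is None:
        raise LabelMismatchError(f"no leaf named {leaf_label!r}")
    length = leaf.edge.length or 0.0
    copy.reroot_at_edge(leaf.edge, length1=length / 2.0, length2=length / 2.0)
    return copy
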