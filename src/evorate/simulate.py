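"""Forward simulation of trees and alignments with known per-site rates.

Generates the exact data-generating process the rate estimator assumes:
a random Yule tree with exponential branch lengths, and characters evolved
along it under the reversible substitution model with a per-site rate
multiplier. Everything is driven by a single seeded generator, so fixtures
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .phylogeny import tree_to_newick, write_newick
from .rates import SubstitutionModel, build_model
from .seq_io import Alignment, SequenceRecord, write_alignment


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    n_leaves: int
    n_sites: int
    alphabet: str = "protein"
    alpha: float | None = 1.0          # gamma shape of the rate distribution
    rates: tuple[float, ...] | None = None  # explicit per-site rates instead
    branch_scale: float = 0.1          # mean branch length (subst./site)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")
        if self.rates is None and self.alpha is None:
            raise ValueError("give either alpha or explicit rates")


def random_tree(n_leaves: int, scale: float, seed: int | np.random.Generator) -> dendropy.Tree:
    """Yule tree: repeatedly split a uniformly chosen leaf; branch lengths
    i.i.d. exponential with the given mean."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    leaves = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        leaves.append(child)
    while len(leaves) < n_leaves:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            leaves.append(child)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    # label leaves in a stable traversal order, then draw branch lengths
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        lf.taxon = ns.new_taxon(f"t{i}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(scale))
    tree.is_rooted = False
    return tree


def draw_gamma_rates(
    alpha: float, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Continuous mean-1 gamma(alpha, alpha) rate multipliers."""
    return rng.gamma(shape=alpha, scale=1.0 / alpha, size=n_sites)


def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    rates_per_site: np.ndarray,
    seed: int | np.random.Generator,
    query_id: str | None = None,
    alphabet: str | None = None,
) -> tuple[Alignment, np.ndarray]:
    """Evolve characters down the tree: root states from the stationary
    distribution, each child state from P(rate * branch) given its parent.

    Returns the leaf alignment (query defaults to the first leaf) and the
    generating rates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.asarray(rates_per_site, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    n_sites = rates.size
    n_states = model.n_states

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(n_states, size=n_sites, p=model.pi)
    leaf_rows: list[tuple[str, np.ndarray]] = []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_states = states[id(root)]
        else:
            b = node.edge.length or 0.0
            parent = states[id(node.parent_node)]
            # per-site transition rows P(r_i * b)[parent_i, :]
            P_rows = _transition_rows(model, rates * b, parent)
            u = rng.random(n_sites)
            cum = np.cumsum(P_rows, axis=1)
            child_states = np.minimum(
                (u[:, None] > cum).sum(axis=1), n_states - 1
            )
            states[id(node)] = child_states
            parent_states = child_states
        if node.is_leaf():
            leaf_rows.append((node.taxon.label, parent_states))

    symbols = np.array(list(model.states))
    records = [
        SequenceRecord(label, "".join(symbols[s])) for label, s in leaf_rows
    ]
    qid = query_id or records[0].id
    aln = Alignment(
        records=records,
        query_id=qid,
        alphabet=alphabet or ("protein" if n_states == 20 else "nucleotide"),
    )
    return aln, rates


def _transition_rows(
    model: SubstitutionModel, ts: np.ndarray, from_states: np.ndarray
) -> np.ndarray:
    """Row ``from_states[s]`` of P(ts[s]) for every site s, via the cached
    eigendecomposition; clipped and renormalized to proper distributions."""
    expw = np.exp(model._eigvals[None, :] * ts[:, None])  # (S, k)
    right_rows = model._right[from_states]                # (S, k)
    rows = (right_rows * expw) @ model._left              # (S, j)
    np.clip(rows, 0.0, None, out=rows)
    rows /= rows.sum(axis=1, keepdims=True)
    return rows


def simulate_hit_set(
    n_hits: int,
    seed: int,
    query_length: int = 80,
    n_families: int = 400,
    alphabet: str = "protein",
) -> tuple[list, "object"]:
    """Synthetic homolog search results for selection testing.

    Builds a query and ``n_hits`` homologues organised into redundancy
    families: members of a family are byte-identical (redundant copies, as
    produced by near-duplicate database entries), while different families
    differ from the query by a family-specific number of substitutions, so
    pre-clustering identities span the accepted range. E-values increase
    with divergence. Returns (hits, query_hit).
    """
    from .homologs import Hit

    rng = np.random.default_rng(seed)
    symbols = "ACDEFGHIKLMNPQRSTVWY" if alphabet == "protein" else "ACGT"
    query_seq = "".join(rng.choice(list(symbols), query_length))
    families = []
    for f in range(n_families):
        # divergence from ~6% to ~55% of positions
        n_mut = 5 + int(round(40 * f / max(1, n_families - 1)))
        seq = list(query_seq)
        for pos in rng.choice(query_length, size=n_mut, replace=False):
            choices = [c for c in symbols if c != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        families.append(("".join(seq), n_mut))
    hits = []
    for i in range(n_hits):
        fam = int(rng.integers(n_families))
        seq, n_mut = families[fam]
        identity = 1.0 - n_mut / query_length
        e_value = float(10.0 ** (-60 * identity + rng.uniform(0, 2)))
        hits.append(
            Hit(
                subject_id=f"hit{i:05d}",
                e_value=e_value,
                identity_to_query=identity,
                coverage_of_query=1.0,
                sequence=seq,
            )
        )
    query_hit = Hit(
        subject_id="query",
        e_value=0.0,
        identity_to_query=1.0,
        coverage_of_query=1.0,
        sequence=query_seq,
    )
    return hits, query_hit


@dataclass(frozen=True)
class SimulatedDataset:
    tree: dendropy.Tree
    alignment: Alignment
    true_rates: np.ndarray
    spec: SimulationSpec


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Tree + alignment + true rates for one SimulationSpec, one seed."""
    rng = np.random.default_rng(spec.seed)
    tree = random_tree(spec.n_leaves, spec.branch_scale, rng)
    model = build_model(spec.alphabet)
    if spec.rates is not None:
        rates = np.asarray(spec.rates, dtype=float)
        if rates.size != spec.n_sites:
            raise ValueError("explicit rates length must equal n_sites")
    else:
        rates = draw_gamma_rates(spec.alpha, spec.n_sites, rng)
    aln, rates = simulate_alignment(
        tree, model, rates, rng, alphabet=spec.alphabet
    )
    return SimulatedDataset(tree=tree, alignment=aln, true_rates=rates, spec=spec)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA alignment, Newick tree and a true-rates TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "tree": out / "tree.nwk",
        "true_rates": out / "true_rates.tsv",
    }
    write_alignment(ds.alignment, paths["alignment"])
    write_newick(ds.tree, paths["tree"])
    with open(paths["true_rates"], "w") as fh:
        fh.write("site\ttrue_rate\n")
        for i, r in enumerate(ds.true_rates):
            fh.write(f"{i}\t{r:.8f}\n")
    return paths
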