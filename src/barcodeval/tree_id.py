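"""Tree-based species identification: neighbor joining, bootstrap, monophyly.

A species is *identified* by a tree when its individuals form a monophyletic
group whose defining branch is well supported — here, strictly greater than a
cut-off of 80 (bootstrap %) or 0.80 (posterior probability). Monophyly is
evaluated on unrooted bipartitions: a set of leaves is monophyletic iff some
single edge separates exactly those leaves from all others, which is the
rooting-free formalization appropriate to neighbor-joining output.

Neighbor joining is implemented natively (Saitou-Nei agglomeration with the
Q-criterion); branch supports come from non-parametric bootstrap over
alignment columns, with each internal edge of the original-data tree scored
by the percentage of replicate trees containing the same bipartition.
Externally built trees (e.g. maximum-likelihood bootstrap consensus or
Bayesian posterior summaries) are consumed via newick with supports as
internal node labels and scored by the same rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import LabeledAlignment
from .distances import DEFAULT_MIN_OVERLAP, DistanceMatrix, distance_matrix_from_codes
from .exceptions import TreeConsistencyError, UndefinedDistanceError, ValidationError

#: Default support cut-offs by scale; a clade counts only if support > cutoff.
DEFAULT_CUTOFFS = {"bootstrap": 80.0, "posterior": 0.80}
_SCALE_BOUNDS = {"bootstrap": (0.0, 100.0), "posterior": (0.0, 1.0)}


# ---------------------------------------------------------------------------
# Native neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    """Lightweight tree node used by the NJ core (leaf_id set on tips only)."""

    __slots__ = ("children", "leaf_id")

    def __init__(self, leaf_id: int | None = None):
        self.children: list[tuple["_Node", float]] = []
        self.leaf_id = leaf_id


def _neighbor_joining(D: np.ndarray) -> _Node:
    """Saitou-Nei neighbor joining on a complete distance matrix.

    Returns the unrooted tree as a trifurcating root node. Negative branch
    lengths are clamped to zero with the deficit shifted to the sibling edge
    so the joined-pair path length is preserved. Ties in the Q-criterion are
    broken by the smallest (i, j) index pair for determinism.
    """
    n = D.shape[0]
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 records")
    if np.isnan(D).any():
        raise UndefinedDistanceError(
            "distance matrix contains undefined pairs; remove or re-sequence the "
            "affected records (or relax min_overlap) before tree building"
        )
    nodes = [_Node(leaf_id=i) for i in range(n)]
    D = D.astype(float, copy=True)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        elif lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = _Node()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        du = 0.5 * (D[i, :] + D[j, :] - dij)

        keep = [k for k in range(m) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        new_row = du[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row
        D[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]

    # Final three nodes: solve the three-point equations exactly.
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = _Node()
    root.children = [(a, max(la, 0.0)), (b, max(lb, 0.0)), (c, max(lc, 0.0))]
    return root


def _node_splits(root: _Node, n_leaves: int) -> set[frozenset[int]]:
    """Nontrivial bipartitions of an NJ tree, as canonical leaf-index sets.

    Each split is represented by the side not containing leaf 0.
    """
    splits: set[frozenset[int]] = set()

    def walk(node: _Node) -> frozenset[int]:
        if node.leaf_id is not None:
            return frozenset([node.leaf_id])
        below = frozenset().union(*(walk(ch) for ch, _ in node.children))
        if 2 <= len(below) <= n_leaves - 2:
            side = below if 0 not in below else frozenset(range(n_leaves)) - below
            splits.add(side)
        return below

    for child, _ in root.children:
        walk(child)
    return splits


def _nj_splits(D: np.ndarray) -> set[frozenset[int]]:
    return _node_splits(_neighbor_joining(D), D.shape[0])


# ---------------------------------------------------------------------------
# SupportTree container
# ---------------------------------------------------------------------------


def _canonical(side: frozenset[str], all_taxa: frozenset[str], ref: str) -> frozenset[str]:
    return side if ref not in side else all_taxa - side


@dataclass
class SupportTree:
    """An unrooted tree over dataset records with per-edge supports.

    ``supports`` maps a bipartition side (a frozenset of leaf labels, as the
    clade was written or built) to its support on the declared ``scale``
    (``"bootstrap"`` in [0, 100] or ``"posterior"`` in [0, 1]); ``None``
    marks an edge whose support was not annotated. Look up supports through
    :meth:`support_of`, which tries the given side first and then its
    complement — on trees written with a bifurcating root the two root-child
    clades name the same unrooted edge, and the side-exact annotation wins.
    """

    taxa: list[str]  # leaf labels "species|sample_id"
    species_of: dict[str, str]  # label -> species
    tree: dendropy.Tree
    scale: str = "bootstrap"
    supports: dict[frozenset[str], float | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in _SCALE_BOUNDS:
            raise ValidationError(f"unknown support scale {self.scale!r}")
        if len(set(self.taxa)) != len(self.taxa):
            raise TreeConsistencyError("leaf labels are not unique")
        lo, hi = _SCALE_BOUNDS[self.scale]
        for split, sup in self.supports.items():
            if sup is not None and not (lo <= sup <= hi):
                raise ValidationError(
                    f"support {sup} outside declared {self.scale} scale [{lo}, {hi}]"
                )

    @property
    def _ref(self) -> str:
        return min(self.taxa)

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions of the topology, canonicalized."""
        all_taxa = frozenset(self.taxa)
        n = len(self.taxa)
        out: set[frozenset[str]] = set()
        for side in self._node_leafsets().values():
            if 2 <= len(side) <= n - 2:
                out.add(_canonical(side, all_taxa, self._ref))
        return out

    def _node_leafsets(self) -> dict[dendropy.Node, frozenset[str]]:
        leafsets: dict[dendropy.Node, frozenset[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[node] = frozenset([node.taxon.label])
            else:
                leafsets[node] = frozenset().union(
                    *(leafsets[ch] for ch in node.child_nodes())
                )
        return leafsets

    def support_of(self, side: frozenset[str]) -> float | None:
        """Support of the edge separating ``side`` from the rest, if annotated."""
        if side in self.supports:
            return self.supports[side]
        return self.supports.get(frozenset(self.taxa) - side)

    def as_newick(self) -> str:
        """Newick string with supports as internal node labels."""
        tree = self.tree.clone(depth=1)
        all_taxa = frozenset(self.taxa)
        n = len(self.taxa)
        leafsets: dict[dendropy.Node, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[node] = frozenset([node.taxon.label])
                continue
            leafsets[node] = frozenset().union(*(leafsets[ch] for ch in node.child_nodes()))
            side = leafsets[node]
            if self.supports and 2 <= len(side) <= n - 2:
                sup = self.supports.get(side)
                if sup is None:
                    sup = self.supports.get(all_taxa - side)
                node.label = None if sup is None else format(sup, "g")
        return tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())


def _support_tree_from_nj(
    root: _Node, labels: list[tuple[str, str]], scale: str = "bootstrap"
) -> SupportTree:
    """Convert the NJ core's node structure into a SupportTree."""
    taxa = [f"{sp}|{sid}" for sp, sid in labels]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    def build(node: _Node, parent: dendropy.Node) -> None:
        for child, bl in node.children:
            dnode = dendropy.Node()
            dnode.edge.length = bl
            if child.leaf_id is not None:
                dnode.taxon = ns.get_taxon(taxa[child.leaf_id])
            parent.add_child(dnode)
            build(child, dnode)

    build(root, tree.seed_node)
    return SupportTree(
        taxa=taxa,
        species_of={t: sp for t, (sp, _) in zip(taxa, labels)},
        tree=tree,
        scale=scale,
    )


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Neighbor-joining tree from a fully defined K2P distance matrix.

    Supports are left unset; see :func:`bootstrap_supports` to fill them.
    """
    if not dm.defined.all():
        raise UndefinedDistanceError(
            "distance matrix contains undefined pairs; remove or re-sequence the "
            "affected records (or relax min_overlap) before tree building"
        )
    root = _neighbor_joining(dm.values)
    return _support_tree_from_nj(root, dm.labels)


def bootstrap_supports(
    aln: LabeledAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> SupportTree:
    """NJ tree with bootstrap supports on its internal edges.

    Alignment columns are resampled with replacement ``n_replicates`` times;
    each internal edge of the original-data NJ tree gets support equal to the
    percentage of replicate NJ trees containing the same bipartition. A
    replicate whose resampled distance matrix has undefined pairs is redrawn;
    more than ``n_replicates / 2`` redraws in total aborts with an error.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    codes = aln.codes()
    labels = [(r.species, r.sample_id) for r in aln.records]
    dm = distance_matrix_from_codes(codes, labels, min_overlap=min_overlap)
    if not dm.defined.all():
        raise UndefinedDistanceError(
            "original alignment yields undefined distances; cannot bootstrap"
        )
    root = _neighbor_joining(dm.values)
    n = len(labels)
    orig_splits = _node_splits(root, n)
    counts = {s: 0 for s in orig_splits}

    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    redraws = 0
    for _ in range(n_replicates):
        while True:
            cols = rng.integers(0, L, size=L)
            rep_dm = distance_matrix_from_codes(
                codes[:, cols], labels, min_overlap=min_overlap
            )
            if rep_dm.defined.all():
                break
            redraws += 1
            if redraws > n_replicates / 2:
                raise UndefinedDistanceError(
                    f"more than {n_replicates // 2} bootstrap replicates had "
                    "undefined distances; the alignment is too gappy or saturated"
                )
        for s in orig_splits & _nj_splits(rep_dm.values):
            counts[s] += 1

    stree = _support_tree_from_nj(root, labels, scale="bootstrap")
    taxa = stree.taxa
    stree.supports = {
        frozenset(taxa[i] for i in split): 100.0 * c / n_replicates
        for split, c in counts.items()
    }
    return stree


# ---------------------------------------------------------------------------
# Monophyly scoring
# ---------------------------------------------------------------------------


@dataclass
class MonophylyReport:
    """Per-species monophyly/support status and the aggregate identification rate."""

    per_species: dict[str, dict]
    pct_correct_individuals: float
    support_cutoff: float
    singleton_mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, **info} for sp, info in sorted(self.per_species.items())
        ]
        return pd.DataFrame(rows)


def score_monophyly(
    tree: SupportTree,
    support_cutoff: float | None = None,
    singleton_mode: str = "count_incorrect",
    expected_labels: list[str] | None = None,
) -> MonophylyReport:
    """Score each species' monophyly on a support-annotated tree.

    A species with >= 2 individuals is monophyletic iff removing a single
    edge separates exactly its individuals from everything else, and
    *identified* iff that edge's support is strictly greater than
    ``support_cutoff`` (default 80 for bootstrap, 0.80 for posterior scale;
    an unannotated edge counts as support 0). Singleton species can never be
    identified by this test; ``singleton_mode`` controls whether their
    individuals stay in the denominator (``"count_incorrect"``, default) or
    are dropped from it (``"exclude"``).
    """
    if singleton_mode not in ("count_incorrect", "exclude"):
        raise ValidationError(f"unknown singleton_mode {singleton_mode!r}")
    if expected_labels is not None and set(expected_labels) != set(tree.taxa):
        missing = set(expected_labels) - set(tree.taxa)
        extra = set(tree.taxa) - set(expected_labels)
        raise TreeConsistencyError(
            f"tree leaves do not cover the dataset (missing {sorted(missing)}, "
            f"unexpected {sorted(extra)})"
        )
    if support_cutoff is None:
        support_cutoff = DEFAULT_CUTOFFS[tree.scale]

    groups: dict[str, set[str]] = {}
    for label in tree.taxa:
        groups.setdefault(tree.species_of[label], set()).add(label)

    n = len(tree.taxa)
    splits = tree.splits()
    per_species: dict[str, dict] = {}
    n_correct_ind = 0
    denom = 0
    for sp, members in groups.items():
        m = len(members)
        if m == 1:
            # Monophyly of a single leaf is vacuous; it cannot be identified.
            mono, supported, identified = True, False, False
        elif m >= n - 1:
            # Complement has <= 1 leaf: separated by a pendant edge (or the
            # whole tree), which is trivially present and not bootstrapped.
            mono, supported, identified = True, True, True
        else:
            split = frozenset(members)
            canon = _canonical(split, frozenset(tree.taxa), min(tree.taxa))
            mono = canon in splits
            sup = tree.support_of(split) if mono else None
            supported = mono and (sup or 0.0) > support_cutoff
            identified = supported
        per_species[sp] = {
            "n_individuals": m,
            "monophyletic": mono,
            "supported": supported,
            "identified": identified,
        }
        if identified:
            n_correct_ind += m
        if m > 1 or singleton_mode == "count_incorrect":
            denom += m

    pct = 100.0 * n_correct_ind / denom if denom else float("nan")
    return MonophylyReport(
        per_species=per_species,
        pct_correct_individuals=pct,
        support_cutoff=support_cutoff,
        singleton_mode=singleton_mode,
    )


# ---------------------------------------------------------------------------
# External trees
# ---------------------------------------------------------------------------


def read_newick_with_supports(
    path,
    scale: str = "bootstrap",
    header_pattern: str = r"^(?P<species>[^|]+)\|(?P<sample>[^|]+)$",
) -> SupportTree:
    """Read a support-annotated newick tree (e.g. from ML or Bayesian runs).

    Supports are taken from internal node labels and interpreted on the
    declared ``scale``; unannotated internal edges trigger a warning and are
    treated as support 0 during scoring. Leaf labels must follow the
    ``species|sample_id`` convention (configurable via ``header_pattern``).
    """
    import re

    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    pattern = re.compile(header_pattern)
    taxa = []
    species_of = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        m = pattern.match(label)
        if not m:
            raise TreeConsistencyError(
                f"leaf label {label!r} does not match pattern {header_pattern!r}"
            )
        taxa.append(label)
        species_of[label] = m.group("species")

    n = len(taxa)
    supports: dict[frozenset[str], float | None] = {}
    leafsets: dict[dendropy.Node, frozenset[str]] = {}
    unannotated = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
            continue
        side = frozenset().union(*(leafsets[ch] for ch in node.child_nodes()))
        leafsets[node] = side
        if 2 <= len(side) <= n - 2:
            sup = None
            if node.label is not None and node.label != "":
                try:
                    sup = float(node.label)
                except ValueError as exc:
                    raise TreeConsistencyError(
                        f"internal node label {node.label!r} is not a numeric support"
                    ) from exc
            if sup is None:
                unannotated += 1
            supports[side] = sup
    if unannotated:
        warnings.warn(
            f"{unannotated} internal edge(s) lack support annotations; "
            "they will be treated as support 0 when scoring",
            stacklevel=2,
        )
    return SupportTree(
        taxa=taxa, species_of=species_of, tree=tree, scale=scale, supports=supports
    )
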