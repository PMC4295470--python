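"""Poisson-corrected distances, neighbor-joining, bootstrap supports and
reference-panel subfamily assignment.

Distances are amino-acid substitutions per site under the Poisson
correction d = −ln(1 − p), assuming rate uniformity among sites.  Trees are
built by the Saitou–Nei neighbor-joining agglomeration on the Q criterion;
ties are broken by the smallest (i, j) index pair under input label order,
and negative branch-length estimates are clamped to zero (raw values
logged).  Bootstrap supports are percentages of column-resampled replicates
containing each internal bipartition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import ProteinAlignment
from .records import SeqRecord

logger = logging.getLogger(__name__)


class DistanceError(ValueError):
    """Raised when a pairwise distance is undefined."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def poisson_distance(aln: ProteinAlignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Poisson-corrected amino-acid distance matrix.

    ``deletion`` is ``pairwise`` (default: each pair compared over columns
    where both are gap-free) or ``complete`` (only columns gap-free in all
    records are used).  p ≥ 1 or zero comparable columns for a pair is an
    error naming the pair.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    rows = [r.residues for r in aln.records]
    labels = tuple(aln.ids)
    n = len(rows)
    if deletion == "complete":
        keep = [c for c in range(aln.n_columns) if all(row[c] != "-" for row in rows)]
        rows = ["".join(row[c] for c in keep) for row in rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = diffs = 0
            for x, y in zip(rows[i], rows[j]):
                if x == "-" or y == "-":
                    continue
                compared += 1
                if x != y:
                    diffs += 1
            if compared == 0:
                raise DistanceError(
                    f"pair ({labels[i]}, {labels[j]}): no comparable columns"
                )
            p = diffs / compared
            if p >= 1:
                raise DistanceError(
                    f"pair ({labels[i]}, {labels[j]}): p = {p:.3f} >= 1, "
                    "Poisson distance undefined"
                )
            d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class TreeNode:
    """A node of an (unrooted, trifurcating-root) phylogenetic tree."""

    label: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # % of bootstrap replicates, internal nodes
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.label for lf in self.leaves()]


@dataclass
class PhyloTree:
    """Leaf-labeled unrooted tree with branch lengths and optional supports."""

    root: TreeNode
    labels: tuple[str, ...]

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions, keyed by the canonical side (the side
        not containing the alphabetically first leaf)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}

        def visit(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(visit(c) for c in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                key = below if anchor not in below else all_leaves - below
                out[key] = node
            return below

        for child in self.root.children:
            visit(child)
        return out

    def topology_key(self) -> frozenset[frozenset[str]]:
        return frozenset(self.bipartitions().keys())

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        labels = tuple(sorted(self.leaf_names()))
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def fill(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            child_maps = []
            for c in node.children:
                cm = {k: v + c.length for k, v in fill(c).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, va in child_maps[a].items():
                        for lb, vb in child_maps[b].items():
                            i, j = index[la], index[lb]
                            d[i, j] = d[j, i] = va + vb
            merged = {}
            for cm in child_maps:
                merged.update(cm)
            return merged

        fill(self.root)
        return DistanceMatrix(labels=labels, d=d)

    def to_newick(self) -> str:
        """Newick string with bootstrap supports as internal node labels."""
        import dendropy

        taxa = dendropy.TaxonNamespace(sorted(self.leaf_names()))
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(node: TreeNode, dnode) -> None:
            for c in node.children:
                dchild = dnode.new_child(edge_length=round(c.length, 10))
                if c.is_leaf:
                    dchild.taxon = taxa.get_taxon(c.label)
                else:
                    if c.support is not None:
                        dchild.label = f"{c.support:g}"
                    build(c, dchild)

        build(self.root, tree.seed_node)
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Deterministic: Q-minimising pair with ties broken by the smallest
    (i, j) index pair under input label order; negative branch-length
    estimates are clamped to zero with the raw value logged.  Requires at
    least 3 labels.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n0))
    dist = {(i, j): d[i, j] for i in range(n0) for j in range(n0)}
    next_id = n0
    node_of = {i: nodes[i] for i in range(n0)}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    def put(i: int, j: int, v: float) -> None:
        dist[(min(i, j), max(i, j))] = v

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.6g at %s clamped to 0", x, context)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)), f"join({i},{j})")
        lj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))), f"join({i},{j})")
        parent = TreeNode()
        ci, cj = node_of[i], node_of[j]
        ci.length, cj.length = li, lj
        parent.children = [ci, cj]
        u = next_id
        next_id += 1
        node_of[u] = parent
        for k in active:
            if k in (i, j):
                continue
            put(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    # final three nodes: closed-form lengths around the trifurcating root
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = clamp(0.5 * (dab + dac - dbc), "final")
    lb = clamp(0.5 * (dab + dbc - dac), "final")
    lc = clamp(0.5 * (dac + dbc - dab), "final")
    root = TreeNode()
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        child = node_of[idx]
        child.length = ln
        root.children.append(child)
    return PhyloTree(root=root, labels=dm.labels)


def bootstrap_support(
    aln: ProteinAlignment,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """NJ tree with bootstrap supports.

    Alignment columns are resampled with replacement per replicate;
    replicates whose Poisson distance is undefined are dropped and counted
    (an error if more than 10% drop).  Supports are the percentage of kept
    replicates containing each internal bipartition of the point-estimate
    tree.  Reproducible given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = nj_tree(poisson_distance(aln, deletion))
    biparts = point.bipartitions()
    counts = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    n_cols = aln.n_columns
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        recs = tuple(
            SeqRecord(id=r.id, residues="".join(r.residues[c] for c in cols),
                      alphabet="aa", aligned=True)
            for r in aln.records
        )
        try:
            rep_tree = nj_tree(poisson_distance(ProteinAlignment(recs), deletion))
        except DistanceError as exc:
            dropped += 1
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        rep_keys = rep_tree.topology_key()
        for key in counts:
            if key in rep_keys:
                counts[key] += 1
    if dropped > 0.10 * replicates:
        raise DistanceError(
            f"{dropped}/{replicates} bootstrap replicates dropped (>10%)"
        )
    kept = replicates - dropped
    for key, node in biparts.items():
        node.support = 100.0 * counts[key] / kept if kept else 0.0
    return point


@dataclass(frozen=True)
class GroupAssignment:
    """Sequence → subfamily labels derived from supported clades."""

    labels: dict[str, str]  # query id -> subfamily or "uncertain"
    support: dict[str, float | None]
    nearest_references: dict[str, tuple[str, ...]]


def assign_groups(
    tree: PhyloTree,
    reference_labels: Mapping[str, str],
    min_support: float = 70.0,
) -> GroupAssignment:
    """Assign each query leaf to a subfamily by its smallest supported
    enclosing clade.

    A query receives subfamily S iff the smallest clade with support ≥
    ``min_support`` containing it has reference leaves of S only; a mixed
    or absent supported clade yields ``uncertain``.
    """
    leaf_set = frozenset(tree.leaf_names())
    refs = {r for r in reference_labels if r in leaf_set}
    if not refs:
        raise ValueError("tree contains no reference leaves")
    sides: list[tuple[frozenset[str], float | None]] = []
    for key, node in tree.bipartitions().items():
        sides.append((key, node.support))
        sides.append((leaf_set - key, node.support))
    labels: dict[str, str] = {}
    support: dict[str, float | None] = {}
    nearest: dict[str, tuple[str, ...]] = {}
    queries = [l for l in tree.leaf_names() if l not in reference_labels]
    for q in queries:
        chosen: str = "uncertain"
        chosen_support: float | None = None
        chosen_refs: tuple[str, ...] = ()
        candidates = [
            (len(side), side, sup) for side, sup in sides
            if q in side and sup is not None and sup >= min_support
        ]
        candidates.sort(key=lambda t: t[0])
        for _, side, sup in candidates:
            side_refs = side & refs
            if not side_refs:
                continue
            families = {reference_labels[r] for r in side_refs}
            if len(families) == 1:
                chosen = families.pop()
                chosen_support = sup
                chosen_refs = tuple(sorted(side_refs))
            break  # smallest supported clade with references decides
        labels[q] = chosen
        support[q] = chosen_support
        nearest[q] = chosen_refs
    return GroupAssignment(labels=labels, support=support, nearest_references=nearest)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# Poisson-corrected distances, substitutions per site\n")
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for i, l in enumerate(dm.labels):
            fh.write(l + "\t" + "\t".join(f"{x:.6f}" for x in dm.d[i]) + "\n")


def read_reference_panel(path) -> dict[str, str]:
    """Reference panel TSV: id, subfamily (``#`` comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise ValueError(f"reference panel row needs 2 columns: {ln!r}")
            out[parts[0]] = parts[1]
    return out
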