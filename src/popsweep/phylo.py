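"""Individual-level population structure: p-distance, NJ tree, PCA.

Distances are allele-sharing p-distances on unphased diploid dosages:
``d(i,j) = Σ|g_i − g_j| / (2·n)`` over the sites called in both samples,
so identical genotypes give 0 and opposite homozygotes across all sites
give 1.  Trees are built with the Saitou–Nei neighbor-joining algorithm,
which reconstructs additive distance matrices exactly, and supports come
from resampling sites with replacement.  PCA uses Patterson scaling
(per-site centering and division by √(p̂(1−p̂))) with mean imputation of
missing dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-site counts."""

    ids: list[str]
    values: np.ndarray
    n_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


def p_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing p-distance over pairwise-complete sites.

    Raises if any pair of samples shares no called site.  Triangle-
    inequality violations (possible with missing data, since pairs use
    different site sets) are counted and logged, not rejected.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    d = matrix.dosages.astype(float)
    d[matrix.dosages == MISSING] = np.nan
    n = matrix.n_samples
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(d[i]) & ~np.isnan(d[j])
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no called site"
                )
            values[i, j] = values[j, i] = (
                np.abs(d[i, both] - d[j, both]).sum() / (2.0 * m)
            )
            counts[i, j] = counts[j, i] = m

    viol = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(values[i] + values[j] < values[i, j] - 1e-12):
                viol += 1
    if viol:
        logger.warning(
            "p-distance: %d pairs violate the triangle inequality "
            "(expected with missing data)", viol
        )
    return DistanceMatrix(list(matrix.samples), values, counts)


def to_phylip(dm: DistanceMatrix) -> str:
    """PHYLIP square-format serialization."""
    lines = [f"{len(dm.ids)}"]
    for name, row in zip(dm.ids, dm.values):
        lines.append(name + "  " + "  ".join(f"{x:.8f}" for x in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Node of an (unrooted, stored root-trifurcating) NJ tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei agglomeration with the Q-criterion.

    Ties in Q are broken by the lexicographically smallest active index
    pair, making the output deterministic.  Negative branch lengths are
    clamped to zero with the excess moved to the sibling edge (the raw
    values are logged at DEBUG level).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    D = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))

    def _clamped(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            logger.debug("clamping negative branch length %g", li)
            lj += li
            li = 0.0
        if lj < 0:
            logger.debug("clamping negative branch length %g", lj)
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: scan in order
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if best is None or Q[a, b] < Q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (R[a] - R[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _clamped(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lengths = [max(x, 0.0) for x in (li, lj, lk)]
    if min(li, lj, lk) < 0:
        logger.debug("clamping negative terminal branch length")
    root = TreeNode(
        children=[(nodes[i], lengths[0]), (nodes[j], lengths[1]), (nodes[k], lengths[2])]
    )
    return root


def tree_distance_matrix(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix (the additivity oracle)."""
    index = {name: i for i, name in enumerate(ids)}
    n = len(ids)
    out = np.zeros((n, n))

    def pair_distances(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for child, length in node.children:
            sub = pair_distances(child)
            below.append({k: v + length for k, v in sub.items()})
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for na, da in below[x].items():
                    for nb, db in below[y].items():
                        out[index[na], index[nb]] = out[index[nb], index[na]] = da + db
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    pair_distances(tree)
    return out


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: TreeNode, all_leaves: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions (one side each) of an unrooted tree."""
    parts: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below
            other = all_leaves - side
            parts.add(min(side, other, key=lambda s: tuple(sorted(s))))
        return below

    for child, _ in tree.children:
        walk(child)
    return parts


def bootstrap_supports(
    matrix: GenotypeMatrix, n_replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """Point-estimate NJ tree with site-resampling bootstrap supports.

    Sites are resampled with replacement *n_replicates* times; each
    internal edge of the point tree gets the percentage of replicate trees
    containing the same leaf bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be ≥ 1")
    if matrix.n_variants < 3:
        raise ValueError("need at least three sites for bootstrapping")
    tree = neighbor_joining(p_distance(matrix))
    all_leaves = frozenset(matrix.samples)
    counts: dict[frozenset[str], int] = {
        bp: 0 for bp in _bipartitions(tree, all_leaves)
    }
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, matrix.n_variants, size=matrix.n_variants)
        rep = matrix.take_variants(idx)
        try:
            rep_tree = neighbor_joining(p_distance(rep))
        except ValueError:
            continue  # replicate with an all-missing pair: uninformative
        rep_parts = _bipartitions(rep_tree, all_leaves)
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            key = min(below, all_leaves - below, key=lambda s: tuple(sorted(s)))
            node.support = 100.0 * counts.get(key, 0) / n_replicates
        return below

    for child, _ in tree.children:
        annotate(child)
    return tree


# ---------------------------------------------------------------------------
# Newick


def to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths and integer supports as inner labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(f"{fmt(c)}:{length:.10g}" for c, length in node.children)
        label = "" if node.support is None else f"{round(node.support):d}"
        return f"({inner}){label}"

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    ids: list[str]
    coordinates: np.ndarray  # samples × components
    eigenvalues: np.ndarray  # non-increasing
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Genotype PCA with Patterson scaling.

    Missing dosages are imputed to the site mean (so they contribute
    nothing after centering); monomorphic sites are dropped; each site is
    scaled by √(p̂(1−p̂)).  Components follow a deterministic sign
    convention: the sample coordinate of largest magnitude is positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    g = matrix.dosages.astype(float)
    g[matrix.dosages == MISSING] = np.nan
    site_mean = np.nanmean(g, axis=0)
    p_hat = site_mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("all sites are monomorphic")
    g = g[:, poly]
    site_mean = site_mean[poly]
    p_hat = p_hat[poly]
    inds = np.where(np.isnan(g))
    g[inds] = site_mean[inds[1]]
    x = (g - site_mean) / np.sqrt(p_hat * (1.0 - p_hat))
    x /= np.sqrt(x.shape[1])  # normalize by number of sites
    cov = x @ x.T
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for c in range(k):
        imax = int(np.argmax(np.abs(coords[:, c])))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    total = float(eigval.sum())
    return PCAResult(
        ids=list(matrix.samples),
        coordinates=coords,
        eigenvalues=eigval[:k],
        variance_explained=eigval[:k] / total if total > 0 else eigval[:k],
    )
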