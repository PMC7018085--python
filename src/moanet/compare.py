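"""Geometry of MoA sets.

Each MoA is a point in protein-signal space (one coordinate per network
protein, the full row of the ensemble matrix).  Sets of MoAs are compared
with the Dubuisson–Jain modified Hausdorff distance (the max-of-means
variant they recommend),

    d(A, B) = max( mean_a min_b ||a - b||, mean_b min_a ||a - b|| ),

which is symmetric and zero iff the sets coincide pointwise, but does NOT
satisfy the triangle inequality in general.  Within-group spread is the mean
Euclidean distance of points to their centroid.  Group-level structure is
summarised by a UPGMA (average-linkage) dendrogram with a deterministic
lexicographic tie-break, and MoA-level structure by a classical (Torgerson)
MDS embedding with a fixed sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import MoA

__all__ = [
    "MoAPointCloud",
    "mhd",
    "dispersion",
    "TreeNode",
    "group_dendrogram",
    "to_newick",
    "classical_mds",
    "mds_embed",
]


@dataclass(frozen=True)
class MoAPointCloud:
    """MoA signal vectors over a fixed, ordered protein list."""

    ids: tuple[int, ...]
    matrix: np.ndarray           # shape (n_points, n_proteins)
    protein_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "protein_order", tuple(self.protein_order))
        if m.ndim != 2 or m.shape != (len(self.ids), len(self.protein_order)):
            raise ValueError("matrix shape must be (n_points, n_proteins)")
        if not np.all(np.isfinite(m)):
            raise ValueError("point cloud contains non-finite values")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_moas(
        cls,
        moas: Sequence[MoA],
        proteins: Sequence[str] | None = None,
        ids: Sequence[int] | None = None,
    ) -> "MoAPointCloud":
        """Build a cloud from MoAs; by default over all proteins, sorted.

        ``proteins`` restricts the coordinates (e.g. to an effector subset).
        """
        if not moas:
            raise ValueError("need at least one MoA")
        order = tuple(proteins) if proteins is not None else tuple(sorted(moas[0].signals))
        mat = np.array([[m.signals[p] for p in order] for m in moas])
        use_ids = tuple(ids) if ids is not None else tuple(m.seed for m in moas)
        return cls(ids=use_ids, matrix=mat, protein_order=order)

    def subset(self, keep_ids: set[int]) -> "MoAPointCloud":
        rows = [k for k, i in enumerate(self.ids) if i in keep_ids]
        if not rows:
            raise ValueError("no matching ids in cloud")
        return MoAPointCloud(
            ids=tuple(self.ids[k] for k in rows),
            matrix=self.matrix[rows],
            protein_order=self.protein_order,
        )


def _check_pair(a: MoAPointCloud, b: MoAPointCloud) -> None:
    if a.protein_order != b.protein_order:
        raise ValueError("point clouds span different protein orders")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point clouds must be non-empty")


def mhd(a: MoAPointCloud, b: MoAPointCloud) -> float:
    """Dubuisson–Jain modified Hausdorff distance between two MoA sets."""
    _check_pair(a, b)
    d = cdist(a.matrix, b.matrix)
    return float(max(d.min(axis=1).mean(), d.min(axis=0).mean()))


def dispersion(a: MoAPointCloud) -> float:
    """Mean Euclidean distance of the points to their centroid."""
    if len(a) == 0:
        raise ValueError("point cloud must be non-empty")
    centroid = a.matrix.mean(axis=0)
    return float(np.linalg.norm(a.matrix - centroid, axis=1).mean())


@dataclass(frozen=True)
class TreeNode:
    """Dendrogram node; leaves have a name and no children."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def leaves(self) -> tuple[str, ...]:
        if not self.children:
            return (self.name,)
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves)
        return tuple(out)


def group_dendrogram(names: Sequence[str], distances: np.ndarray) -> TreeNode:
    """UPGMA tree over named groups from a symmetric distance matrix.

    At each step the closest pair of clusters merges at height equal to
    their average-linkage distance (arithmetic mean of all between-cluster
    leaf distances); distance ties are broken by the lexicographically
    smallest (leaf-name) pair so the tree is deterministic.
    """
    D = np.asarray(distances, dtype=np.float64)
    n = len(names)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if n == 0:
        raise ValueError("need at least one group")
    clusters: dict[tuple[str, ...], tuple[TreeNode, list[int]]] = {
        (nm,): (TreeNode(height=0.0, name=nm), [i]) for i, nm in enumerate(names)
    }
    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        keys = sorted(clusters)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                ia, ib = clusters[ka][1], clusters[kb][1]
                d = float(D[np.ix_(ia, ib)].mean())
                cand = (d, ka, kb)
                if best is None or cand < best:
                    best = cand
        d, ka, kb = best
        (ta, ia), (tb, ib) = clusters.pop(ka), clusters.pop(kb)
        merged_key = tuple(sorted(ka + kb))
        children = tuple(sorted((ta, tb), key=lambda t: t.leaves))
        clusters[merged_key] = (TreeNode(height=d, children=children), ia + ib)
    return next(iter(clusters.values()))[0]


def to_newick(tree: TreeNode) -> str:
    """Serialise a dendrogram as a Newick string with branch lengths."""

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if not node.children:
            return f"{node.name}:{length:.6g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:.6g}"

    if not tree.children:
        return f"{tree.name};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def classical_mds(points: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a point matrix.

    Double-centres the squared Euclidean distance matrix, eigendecomposes,
    and returns (coordinates, all eigenvalues sorted descending).  Axes are
    ordered by decreasing eigenvalue; each axis's sign is fixed so its first
    nonzero loading is positive.
    """
    X = np.asarray(points, dtype=np.float64)
    n = X.shape[0]
    if n < dims + 1:
        raise ValueError(f"need >= {dims + 1} points for a {dims}-D embedding")
    sq = cdist(X, X) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-12 * max(abs(eigval[0]), 1.0))
    # zero eigenvalues contribute zero coordinates (e.g. collinear points in
    # 2-D); only a genuinely negative eigenvalue cannot back an axis
    if eigval[dims - 1] < -tol:
        n_pos = int(np.sum(eigval > tol))
        raise ValueError(
            f"only {n_pos} non-negative eigenvalues available for {dims} "
            f"dimensions; spectrum: {np.round(eigval, 10).tolist()}"
        )
    coords = eigvec[:, :dims] * np.sqrt(np.clip(eigval[:dims], 0.0, None))
    for k in range(dims):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords, eigval


def mds_embed(cloud: MoAPointCloud, dims: int = 2) -> dict[int, np.ndarray]:
    """2-D (by default) Torgerson embedding of the MoAs, keyed by MoA id."""
    coords, _ = classical_mds(cloud.matrix, dims=dims)
    return {i: coords[k] for k, i in enumerate(cloud.ids)}
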