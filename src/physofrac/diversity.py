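"""Alpha diversity, Bray-Curtis, UniFrac and principal coordinates.

UniFrac is computed from per-branch descendant mass: for each branch of the
rooted phylogeny, the summed relative abundance of the leaves below it.
Weighted UniFrac is the branch-length-weighted L1 difference of those masses;
unweighted UniFrac is the Jaccard-type ratio on branch presence.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .exceptions import InvalidArgument

METRICS = ("weighted_unifrac", "unweighted_unifrac", "bray_curtis")


# ---------------------------------------------------------------------------
# tree flattening
# ---------------------------------------------------------------------------

@dataclass
class TreeIndex:
    """Postorder arrays for fast repeated branch-mass computation.

    Branch i connects node i to parent[i]; the root carries no branch and is
    the last node in postorder. leaf_rows maps each taxon to its node index.
    """

    taxa: list
    parent: np.ndarray  # node index -> parent node index
    lengths: np.ndarray  # branch length per node (0.0 for root)
    leaf_rows: np.ndarray  # taxon position -> node index
    n_nodes: int

    @classmethod
    def from_tree(cls, tree: TreeNode) -> "TreeIndex":
        nodes = list(tree.postorder(include_self=True))
        idx = {id(n): i for i, n in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=np.int64)
        lengths = np.zeros(len(nodes))
        taxa, leaf_rows = [], []
        for i, node in enumerate(nodes):
            parent[i] = idx[id(node.parent)] if node.parent is not None else -1
            if node.parent is not None:
                if node.length is None:
                    raise InvalidArgument("tree has branches without lengths")
                lengths[i] = node.length
            if node.is_tip():
                taxa.append(node.name)
                leaf_rows.append(i)
        return cls(taxa=taxa, parent=parent, lengths=lengths,
                   leaf_rows=np.asarray(leaf_rows), n_nodes=len(nodes))

    def mass_matrix(self, abundances: np.ndarray) -> np.ndarray:
        """Per-branch descendant mass for each column of `abundances`.

        abundances: (n_taxa, n_samples), taxa ordered as self.taxa.
        Returns (n_nodes, n_samples); the root row equals the column sums.
        """
        n_samples = abundances.shape[1]
        mass = np.zeros((self.n_nodes, n_samples))
        mass[self.leaf_rows] = abundances
        for i in range(self.n_nodes - 1):  # postorder: children before parents
            mass[self.parent[i]] += mass[i]
        return mass


def branch_mass(tree: TreeNode, abundances) -> pd.Series:
    """Per-branch descendant proportion for one sample.

    abundances: mapping or Series taxon -> relative abundance (sums to 1).
    Returns a Series indexed by branch (child node name or postorder index).
    """
    index = TreeIndex.from_tree(tree)
    vec = _align(abundances, index.taxa)
    mass = index.mass_matrix(vec[:, None])[:, 0]
    if not np.isclose(mass[-1], 1.0, atol=1e-9):
        raise InvalidArgument(f"abundances sum to {mass[-1]}, expected 1")
    return pd.Series(mass, index=np.arange(index.n_nodes))


def _align(abundances, taxa) -> np.ndarray:
    if isinstance(abundances, pd.Series):
        missing = set(abundances.index) - set(taxa)
        if missing:
            raise InvalidArgument(f"taxa absent from tree: {sorted(missing)[:5]}")
        return abundances.reindex(taxa, fill_value=0.0).to_numpy(dtype=float)
    vec = np.asarray(abundances, dtype=float)
    if vec.shape[0] != len(taxa):
        raise InvalidArgument("abundance vector length does not match tree leaves")
    return vec


def _as_relative(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise InvalidArgument("zero-total sample")
    return v / total


# ---------------------------------------------------------------------------
# pairwise metrics
# ---------------------------------------------------------------------------

def weighted_unifrac(tree: TreeNode, A, B, normalized: bool = False) -> float:
    """Weighted UniFrac between two relative-abundance vectors.

    raw: sum_b l_b |pA_b - pB_b|; normalized divides by sum_b l_b (pA_b + pB_b).
    """
    index = TreeIndex.from_tree(tree)
    a = _as_relative(_align(A, index.taxa))
    b = _as_relative(_align(B, index.taxa))
    mass = index.mass_matrix(np.column_stack([a, b]))
    diff = float(np.sum(index.lengths * np.abs(mass[:, 0] - mass[:, 1])))
    if not normalized:
        return diff
    denom = float(np.sum(index.lengths * (mass[:, 0] + mass[:, 1])))
    return diff / denom if denom > 0 else 0.0


def unweighted_unifrac(tree: TreeNode, A, B) -> float:
    """Unweighted UniFrac: unique branch length / total covered branch length."""
    index = TreeIndex.from_tree(tree)
    a = _align(A, index.taxa) > 0
    b = _align(B, index.taxa) > 0
    if not a.any() or not b.any():
        raise InvalidArgument("zero-total sample")
    mass = index.mass_matrix(np.column_stack([a, b]).astype(float)) > 0
    either = mass[:, 0] | mass[:, 1]
    one_only = mass[:, 0] ^ mass[:, 1]
    total = float(np.sum(index.lengths[either]))
    if total == 0:
        return 0.0
    return float(np.sum(index.lengths[one_only])) / total


def bray_curtis(A, B) -> float:
    """Bray-Curtis dissimilarity on relative abundances."""
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgument("vectors must have equal length")
    a = _as_relative(a)
    b = _as_relative(b)
    return float(np.abs(a - b).sum() / (a + b).sum())


# ---------------------------------------------------------------------------
# sample-set computations
# ---------------------------------------------------------------------------

def distance_matrix(abundance: pd.DataFrame, metric: str,
                    tree: TreeNode | None = None,
                    normalized: bool = False) -> DistanceMatrix:
    """All pairwise distances between the rows of a samples x taxa
    relative-abundance DataFrame."""
    if metric not in METRICS:
        raise InvalidArgument(f"metric must be one of {METRICS}")
    ids = list(abundance.index)
    X = abundance.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = [ids[i] for i in np.where(totals <= 0)[0]]
        raise InvalidArgument(f"zero-total samples: {bad[:5]}")
    X = X / totals[:, None]
    n = len(ids)
    D = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
            s = (X[i] + X[i + 1:]).sum(axis=1)
            D[i, i + 1:] = diff / s
    else:
        if tree is None:
            raise InvalidArgument(f"{metric} requires a phylogeny")
        index = TreeIndex.from_tree(tree)
        aligned = abundance.div(abundance.sum(axis=1), axis=0)
        mat = np.zeros((len(index.taxa), n))
        col_pos = {t: j for j, t in enumerate(abundance.columns)}
        missing = set(abundance.columns) - set(index.taxa)
        if missing:
            raise InvalidArgument(f"taxa absent from tree: {sorted(missing)[:5]}")
        for row, taxon in enumerate(index.taxa):
            j = col_pos.get(taxon)
            if j is not None:
                mat[row] = aligned.iloc[:, j].to_numpy()
        mass = index.mass_matrix(mat)
        lengths = index.lengths
        if metric == "weighted_unifrac":
            for i in range(n):
                diff = np.sum(lengths[:, None] * np.abs(mass[:, [i]] - mass[:, i + 1:]), axis=0)
                if normalized:
                    denom = np.sum(lengths[:, None] * (mass[:, [i]] + mass[:, i + 1:]), axis=0)
                    diff = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
                D[i, i + 1:] = diff
        else:
            pres = mass > 0
            for i in range(n):
                either = pres[:, [i]] | pres[:, i + 1:]
                one = pres[:, [i]] ^ pres[:, i + 1:]
                tot = np.sum(lengths[:, None] * either, axis=0)
                uniq = np.sum(lengths[:, None] * one, axis=0)
                D[i, i + 1:] = np.where(tot > 0, uniq / np.where(tot > 0, tot, 1.0), 0.0)
    D = D + D.T
    return DistanceMatrix(D, ids=ids)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Classical multidimensional scaling of a distance matrix."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing
    proportion_explained: np.ndarray  # per retained (positive) axis


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Gower-centered eigendecomposition of -0.5 * D^2.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; negative eigenvalues are reported, not corrected.
    """
    D = dm.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        import logging

        logging.getLogger(__name__).warning("all eigenvalues ~0: degenerate PCoA")
        coords = np.zeros((n, 1))
        return PCoAResult(pd.DataFrame(coords, index=list(dm.ids), columns=["PC1"]),
                          evals, np.zeros(1))
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    prop = evals[:keep] / evals[pos].sum()
    cols = [f"PC{i + 1}" for i in range(keep)]
    return PCoAResult(pd.DataFrame(coords, index=list(dm.ids), columns=cols), evals, prop)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon index H = -sum q ln q over nonzero proportions (nats)."""
    v = np.asarray(counts, dtype=float)
    total = v.sum()
    if total <= 0:
        raise InvalidArgument("zero-total sample")
    q = v[v > 0] / total
    return float(-(q * np.log(q)).sum())


def alpha_diversity(table, rarefy_depth: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Per-sample Shannon index, optionally on counts rarefied to a common depth."""
    from .preprocess import rarefy

    if rarefy_depth is not None:
        table = rarefy(table, depth=rarefy_depth, seed=seed)
    rows = [{"sample_id": s,
             "shannon": shannon(table.counts.loc[s].to_numpy()),
             "rarefy_depth": rarefy_depth if rarefy_depth is not None else np.nan}
            for s in table.sample_ids]
    return pd.DataFrame(rows).set_index("sample_id")
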