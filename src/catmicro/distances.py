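"""Beta-diversity distance matrices.

Bray-Curtis and Jaccard operate on the count table alone; the UniFrac family
additionally uses a rooted phylogeny with branch lengths. All functions
return a :class:`DistanceMatrix` (symmetric, zero diagonal, nonnegative).

UniFrac is computed through a leaf-by-branch incidence matrix cached on the
tree, so that repeated calls on permuted copies of the same table — the
inner loop of the conditional association test — cost one sparse matrix
product and one pairwise reduction each.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from catmicro.data_model import CountTable, PhylogeneticTree

METRIC_NAMES = ("braycurtis", "jaccard", "unifrac", "wunifrac", "euclidean")


@dataclass
class DistanceMatrix:
    """Pairwise sample distances D with d_ij = d_ji >= 0, d_ii = 0."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite values")
        if np.any(v < 0):
            raise ValueError("distance matrix contains negative values")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix has a nonzero diagonal")
        np.fill_diagonal(v, 0.0)
        self.values = 0.5 * (v + v.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def _check_positive_totals(table: CountTable) -> None:
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on raw counts:
    d_ij = sum_k |z_ik - z_jk| / sum_k (z_ik + z_jk)."""
    _check_positive_totals(table)
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def jaccard(table: CountTable) -> DistanceMatrix:
    """Presence/absence Jaccard dissimilarity 1 - |intersection|/|union|."""
    _check_positive_totals(table)
    d = squareform(pdist(table.counts > 0, metric="jaccard"))
    return DistanceMatrix(list(table.sample_ids), d)


def euclidean(table) -> DistanceMatrix:
    """Plain Euclidean distance on a numeric table (the classical-ANOVA bridge)."""
    if isinstance(table, CountTable):
        values = table.counts.astype(float)
        ids = list(table.sample_ids)
    else:
        values = np.atleast_2d(np.asarray(table, dtype=float))
        if values.shape[0] == 1 and values.size > 1:
            values = values.T
        ids = [str(i) for i in range(values.shape[0])]
    d = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(ids, d)


def _branch_loads(
    table: CountTable, tree: PhylogeneticTree, matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mass descending through each branch, plus branch lengths.

    ``matrix`` is the n x m sample profile (presence or proportions). Errors
    if any feature with a nonzero column is absent from the tree.
    """
    incidence, lengths, present = tree.branch_matrix(table.feature_ids)
    used = np.asarray(matrix).any(axis=0)
    missing = used & ~present
    if np.any(missing):
        fid = table.feature_ids[int(np.argmax(missing))]
        raise ValueError(f"feature {fid!r} has nonzero counts but is not a tree leaf")
    loads = np.asarray(matrix) @ incidence  # dense (n x branches)
    return np.asarray(loads), lengths


def unifrac_unweighted(table: CountTable, tree: PhylogeneticTree) -> DistanceMatrix:
    """Unweighted UniFrac: branch length unique to one sample's support,
    divided by branch length spanned by either sample."""
    _check_positive_totals(table)
    loads, lengths = _branch_loads(table, tree, table.counts > 0)
    occupied = (loads > 0).astype(float)
    shared = (occupied * lengths) @ occupied.T  # sum of l_b over branches in both
    total = occupied @ lengths  # per-sample spanned length
    union = total[:, None] + total[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - shared / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)  # guard float residue when supports coincide
    return DistanceMatrix(list(table.sample_ids), d)


def unifrac_weighted(
    table: CountTable, tree: PhylogeneticTree, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac on per-sample proportions.

    Unnormalized (default): d_ij = sum_b l_b |p_i(b) - p_j(b)| where p(b) is
    the fraction of a sample's counts descending through branch b. The
    normalized variant divides by sum_b l_b (p_i(b) + p_j(b)).
    """
    loads, lengths = _branch_loads(table, tree, table.proportions())
    weighted = loads * lengths
    d = squareform(pdist(weighted, metric="cityblock"))
    if normalized:
        totals = weighted.sum(axis=1)
        denom = totals[:, None] + totals[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = d / denom
        d[denom == 0] = 0.0
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d)


def compute_distance(
    name: str,
    table: CountTable,
    tree: PhylogeneticTree | None = None,
    unifrac_normalized: bool = False,
) -> DistanceMatrix:
    """Dispatch a distance by name (see METRIC_NAMES)."""
    if name == "braycurtis":
        return bray_curtis(table)
    if name == "jaccard":
        return jaccard(table)
    if name == "euclidean":
        return euclidean(table)
    if name in ("unifrac", "wunifrac"):
        if tree is None:
            raise ValueError(f"metric {name!r} requires a phylogenetic tree")
        if name == "unifrac":
            return unifrac_unweighted(table, tree)
        return unifrac_weighted(table, tree, normalized=unifrac_normalized)
    raise ValueError(f"unknown distance metric {name!r}; choose from {METRIC_NAMES}")
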