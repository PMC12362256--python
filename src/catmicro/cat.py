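"""The conditional association test (CAT).

A taxon is conditionally null when the outcome is independent of it given
all other features. CAT probes this by destroying the taxon's sample
alignment — permuting the counts of its leaf descendants across samples —
while leaving every other feature untouched, then measuring how much the
global-association R^2 drops. If the taxon carries outcome information not
duplicated elsewhere in the community, the permuted datasets lose R^2; if
its signal is redundant, R^2 barely moves and the test does not reject.

Procedure, for a taxon t with leaf set L(t):

1. compute the distance matrix D from the original counts Z;
2. run the global engine (PERMANOVA or kernel score) to get R^2;
3. build B permuted tables Z^b by permuting the columns in L(t);
4. recompute D^b and the engine R^2_b for each;
5. report the empirical p-value for how often R^2_b reaches R^2.

The default p-value rule is add-one and tie-inclusive,
p = (1 + #{R^2_b >= R^2}) / (B + 1), which is valid at finite B and returns
p = 1 for a taxon whose permutation cannot change D. The strict rule
p = (1/B) #{R^2_b > R^2} is available as ``tie_rule='strict'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from hashlib import sha256
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from catmicro.data_model import CountTable, OutcomeSpec, PhylogeneticTree, TaxonomyTree
from catmicro.distances import METRIC_NAMES, compute_distance
from catmicro.global_tests import (
    build_design,
    double_center,
    mirkat_null_fit,
    projector,
)

logger = logging.getLogger(__name__)

TIE_RULES = ("add_one_tie_inclusive", "strict")
PERMUTE_MODES = ("per_column", "joint")


@dataclass
class CatResult:
    """Outcome of one conditional test."""

    taxon: str
    rank: str
    n_leaves: int
    r2_original: float
    r2_perm: np.ndarray
    p_value: float
    b: int
    seed: int | None
    tie_rule: str
    engine: str
    metrics: tuple[str, ...]

    @property
    def r2_perm_mean(self) -> float:
        return float(np.mean(self.r2_perm))

    def summary(self) -> dict:
        return {
            "taxon": self.taxon,
            "rank": self.rank,
            "n_leaves": self.n_leaves,
            "r2_original": self.r2_original,
            "r2_perm_mean": self.r2_perm_mean,
            "p_value": self.p_value,
            "B": self.b,
            "seed": self.seed,
        }


def leaf_descendants(tree: TaxonomyTree, taxon) -> list[str]:
    """Feature ids of the leaves at or below ``taxon`` (name, rank-qualified
    name, or TaxonomyNode)."""
    leaves = tree.leaves(taxon)
    if not leaves:
        raise KeyError(f"taxon {taxon!r} has no leaf descendants")
    return leaves


def permute_taxon(
    table: CountTable,
    leaves: Sequence[str] | np.ndarray,
    rng: np.random.Generator | int | None = None,
    mode: str = "per_column",
) -> CountTable:
    """Permute the selected leaf columns across samples.

    ``per_column`` (default) permutes each column independently; ``joint``
    applies one shared sample permutation to the whole block, preserving
    within-taxon correlation. Column multisets are preserved either way and
    unselected columns are returned bit-identical.
    """
    if mode not in PERMUTE_MODES:
        raise ValueError(f"unknown permute mode {mode!r}")
    idx = _leaf_indices(table, leaves)
    rng = np.random.default_rng(rng)
    counts = table.counts.copy()
    block = counts[:, idx]
    n, k = block.shape
    if mode == "joint":
        counts[:, idx] = block[rng.permutation(n)]
    else:
        perms = np.argsort(rng.random((n, k)), axis=0)
        counts[:, idx] = block[perms, np.arange(k)]
    return CountTable(list(table.sample_ids), list(table.feature_ids), counts)


def _leaf_indices(table: CountTable, leaves) -> np.ndarray:
    if len(leaves) == 0:
        raise ValueError("empty leaf set")
    arr = np.asarray(leaves)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.intp)
    return table.feature_index([str(x) for x in leaves])


def empirical_pvalue(
    r2_original: float, r2_perm: Sequence[float], tie_rule: str = "add_one_tie_inclusive"
) -> float:
    """Empirical p-value for the drop in R^2 under taxon permutation."""
    perm = np.asarray(r2_perm, dtype=float)
    if perm.size == 0:
        raise ValueError("r2_perm is empty")
    if tie_rule == "strict":
        return float(np.mean(perm > r2_original))
    if tie_rule == "add_one_tie_inclusive":
        return float((1 + np.sum(perm >= r2_original)) / (perm.size + 1))
    raise ValueError(f"unknown tie rule {tie_rule!r}; choose from {TIE_RULES}")


# ---------------------------------------------------------------------------
# Engines: map a permuted table to an R^2, with the outcome side fixed
# ---------------------------------------------------------------------------


def _make_r2_engine(
    outcome: OutcomeSpec,
    engine: str,
    covariates: pd.DataFrame | None,
) -> Callable[[np.ndarray], float]:
    """Build a G -> R^2 map. Everything outcome-side (design projectors or
    null-model residuals) is computed once: it never depends on the counts."""
    if engine == "permanova":
        if outcome.kind == "survival":
            raise ValueError("engine 'permanova' does not support survival outcomes; use 'mirkat'")
        cov = covariates if covariates is not None else outcome.covariates
        h_full = projector(build_design(outcome, covariates=cov))
        if cov is not None and len(pd.DataFrame(cov).columns) > 0:
            h_reduced = projector(build_design(None, covariates=cov))
        else:
            h_reduced = None

        def r2_of(g: np.ndarray) -> float:
            ss_total = float(np.trace(g))
            if ss_total == 0:
                raise ValueError("total sum of squares is zero")
            ss_among = float(np.sum(h_full * g))
            if h_reduced is not None:
                ss_among -= float(np.sum(h_reduced * g))
            return ss_among / ss_total

        return r2_of

    if engine == "mirkat":
        if outcome.kind == "categorical":
            raise ValueError("engine 'mirkat' does not support categorical outcomes; use 'permanova'")
        r, _phi = mirkat_null_fit(outcome, covariates=covariates)
        rr = float(r @ r)
        if rr == 0:
            raise ValueError("null-model residuals are identically zero")

        def r2_of(g: np.ndarray) -> float:
            tr_g = float(np.trace(g))
            if tr_g <= 0:
                raise ValueError("tr(G) must be positive")
            return float(r @ g @ r) / (tr_g * rr)

        return r2_of

    raise ValueError(f"unknown engine {engine!r}; choose 'permanova' or 'mirkat'")


def _r2_for_table(
    table: CountTable,
    metrics: Sequence[str],
    tree: PhylogeneticTree | None,
    unifrac_normalized: bool,
    r2_of: Callable[[np.ndarray], float],
) -> float:
    vals = []
    for metric in metrics:
        d = compute_distance(metric, table, tree=tree, unifrac_normalized=unifrac_normalized)
        g = double_center(-0.5 * d.values**2)
        vals.append(r2_of(g))
    return float(max(vals))


def cat_test(
    table: CountTable,
    tax_tree: TaxonomyTree,
    outcome: OutcomeSpec,
    taxon,
    metrics: Sequence[str] = ("braycurtis",),
    engine: str = "permanova",
    phylo_tree: PhylogeneticTree | None = None,
    covariates: pd.DataFrame | None = None,
    b: int = 999,
    rng: np.random.Generator | int | None = None,
    tie_rule: str = "add_one_tie_inclusive",
    permute_mode: str = "per_column",
    unifrac_normalized: bool = False,
) -> CatResult:
    """Run CAT for one taxon.

    ``metrics`` names one or more distances (``braycurtis``, ``jaccard``,
    ``unifrac``, ``wunifrac``, ``euclidean``); with several, the per-dataset
    maximum R^2 is used. ``engine`` is ``permanova`` (group/continuous
    designs; with covariates the partial R^2 of the outcome after covariates
    is used) or ``mirkat`` (continuous, binary, survival via the kernel
    score R^2 analogue).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    unknown = [m for m in metrics if m not in METRIC_NAMES]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; choose from {METRIC_NAMES}")
    if any(m in ("unifrac", "wunifrac") for m in metrics) and phylo_tree is None:
        raise ValueError("UniFrac metrics require a phylogenetic tree")
    if outcome.n != table.n_samples:
        raise ValueError(
            f"outcome has {outcome.n} samples but count table has {table.n_samples}"
        )

    node = tax_tree.find(taxon) if isinstance(taxon, str) else taxon
    leaves = leaf_descendants(tax_tree, node)
    idx = table.feature_index(leaves)

    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    r2_of = _make_r2_engine(outcome, engine, covariates)
    r2_original = _r2_for_table(table, metrics, phylo_tree, unifrac_normalized, r2_of)

    r2_perm = np.empty(b)
    for i in range(b):
        permuted = permute_taxon(table, idx, rng=rng, mode=permute_mode)
        r2_perm[i] = _r2_for_table(permuted, metrics, phylo_tree, unifrac_normalized, r2_of)

    return CatResult(
        taxon=node.name if node.name else node.path(),
        rank=node.rank,
        n_leaves=len(leaves),
        r2_original=r2_original,
        r2_perm=r2_perm,
        p_value=empirical_pvalue(r2_original, r2_perm, tie_rule),
        b=b,
        seed=int(seed) if seed is not None else None,
        tie_rule=tie_rule,
        engine=engine,
        metrics=tuple(metrics),
    )


def _taxon_substream(master_seed: int | None, taxon: str) -> np.random.Generator:
    """Reproducible per-taxon stream independent of evaluation order: the
    stream is keyed on the taxon name, so duplicates get identical results."""
    digest = int.from_bytes(sha256(str(taxon).encode()).digest()[:4], "big")
    entropy = [digest] if master_seed is None else [int(master_seed), digest]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def cat_test_many(
    table: CountTable,
    tax_tree: TaxonomyTree,
    outcome: OutcomeSpec,
    taxa: Sequence[str],
    seed: int | None = None,
    **settings,
) -> pd.DataFrame:
    """Run CAT on several taxa, one summary row each.

    Each taxon gets an independent RNG substream derived from ``seed`` and
    the taxon name, so results do not depend on list order. Per-taxon
    failures are recorded in the ``error`` column rather than raised.
    p-values are unadjusted; multiplicity control is left to the caller.
    """
    if len(taxa) == 0:
        raise ValueError("taxa list is empty")
    rows = []
    details: dict[str, CatResult] = {}
    for taxon in taxa:
        try:
            result = cat_test(
                table,
                tax_tree,
                outcome,
                taxon,
                rng=_taxon_substream(seed, taxon),
                **settings,
            )
            row = result.summary()
            row["taxon"] = str(taxon)
            row["seed"] = seed
            row["error"] = ""
            details[str(taxon)] = result
        except Exception as exc:  # recorded per-row, not fatal
            logger.warning("taxon %r failed: %s", taxon, exc)
            row = {
                "taxon": str(taxon),
                "rank": "",
                "n_leaves": 0,
                "r2_original": np.nan,
                "r2_perm_mean": np.nan,
                "p_value": np.nan,
                "B": settings.get("b", 999),
                "seed": seed,
                "error": str(exc),
            }
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["details"] = details
    return df
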