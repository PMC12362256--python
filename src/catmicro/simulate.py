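"""Synthetic microbiome data with controlled group differences.

The generator emulates a two-group 16S study: counts for each sample are
drawn from a Dirichlet-multinomial (DM) — per-sample composition
p ~ Dirichlet(theta * base), counts ~ Multinomial(depth, p) — over a highly
skewed base composition, and a group difference is constructed by
"spiking in" Poisson-distributed extra reads on the leaf ASVs of one chosen
taxon in group 1. With spike mean lambda = 0 the two groups are draws from
one DM distribution, which is the null scenario used for type-I-error
calibration.

Defaults mirror a melanoma immunotherapy cohort: 31 samples per group,
sequencing depth 48,765 reads per sample, DM concentration sum theta = 62,
and a log-normal base composition whose family-level shares are heavily
skewed (top family tens of percent, median around 0.01%). Trees and
taxonomies are generated synthetically so no external data is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from catmicro.data_model import (
    CountTable,
    OutcomeSpec,
    PhylogeneticTree,
    RANK_PREFIXES,
    TaxonomyTree,
)

DEFAULT_N_PER_GROUP = 31
DEFAULT_DEPTH = 48_765
DEFAULT_THETA = 62.0
DEFAULT_SKEW_SIGMA = 3.5
LAMBDA_GRID = (5, 10, 30, 50, 70)


@dataclass
class SimulationConfig:
    """Parameters of the two-group Dirichlet-multinomial spike-in design."""

    base_proportions: np.ndarray
    n_per_group: int = DEFAULT_N_PER_GROUP
    depth: int = DEFAULT_DEPTH
    theta: float = DEFAULT_THETA
    spiked_taxon: str | None = None
    lambda_: float = 0.0
    spike_mode: str = "per_asv"  # or "shared_draw": one draw per sample
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.base_proportions, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("base_proportions must be a 1-D vector of length >= 2")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("base_proportions must be nonnegative and sum to 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.spike_mode not in ("per_asv", "shared_draw"):
            raise ValueError(f"unknown spike_mode {self.spike_mode!r}")
        self.base_proportions = p


# ---------------------------------------------------------------------------
# Synthetic tree + taxonomy
# ---------------------------------------------------------------------------


def make_synthetic_tree(
    m: int, seed: int | None = None
) -> tuple[PhylogeneticTree, TaxonomyTree]:
    """Random rooted bifurcating tree with Exponential(1) branch lengths,
    plus a taxonomy obtained by cutting the tree at 7 nested depth quantiles.

    Each leaf ("ASV0001", ...) gets a full 7-rank lineage: for rank k the
    leaf's clade is its deepest ancestor no deeper than the k-th depth
    threshold, so clades at successive ranks are nested by construction.
    """
    if m < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    width = len(str(m))
    names = [f"ASV{i + 1:0{max(4, width)}d}" for i in range(m)]

    # random joins; each subtree remembers its newick string
    parent = list(range(2 * m - 1))
    children: dict[int, tuple[int, int]] = {}
    lengths = np.zeros(2 * m - 1)
    active = list(range(m))
    nxt = m
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b_ = active[i], active[j]
        children[nxt] = (a, b_)
        parent[a] = parent[b_] = nxt
        lengths[a] = rng.exponential(1.0)
        lengths[b_] = rng.exponential(1.0)
        active[i] = nxt
        active.pop(j)
        nxt += 1
    root = active[0]

    def newick(node: int) -> str:
        if node < m:
            return f"{names[node]}:{lengths[node]:.6f}"
        a, b_ = children[node]
        tail = "" if node == root else f":{lengths[node]:.6f}"
        return f"({newick(a)},{newick(b_)}){tail}"

    phylo = PhylogeneticTree.from_newick(newick(root) + ";")

    # taxonomy by nested depth cuts
    depth = np.zeros(2 * m - 1)

    def set_depths(node: int, d: float) -> None:
        depth[node] = d
        if node in children:
            for c in children[node]:
                set_depths(c, d + lengths[c])

    set_depths(root, 0.0)
    internal_depths = np.array([depth[v] for v in children])
    thresholds = np.quantile(internal_depths, [k / 8 for k in range(1, 8)])

    def ancestors(node: int) -> list[int]:
        chain = []
        while node != root:
            node = parent[node]
            chain.append(node)
        return chain[::-1]  # root first

    lineages: dict[str, str] = {}
    for leaf in range(m):
        chain = ancestors(leaf)
        parts = []
        for k, thr in enumerate(thresholds):
            eligible = [v for v in chain if depth[v] <= thr]
            clade = eligible[-1] if eligible else root
            parts.append(f"{RANK_PREFIXES[k]}T{clade}")
        lineages[names[leaf]] = "; ".join(parts)
    taxonomy = TaxonomyTree.from_lineages(lineages)
    return phylo, taxonomy


def make_base_composition(
    m: int,
    skew_sigma: float = DEFAULT_SKEW_SIGMA,
    seed: int | None = None,
    tax_tree: TaxonomyTree | None = None,
) -> tuple[np.ndarray, dict]:
    """Log-normal base composition on the simplex, plus achieved skew summary.

    If a taxonomy is supplied (with leaves named like the composition's
    implied ASV order), the summary reports the top and median family-level
    shares so a configuration matching a target skew profile can be chosen.
    """
    if m < 2:
        raise ValueError("need at least 2 features")
    if skew_sigma <= 0:
        raise ValueError("skew_sigma must be > 0")
    rng = np.random.default_rng(seed)
    masses = rng.lognormal(mean=0.0, sigma=skew_sigma, size=m)
    p = masses / masses.sum()
    summary: dict = {"top_feature_share": float(p.max()), "median_feature_share": float(np.median(p))}
    if tax_tree is not None:
        order = {fid: i for i, fid in enumerate(tax_tree.feature_ids)}
        if len(order) != m:
            raise ValueError("taxonomy leaf count does not match m")
        shares = []
        for fam in tax_tree.nodes_at_rank("family"):
            idx = [order[f] for f in fam.leaf_features()]
            shares.append(p[idx].sum())
        shares = np.sort(shares)[::-1]
        summary["n_families"] = len(shares)
        summary["top_family_share"] = float(shares[0])
        summary["median_family_share"] = float(np.median(shares))
    return p, summary


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig, tax_tree: TaxonomyTree
) -> tuple[CountTable, np.ndarray]:
    """Draw the two-group DM count table; returns (table, group labels 0/1).

    Group-0 sample totals equal ``depth`` exactly; the spike adds
    Poisson(lambda) reads per spiked leaf (``per_asv``) or one shared draw
    per sample (``shared_draw``) on top, so group-1 totals drift upward.
    """
    rng = np.random.default_rng(config.seed)
    m = len(config.base_proportions)
    if len(tax_tree.feature_ids) != m:
        raise ValueError("taxonomy leaf count does not match base_proportions length")
    feature_ids = tax_tree.feature_ids
    n = 2 * config.n_per_group
    alpha = config.theta * config.base_proportions
    counts = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(config.depth, p)
    groups = np.repeat([0, 1], config.n_per_group)

    if config.spiked_taxon is not None and config.lambda_ > 0:
        leaves = tax_tree.leaves(config.spiked_taxon)
        if not leaves:
            raise ValueError(f"spiked taxon {config.spiked_taxon!r} has no leaves")
        order = {fid: j for j, fid in enumerate(feature_ids)}
        idx = np.array([order[f] for f in leaves])
        g1 = np.where(groups == 1)[0]
        if config.spike_mode == "per_asv":
            counts[np.ix_(g1, idx)] += rng.poisson(config.lambda_, size=(len(g1), len(idx)))
        else:
            counts[np.ix_(g1, idx)] += rng.poisson(config.lambda_, size=(len(g1), 1))

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    return CountTable(sample_ids, list(feature_ids), counts), groups


def group_outcome(groups: np.ndarray, sample_ids=None) -> OutcomeSpec:
    """Wrap 0/1 group labels as a binary OutcomeSpec."""
    return OutcomeSpec(kind="binary", values=np.asarray(groups, dtype=float), sample_ids=sample_ids)


def pick_family_by_share(
    tax_tree: TaxonomyTree,
    base_proportions: np.ndarray,
    target_share: float = 0.03,
    min_leaves: int = 2,
) -> str:
    """Family whose base-composition share is closest to ``target_share``
    (mid-size spike target), among families with at least ``min_leaves``."""
    order = {fid: i for i, fid in enumerate(tax_tree.feature_ids)}
    best, best_gap = None, np.inf
    for fam in tax_tree.nodes_at_rank("family"):
        leaves = fam.leaf_features()
        if len(leaves) < min_leaves:
            continue
        share = base_proportions[[order[f] for f in leaves]].sum()
        gap = abs(share - target_share)
        if gap < best_gap:
            best, best_gap = fam, gap
    if best is None:
        raise ValueError(f"no family has >= {min_leaves} leaves")
    return f"family:{best.name}"


# ---------------------------------------------------------------------------
# Calibration / power study
# ---------------------------------------------------------------------------


def run_calibration_study(
    lambdas,
    n_datasets: int = 100,
    m: int = 200,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    depth: int = DEFAULT_DEPTH,
    theta: float = DEFAULT_THETA,
    skew_sigma: float = DEFAULT_SKEW_SIGMA,
    taxon: str | None = None,
    target_share: float = 0.03,
    metrics=("wunifrac",),
    engine: str = "permanova",
    b: int = 99,
    seed: int | None = None,
    alpha: float = 0.05,
    tie_rule: str = "add_one_tie_inclusive",
    permute_mode: str = "per_column",
    spike_mode: str = "per_asv",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rejection rates of the conditional test across a spike-strength grid.

    One synthetic tree and base composition are generated from ``seed`` and
    shared by all datasets (mirroring a fixed real phylogeny); each dataset
    draws fresh DM counts, spikes the taxon under test in group 1 when
    lambda > 0, and runs the conditional test on it. lambda = 0 is the null
    scenario: the rejection rate estimates the type-I error at ``alpha``.

    Returns (summary, detail): per-lambda rejection rate with binomial
    standard error, and per-dataset p-value / R^2 streams.
    """
    from catmicro.cat import cat_test

    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    master = np.random.SeedSequence(seed if seed is not None else 0)
    tree_seed, comp_seed, data_seed = master.spawn(3)
    phylo, taxonomy = make_synthetic_tree(m, seed=np.random.default_rng(tree_seed).integers(2**31))
    base, skew = make_base_composition(
        m, skew_sigma=skew_sigma, seed=np.random.default_rng(comp_seed).integers(2**31), tax_tree=taxonomy
    )
    if taxon is None:
        taxon = pick_family_by_share(taxonomy, base, target_share=target_share)

    detail_rows = []
    summary_rows = []
    for lam in np.atleast_1d(lambdas):
        streams = data_seed.spawn(n_datasets)  # spawning is stateful: fresh streams per lambda
        rejections = 0
        for ds, stream in enumerate(streams):
            rng = np.random.default_rng(stream)
            config = SimulationConfig(
                base_proportions=base,
                n_per_group=n_per_group,
                depth=depth,
                theta=theta,
                spiked_taxon=taxon if lam > 0 else None,
                lambda_=float(lam),
                spike_mode=spike_mode,
                seed=int(rng.integers(2**31)),
            )
            table, groups = simulate_counts(config, taxonomy)
            outcome = group_outcome(groups)
            try:
                result = cat_test(
                    table,
                    taxonomy,
                    outcome,
                    taxon,
                    metrics=metrics,
                    engine=engine,
                    phylo_tree=phylo,
                    b=b,
                    rng=np.random.default_rng(int(rng.integers(2**31))),
                    tie_rule=tie_rule,
                    permute_mode=permute_mode,
                )
            except Exception as exc:  # recorded, not fatal
                detail_rows.append(
                    {"lambda": float(lam), "dataset": ds, "p_value": np.nan,
                     "r2_original": np.nan, "r2_perm_mean": np.nan, "error": str(exc)}
                )
                continue
            detail_rows.append(
                {
                    "lambda": float(lam),
                    "dataset": ds,
                    "p_value": result.p_value,
                    "r2_original": result.r2_original,
                    "r2_perm_mean": result.r2_perm_mean,
                    "error": "",
                }
            )
            if result.p_value < alpha:
                rejections += 1
        rate = rejections / n_datasets
        summary_rows.append(
            {
                "lambda": float(lam),
                "taxon": taxon,
                "n_datasets": n_datasets,
                "rejection_rate": rate,
                "binomial_se": float(np.sqrt(rate * (1 - rate) / n_datasets)),
            }
        )
    summary = pd.DataFrame(summary_rows)
    detail = pd.DataFrame(detail_rows)
    summary.attrs["skew_summary"] = skew
    summary.attrs["taxon"] = taxon
    return summary, detail


# ---------------------------------------------------------------------------
# Survival outcomes for desk-scale testing of the survival engine
# ---------------------------------------------------------------------------


def simulate_survival_outcome(
    table: CountTable,
    effect_taxon: str | None = None,
    tax_tree: TaxonomyTree | None = None,
    effect_size: float = 0.0,
    censor_rate: float = 0.0,
    seed: int | None = None,
) -> OutcomeSpec:
    """Exponential event times with a log-hazard linear in the (optional)
    effect taxon's relative abundance, plus independent uniform censoring
    tuned to hit approximately the requested censoring fraction.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    log_hazard = np.zeros(n)
    if effect_taxon is not None and effect_size != 0.0:
        if tax_tree is None:
            raise ValueError("effect_taxon requires tax_tree")
        leaves = tax_tree.leaves(effect_taxon)
        idx = table.feature_index(leaves)
        abundance = table.proportions()[:, idx].sum(axis=1)
        scale = abundance.std()
        z = (abundance - abundance.mean()) / (scale if scale > 0 else 1.0)
        log_hazard = effect_size * z
    times = rng.exponential(1.0 / np.exp(log_hazard))
    event = np.ones(n, dtype=int)
    if censor_rate > 0:
        # a sample is censored when C < T; with C ~ Uniform(0, u) that has
        # probability min(t_i/u, 1), so pick u by bisection on the mean
        lo, hi = 1e-9, float(times.max()) * 1e6

        def mean_censor(u: float) -> float:
            return float(np.mean(np.minimum(times / u, 1.0)))

        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if mean_censor(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        u = np.sqrt(lo * hi)
        censor_times = rng.uniform(0.0, u, size=n)
        event = (times <= censor_times).astype(int)
        times = np.minimum(times, censor_times)
    times = np.maximum(times, 1e-12)  # strictly positive follow-up
    return OutcomeSpec(kind="survival", values=times, event=event, sample_ids=list(table.sample_ids))
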