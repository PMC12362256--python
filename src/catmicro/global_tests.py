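"""Global association machinery: PERMANOVA R-squared and kernel score statistics.

PERMANOVA partitions the trace of the Gower-centered matrix G into an
among-group part tr(HG) — H the orthogonal projector onto the design's
column space — and a residual part, giving R^2 = SS_A / SS_T. The kernel
(MiRKAT-style) route instead fits the outcome on covariates alone under the
null and forms the score statistic Q = r'Gr / (2 phi) from the residuals r;
the scale-free analogue r'Gr / (tr(G) r'r) plays the role of R^2 so either
engine can drive the conditional test.

Both engines treat G as given: distances may be semimetric, in which case G
has negative eigenvalues and R^2 can leave [0,1]; values are reported as
computed, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from catmicro.data_model import OutcomeSpec
from catmicro.distances import DistanceMatrix


@dataclass
class GowerMatrix:
    """Double-centered matrix G = J(-1/2 D^2)J with J = I - 11'/n."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Gower matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10 * max(1.0, float(np.abs(v).max(initial=0.0)))):
            raise ValueError("Gower matrix must be symmetric")
        tol = 1e-10 * max(1.0, float(np.abs(v).max(initial=0.0))) * v.shape[0]
        if np.abs(v.sum(axis=0)).max(initial=0.0) > tol:
            raise ValueError("Gower matrix rows/columns do not sum to zero")
        self.values = v

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SSDecomposition:
    """Sum-of-squares split SS_T = SS_A + SS_R and R^2 = SS_A / SS_T."""

    ss_total: float
    ss_among: float
    ss_residual: float
    r2: float


@dataclass
class KernelScore:
    """Kernel score statistic Q and its scale-free R^2 analogue."""

    q: float
    r2_kernel: float


def _as_matrix(g) -> np.ndarray:
    if isinstance(g, GowerMatrix):
        return g.values
    if isinstance(g, DistanceMatrix):
        raise TypeError("pass gower_center(d), not the raw DistanceMatrix")
    return np.asarray(g, dtype=float)


def double_center(a: np.ndarray) -> np.ndarray:
    """J A J without forming J: subtract row/column means, add grand mean."""
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def gower_center(d: DistanceMatrix | np.ndarray) -> GowerMatrix:
    """Gower's centered matrix G = J(-1/2 D^2)J from a distance matrix."""
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return GowerMatrix(double_center(-0.5 * values**2))


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _encode_column(values, name: str) -> tuple[np.ndarray, list[str]]:
    """Numeric columns pass through; non-numeric get reference-coded dummies."""
    series = pd.Series(values)
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(dtype=float)[:, None], [name]
    dummies = pd.get_dummies(series.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"variable {name!r} is constant")
    return dummies.to_numpy(dtype=float), [f"{name}[{c}]" for c in dummies.columns]


def build_design(
    outcome,
    covariates: pd.DataFrame | None = None,
    include_intercept: bool = True,
) -> np.ndarray:
    """Full-rank design matrix: intercept, covariate columns, outcome terms.

    ``outcome`` may be an OutcomeSpec (categorical/binary outcomes become
    reference-coded dummies, continuous ones a single numeric column), a 1-D
    array of group labels, or None (covariates only). Linearly dependent
    columns are dropped with a warning.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    n = None

    if isinstance(outcome, OutcomeSpec):
        if covariates is None:
            covariates = outcome.covariates
        if outcome.kind == "survival":
            raise ValueError("survival outcomes have no PERMANOVA design; use the kernel engine")
        values = outcome.values
        if outcome.kind in ("binary", "categorical"):
            block, bn = _encode_column(values, "outcome")
        else:
            block, bn = np.asarray(values, dtype=float)[:, None], ["outcome"]
        n = len(values)
    elif outcome is None:
        block, bn = None, []
    else:
        values = np.asarray(outcome)
        n = len(values)
        block, bn = _encode_column(values, "outcome")

    if covariates is not None:
        cov = pd.DataFrame(covariates)
        if n is None:
            n = len(cov)
        for col in cov.columns:
            b, cn = _encode_column(cov[col], str(col))
            blocks.append(b)
            names.extend(cn)
    if block is not None:
        blocks.append(block)  # variable of interest enters last (sequential SS)
        names.extend(bn)
    if n is None or not blocks and not include_intercept:
        raise ValueError("empty design")

    cols = [np.ones((n, 1))] if include_intercept else []
    colnames = ["intercept"] if include_intercept else []
    for b, bn_ in zip(blocks, _chunk_names(names, blocks)):
        cols.append(b)
        colnames.extend(bn_)
    x = np.hstack(cols)

    # greedy full-rank reduction
    keep: list[int] = []
    rank = 0
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(
                f"design column {colnames[j]!r} is linearly dependent; dropped",
                stacklevel=2,
            )
    x = x[:, keep]
    if include_intercept and x.shape[1] == 1 and blocks:
        raise ValueError("design has no information beyond the intercept (constant grouping)")
    return x


def _chunk_names(names: list[str], blocks: list[np.ndarray]):
    out, i = [], 0
    for b in blocks:
        out.append(names[i : i + b.shape[1]])
        i += b.shape[1]
    return out


def projector(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x (pseudo-inverse based)."""
    return x @ np.linalg.pinv(x)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def permanova_r2(g, design: np.ndarray) -> SSDecomposition:
    """Decompose tr(G) into among (tr(HG)) and residual parts.

    With G double-centered the intercept column contributes nothing to
    tr(HG), so the full projector gives the among-group sum of squares
    directly.
    """
    gm = _as_matrix(g)
    x = np.asarray(design, dtype=float)
    if x.shape[0] != gm.shape[0]:
        raise ValueError(f"design has {x.shape[0]} rows for {gm.shape[0]} samples")
    h = projector(x)
    ss_total = float(np.trace(gm))
    ss_among = float(np.sum(h * gm))  # tr(HG) for symmetric H
    ss_residual = ss_total - ss_among
    if ss_total == 0:
        raise ValueError("total sum of squares is zero (all distances zero)")
    return SSDecomposition(ss_total, ss_among, ss_residual, ss_among / ss_total)


def partial_r2(g, design_full: np.ndarray, design_reduced: np.ndarray) -> float:
    """Sequential share of tr(G) explained by the full design beyond the
    reduced one: (tr(H_full G) - tr(H_reduced G)) / tr(G).

    The reduced design's column space must be contained in the full one.
    """
    gm = _as_matrix(g)
    xf = np.asarray(design_full, dtype=float)
    xr = np.asarray(design_reduced, dtype=float)
    hf = projector(xf)
    resid = xr - hf @ xr
    if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(xr)):
        raise ValueError("designs are not nested: reduced columns leave the full column space")
    hr = projector(xr)
    ss_total = float(np.trace(gm))
    if ss_total == 0:
        raise ValueError("total sum of squares is zero")
    return float(np.sum(hf * gm) - np.sum(hr * gm)) / ss_total


def permanova_pvalue(
    d: DistanceMatrix,
    grouping,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Permutation PERMANOVA: pseudo-F under sample-label permutation.

    Returns a dict with keys ``f``, ``r2``, ``p_value``, ``df_among``,
    ``df_residual``, ``n_perm``. The p-value uses the add-one rule
    p = (1 + #{F_b >= F}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    g = gower_center(d).values
    x = build_design(grouping, covariates=covariates)
    n = g.shape[0]
    rank = int(np.linalg.matrix_rank(x))
    df_among = rank - 1
    df_residual = n - rank
    if df_among < 1 or df_residual < 1:
        raise ValueError(f"degenerate degrees of freedom (among={df_among}, residual={df_residual})")
    h = projector(x)
    ss_total = float(np.trace(g))
    ss_among = float(np.sum(h * g))
    f_obs = (ss_among / df_among) / ((ss_total - ss_among) / df_residual)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        ssa = float(np.sum(h * gp))
        f_b = (ssa / df_among) / ((ss_total - ssa) / df_residual)
        if f_b >= f_obs:
            count += 1
    return {
        "f": f_obs,
        "r2": ss_among / ss_total,
        "p_value": (1 + count) / (n_perm + 1),
        "df_among": df_among,
        "df_residual": df_residual,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# Kernel (MiRKAT-style) machinery
# ---------------------------------------------------------------------------


def mirkat_null_fit(
    outcome: OutcomeSpec, covariates: pd.DataFrame | None = None
) -> tuple[np.ndarray, float]:
    """Fit the outcome on covariates alone and return (residuals, dispersion).

    continuous: least squares, phi = residual variance; binary: logistic
    regression, residuals X - p_hat, phi = 1; survival: null proportional-
    hazards fit (Nelson-Aalen / Cox on covariates only), martingale
    residuals, phi = 1. The microbiome never enters, so these are constant
    across the conditional test's permutations.
    """
    if covariates is None:
        covariates = outcome.covariates
    if outcome.kind == "categorical":
        raise ValueError("categorical outcomes are not supported by the kernel engine")

    if outcome.kind == "survival":
        return _survival_null_fit(outcome, covariates), 1.0

    y = np.asarray(outcome.values, dtype=float)
    x = build_design(None, covariates=covariates) if covariates is not None else np.ones((len(y), 1))

    if outcome.kind == "continuous":
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = len(y) - np.linalg.matrix_rank(x)
        if dof < 1:
            raise ValueError("no residual degrees of freedom in the null fit")
        phi = float(resid @ resid) / dof
        return resid, phi

    # binary: logistic null fit
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    except PerfectSeparationError as exc:
        raise ValueError(
            "perfect separation in the logistic null fit; remove or combine covariates"
        ) from exc
    mu = np.asarray(fit.fittedvalues)
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        raise ValueError(
            "perfect separation in the logistic null fit; remove or combine covariates"
        )
    return y - mu, 1.0


def _survival_null_fit(outcome: OutcomeSpec, covariates: pd.DataFrame | None) -> np.ndarray:
    """Martingale residuals from the null (covariates-only) hazard model."""
    times = np.asarray(outcome.values, dtype=float)
    event = np.asarray(outcome.event, dtype=int)
    if covariates is None or len(pd.DataFrame(covariates).columns) == 0:
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, event_observed=event)
        h0 = naf.cumulative_hazard_at_times(times).to_numpy()
        return event - h0

    from lifelines import CoxPHFitter

    df = pd.DataFrame(covariates).reset_index(drop=True).copy()
    df = pd.get_dummies(df, drop_first=True, dtype=float)
    df["__time"] = times
    df["__event"] = event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="__time", event_col="__event")
    resid = cph.compute_residuals(df, kind="martingale")["martingale"]
    return resid.sort_index().to_numpy()


def mirkat_q(r: np.ndarray, phi: float, g) -> KernelScore:
    """Kernel score statistic Q = r'Gr / (2 phi) and the scale-free
    r2_kernel = r'Gr / (tr(G) * r'r)."""
    gm = _as_matrix(g)
    r = np.asarray(r, dtype=float)
    if len(r) != gm.shape[0]:
        raise ValueError("residual length does not match kernel dimension")
    tr_g = float(np.trace(gm))
    rr = float(r @ r)
    if tr_g <= 0:
        raise ValueError("tr(G) must be positive")
    if rr == 0:
        # identically-zero residuals carry no information: Q = 0 by definition
        return KernelScore(q=0.0, r2_kernel=0.0)
    rgr = float(r @ gm @ r)
    return KernelScore(q=rgr / (2.0 * phi), r2_kernel=rgr / (tr_g * rr))


def max_over_metrics(r2_values: Sequence[float]) -> float:
    """Omnibus rule over candidate metrics: take the largest R^2.

    In the conditional test the max is applied per dataset (original and each
    permuted copy) before the permuted values are compared with the original.
    """
    vals = list(r2_values)
    if not vals:
        raise ValueError("r2_values is empty")
    return float(max(vals))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # n x k' (axes with nonnegative eigenvalues only)
    eigenvalues: np.ndarray  # all n, descending


def pcoa(g, k: int) -> PCoAResult:
    """Principal coordinates: top-k eigenpairs of G.

    Axes with negative eigenvalues (semimetric distances) are reported in
    ``eigenvalues`` but omitted from the coordinates.
    """
    gm = _as_matrix(g)
    n = gm.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    eigvals, eigvecs = np.linalg.eigh(gm)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    top_vals = eigvals[:k]
    keep = top_vals > max(0.0, 1e-12 * abs(eigvals[0]))
    coords = eigvecs[:, :k][:, keep] * np.sqrt(top_vals[keep])
    return PCoAResult(coordinates=coords, eigenvalues=eigvals)
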