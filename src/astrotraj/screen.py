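"""Trajectory regression screen.

Pseudotime is rank-uniformized to [0, 1] so the regression design is not
dominated by dense pockets of nuclei, then every gene's normalized-log
expression is regressed on it by ordinary least squares. A gene is
called dysregulated when its slope clears an effect-size floor
(|beta| > beta_min), its fit explains enough variance (R^2 > r2_min),
and its Bonferroni-corrected slope p-value is significant. The screen's
output feeds MA-style tables (mean expression vs beta, and beta vs R^2),
with very-high-abundance transcripts (MALAT1 by default) excluded from
the tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .containers import ExpressionMatrix
from .enrichment import SignatureSet

__all__ = [
    "ScreenConfig",
    "rank_uniform",
    "gene_trajectory_regression",
    "classify_dysregulated",
    "refine_trajectory",
    "ma_table",
]


@dataclass
class ScreenConfig:
    """Thresholds of the dysregulation call.

    ``beta_min`` applies to |beta|: the effect-size floor is two-sided so
    that down-regulated genes (negative slopes) are screened with the
    same stringency as up-regulated ones. ``rescale_ranks`` maps ranks to
    [0, 1]; disable it to regress on raw integer ranks (which scales beta
    by n - 1).
    """

    beta_min: float = 0.1
    r2_min: float = 0.1
    alpha: float = 0.05
    plot_exclusions: list[str] = field(default_factory=lambda: ["MALAT1"])
    rescale_ranks: bool = True
    # depth normalization makes every gene's apparent slope drift when a
    # large expression program changes along the trajectory (closed
    # compositions): every other gene picks up a spurious slope
    # proportional to its compositional sensitivity x/(1+x). The drift
    # line is fit by median (LAD) regression of the gene slopes on that
    # sensitivity — most genes are trajectory-flat, so the median line
    # tracks the artifact, in the spirit of median-ratio normalization —
    # and subtracted before thresholding
    drift_correction: bool = True

    def __post_init__(self) -> None:
        if self.beta_min < 0 or self.r2_min < 0:
            raise ValueError("beta_min and r2_min must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def rank_uniform(t: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Rank-order pseudotime into a uniform grid on [0, 1].

    Value i maps to (rank_i - 1) / (n - 1) with midranks for ties, so any
    strictly monotone transform of ``t`` yields identical output.
    With ``rescale=False`` raw (mid)ranks are returned instead.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two nuclei to rank pseudotime")
    ranks = scipy.stats.rankdata(t)
    return (ranks - 1) / (t.size - 1) if rescale else ranks


def _ols_columns(y: np.ndarray, x: np.ndarray, n_eff: float | None = None):
    """Column-wise simple OLS: beta, R^2, two-sided slope p.

    ``n_eff`` substitutes an effective sample size into the t test when
    the columns carry dependent (e.g. neighbor-averaged) observations.
    """
    n = y.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("ranked pseudotime has zero variance")
    yc = y - y.mean(axis=0)
    sxy = xc @ yc
    syy = (yc**2).sum(axis=0)
    beta = sxy / sxx
    df = (n_eff if n_eff is not None else n) - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (sxy**2) / (sxx * syy), 0.0)
        tstat = np.where(r2 < 1, np.sqrt(df * r2 / (1 - r2)), np.inf)
    p = np.where(syy > 0, 2.0 * scipy.stats.t.sf(tstat, df=df), 1.0)
    # perfect fits (r2 = 1) are infinitely significant: p = 0
    p = np.where((syy > 0) & (r2 >= 1), 0.0, p)
    beta = np.where(syy > 0, beta, 0.0)
    return beta, np.clip(r2, 0.0, 1.0), p


def _composition_drift(beta: np.ndarray, mean_expr: np.ndarray) -> np.ndarray:
    """Per-gene normalization drift, LAD-fit against x/(1+x) sensitivity.

    When a large program changes along the trajectory, depth
    normalization gives every gene a spurious slope ~ -c_g * dlnS/dt
    with c_g = x/(1+x) at the gene's mean. Most genes are flat, so a
    median regression of slopes on c_g recovers the drift line without
    being pulled by the truly dysregulated minority.
    """
    comp = 1.0 - np.exp(-mean_expr)  # ~ x / (1 + x) at the gene's mean
    # the line is only identifiable when sensitivities actually spread
    if beta.size < 10 or np.std(comp) < 0.05:
        return np.full_like(beta, np.median(beta))
    model = sm.QuantReg(beta, sm.add_constant(comp))
    fit = model.fit(q=0.5)
    return fit.params[0] + fit.params[1] * comp


def gene_trajectory_regression(
    expr: ExpressionMatrix,
    ranked_t: np.ndarray,
    config: ScreenConfig | None = None,
    raw_expr: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of expression on ranked pseudotime.

    Returns one record per gene: beta (slope per unit ranked pseudotime),
    R^2, two-sided slope p (t distribution, n - 2 df), Bonferroni p over
    the tested genes, mean expression, and status per the thresholds.
    Constant genes get beta 0, R^2 0 and p defined as 1.

    Neighbor-smoothed expression violates the OLS independence
    assumption, so p-values on smoothed input would be anticonservative.
    When the screen runs on denoised expression, pass the un-smoothed
    matrix as ``raw_expr``: effect sizes (beta, R^2, mean) come from the
    denoised values while slope inference runs on the raw values, whose
    residuals are independent across nuclei. Without ``raw_expr``,
    smoothed input falls back to an effective sample size of
    n / (k + 1) in the t test.
    """
    if config is None:
        config = ScreenConfig()
    ranked_t = np.asarray(ranked_t, dtype=float)
    y = expr.values
    n = y.shape[0]
    if ranked_t.shape[0] != n:
        raise ValueError("ranked pseudotime must align with expression rows")
    if n < 3:
        raise ValueError("need at least three nuclei for slope inference")
    n_eff = None
    if raw_expr is None and expr.smoothed and expr.smooth_k:
        n_eff = max(4.0, n / (expr.smooth_k + 1))
    beta, r2, p = _ols_columns(y, ranked_t, n_eff)
    if raw_expr is not None:
        if raw_expr.values.shape != y.shape or not np.array_equal(
            raw_expr.gene_ids, expr.gene_ids
        ):
            raise ValueError("raw_expr must align with expr (same nuclei and genes)")
        _, _, p = _ols_columns(raw_expr.values, ranked_t)
    m = y.shape[1]
    mean_expr = y.mean(axis=0)
    beta_centered = beta - _composition_drift(beta, mean_expr) if config.drift_correction else beta
    records = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "beta": beta,
            "beta_centered": beta_centered,
            "r2": r2,
            "p_raw": p,
            "p_bonf": np.minimum(1.0, p * m),
            "mean_expr": mean_expr,
        }
    )
    records["status"] = _status(records, config)
    return records


def _status(records: pd.DataFrame, config: ScreenConfig) -> np.ndarray:
    """Threshold rule; effect size is the drift-centered slope when the
    correction is active (``beta_centered`` equals ``beta`` otherwise)."""
    eff = records["beta_centered"] if "beta_centered" in records else records["beta"]
    passing = (
        (records["r2"] > config.r2_min)
        & (records["p_bonf"] < config.alpha)
        & (eff.abs() > config.beta_min)
    )
    return np.where(passing & (eff > 0), "up", np.where(passing, "down", "ns"))


def refine_trajectory(
    expr: ExpressionMatrix,
    t: np.ndarray,
    config: ScreenConfig | None = None,
    raw_expr: ExpressionMatrix | None = None,
    n_iter: int = 1,
) -> np.ndarray:
    """Principal-curve-style refinement of a pseudotime ordering.

    Each iteration regresses every gene on the ranked ordering, projects
    the (denoised) expression onto the vector of significant slopes, and
    re-ranks nuclei along that projection. Because the projection pools
    hundreds of trajectory genes it orders nuclei with less noise than a
    diffusion distance; orientation is kept aligned with the input.
    Returns a refined ordering in [0, 1] (unchanged if no gene is
    significant).
    """
    if config is None:
        config = ScreenConfig()
    t = np.asarray(t, dtype=float)
    for _ in range(n_iter):
        ranked = rank_uniform(t, rescale=True)
        records = gene_trajectory_regression(expr, ranked, config, raw_expr=raw_expr)
        weights = np.where(
            records["p_bonf"].to_numpy() < config.alpha,
            records["beta_centered"].to_numpy(),
            0.0,
        )
        if not np.any(weights):
            break
        proj = (expr.values - expr.values.mean(axis=0)) @ weights
        if np.corrcoef(proj, ranked)[0, 1] < 0:
            proj = -proj
        t = rank_uniform(proj, rescale=True)
    return t


def classify_dysregulated(
    records: pd.DataFrame, config: ScreenConfig | None = None
) -> SignatureSet:
    """Signature of up/down genes passing all three screen thresholds."""
    if config is not None:
        records = records.assign(status=_status(records, config))
    up = records.loc[records["status"] == "up", "gene"].tolist()
    down = records.loc[records["status"] == "down", "gene"].tolist()
    directions = {g: "up" for g in up} | {g: "down" for g in down}
    return SignatureSet("dysregulated", up + down, directions)


def ma_table(records: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """MA-style table: per-gene mean expression, beta, R^2 and status.

    Keeps genes with Bonferroni-significant slopes (the plot filter) and
    drops configured exclusions (MALAT1 by default, whose extreme nuclear
    abundance would dominate the expression axis).
    """
    if config is None:
        config = ScreenConfig()
    keep = (~records["gene"].isin(config.plot_exclusions)) & (
        records["p_bonf"] < config.alpha
    )
    cols = ["gene", "mean_expr", "beta", "r2", "status"]
    return records.loc[keep, cols].reset_index(drop=True)
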