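import numpy as np
import pandas as pd
import pytest
import scipy.stats

from astrotraj.containers import ExpressionMatrix
from astrotraj.screen import (
    ScreenConfig,
    classify_dysregulated,
    gene_trajectory_regression,
    ma_table,
    rank_uniform,
    refine_trajectory,
)


def expr_from(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{j}" for j in range(values.shape[1])],
        [f"n{i}" for i in range(values.shape[0])],
    )


# ------------------------------------------------------------ rank_uniform


def test_rank_uniform_example():
    assert np.allclose(rank_uniform(np.array([0.5, 0.1, 0.9])), [0.5, 0.0, 1.0])


def test_rank_uniform_span_and_spacing(rng):
    t = rng.normal(size=17)
    out = rank_uniform(t)
    assert out.min() == 0 and out.max() == 1
    assert np.allclose(np.sort(np.diff(np.sort(out))), 1 / 16)


def test_rank_uniform_invariant_to_monotone_transform(rng):
    t = rng.uniform(size=30)
    assert np.allclose(rank_uniform(t), rank_uniform(np.exp(5 * t)))


def test_rank_uniform_requires_two_values():
    with pytest.raises(ValueError):
        rank_uniform(np.array([1.0]))


# --------------------------------------------------------------- regression


def closed_form_ols(y, x):
    """Textbook simple-regression formulas, computed longhand."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    beta = (xc * yc).sum() / (xc**2).sum()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    r2 = r**2
    t = r * np.sqrt((n - 2) / (1 - r2))
    p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
    return beta, r2, p


def test_regression_matches_closed_form(rng):
    y = rng.normal(size=(50, 20))
    t = rng.uniform(size=50)
    ranked = rank_uniform(t)
    config = ScreenConfig(drift_correction=False)
    records = gene_trajectory_regression(expr_from(y), ranked, config)
    for j in range(20):
        beta, r2, p = closed_form_ols(y[:, j], ranked)
        assert records["beta"].iloc[j] == pytest.approx(beta, abs=1e-10)
        assert records["r2"].iloc[j] == pytest.approx(r2, abs=1e-10)
        assert records["p_raw"].iloc[j] == pytest.approx(p, abs=1e-10)
        assert records["p_bonf"].iloc[j] == pytest.approx(min(1.0, p * 20), abs=1e-9)


def test_perfect_fit_gene():
    t = np.linspace(0, 1, 30)
    y = np.column_stack([t, np.full(30, 2.0)])
    records = gene_trajectory_regression(expr_from(y), t, ScreenConfig(drift_correction=False))
    assert records["beta"].iloc[0] == pytest.approx(1.0)
    assert records["r2"].iloc[0] == pytest.approx(1.0)
    assert records["p_raw"].iloc[0] == 0.0
    # constant gene: beta 0, r2 0, p defined as 1
    assert records["beta"].iloc[1] == 0.0
    assert records["r2"].iloc[1] == 0.0
    assert records["p_raw"].iloc[1] == 1.0


def test_zero_variance_pseudotime_errors():
    with pytest.raises(ValueError, match="variance"):
        gene_trajectory_regression(expr_from(np.eye(5)), np.ones(5))


def test_planted_slope_estimated_unbiased(rng):
    """Across 20 replicates the estimated slope of a planted 0.3 trend
    is within +-0.05 of truth at n = 2000."""
    betas = []
    for _ in range(20):
        t = rank_uniform(rng.uniform(size=2000))
        y = 1.0 + 0.3 * t + rng.normal(0, 0.5, size=2000)
        rec = gene_trajectory_regression(
            expr_from(y[:, None]), t, ScreenConfig(drift_correction=False)
        )
        betas.append(rec["beta"].iloc[0])
    assert np.mean(betas) == pytest.approx(0.3, abs=0.05)


def test_smoothed_input_uses_effective_sample_size(rng):
    y = rng.normal(size=(120, 5))
    t = rank_uniform(rng.uniform(size=120))
    plain = expr_from(y)
    smoothed = ExpressionMatrix(
        y, plain.gene_ids, plain.nucleus_ids, smoothed=True, smooth_k=9
    )
    p_plain = gene_trajectory_regression(plain, t)["p_raw"]
    p_eff = gene_trajectory_regression(smoothed, t)["p_raw"]
    # same data, fewer effective observations -> weaker evidence
    assert (p_eff >= p_plain - 1e-12).all()


def test_raw_expression_overrides_inference(rng):
    y = rng.normal(size=(80, 4))
    t = rank_uniform(rng.uniform(size=80))
    smoothed = ExpressionMatrix(
        y * 0.1, [f"g{j}" for j in range(4)], [f"n{i}" for i in range(80)],
        smoothed=True, smooth_k=7,
    )
    raw = expr_from(y)
    rec = gene_trajectory_regression(smoothed, t, raw_expr=raw)
    ref = gene_trajectory_regression(raw, t, ScreenConfig(drift_correction=False))
    assert np.allclose(rec["p_raw"], ref["p_raw"])
    # effect sizes still come from the (here: scaled) smoothed values
    assert np.allclose(rec["beta"], 0.1 * ref["beta"])


# ----------------------------------------------------------- classification


def make_records(rows):
    df = pd.DataFrame(rows, columns=["gene", "beta", "r2", "p_raw", "p_bonf", "mean_expr"])
    df["status"] = "ns"
    return df


@pytest.mark.parametrize(
    "beta,r2,p_bonf,expected",
    [
        (0.12, 0.15, 0.01, "up"),
        (-0.2, 0.3, 1e-5, "down"),
        (0.05, 0.5, 1e-9, "ns"),   # fails the effect-size floor
        (0.3, 0.05, 1e-9, "ns"),   # fails the variance floor
        (0.3, 0.5, 0.2, "ns"),     # fails significance
    ],
)
def test_classification_thresholds(beta, r2, p_bonf, expected):
    records = make_records([("g", beta, r2, p_bonf / 2, p_bonf, 1.0)])
    sig = classify_dysregulated(records, ScreenConfig())
    if expected == "ns":
        assert len(sig.genes) == 0
    else:
        assert sig.directions == {"g": expected}


def test_drift_correction_recenters_compositional_shift(rng):
    """A shared positive drift on otherwise-null genes is removed, while
    a genuinely dysregulated gene keeps its call."""
    n, g = 400, 60
    t = rank_uniform(rng.uniform(size=n))
    y = 2.0 + rng.normal(0, 0.05, size=(n, g)) + 0.2 * t[:, None]  # drift on everyone
    y[:, 0] += 0.4 * t  # one planted gene on top of the drift
    records = gene_trajectory_regression(expr_from(y), t, ScreenConfig())
    assert records["status"].iloc[0] == "up"
    assert (records["status"].iloc[1:] == "ns").all()
    assert abs(records["beta_centered"].iloc[1:].median()) < 0.05


# ------------------------------------------------------------------ tables


def test_ma_table_excludes_configured_genes():
    records = make_records(
        [
            ("MALAT1", 0.5, 0.5, 1e-9, 1e-7, 8.0),
            ("VIM", 0.3, 0.4, 1e-9, 1e-7, 2.0),
            ("SOX9", 0.0, 0.0, 0.9, 1.0, 1.5),
        ]
    )
    table = ma_table(records, ScreenConfig())
    assert "MALAT1" not in set(table["gene"])   # abundance outlier removed
    assert "SOX9" not in set(table["gene"])     # not Bonferroni-significant
    assert set(table["gene"]) == {"VIM"}
    assert list(table.columns) == ["gene", "mean_expr", "beta", "r2", "status"]


def test_ma_table_keeps_all_when_no_exclusions():
    records = make_records([("A", 0.2, 0.2, 1e-8, 1e-6, 1.0), ("B", -0.2, 0.2, 1e-8, 1e-6, 2.0)])
    config = ScreenConfig(plot_exclusions=[])
    assert len(ma_table(records, config)) == 2


# -------------------------------------------------------------- refinement


def test_refine_trajectory_improves_noisy_ordering(rng):
    n, g = 600, 120
    r = rng.uniform(size=n)
    slopes = np.zeros(g)
    slopes[:30] = 0.8
    y = rng.normal(0, 0.3, size=(n, g)) + np.outer(r, slopes)
    noisy_t = rank_uniform(r + rng.normal(0, 0.25, size=n))
    expr = expr_from(y)
    refined = refine_trajectory(expr, noisy_t, ScreenConfig(drift_correction=False), n_iter=2)
    before = scipy.stats.spearmanr(noisy_t, r).statistic
    after = scipy.stats.spearmanr(refined, r).statistic
    assert after > before


def test_refine_trajectory_without_signal_is_identity(rng):
    y = rng.normal(size=(100, 20))
    t = rank_uniform(rng.uniform(size=100))
    refined = refine_trajectory(expr_from(y), t, ScreenConfig(drift_correction=False))
    assert np.allclose(refined, rank_uniform(t))
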