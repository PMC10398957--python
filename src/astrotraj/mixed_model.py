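"""Random-intercept mixed model linking pseudotime to donor pathology.

Per-nucleus pseudotime is regressed on donor-level covariates — binary
amyloid and tau pathology, TREM2 R47H (vs WT), APOE E3/E4 and E4/E4
(vs E3/E3), and age at death — with a random intercept per donor to
absorb between-sample variation, fit by REML. Estimation delegates to
statsmodels' MixedLM; this module owns the design coding (reference
levels, binary pathology, per-sample grouping) and a tidy output schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["LmmFit", "fit_random_intercept_lmm"]

_APOE_REF = "E3/E3"
_TREM2_REF = "WT"


@dataclass
class LmmFit:
    """Fixed-effect table plus variance components of the fit."""

    coefficients: pd.DataFrame  # term, estimate, se, p
    group_variance: float
    residual_variance: float
    n_obs: int
    n_groups: int
    converged: bool

    def coef(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])

    def pvalue(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])


def _clean_term(term: str) -> str:
    """Map patsy design names onto readable terms."""
    if term.startswith("C(apoe"):
        return "apoe_" + term.split("[T.")[1].rstrip("]")
    if term.startswith("C(trem2"):
        return "trem2_" + term.split("[T.")[1].rstrip("]")
    if term == "Intercept":
        return "intercept"
    return term


def fit_random_intercept_lmm(
    t: np.ndarray, meta: pd.DataFrame, reml: bool = True
) -> LmmFit:
    """Fit pseudotime ~ amyloid + tau + TREM2 + APOE + age, (1 | sample).

    ``meta`` needs columns sample, amyloid, tau, apoe, trem2, age aligned
    with ``t``. Amyloid/tau must be coded 0/1; E3/E3 and WT are the
    genotype reference levels. A constant response returns a zero fit; a
    covariate constant over the whole design and collinear with the
    intercept raises naming the column.
    """
    t = np.asarray(t, dtype=float)
    if len(meta) != t.size:
        raise ValueError("metadata rows must align with pseudotime values")
    required = ["sample", "amyloid", "tau", "apoe", "trem2", "age"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample"].nunique() < 2:
        raise ValueError("need at least two donors (groups) for a mixed model")
    df = meta[required].copy()
    df["t"] = t
    if np.ptp(t) == 0:
        terms = _design_terms(df)
        coeffs = pd.DataFrame(
            {"term": terms, "estimate": 0.0, "se": 0.0, "p": np.nan}
        )
        coeffs.loc[coeffs["term"] == "intercept", "estimate"] = float(t[0]) if t.size else 0.0
        return LmmFit(coeffs, 0.0, 0.0, int(t.size), int(df["sample"].nunique()), True)

    fixed_terms = []
    for col in ("amyloid", "tau", "age"):
        if df[col].nunique() > 1:
            fixed_terms.append(col)
    for col, ref in (("trem2", _TREM2_REF), ("apoe", _APOE_REF)):
        levels = df[col].unique()
        if len(levels) > 1:
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} absent from column {col!r}"
                )
            fixed_terms.append(f"C({col}, Treatment('{ref}'))")
    if not fixed_terms:
        raise ValueError(
            "all covariates are constant: singular design (amyloid, tau, "
            "apoe, trem2, age)"
        )
    donor_ols = _check_donor_level_identifiability(df)
    formula = "t ~ " + " + ".join(fixed_terms)
    model = smf.mixedlm(formula, df, groups=df["sample"])
    fit = model.fit(reml=reml)
    # a boundary variance estimate may flag non-convergence while the
    # fixed effects are fine; reject only fits that left the vicinity of
    # the donor-level least-squares solution
    for name in fit.fe_params.index:
        term = _clean_term(name)
        if term in donor_ols and abs(fit.fe_params[name] - donor_ols[term]) > 0.5:
            raise ValueError(
                "mixed model estimation diverged (near-singular donor-level "
                f"design? term {term!r})"
            )
    params = fit.params
    bse = fit.bse
    pvals = fit.pvalues
    rows = []
    for name in fit.fe_params.index:
        rows.append(
            {
                "term": _clean_term(name),
                "estimate": float(params[name]),
                "se": float(bse[name]),
                "p": float(pvals[name]),
            }
        )
    group_var = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    return LmmFit(
        coefficients=pd.DataFrame(rows),
        group_variance=group_var,
        residual_variance=float(fit.scale),
        n_obs=int(t.size),
        n_groups=int(df["sample"].nunique()),
        converged=bool(fit.converged),
    )


def _check_donor_level_identifiability(df: pd.DataFrame) -> dict[str, float]:
    """All fixed covariates are donor-level, so they must be linearly
    independent across donors; otherwise the fixed effects are
    unidentifiable (e.g. a cohort where genotype perfectly predicts
    pathology). Raises naming the collinear columns; returns the
    donor-means least-squares coefficients as a sanity reference."""
    donors = df.groupby("sample").first()
    cols: list[np.ndarray] = [np.ones(len(donors))]
    names = ["intercept"]
    for col in ("amyloid", "tau", "age"):
        if donors[col].nunique() > 1:
            cols.append(donors[col].to_numpy(dtype=float))
            names.append(col)
    for col, ref in (("trem2", _TREM2_REF), ("apoe", _APOE_REF)):
        for level in sorted(set(donors[col]) - {ref}):
            cols.append((donors[col] == level).to_numpy(dtype=float))
            names.append(f"{col}_{level}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedily drop columns whose removal restores full rank
        involved = []
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                involved.append(names[j])
        raise ValueError(
            "singular design: donor-level covariates are collinear "
            f"(columns {involved or names[1:]})"
        )
    donor_means = df.groupby("sample")["t"].mean().loc[donors.index].to_numpy()
    coef = np.linalg.lstsq(X, donor_means, rcond=None)[0]
    return dict(zip(names, coef))


def _design_terms(df: pd.DataFrame) -> list[str]:
    terms = ["intercept"]
    for col in ("amyloid", "tau", "age"):
        if df[col].nunique() > 1:
            terms.append(col)
    for col, ref in (("trem2", _TREM2_REF), ("apoe", _APOE_REF)):
        for level in sorted(set(df[col]) - {ref}):
            terms.append(f"{col}_{level}")
    return terms
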