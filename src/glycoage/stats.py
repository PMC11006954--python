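"""Cohort biostatistics: group tests, FDR, interaction models, correlations.

These are the workhorse analyses for a glycomics cohort: two-group
comparisons of trait levels with Benjamini–Hochberg FDR across the marker
panel, multivariable linear models with an exposure interaction term
(e.g. HIV × sex adjusted for age, ethnicity and BMI), age-slope
comparisons via an age × status interaction, Spearman correlation
matrices between trait blocks (optionally partialled on covariates via
rank residualisation), and a generic stratified runner for secondary
analyses (e.g. by menopause status).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "StatResult",
    "two_group_test",
    "bh_fdr",
    "significance_stars",
    "interaction_model",
    "slope_difference",
    "spearman_matrix",
    "stratified_run",
]


@dataclass(frozen=True)
class StatResult:
    """One tidy test result; ``fdr_q`` is filled by the caller's BH family."""

    variable: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    fdr_q: float | None
    n_used: int


def two_group_test(
    values, group_labels, *, equal_var: bool = False, variable: str = ""
) -> StatResult:
    """Two-sided unpaired t test between the two label groups.

    Welch's unequal-variance form by default (``equal_var=False``); pass
    ``equal_var=True`` for the pooled-variance Student form.  The estimate
    is mean(group2) − mean(group1) with groups in sorted label order, and
    the CI is the 95% interval for that difference.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(b, a, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return StatResult(
        variable=variable,
        estimate=float(np.mean(b) - np.mean(a)),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        fdr_q=None,
        n_used=len(a) + len(b),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q values, order-preserving with input.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significance_stars(p: float) -> str:
    """Figure-legend star bands: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def interaction_model(
    data: pd.DataFrame,
    y: str,
    exposure_a: str,
    exposure_b: str,
    covariates: tuple[str, ...] | list[str] = (),
    categorical: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """OLS of ``y ~ A + B + A:B + covariates``; returns the coefficient table.

    Categorical columns (listed in ``categorical``, or of object/category
    dtype) are treatment-coded with the default (first sorted) reference
    level.  Rows with missing values in any used column are dropped
    (listwise).  Raises on a rank-deficient design, naming the collinear
    columns.

    Returns a DataFrame indexed by term with columns
    ``coef, se, t, p, ci_low, ci_high``; the interaction term is named
    ``"{exposure_a}:{exposure_b}"``.
    """
    cols = [y, exposure_a, exposure_b, *covariates]
    df = data[cols].dropna().copy()

    def term(name: str) -> str:
        if name in categorical or df[name].dtype == object or str(df[name].dtype) == "category":
            return f"C({name})"
        return name

    rhs = [term(exposure_a), term(exposure_b),
           f"{term(exposure_a)}:{term(exposure_b)}"]
    rhs += [term(c) for c in covariates]
    formula = f"Q('{y}') ~ " + " + ".join(rhs)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        bad = [model.exog_names[i] for i in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = model.fit()
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    table["n_used"] = int(fit.nobs)
    # strip patsy decoration so callers can address terms by plain name
    rename = {}
    for name in table.index:
        clean = name.replace(f"Q('{y}')", y)
        for c in cols:
            clean = clean.replace(f"C({c})", c)
        rename[name] = clean
    table = table.rename(index=rename)
    inter = [i for i in table.index if ":" in i]
    table.attrs["interaction_terms"] = inter
    return table


def slope_difference(
    data: pd.DataFrame, y: str, age: str = "age", status: str = "hiv"
) -> dict:
    """Compare age trends of ``y`` between two status groups.

    Reports the Spearman rho of ``y`` vs age within each group, the OLS
    slope within each group, and the p value of the age × status
    interaction from :func:`interaction_model` with no extra covariates.
    """
    df = data[[y, age, status]].dropna()
    levels = sorted(df[status].unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 status groups, got {levels}")
    per_group = {}
    for lev in levels:
        sub = df[df[status] == lev]
        if sub[age].nunique() < 2:
            raise ValueError(f"constant age within stratum {status}={lev}")
        rho, rho_p = sps.spearmanr(sub[age], sub[y])
        slope = np.polyfit(sub[age], sub[y], 1)[0]
        per_group[lev] = {
            "rho": float(rho),
            "rho_p": float(rho_p),
            "slope": float(slope),
            "n": len(sub),
        }
    table = interaction_model(df, y, age, status, categorical=(status,))
    inter_term = table.attrs["interaction_terms"][0]
    return {
        "groups": per_group,
        "interaction_coef": float(table.loc[inter_term, "coef"]),
        "interaction_p": float(table.loc[inter_term, "p"]),
        "slope_difference": per_group[levels[1]]["slope"] - per_group[levels[0]]["slope"],
    }


def _rank_residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of rank-transformed values on rank-transformed covariates."""
    r = sps.rankdata(values)
    Z = np.column_stack([np.ones(len(r))] + [sps.rankdata(c) for c in covariates.T])
    beta, *_ = np.linalg.lstsq(Z, r, rcond=None)
    return r - Z @ beta


def spearman_matrix(
    x_block: pd.DataFrame,
    y_block: pd.DataFrame,
    partial_on: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman rank correlations between every X column and every Y column.

    Average-rank tie handling, two-sided p values, and BH q computed across
    the whole matrix as one family.  Pairwise-complete observations are
    used per pair; a pair with a constant column (or < 4 complete
    observations) gets NaN rho (undefined sentinel).

    When ``partial_on`` is given, correlations are partial Spearman via
    rank residualisation: both variables are rank-transformed, the
    rank-transformed covariates regressed out, and the Pearson correlation
    of the residuals tested with the usual t approximation.

    Returns a tidy DataFrame with columns
    ``x, y, rho, p, q, n_used, stars``.
    """
    rows = []
    for xc in x_block.columns:
        for yc in y_block.columns:
            xs = x_block[xc].to_numpy(dtype=float)
            ys = y_block[yc].to_numpy(dtype=float)
            keep = ~(np.isnan(xs) | np.isnan(ys))
            if partial_on is not None:
                Z = partial_on.to_numpy(dtype=float)
                keep &= ~np.isnan(Z).any(axis=1)
            xv, yv = xs[keep], ys[keep]
            n = len(xv)
            if n < 4 or np.all(xv == xv[0]) or np.all(yv == yv[0]):
                rows.append((xc, yc, np.nan, np.nan, n))
                continue
            if partial_on is None:
                rho, p = sps.spearmanr(xv, yv)
            else:
                rx = _rank_residualize(xv, Z[keep])
                ry = _rank_residualize(yv, Z[keep])
                rho, p = sps.pearsonr(rx, ry)
            rows.append((xc, yc, float(rho), float(p), n))
    out = pd.DataFrame(rows, columns=["x", "y", "rho", "p", "n_used"])
    q = np.full(len(out), np.nan)
    valid = out["p"].notna().to_numpy()
    if valid.any():
        q[valid] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    return out


def stratified_run(analysis, data: pd.DataFrame, strata: str, min_n: int = 4) -> dict:
    """Apply ``analysis(sub_dataframe)`` within each level of ``strata``.

    Empty or undersized strata are skipped with a warning and recorded in
    the result under ``"skipped"``.  Returns ``{level: result}`` plus the
    skipped list.
    """
    results: dict = {"skipped": []}
    for level, sub in data.groupby(strata, observed=True, dropna=True):
        if len(sub) < min_n:
            warnings.warn(
                f"stratum {strata}={level!r} has n={len(sub)} < {min_n}; skipped",
                stacklevel=2,
            )
            results["skipped"].append((level, len(sub)))
            continue
        results[level] = analysis(sub)
    return results
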