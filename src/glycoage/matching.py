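"""1:1 nearest-neighbor case-control matching and odds-ratio models.

Matching is greedy without replacement in randomized (seeded) case order.
The distance is Mahalanobis over standardized numeric covariates, computed
within strata of any covariates that must agree exactly (e.g. ethnicity).
Balance is reported as standardized mean differences before and after
matching.  Case/control contrasts of exposures use covariate-adjusted
logistic regression with Wald 95% CIs, with BH FDR across the exposure
panel; longitudinal designs are collapsed to per-subject means first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import mahalanobis

from .stats import StatResult, bh_fdr, two_group_test

__all__ = [
    "MatchSpec",
    "MatchResult",
    "OddsRatioResult",
    "nearest_neighbor_match",
    "adjusted_logistic",
    "odds_ratio_panel",
    "longitudinal_group_average",
]


@dataclass(frozen=True)
class MatchSpec:
    """What to match on.

    numeric
        Columns entering the Mahalanobis distance (standardized).
    exact_on
        Categorical columns that must agree exactly between a case and its
        control (matching runs within these strata).
    caliper
        Optional maximum acceptable distance; cases whose nearest available
        control exceeds it go unmatched (and are reported, never dropped
        silently).
    """

    numeric: tuple[str, ...]
    exact_on: tuple[str, ...] = ()
    caliper: float | None = None

    def __post_init__(self) -> None:
        if not self.numeric and not self.exact_on:
            raise ValueError("at least one matching covariate is required")
        if self.caliper is not None and self.caliper <= 0:
            raise ValueError("caliper must be positive")


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # case_id, control_id, distance
    unmatched_cases: list = field(default_factory=list)
    balance: pd.DataFrame | None = None  # covariate, smd_before, smd_after


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD denominator."""
    sd = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if sd == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / sd)


def nearest_neighbor_match(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    spec: MatchSpec,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Cases are visited in a seeded random order; each takes its nearest
    remaining control by Mahalanobis distance over the standardized
    numeric covariates, within the exact-agreement strata.  The covariance
    used for the Mahalanobis metric is estimated from the concatenated
    case+pool rows.
    """
    rng = np.random.default_rng(seed)
    for col in (*spec.numeric, *spec.exact_on):
        for df, label in ((cases, "cases"), (pool, "pool")):
            if col not in df.columns:
                raise KeyError(f"matching covariate {col!r} missing from {label}")

    both = pd.concat([cases[list(spec.numeric)], pool[list(spec.numeric)]])
    mu = both.mean().to_numpy(dtype=float)
    sd = both.std(ddof=1).replace(0.0, 1.0).to_numpy(dtype=float)

    def standardize(df: pd.DataFrame) -> np.ndarray:
        return (df[list(spec.numeric)].to_numpy(dtype=float) - mu) / sd

    Zc, Zp = standardize(cases), standardize(pool)
    Zall = np.vstack([Zc, Zp])
    cov = np.atleast_2d(np.cov(Zall, rowvar=False))
    # shrink towards the identity so near-collinear covariates (common at
    # small n) cannot dominate the metric through a near-null eigenvalue
    alpha = 0.05
    cov = (1 - alpha) * cov + alpha * np.eye(cov.shape[0])
    vi = np.linalg.inv(cov)

    def stratum_key(row) -> tuple:
        return tuple(row[c] for c in spec.exact_on)

    available = np.ones(len(pool), dtype=bool)
    pool_keys = [stratum_key(r) for _, r in pool.iterrows()]
    case_order = rng.permutation(len(cases))
    pairs, unmatched = [], []
    case_ids = cases.index.to_list()
    pool_ids = pool.index.to_list()
    for i in case_order:
        key = stratum_key(cases.iloc[i])
        candidates = [
            j for j in range(len(pool)) if available[j] and pool_keys[j] == key
        ]
        if not candidates:
            unmatched.append(case_ids[i])
            continue
        dists = np.array([mahalanobis(Zc[i], Zp[j], vi) for j in candidates])
        best = int(np.argmin(dists))
        if spec.caliper is not None and dists[best] > spec.caliper:
            unmatched.append(case_ids[i])
            continue
        j = candidates[best]
        available[j] = False
        pairs.append((case_ids[i], pool_ids[j], float(dists[best])))

    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "distance"])
    # balance diagnostics on the numeric matching covariates
    rows = []
    if len(pairs_df):
        matched_controls = pool.loc[pairs_df["control_id"]]
        matched_cases = cases.loc[pairs_df["case_id"]]
        for col in spec.numeric:
            rows.append(
                (
                    col,
                    _smd(
                        cases[col].to_numpy(dtype=float),
                        pool[col].to_numpy(dtype=float),
                    ),
                    _smd(
                        matched_cases[col].to_numpy(dtype=float),
                        matched_controls[col].to_numpy(dtype=float),
                    ),
                )
            )
    balance = pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after"])
    if unmatched:
        warnings.warn(f"{len(unmatched)} case(s) unmatched: {unmatched}", stacklevel=2)
    return MatchResult(pairs=pairs_df, unmatched_cases=unmatched, balance=balance)


@dataclass(frozen=True)
class OddsRatioResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    fdr_q: float | None = None
    n_used: int = 0


def adjusted_logistic(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: tuple[str, ...] | list[str] = (),
) -> OddsRatioResult:
    """Covariate-adjusted logistic regression odds ratio for one exposure.

    Maximum-likelihood fit of ``outcome ~ exposure + covariates``; the OR
    is exp(coefficient) per unit of exposure with a Wald 95% CI.  Complete
    separation raises with a pointer to penalised alternatives.
    """
    cols = [outcome, exposure, *covariates]
    df = data[cols].dropna()
    yv = df[outcome].to_numpy(dtype=float)
    if not set(np.unique(yv)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X = sm.add_constant(df[[exposure, *covariates]].astype(float))
    try:
        fit = sm.Logit(yv, X).fit(disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as err:
        # separation drives coefficients to infinity; the Hessian then
        # degenerates, which statsmodels may surface as a singular matrix
        raise ValueError(
            f"complete separation fitting {exposure!r}; consider a "
            "penalized (Firth-type) fit"
        ) from err
    coef = fit.params[exposure]
    ci = fit.conf_int().loc[exposure]
    return OddsRatioResult(
        variable=exposure,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p=float(fit.pvalues[exposure]),
        n_used=len(df),
    )


def odds_ratio_panel(
    data: pd.DataFrame,
    outcome: str,
    exposures: list[str],
    covariates: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Adjusted ORs for a panel of exposures with BH FDR across the panel."""
    results = [adjusted_logistic(data, outcome, e, covariates) for e in exposures]
    q = bh_fdr([r.p for r in results])
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "fdr_q": q,
            "n_used": [r.n_used for r in results],
        }
    )


def longitudinal_group_average(
    series_table: pd.DataFrame,
    traits: list[str],
    subject_col: str = "subject_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """Collapse repeated visits to per-subject means, then test groups.

    Each trait is averaged over a subject's visits; the two study groups
    are compared by Welch t test with BH FDR across traits.  Subjects with
    all-missing values for a trait are excluded from that trait's test
    with a warning.
    """
    per_subject = series_table.groupby(subject_col).agg(
        {**{t: "mean" for t in traits}, group_col: "first"}
    )
    rows = []
    for t in traits:
        sub = per_subject[[t, group_col]]
        n_all = len(sub)
        sub = sub.dropna(subset=[t])
        if len(sub) < n_all:
            warnings.warn(
                f"{n_all - len(sub)} subject(s) with all-missing {t!r} excluded",
                stacklevel=2,
            )
        res = two_group_test(sub[t], sub[group_col], variable=t)
        rows.append(res)
    q = bh_fdr([r.p_value for r in rows])
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "estimate": [r.estimate for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p": [r.p_value for r in rows],
            "fdr_q": q,
            "n_used": [r.n_used for r in rows],
        }
    )
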