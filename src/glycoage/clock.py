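"""Stability-selection LASSO glycan aging clock.

The clock estimates biological age from IgG glycan features (optionally
combined with inflammatory markers).  Feature selection runs in a control
group only:

1. one round of 5-fold cross-validated LASSO chooses the penalty by the
   one-standard-error rule (largest penalty whose mean CV error is within
   one SE of the minimum) and records the features with nonzero
   coefficients at that penalty;
2. the round is repeated (default 100 times) with reshuffled fold
   assignments; features selected in >= 80 of 100 rounds form the final
   predictor set (stability selection);
3. the final clock is an *unpenalized* least-squares refit of chronological
   age on the selected features in controls, so the mean residual in the
   training controls is exactly zero ("zero-mean calibration").

Age acceleration in a test group is then predicted-minus-chronological
age; by construction the control reference is zero-mean, and the group
contrast is a two-sided Welch t test of case deltas against control
deltas.  Nested models (e.g. glycans vs glycans + inflammatory markers)
are compared with a Gaussian likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, lasso_path

from .stats import bh_fdr

__all__ = [
    "ClockModel",
    "AccelerationResult",
    "cv_lasso_round",
    "stability_select",
    "fit_clock",
    "age_acceleration",
    "nested_lrt",
    "screen_markers_by_age",
]


@dataclass(frozen=True)
class ClockModel:
    """A fitted linear age clock.

    Coefficients are in years per unit of the (unstandardised) feature;
    the intercept absorbs the zero-mean calibration on the training
    controls.
    """

    features: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    selection_frequency: dict[str, int] = field(default_factory=dict)
    training_group: str = ""
    n_train: int = 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        M = X[list(self.features)].to_numpy(dtype=float)
        return self.intercept + M @ np.asarray(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "selection_frequency": dict(self.selection_frequency),
            "training_group": self.training_group,
            "n_train": self.n_train,
        }


@dataclass(frozen=True)
class AccelerationResult:
    """Group-level age acceleration: predicted minus chronological age."""

    per_sample_delta: np.ndarray
    group_mean: float
    group_sd: float
    p_value: float
    pooled_sd: float | None = None


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all-zero fit) down 4 decades."""
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - 4.0, n_lambda)


def _fold_assignment(
    y: np.ndarray, n_folds: int, rng: np.random.Generator, stratify: bool
) -> np.ndarray:
    """Fold labels; stratified by response quintile to stabilise small folds."""
    n = len(y)
    folds = np.empty(n, dtype=int)
    if stratify:
        quintile = pd.qcut(pd.Series(y).rank(method="first"), 5, labels=False).to_numpy()
        for q in np.unique(quintile):
            idx = np.where(quintile == q)[0]
            labels = np.arange(len(idx)) % n_folds
            rng.shuffle(labels)
            folds[idx] = labels
    else:
        labels = np.arange(n) % n_folds
        rng.shuffle(labels)
        folds = labels
    return folds


def cv_lasso_round(
    X: pd.DataFrame,
    y,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    stratify_folds: bool = True,
) -> tuple[float, tuple[str, ...]]:
    """One round of K-fold CV LASSO with the one-standard-error rule.

    Features are standardised internally (training-fold mean/SD).  Returns
    ``(lambda_1se, selected_features)`` where ``lambda_1se`` is the largest
    penalty whose mean CV error is <= min(mean CV error) + one SE of that
    minimum, and the selected features are those with nonzero coefficients
    in a full-data fit at that penalty.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.all(y == y[0]):
        raise ValueError("constant response")
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} rows for {n_folds}-fold CV")
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xa - mu) / sd
    lambdas = _lambda_grid(Xs, y)

    rng = np.random.default_rng(seed)
    folds = _fold_assignment(y, n_folds, rng, stratify_folds)
    cv_err = np.empty((n_folds, len(lambdas)))
    for k in range(n_folds):
        tr, te = folds != k, folds == k
        Xtr, ytr = Xs[tr], y[tr]
        # center within the training fold; the path solver fits no intercept
        m_tr, s_tr = Xtr.mean(axis=0), Xtr.std(axis=0)
        s_tr = np.where(s_tr > 0, s_tr, 1.0)
        Xtr_s = (Xtr - m_tr) / s_tr
        Xte_s = (Xs[te] - m_tr) / s_tr
        y_mean = ytr.mean()
        _, coefs, _ = lasso_path(
            Xtr_s, ytr - y_mean, alphas=lambdas, max_iter=50_000, tol=1e-8
        )
        pred = Xte_s @ coefs + y_mean  # (n_test, n_lambda)
        cv_err[k] = np.mean((y[te, None] - pred) ** 2, axis=0)
    mean_err = cv_err.mean(axis=0)
    se_err = cv_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    j_min = int(np.argmin(mean_err))
    threshold = mean_err[j_min] + se_err[j_min]
    # grid is decreasing in lambda, so the first index meeting the
    # threshold is the largest qualifying penalty
    j_1se = int(np.argmax(mean_err <= threshold))
    lam_1se = float(lambdas[j_1se])

    final = Lasso(alpha=lam_1se, max_iter=50_000, tol=1e-8)
    final.fit(Xs, y)
    selected = tuple(names[i] for i in np.where(final.coef_ != 0)[0])
    return lam_1se, selected


def stability_select(
    X: pd.DataFrame,
    y,
    rounds: int = 100,
    keep_threshold: int = 80,
    base_seed: int = 0,
    n_folds: int = 5,
    stratify_folds: bool = True,
) -> tuple[dict[str, int], tuple[str, ...]]:
    """Stability selection over repeated CV LASSO rounds.

    Runs :func:`cv_lasso_round` with seeds ``base_seed .. base_seed +
    rounds - 1`` (fold reshuffling is the only source of randomness) and
    keeps features selected in at least ``keep_threshold`` rounds.
    Returns ``(selection_frequency, final_feature_set)`` with frequencies
    reported for every candidate.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not (0 < keep_threshold <= rounds):
        raise ValueError("keep_threshold must be in (0, rounds]")
    freq = {name: 0 for name in X.columns}
    for r in range(rounds):
        _, selected = cv_lasso_round(
            X, y, n_folds=n_folds, seed=base_seed + r, stratify_folds=stratify_folds
        )
        for name in selected:
            freq[name] += 1
    final = tuple(name for name in X.columns if freq[name] >= keep_threshold)
    if not final:
        warnings.warn("stability selection kept no features", stacklevel=2)
    return freq, final


def fit_clock(
    X_controls: pd.DataFrame,
    age_controls,
    features,
    selection_frequency: dict[str, int] | None = None,
    training_group: str = "",
) -> ClockModel:
    """Unpenalized least-squares refit of age on the selected features.

    The intercept absorbs calibration, so the mean residual on the
    training controls is exactly zero (ordinary least squares with an
    intercept).  Raises on collinear selected features.
    """
    features = tuple(features)
    age = np.asarray(age_controls, dtype=float)
    M = X_controls[list(features)].to_numpy(dtype=float)
    D = np.column_stack([np.ones(len(age)), M])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(f"collinear selected features among {features}")
    beta, *_ = np.linalg.lstsq(D, age, rcond=None)
    return ClockModel(
        features=features,
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        selection_frequency=dict(selection_frequency or {}),
        training_group=training_group,
        n_train=len(age),
    )


def age_acceleration(
    model: ClockModel,
    X_cases: pd.DataFrame,
    age_cases,
    X_controls: pd.DataFrame | None = None,
    age_controls=None,
) -> AccelerationResult:
    """Age acceleration of a case group under a fitted clock.

    Per-sample delta = predicted − chronological age.  The two-sided
    Welch t test compares case deltas against control deltas when the
    control data are supplied (the training controls are zero-mean by
    construction); otherwise a one-sample t test against zero is used.
    ``pooled_sd`` is the SD of the case-minus-control pooled deltas,
    reported alongside the case-only ``group_sd``.
    """
    delta = model.predict(X_cases) - np.asarray(age_cases, dtype=float)
    if X_controls is not None and age_controls is not None:
        ref = model.predict(X_controls) - np.asarray(age_controls, dtype=float)
        t = sps.ttest_ind(delta, ref, equal_var=False)
        pooled = float(np.std(np.concatenate([delta, ref]), ddof=1))
    else:
        t = sps.ttest_1samp(delta, 0.0)
        pooled = None
    sd = float(np.std(delta, ddof=1)) if len(delta) > 1 else float("nan")
    return AccelerationResult(
        per_sample_delta=delta,
        group_mean=float(np.mean(delta)),
        group_sd=sd,
        p_value=float(t.pvalue),
        pooled_sd=pooled,
    )


def nested_lrt(
    model_small: ClockModel, model_large: ClockModel, X: pd.DataFrame, y
) -> tuple[float, int, float]:
    """Gaussian likelihood-ratio test between nested linear clocks.

    Both models are refit on the given rows (same response).  The statistic
    is ``n * log(RSS_small / RSS_large)`` referred to a chi-square with
    df = difference in feature counts.
    """
    small, large = set(model_small.features), set(model_large.features)
    if not small < large:
        raise ValueError("model_small's features must be a proper subset of model_large's")
    y = np.asarray(y, dtype=float)
    n = len(y)

    def rss(features: tuple[str, ...]) -> float:
        refit = fit_clock(X, y, features)
        return float(np.sum((y - refit.predict(X)) ** 2))

    rss_s, rss_l = rss(model_small.features), rss(model_large.features)
    lr = n * np.log(rss_s / rss_l)
    df = len(large) - len(small)
    p = float(sps.chi2.sf(lr, df))
    return float(lr), df, p


def screen_markers_by_age(
    markers: pd.DataFrame, age, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Pre-screen candidate markers by Spearman correlation with age.

    Returns a tidy table (marker, rho, p, q, selected) where ``selected``
    means BH q < ``fdr_threshold`` across the panel — the gate used before
    admitting inflammatory markers into a combined clock.
    """
    age = np.asarray(age, dtype=float)
    rows = []
    for col in markers.columns:
        v = markers[col].to_numpy(dtype=float)
        keep = ~(np.isnan(v) | np.isnan(age))
        rho, p = sps.spearmanr(age[keep], v[keep])
        rows.append((col, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["marker", "rho", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["selected"] = out["q"] < fdr_threshold
    return out
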