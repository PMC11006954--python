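"""Synthetic glycomics cohort generator.

Real individual-level cohort data of this kind (ART-suppressed HIV cohorts
with IgG glycomics) are access-restricted, so every analysis stage in this
package is exercised against a generator that emulates the statistical
structure those analyses assume:

- four study groups (sex × HIV status) with sizes and age-band composition
  mirroring the reference cohort design (235/254/253/243 across six age
  bands from <=45 to >65);
- compositional glycan profiles over the 20-structure panel plus an
  unidentified component, summing to 100%;
- linear age trends per structure, HIV- and sex-dependent level shifts,
  additive Gaussian noise, and projection back onto the simplex;
- inflammatory markers driven linearly by the derived glycan groups;
- CE peak tables back-generated from the percentages at the reference RMU
  positions (with an arbitrary per-sample area scale and an optional
  carryover peak at RMU 220);
- a planted "age acceleration" in the HIV-positive group, implemented by
  shifting every age-sloped structure by delta x its generating slope —
  exactly the displacement delta extra years of aging would produce, so
  the planted value has an exact interpretation in years;
- case/control outcome labels drawn from a logistic model on the derived
  traits.

Defaults: generating age slopes, HIV shifts and sex shifts each sum to
zero across structures so the simplex renormalisation is neutral; HIV
level-shifts are confined to structures with zero age slope so that the
planted acceleration parameter is the only clock-relevant displacement.
Every random draw comes from one seeded generator: the same seed gives a
bit-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import UNIDENTIFIED, PeakTable, default_reference, derive_traits_frame

__all__ = [
    "STUDY_DESIGN",
    "MARKER_PANEL",
    "GeneratorConfig",
    "SyntheticBundle",
    "generate_cohort",
    "truth_report",
]

#: Reference cohort design the default generator mimics: group sizes and
#: per-age-band counts (bands <=45, 46-50, 51-55, 56-60, 61-65, >65).
STUDY_DESIGN: dict[tuple[str, str], tuple[int, ...]] = {
    ("F", "negative"): (33, 56, 55, 50, 35, 6),
    ("F", "positive"): (23, 50, 68, 59, 45, 9),
    ("M", "negative"): (17, 36, 54, 63, 49, 34),
    ("M", "positive"): (20, 43, 58, 54, 36, 32),
}

#: Reference substudy designs: the inflammation panel measured a matched
#: subsample of 100 per group, and the coronary-plaque case-control design
#: used (controls, cases) pairs of (22, 22) in the HIV-negative and
#: (34, 34) in the HIV-positive stratum.
INFLAMMATION_SUBSTUDY_N: dict[tuple[str, str], int] = {
    k: 100 for k in (
        ("F", "negative"), ("F", "positive"), ("M", "negative"), ("M", "positive"),
    )
}
CORONARY_CASE_CONTROL_N: dict[str, tuple[int, int]] = {
    "negative": (22, 22),
    "positive": (34, 34),
}

AGE_BANDS: tuple[tuple[float, float], ...] = (
    (40.0, 45.0),
    (46.0, 50.0),
    (51.0, 55.0),
    (56.0, 60.0),
    (61.0, 65.0),
    (66.0, 75.0),
)

#: 22-analyte inflammation panel (pg/mL).
MARKER_PANEL: tuple[str, ...] = (
    "CXCL9", "Eotaxin", "Leptin", "TNF-a", "IP-10", "sCD14", "sCD163",
    "IL-6", "IL-4", "IL-5", "IL-12p70", "MIP-1a", "MCP-2", "IL-1b", "IL-2",
    "IL-8", "IL-10", "IFN-g", "MCP-1", "MIP-1b", "GM-CSF", "CRP",
)

_BASELINE = {
    "A2": 1.5, "A2B": 1.0, "FA2": 18.0, "FA2B": 6.0,
    "A2[6]G1": 1.0, "A2[3]G1": 0.8, "FA2[6]G1": 17.0, "FA2[3]G1": 8.0,
    "FA2BG1": 5.0, "A2G2": 1.2, "A2BG2": 0.8, "FA2G2": 12.0,
    "FA2BG2": 3.5, "A2G1S1": 0.7, "A2G2S1": 1.5, "FA2G2S1": 11.0,
    "FA2BG2S1": 2.5, "A2G2S2": 2.0, "FA2G2S2": 3.0, "FA2BG2S2": 1.5,
    UNIDENTIFIED: 2.0,
}

# percent per year; sums to zero so renormalisation stays neutral.
# Agalactosylated structures accumulate with age; galactosylated and
# sialylated structures decline.
_AGE_SLOPES = {
    "A2": 0.10, "FA2B": 0.08, "FA2BG1": 0.04, "A2G2S2": -0.22,
    "FA2": 0.25, "FA2[6]G1": -0.08, "FA2[3]G1": -0.05, "FA2G2": -0.12,
}

# HIV level shifts (percent), on zero-slope structures only; sums to zero.
_HIV_SHIFTS = {
    "A2B": 0.5, "A2BG2": 0.3, "A2G2": -0.2,
    "FA2BG2": -0.3, "FA2BG2S1": -0.2, "FA2BG2S2": -0.1,
}

# shifts applied to men relative to women (percent); zero-slope structures.
_SEX_SHIFTS = {
    "A2B": 0.3, "A2BG2": 0.2, "FA2BG2S1": -0.3, "A2G1S1": -0.2,
}

# marker = baseline + sum loading * (group - its generating baseline) + noise
_MARKER_BASELINES = {
    "CXCL9": 120.0, "Eotaxin": 90.0, "Leptin": 9000.0, "TNF-a": 12.0,
    "IP-10": 150.0, "sCD14": 1.6e6, "sCD163": 6.0e5, "IL-6": 2.5,
    "IL-4": 1.2, "IL-5": 1.5, "IL-12p70": 1.0, "MIP-1a": 25.0,
    "MCP-2": 40.0, "IL-1b": 0.8, "IL-2": 1.0, "IL-8": 12.0, "IL-10": 1.5,
    "IFN-g": 6.0, "MCP-1": 180.0, "MIP-1b": 80.0, "GM-CSF": 1.2,
    "CRP": 2.0e6,
}
_MARKER_LOADINGS = {
    "CXCL9": {"agalactosylated": 8.0, "sialylated": -5.0},
    "Eotaxin": {"agalactosylated": 6.0},
    "TNF-a": {"bisected": 1.5},
    "IP-10": {"agalactosylated": 10.0},
    "sCD14": {"sialylated": -4.0e4},
    "sCD163": {"agalactosylated": 1.5e4},
    "IL-6": {"agalactosylated": 0.15},
}
_MARKER_NOISE_FRAC = 0.2  # noise SD as a fraction of the marker baseline


@dataclass
class GeneratorConfig:
    """Stated world for the synthetic cohort; defaults mirror the reference design."""

    n_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {k: sum(v) for k, v in STUDY_DESIGN.items()}
    )
    glycan_means: dict[str, float] = field(default_factory=lambda: dict(_BASELINE))
    age_slopes: dict[str, float] = field(default_factory=lambda: dict(_AGE_SLOPES))
    hiv_shifts: dict[str, float] = field(default_factory=lambda: dict(_HIV_SHIFTS))
    sex_shifts: dict[str, float] = field(default_factory=lambda: dict(_SEX_SHIFTS))
    noise_sd: float = 0.4
    subject_sd: float = 0.3
    planted_acceleration: float = 3.5
    outcome_model: dict[str, float] = field(
        default_factory=lambda: {"agalactosylated": 0.12, "bisected": 0.15}
    )
    outcome_intercept: float = -0.8
    marker_loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _MARKER_LOADINGS.items()}
    )
    n_visits: int = 1
    visit_interval: float = 2.0
    area_scale: float = 1e5
    carryover_percent: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        if any(m <= 0 for m in self.glycan_means.values()):
            raise ValueError("baseline means must be positive")
        if sum(self.glycan_means.values()) > 100.0 + 1e-9:
            raise ValueError("baseline means must sum to <= 100")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        unknown = set(self.age_slopes) | set(self.hiv_shifts) | set(self.sex_shifts)
        unknown -= set(self.glycan_means)
        if unknown:
            raise ValueError(f"slopes/shifts reference unknown structures: {unknown}")


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes plus the planted truth."""

    cohort: pd.DataFrame
    profiles: pd.DataFrame  # sample x structure percent, incl. UNIDENTIFIED
    markers: pd.DataFrame
    peak_tables: list[PeakTable]
    truth: dict


def _band_counts(total: int, design_bands: tuple[int, ...]) -> list[int]:
    """Scale the design's band counts to the requested group size."""
    design_total = sum(design_bands)
    raw = [total * b / design_total for b in design_bands]
    counts = [int(np.floor(r)) for r in raw]
    # distribute the remainder to the largest fractional parts
    rem = total - sum(counts)
    frac_order = np.argsort([c - np.floor(c) for c in raw])[::-1]
    for i in frac_order[:rem]:
        counts[i] += 1
    return counts


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Draw a full synthetic cohort bundle from the configured world."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    structures = list(cfg.glycan_means)
    baseline = np.array([cfg.glycan_means[s] for s in structures])
    slopes = np.array([cfg.age_slopes.get(s, 0.0) for s in structures])
    hiv_shift = np.array([cfg.hiv_shifts.get(s, 0.0) for s in structures])
    sex_shift = np.array([cfg.sex_shifts.get(s, 0.0) for s in structures])

    subj_rows = []
    for (sex, hiv), n in cfg.n_per_group.items():
        bands = _band_counts(n, STUDY_DESIGN.get((sex, hiv), STUDY_DESIGN[("F", "negative")]))
        for (lo, hi), cnt in zip(AGE_BANDS, bands):
            ages = rng.uniform(lo, hi, size=cnt)
            for a in ages:
                subj_rows.append((sex, hiv, float(a)))
    n_subj = len(subj_rows)

    meta, profile_rows, marker_rows, peak_tables = [], [], [], []
    ref = default_reference()
    centers = {name: c for c, name, _ in ref.entries}
    group_base = _group_baselines(cfg)

    for i, (sex, hiv, age0) in enumerate(subj_rows):
        subject_id = f"S{i:04d}"
        ethnicity = _draw_ethnicity(rng, sex)
        bmi = float(rng.normal(30.4 if sex == "F" else 25.9, 4.0 if sex == "F" else 3.0))
        menopause = _menopause(age0) if sex == "F" else None
        cd4 = float(rng.normal(720, 180)) if hiv == "positive" else np.nan
        nadir = float(rng.normal(260, 120)) if hiv == "positive" else np.nan
        subj_re = rng.normal(0.0, cfg.subject_sd, size=len(structures))
        for visit in range(1, cfg.n_visits + 1):
            age = age0 + (visit - 1) * cfg.visit_interval
            mean = (
                baseline
                + slopes * (age - 50.0)
                + (hiv_shift if hiv == "positive" else 0.0)
                + (sex_shift if sex == "M" else 0.0)
                + (cfg.planted_acceleration * slopes if hiv == "positive" else 0.0)
            )
            values = mean + subj_re + rng.normal(0.0, cfg.noise_sd, size=len(structures))
            values = np.clip(values, 0.0, None)
            total = values.sum()
            if total <= 0:
                raise ValueError(
                    "infeasible simplex projection (negative mass); "
                    "use a smaller noise_sd"
                )
            values = 100.0 * values / total

            sample_id = f"{subject_id}V{visit}"
            profile_rows.append(pd.Series(values, index=structures, name=sample_id))
            meta.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject_id,
                    "visit_index": visit,
                    "age": age,
                    "sex": sex,
                    "hiv": hiv,
                    "ethnicity": ethnicity,
                    "bmi": bmi,
                    "menopause": menopause,
                    "cd4": cd4,
                    "nadir_cd4": nadir,
                }
            )
            peak_tables.append(
                _peaks_from_percentages(
                    sample_id, dict(zip(structures, values)), centers, cfg, rng
                )
            )

    cohort = pd.DataFrame(meta).set_index("sample_id")
    profiles = pd.DataFrame(profile_rows)
    profiles.index.name = "sample_id"

    traits = derive_traits_frame(profiles)
    markers = _draw_markers(cfg, traits, group_base, rng)

    logit = np.full(len(traits), cfg.outcome_intercept)
    for trait, coef in cfg.outcome_model.items():
        logit += coef * (traits[trait].to_numpy() - group_base[trait])
    p_case = 1.0 / (1.0 + np.exp(-logit))
    cohort["outcome"] = (rng.uniform(size=len(p_case)) < p_case).astype(int)

    truth = {
        "seed": cfg.seed,
        "planted_acceleration_years": cfg.planted_acceleration,
        "age_slopes": dict(cfg.age_slopes),
        "hiv_shifts": dict(cfg.hiv_shifts),
        "sex_shifts": dict(cfg.sex_shifts),
        "outcome_model": dict(cfg.outcome_model),
        "outcome_intercept": cfg.outcome_intercept,
        "noise_sd": cfg.noise_sd,
        "n_per_group": {f"{s}|{h}": n for (s, h), n in cfg.n_per_group.items()},
    }
    return SyntheticBundle(
        cohort=cohort,
        profiles=profiles,
        markers=markers,
        peak_tables=peak_tables,
        truth=truth,
    )


def _group_baselines(cfg: GeneratorConfig) -> dict[str, float]:
    """Derived-group values of the noise-free baseline profile (for centering)."""
    base = pd.DataFrame(
        [pd.Series(cfg.glycan_means, name="baseline")]
    )
    total = base.sum(axis=1).iloc[0]
    base = 100.0 * base / total
    t = derive_traits_frame(base)
    return {c: float(t[c].iloc[0]) for c in t.columns}


def _draw_ethnicity(rng: np.random.Generator, sex: str) -> str:
    levels = ("Black", "White", "Hispanic")
    probs = (0.70, 0.12, 0.18) if sex == "F" else (0.30, 0.58, 0.12)
    return str(rng.choice(levels, p=probs))


def _menopause(age: float) -> str:
    if age < 48:
        return "pre"
    if age < 52:
        return "peri"
    return "post"


def _peaks_from_percentages(
    sample_id: str,
    percentages: dict[str, float],
    centers: dict[str, float],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> PeakTable:
    """Back-generate a CE peak table from a percent profile.

    A per-sample lognormal exposure multiplies all areas (total AUC is
    arbitrary); RMU positions jitter within a third of the assignment
    tolerance; a carryover peak is planted at RMU 220.
    """
    exposure = float(rng.lognormal(0.0, 0.25)) * cfg.area_scale
    peaks = []
    for name, pct in percentages.items():
        rmu = centers[name] + float(rng.uniform(-0.5, 0.5))
        peaks.append((rmu, pct / 100.0 * exposure))
    if cfg.carryover_percent > 0:
        peaks.append(
            (220.0 + float(rng.uniform(-0.5, 0.5)),
             cfg.carryover_percent / 100.0 * exposure)
        )
    return PeakTable(sample_id=sample_id, peaks=tuple(peaks))


def _draw_markers(
    cfg: GeneratorConfig,
    traits: pd.DataFrame,
    group_base: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    cols = {}
    for marker in MARKER_PANEL:
        base = _MARKER_BASELINES[marker]
        level = np.full(len(traits), base)
        for group, loading in cfg.marker_loadings.get(marker, {}).items():
            level = level + loading * (traits[group].to_numpy() - group_base[group])
        level = level + rng.normal(0.0, _MARKER_NOISE_FRAC * base, size=len(traits))
        cols[marker] = np.clip(level, 0.0, None)
    return pd.DataFrame(cols, index=traits.index)


def truth_report(bundle: SyntheticBundle) -> pd.DataFrame:
    """Planted parameters as a tidy table keyed to analysis outputs.

    Columns: ``parameter, target, value`` — e.g. the per-structure age
    slopes in percent/year (what `slope_difference` estimates), HIV and
    sex shifts in percent (what `two_group_test` estimates), the planted
    acceleration in years (what `age_acceleration` estimates) and the
    outcome log-odds coefficients (what `adjusted_logistic` estimates).
    The table round-trips through CSV unchanged.
    """
    rows = []
    t = bundle.truth
    for s, v in t["age_slopes"].items():
        rows.append(("age_slope_percent_per_year", s, float(v)))
    for s, v in t["hiv_shifts"].items():
        rows.append(("hiv_shift_percent", s, float(v)))
    for s, v in t["sex_shifts"].items():
        rows.append(("sex_shift_percent", s, float(v)))
    rows.append(("planted_acceleration_years", "", float(t["planted_acceleration_years"])))
    for trait, v in t["outcome_model"].items():
        rows.append(("outcome_log_odds_per_percent", trait, float(v)))
    rows.append(("outcome_intercept", "", float(t["outcome_intercept"])))
    return pd.DataFrame(rows, columns=["parameter", "target", "value"])
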