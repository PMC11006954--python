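"""Reproducible end-to-end runs: config, stage orchestration, manifest.

`run_pipeline` ties the stages together — simulate (or load inputs),
peak-table annotation into derived traits, cohort statistics, the glycan
clock, and case-control matching — writing tidy CSV/JSON outputs plus a
manifest recording package version, seeds, input checksums and every
data-quality warning (dropped peaks, unmatched cases, skipped strata).
Identical config + seed gives identical outputs and an identical manifest
(timestamps aside).

Configs may be built in Python (`RunConfig`) or loaded from YAML.  All
CSV output is comma-separated, UTF-8, "." decimal, with a header row, and
numbers are serialized at full precision (`repr` round-trip).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import age_acceleration, fit_clock, stability_select
from .matching import MatchSpec, nearest_neighbor_match, odds_ratio_panel
from .simulate import GeneratorConfig, SyntheticBundle, generate_cohort, truth_report
from .stats import bh_fdr, spearman_matrix, two_group_test
from .traits import (
    DERIVED_TRAIT_NAMES,
    RmuReference,
    default_reference,
    derive_traits_frame,
    profile_from_peaks,
    profiles_to_frame,
    PeakTable,
)

__all__ = ["RunConfig", "run_pipeline", "read_peak_csv", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` is set (a GeneratorConfig for the synthetic
    cohort) or ``peaks_csv`` + ``cohort_csv`` point at input files.
    """

    out_dir: str | Path = "glycoage_run"
    seed: int = 0
    simulate: GeneratorConfig | None = None
    peaks_csv: str | Path | None = None
    cohort_csv: str | Path | None = None
    reference_csv: str | Path | None = None
    rmu_tolerance: float = 1.5
    stages: tuple[str, ...] = ("traits", "stats", "clock", "match")
    clock_rounds: int = 100
    clock_threshold: int = 80
    match_covariates: tuple[str, ...] = ("age", "bmi")
    match_exact_on: tuple[str, ...] = ("ethnicity",)

    def validate(self) -> None:
        if self.simulate is None:
            if self.peaks_csv is None or self.cohort_csv is None:
                raise ValueError(
                    "config error: either `simulate` or both `peaks_csv` and "
                    "`cohort_csv` must be given"
                )
            for path in (self.peaks_csv, self.cohort_csv, self.reference_csv):
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"config error: missing input file {path}")
        unknown = set(self.stages) - {"traits", "stats", "clock", "match"}
        if unknown:
            raise ValueError(f"config error: unknown stages {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "simulate"})
    if sim is not None:
        cfg.simulate = GeneratorConfig(**sim) if isinstance(sim, dict) else GeneratorConfig()
    return cfg


def read_peak_csv(path: str | Path) -> list[PeakTable]:
    """Read a long-form peak CSV (sample_id, rmu, area) into PeakTables."""
    df = pd.read_csv(path)
    tables = []
    for sid, sub in df.groupby("sample_id", sort=True):
        peaks = tuple(
            (float(r.rmu), float(r.area)) for r in sub.itertuples()
        )
        tables.append(PeakTable(sample_id=str(sid), peaks=peaks))
    return tables


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format=None)  # full repr precision


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "glycoage",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {},
        "outputs": {},
        "warnings": [],
    }

    caught: list[str] = []

    def log_warnings(ws) -> None:
        for w in ws:
            caught.append(str(w.message))

    # ---- inputs ---------------------------------------------------------
    ref = (
        RmuReference.from_csv(config.reference_csv, tolerance=config.rmu_tolerance,
                              exclusion_zones=((215.0, 225.0, "carryover"),))
        if config.reference_csv
        else default_reference(tolerance=config.rmu_tolerance)
    )
    if config.simulate is not None:
        sim_cfg = config.simulate
        sim_cfg.seed = config.seed
        bundle: SyntheticBundle = generate_cohort(sim_cfg)
        cohort = bundle.cohort
        peak_tables = bundle.peak_tables
        _write_csv(truth_report(bundle), out / "truth.csv", index=False)
        manifest["outputs"]["truth"] = "truth.csv"
        manifest["inputs"]["simulated"] = {"seed": config.seed}
    else:
        peak_tables = read_peak_csv(config.peaks_csv)
        cohort = pd.read_csv(config.cohort_csv).set_index("sample_id")
        for key, path in (("peaks", config.peaks_csv), ("cohort", config.cohort_csv)):
            manifest["inputs"][key] = {
                "path": str(path),
                "sha256": _sha256(Path(path)),
            }

    # ---- traits ---------------------------------------------------------
    profiles = traits = None
    if "traits" in config.stages:
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            prof_list = [profile_from_peaks(t, ref) for t in peak_tables]
        log_warnings(ws)
        profiles = profiles_to_frame(prof_list)
        traits = derive_traits_frame(profiles)
        _write_csv(profiles, out / "profiles.csv")
        _write_csv(traits, out / "derived_traits.csv")
        manifest["outputs"]["profiles"] = "profiles.csv"
        manifest["outputs"]["derived_traits"] = "derived_traits.csv"

    # ---- stats ----------------------------------------------------------
    if "stats" in config.stages and traits is not None:
        joined = traits.join(cohort[["sex", "hiv"]])
        rows = []
        for sex in sorted(joined["sex"].unique()):
            sub = joined[joined["sex"] == sex]
            for trait in DERIVED_TRAIT_NAMES:
                if trait == "gal_ratio":
                    continue
                res = two_group_test(sub[trait], sub["hiv"], variable=trait)
                rows.append(
                    {
                        "stratum": sex,
                        "variable": trait,
                        "estimate": res.estimate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p_value,
                        "n_used": res.n_used,
                    }
                )
        stats_df = pd.DataFrame(rows)
        stats_df["fdr_q"] = np.concatenate(
            [
                bh_fdr(stats_df.loc[stats_df["stratum"] == s, "p"].to_numpy())
                for s in sorted(stats_df["stratum"].unique())
            ]
        )
        _write_csv(stats_df, out / "group_tests.csv", index=False)
        manifest["outputs"]["group_tests"] = "group_tests.csv"

    # ---- clock ----------------------------------------------------------
    if "clock" in config.stages and traits is not None:
        glycan_cols = [c for c in profiles.columns if c != "UNIDENTIFIED"]
        men = cohort[cohort["sex"] == "M"]
        controls = men[men["hiv"] == "negative"]
        cases = men[men["hiv"] == "positive"]
        Xc = profiles.loc[controls.index, glycan_cols]
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            freq, selected = stability_select(
                Xc,
                controls["age"],
                rounds=config.clock_rounds,
                keep_threshold=config.clock_threshold,
                base_seed=config.seed,
            )
        log_warnings(ws)
        if selected:
            model = fit_clock(Xc, controls["age"], selected, freq, training_group="M|negative")
            accel = age_acceleration(
                model,
                profiles.loc[cases.index, glycan_cols],
                cases["age"],
                Xc,
                controls["age"],
            )
            deltas = pd.DataFrame(
                {"delta_years": accel.per_sample_delta}, index=cases.index
            )
            _write_csv(deltas, out / "clock_deltas.csv")
            with open(out / "clock_model.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        **model.to_dict(),
                        "acceleration_mean_years": accel.group_mean,
                        "acceleration_sd_years": accel.group_sd,
                        "acceleration_p": accel.p_value,
                        "base_seed": config.seed,
                        "rounds": config.clock_rounds,
                        "threshold": config.clock_threshold,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            manifest["outputs"]["clock_model"] = "clock_model.json"
            manifest["outputs"]["clock_deltas"] = "clock_deltas.csv"
        else:
            caught.append("clock: stability selection kept no features")

    # ---- match ----------------------------------------------------------
    if "match" in config.stages and traits is not None and "outcome" in cohort.columns:
        hiv_pos = cohort[cohort["hiv"] == "positive"]
        case_rows = hiv_pos[hiv_pos["outcome"] == 1]
        pool_rows = hiv_pos[hiv_pos["outcome"] == 0]
        if len(case_rows) and len(pool_rows):
            spec = MatchSpec(
                numeric=config.match_covariates, exact_on=config.match_exact_on
            )
            with warnings.catch_warnings(record=True) as ws:
                warnings.simplefilter("always")
                match = nearest_neighbor_match(case_rows, pool_rows, spec, seed=config.seed)
            log_warnings(ws)
            _write_csv(match.pairs, out / "matched_pairs.csv", index=False)
            manifest["outputs"]["matched_pairs"] = "matched_pairs.csv"
            matched_ids = list(match.pairs["case_id"]) + list(match.pairs["control_id"])
            matched = traits.loc[matched_ids].join(cohort["outcome"])
            panel = [t for t in DERIVED_TRAIT_NAMES if t != "gal_ratio"]
            ors = odds_ratio_panel(matched, "outcome", panel)
            _write_csv(ors, out / "odds_ratios.csv", index=False)
            manifest["outputs"]["odds_ratios"] = "odds_ratios.csv"
        else:
            caught.append("match: not enough cases/controls to match")

    manifest["warnings"] = caught
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
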