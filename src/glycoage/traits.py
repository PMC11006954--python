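"""Capillary-electrophoresis peak annotation and derived IgG glycan traits.

A CE run of APTS-labelled IgG N-glycans yields a table of peaks, each with a
relative migration unit (RMU) position and an area under the curve.  Peaks
are assigned to known glycan structures by proximity to reference RMU
centers; some RMU regions are excluded outright (e.g. a carryover peak seen
in blank runs around RMU 220), and one peak (around RMU 334) is assigned to
the profile but deliberately left unidentified because published libraries
disagree on its identity.

Assigned areas are normalised to percent of total assigned area, giving a
compositional glycan profile per sample.  From the profile, five derived
glycan groups are computed from the presence/absence of four key
monosaccharides (sialic acid, galactose, core fucose, bisecting GlcNAc),
plus the Gal-ratio G0/(G1 + 2*G2), a galactosylation-distribution index.

The default RMU reference shipped with the package
(``data/rmu_reference_synthetic_v1.csv``) carries the 20-structure IgG
panel; its RMU centers are synthetic placeholders (only the excluded 220
and unidentified 334 positions are anchored to the assay) — override it
with your instrument's calibrated table for real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .nomenclature import parse_oxford_name

__all__ = [
    "UNIDENTIFIED",
    "PeakTable",
    "RmuReference",
    "GlycanProfile",
    "DerivedTraits",
    "DERIVED_TRAIT_NAMES",
    "default_reference",
    "assign_peaks",
    "normalize_abundances",
    "profile_from_peaks",
    "derive_groups",
    "gal_ratio",
    "derive_traits_frame",
    "profiles_to_frame",
]

#: Sentinel name for a peak that is assigned to the profile but whose
#: structural identity is not called.
UNIDENTIFIED = "UNIDENTIFIED"

DERIVED_TRAIT_NAMES = (
    "agalactosylated",
    "terminal_galactosylated",
    "sialylated",
    "fucosylated",
    "bisected",
    "gal_ratio",
)


@dataclass(frozen=True)
class PeakTable:
    """CE peaks for one sample: (RMU position, AUC area) pairs."""

    sample_id: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for rmu, area in self.peaks:
            if rmu <= 0:
                raise ValueError(f"{self.sample_id}: RMU must be positive, got {rmu}")
            if area < 0:
                raise ValueError(f"{self.sample_id}: area must be >= 0, got {area}")


@dataclass(frozen=True)
class RmuReference:
    """Reference RMU centers for peak assignment.

    entries
        ``(rmu_center, name, identified)`` triples; ``name`` may be the
        :data:`UNIDENTIFIED` sentinel (then ``identified`` must be False).
    tolerance
        Half-width of the assignment window in RMU; the window is closed on
        both ends.
    exclusion_zones
        ``(rmu_low, rmu_high, reason)`` open intervals whose peaks are
        dropped (with the reason logged) before assignment.
    """

    entries: tuple[tuple[float, str, bool], ...]
    tolerance: float = 1.5
    exclusion_zones: tuple[tuple[float, float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        centers = sorted((c, n) for c, n, _ in self.entries)
        for (c1, n1), (c2, n2) in zip(centers, centers[1:]):
            if c2 - c1 <= 2 * self.tolerance:
                raise ValueError(
                    f"entry windows overlap at tolerance {self.tolerance}: "
                    f"{n1}@{c1} and {n2}@{c2}"
                )
        for lo, hi, reason in self.exclusion_zones:
            if lo >= hi:
                raise ValueError(f"empty exclusion zone ({lo}, {hi})")
            for c, n, _ in self.entries:
                if lo < c < hi:
                    raise ValueError(
                        f"exclusion zone ({lo}, {hi}, {reason!r}) contains "
                        f"entry center {n}@{c}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n, _ in self.entries)

    @property
    def identified_names(self) -> tuple[str, ...]:
        return tuple(n for _, n, ident in self.entries if ident)

    @classmethod
    def from_csv(
        cls,
        path,
        tolerance: float = 1.5,
        exclusion_zones: tuple[tuple[float, float, str], ...] = (),
    ) -> "RmuReference":
        """Load entries from a CSV with columns rmu_center, name, identified."""
        df = pd.read_csv(path)
        entries = tuple(
            (float(r.rmu_center), str(r.name), bool(int(r.identified)))
            for r in df.itertuples()
        )
        return cls(entries=entries, tolerance=tolerance, exclusion_zones=exclusion_zones)


def default_reference(tolerance: float = 1.5) -> RmuReference:
    """The shipped 20-structure panel plus the unidentified RMU-334 entry.

    Includes the carryover exclusion zone (215, 225) around RMU 220.  The
    RMU centers other than 220/334 are synthetic placeholders; see module
    docstring.
    """
    src = resources.files("glycoage.data") / "rmu_reference_synthetic_v1.csv"
    with resources.as_file(src) as p:
        return RmuReference.from_csv(
            p,
            tolerance=tolerance,
            exclusion_zones=((215.0, 225.0, "carryover"),),
        )


@dataclass(frozen=True)
class GlycanProfile:
    """Per-sample relative abundances (percent of total assigned area)."""

    sample_id: str
    abundances: dict[str, float]
    unidentified_percent: float = 0.0

    def __post_init__(self) -> None:
        for name, pct in self.abundances.items():
            if pct < 0:
                raise ValueError(f"{self.sample_id}: negative abundance for {name}")
        if self.unidentified_percent < 0:
            raise ValueError(f"{self.sample_id}: negative unidentified percent")
        total = sum(self.abundances.values()) + self.unidentified_percent
        if not math.isclose(total, 100.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"{self.sample_id}: abundances + unidentified sum to {total}, not 100"
            )


@dataclass(frozen=True)
class DerivedTraits:
    """The five glycan groups (percent) plus the Gal-ratio.

    ``gal_ratio`` is NaN when the profile has no galactosylated structures
    (zero denominator) — an undefined sentinel rather than an error.
    """

    agalactosylated: float
    terminal_galactosylated: float
    sialylated: float
    fucosylated: float
    bisected: float
    gal_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DERIVED_TRAIT_NAMES}


@dataclass
class AssignmentResult:
    """Outcome of peak assignment: every input peak lands in exactly one bin."""

    sample_id: str
    assigned: dict[str, float]
    excluded: list[tuple[float, float, str]] = field(default_factory=list)
    residual: list[tuple[float, float]] = field(default_factory=list)


def assign_peaks(table: PeakTable, ref: RmuReference) -> AssignmentResult:
    """Assign CE peaks to reference entries by RMU proximity.

    Each peak is classified as exactly one of: *excluded* (inside an
    exclusion zone, dropped with the zone's reason), *assigned* (within
    ``ref.tolerance`` of exactly one entry center, closed window), or
    *residual* (unmatched, returned — never silently discarded).  Areas of
    multiple peaks assigned to the same entry accumulate.
    """
    out = AssignmentResult(sample_id=table.sample_id, assigned={})
    for rmu, area in table.peaks:
        zone = next(
            ((lo, hi, why) for lo, hi, why in ref.exclusion_zones if lo < rmu < hi),
            None,
        )
        if zone is not None:
            out.excluded.append((rmu, area, zone[2]))
            continue
        hits = [n for c, n, _ in ref.entries if abs(rmu - c) <= ref.tolerance]
        if len(hits) > 1:
            raise ValueError(
                f"{table.sample_id}: peak at RMU {rmu} within tolerance of "
                f"multiple entries {hits}"
            )
        if hits:
            out.assigned[hits[0]] = out.assigned.get(hits[0], 0.0) + area
        else:
            out.residual.append((rmu, area))
    return out


def normalize_abundances(
    assigned: dict[str, float], sample_id: str = "sample"
) -> GlycanProfile:
    """Normalise assigned areas to percent of total assigned area.

    The denominator is the total over all assigned entries, identified and
    unidentified alike; residual (unassigned) peaks never enter it.
    """
    total = float(sum(assigned.values()))
    if total <= 0:
        raise ValueError(f"{sample_id}: empty profile (total assigned area is 0)")
    abundances = {
        name: 100.0 * area / total
        for name, area in assigned.items()
        if name != UNIDENTIFIED
    }
    unid = 100.0 * assigned.get(UNIDENTIFIED, 0.0) / total
    return GlycanProfile(
        sample_id=sample_id, abundances=abundances, unidentified_percent=unid
    )


def profile_from_peaks(table: PeakTable, ref: RmuReference) -> GlycanProfile:
    """Convenience: assign then normalise one sample's peak table."""
    return normalize_abundances(assign_peaks(table, ref).assigned, table.sample_id)


def _galactose_strata(profile: GlycanProfile) -> tuple[float, float, float]:
    """Percent abundance with exactly 0, 1 and 2 galactoses.

    Sialylated structures are counted by their galactose number.
    """
    g = [0.0, 0.0, 0.0]
    for name, pct in profile.abundances.items():
        comp = parse_oxford_name(name)
        g[min(comp.galactoses, 2)] += pct
    return g[0], g[1], g[2]


def gal_ratio(profile: GlycanProfile) -> float:
    """Gal-ratio: G0 / (G1 + 2*G2) over the galactosylation strata.

    Returns NaN when the denominator is zero (all-agalactosylated profile);
    returns 0.0 when only the numerator is zero.
    """
    g0, g1, g2 = _galactose_strata(profile)
    denom = g1 + 2.0 * g2
    if denom == 0.0:
        return float("nan")
    return g0 / denom


def derive_groups(profile: GlycanProfile) -> DerivedTraits:
    """Compute the five glycan groups and the Gal-ratio for one profile.

    Group membership by composition:

    - sialylated: at least one sialic acid;
    - terminal galactosylated: at least one galactose and no sialic acid
      (sialic acid caps the galactose terminus);
    - agalactosylated: zero galactoses;
    - fucosylated: core fucose present;
    - bisected: bisecting GlcNAc present.

    The first three partition the identified abundance, so
    ``agalactosylated + terminal_galactosylated + sialylated +
    unidentified_percent == 100``.  Unidentified abundance contributes to
    no group.
    """
    agal = tgal = sial = fuc = bis = 0.0
    for name, pct in profile.abundances.items():
        comp = parse_oxford_name(name)
        if comp.sialic_acids >= 1:
            sial += pct
        elif comp.galactoses >= 1:
            tgal += pct
        else:
            agal += pct
        if comp.core_fucose:
            fuc += pct
        if comp.bisecting:
            bis += pct
    return DerivedTraits(
        agalactosylated=agal,
        terminal_galactosylated=tgal,
        sialylated=sial,
        fucosylated=fuc,
        bisected=bis,
        gal_ratio=gal_ratio(profile),
    )


def profiles_to_frame(profiles: list[GlycanProfile]) -> pd.DataFrame:
    """Stack profiles into a sample × structure DataFrame (percent).

    Adds an ``UNIDENTIFIED`` column carrying the unidentified percent.
    Structures absent from a sample get 0.
    """
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, **p.abundances, UNIDENTIFIED: p.unidentified_percent}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    return df.fillna(0.0)


def derive_traits_frame(profile_frame: pd.DataFrame) -> pd.DataFrame:
    """Derived-trait table from a sample × structure percent DataFrame.

    ``profile_frame`` is as produced by :func:`profiles_to_frame`; an
    ``UNIDENTIFIED`` column, if present, is ignored for group membership.
    Rows need not sum exactly to 100 (the groups are linear in the columns).
    """
    cols = [c for c in profile_frame.columns if c != UNIDENTIFIED]
    comps = {c: parse_oxford_name(c) for c in cols}
    X = profile_frame[cols].to_numpy(dtype=float)

    def mask(pred) -> np.ndarray:
        return np.array([1.0 if pred(comps[c]) else 0.0 for c in cols])

    sial_m = mask(lambda c: c.sialic_acids >= 1)
    tgal_m = mask(lambda c: c.galactoses >= 1 and c.sialic_acids == 0)
    agal_m = mask(lambda c: c.galactoses == 0)
    fuc_m = mask(lambda c: c.core_fucose == 1)
    bis_m = mask(lambda c: c.bisecting == 1)
    g0_m = mask(lambda c: c.galactoses == 0)
    g1_m = mask(lambda c: c.galactoses == 1)
    g2_m = mask(lambda c: c.galactoses >= 2)

    denom = X @ g1_m + 2.0 * (X @ g2_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, (X @ g0_m) / denom, np.nan)

    return pd.DataFrame(
        {
            "agalactosylated": X @ agal_m,
            "terminal_galactosylated": X @ tgal_m,
            "sialylated": X @ sial_m,
            "fucosylated": X @ fuc_m,
            "bisected": X @ bis_m,
            "gal_ratio": ratio,
        },
        index=profile_frame.index,
    )
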