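"""Per-zone feature prioritization: the four-rule filter cascade.

A feature plausibly responsible for the bioactivity of an HPTLC zone
must (1) be genuinely detected above the abundance threshold in the
unfractionated parent extract, (2) carry a fraction/parent abundance
ratio inside the expected recovery window, (3) stand clear of plate
blanks, and (4) be exclusive to the zone's fractions.  The cascade is a
pure conjunction: rule order never changes the surviving set, and every
tested feature gets an audit record with the computed values.

Suspect matching by exact neutral mass and the solvent-fraction
intersection used in two-dimensional fractionation live here as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chemmass import ChemicalFormula, monoisotopic_mass, parse_formula, ppm_error, round_half_up
from .feature_model import Feature, FeatureTable, FeatureTableError, replicate_mean_area

__all__ = [
    "PrioritizationConfig",
    "RuleResult",
    "ZonePrioritization",
    "SuspectEntry",
    "SuspectHit",
    "rule_parent_abundance",
    "rule_fraction_ratio",
    "rule_blank",
    "rule_zone_exclusivity",
    "prioritize_zone",
    "intersect_methods",
    "suspect_match",
    "read_suspect_list",
    "percent_reduction",
    "write_audit_report",
]

RULE_NAMES = ("parent_abundance", "fraction_ratio", "blank", "zone_exclusivity")


@dataclass(frozen=True)
class PrioritizationConfig:
    """Thresholds of the filter cascade.

    Defaults follow the screening workflow this package models: a
    1e6-count picking threshold, a 10–75% fraction/parent recovery
    window, a 10-fold blank factor and a 2-ppm suspect-match tolerance.
    ``offzone_use_threshold`` decides whether "detected in an off-zone
    fraction" requires a peak above the abundance threshold (default)
    or any genuine peak at all.
    """

    abundance_threshold: float = 1e6
    ratio_low: float = 0.10
    ratio_high: float = 0.75
    blank_factor: float = 10.0
    suspect_ppm_tol: float = 2.0
    offzone_use_threshold: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ratio_low < self.ratio_high <= 1):
            raise ValueError("require 0 < ratio_low < ratio_high <= 1")
        if self.blank_factor <= 0 or self.abundance_threshold <= 0:
            raise ValueError("blank_factor and abundance_threshold must be positive")
        if self.suspect_ppm_tol <= 0:
            raise ValueError("suspect_ppm_tol must be positive")


@dataclass(frozen=True)
class RuleResult:
    rule: str
    passed: bool
    value: float | None = None  # the computed quantity the rule tested, where meaningful


@dataclass
class ZonePrioritization:
    """Surviving feature set for one bioactive zone, with full audit trail."""

    zone_id: str
    method: str | None
    surviving: set[str]
    audit: dict[str, dict[str, RuleResult]]

    def ratio(self, feature_id: str) -> float | None:
        return self.audit[feature_id]["fraction_ratio"].value


@dataclass(frozen=True)
class SuspectEntry:
    """One suspect-list row: name plus neutral monoisotopic mass.

    The mass may be given directly or derived from the formula; when
    both are present they must agree within 2 ppm.
    """

    name: str
    formula: ChemicalFormula | None = None
    neutral_mass: float | None = None

    def __post_init__(self) -> None:
        if self.formula is None and self.neutral_mass is None:
            raise ValueError(f"suspect {self.name!r} needs a formula or a neutral mass")
        if self.formula is not None:
            theo = float(monoisotopic_mass(self.formula))
            if self.neutral_mass is None:
                object.__setattr__(self, "neutral_mass", theo)
            elif abs(ppm_error(self.neutral_mass, theo)) > 2.0:
                raise ValueError(
                    f"suspect {self.name!r}: stated mass {self.neutral_mass} disagrees with "
                    f"formula mass {theo:.6f} by more than 2 ppm"
                )


@dataclass(frozen=True)
class SuspectHit:
    suspect: str
    suspect_mass: float
    delta_ppm: float


# ---------------------------------------------------------------------------
# The four rules
# ---------------------------------------------------------------------------

def rule_parent_abundance(
    feature: Feature, parent_ids: Sequence[str], cfg: PrioritizationConfig
) -> RuleResult:
    """Genuine detection above the abundance threshold in the parent extract.

    Gap-filled replicates never count as detections, so a feature whose
    parent presence is imputation only always fails.
    """
    if not parent_ids:
        raise FeatureTableError("study has no parent samples")
    mean = replicate_mean_area(feature, parent_ids, exclude_gap_filled=True)
    genuine = any(
        (m := feature.areas.get(sid)) is not None and not m.gap_filled for sid in parent_ids
    )
    return RuleResult("parent_abundance", genuine and mean > cfg.abundance_threshold, mean)


def rule_fraction_ratio(
    feature: Feature,
    fraction_ids: Sequence[str],
    parent_ids: Sequence[str],
    cfg: PrioritizationConfig,
) -> RuleResult:
    """Fraction/parent abundance ratio inside [ratio_low, ratio_high]."""
    parent_mean = replicate_mean_area(feature, parent_ids, exclude_gap_filled=True)
    if parent_mean <= 0:
        return RuleResult("fraction_ratio", False, None)
    frac_mean = replicate_mean_area(feature, fraction_ids, exclude_gap_filled=True)
    ratio = frac_mean / parent_mean
    return RuleResult("fraction_ratio", cfg.ratio_low <= ratio <= cfg.ratio_high, ratio)


def rule_blank(
    feature: Feature,
    fraction_ids: Sequence[str],
    blank_ids: Sequence[str],
    cfg: PrioritizationConfig,
) -> RuleResult:
    """Fraction abundance more than blank_factor times any plate-blank peak.

    "Any peak detected" in a blank means a genuine (non-gap-filled)
    measurement of any size; a feature absent from all blanks has blank
    maximum 0 and passes whenever its fraction mean is positive.
    """
    frac_mean = replicate_mean_area(feature, fraction_ids, exclude_gap_filled=True)
    blank_max = 0.0
    for sid in blank_ids:
        meas = feature.areas.get(sid)
        if meas is not None and not meas.gap_filled:
            blank_max = max(blank_max, meas.area)
    return RuleResult("blank", frac_mean > cfg.blank_factor * blank_max and frac_mean > 0, blank_max)


def rule_zone_exclusivity(
    feature: Feature,
    zone_id: str,
    table: FeatureTable,
    cfg: PrioritizationConfig,
) -> RuleResult:
    """No genuine detection in any fraction of a different zone.

    A gap-filled value is not a detection; by default a detection must
    also exceed the abundance threshold (cfg.offzone_use_threshold).
    """
    limit = cfg.abundance_threshold if cfg.offzone_use_threshold else 0.0
    offzone_hits = 0
    for s in table.samples:
        if s.role not in ("zone_fraction", "off_zone_fraction"):
            continue
        if s.zone_id is None:
            raise FeatureTableError(f"fraction sample {s.sample_id!r} lacks a zone assignment")
        if s.zone_id == zone_id:
            continue
        meas = feature.areas.get(s.sample_id)
        if meas is not None and not meas.gap_filled and meas.area > limit:
            offzone_hits += 1
    return RuleResult("zone_exclusivity", offzone_hits == 0, float(offzone_hits))


def prioritize_zone(
    table: FeatureTable,
    zone_id: str,
    method: str | None = None,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> ZonePrioritization:
    """Apply the full cascade to every feature for one zone (and method).

    All four rules are evaluated for every feature regardless of earlier
    failures, so the audit is complete and the conjunction is manifestly
    order-independent.
    """
    parent_ids = table.sample_ids(role="parent")
    if not parent_ids:
        raise FeatureTableError("study has no parent samples")
    fraction_ids = table.sample_ids(role="zone_fraction", zone_id=zone_id, method=method)
    if not fraction_ids:
        raise FeatureTableError(
            f"no zone_fraction samples for zone {zone_id!r}"
            + (f" with method {method!r}" if method else "")
        )
    blank_ids = table.sample_ids(role="blank_fraction")

    audit: dict[str, dict[str, RuleResult]] = {}
    surviving: set[str] = set()
    for f in table.features:
        results = {
            "parent_abundance": rule_parent_abundance(f, parent_ids, cfg),
            "fraction_ratio": rule_fraction_ratio(f, fraction_ids, parent_ids, cfg),
            "blank": rule_blank(f, fraction_ids, blank_ids, cfg),
            "zone_exclusivity": rule_zone_exclusivity(f, zone_id, table, cfg),
        }
        audit[f.feature_id] = results
        if all(r.passed for r in results.values()):
            surviving.add(f.feature_id)
    return ZonePrioritization(zone_id=zone_id, method=method, surviving=surviving, audit=audit)


def intersect_methods(a: ZonePrioritization, b: ZonePrioritization) -> set[str]:
    """Features prioritized by both elution solvents for the same zone."""
    if a.zone_id != b.zone_id:
        raise ValueError(f"zone mismatch: {a.zone_id!r} vs {b.zone_id!r}")
    return a.surviving & b.surviving


# ---------------------------------------------------------------------------
# Suspect matching
# ---------------------------------------------------------------------------

def suspect_match(
    table: FeatureTable,
    suspects: Sequence[SuspectEntry],
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> dict[str, list[SuspectHit]]:
    """Annotate features whose neutral mass matches a suspect within tolerance.

    All hits are recorded, sorted by absolute ppm deviation (then by
    name for ties); hits are also appended to each feature's
    annotations.
    """
    out: dict[str, list[SuspectHit]] = {}
    for f in table.features:
        hits = []
        for s in suspects:
            assert s.neutral_mass is not None
            dppm = ppm_error(f.neutral_mass, s.neutral_mass)
            if abs(dppm) <= cfg.suspect_ppm_tol:
                hits.append(SuspectHit(suspect=s.name, suspect_mass=s.neutral_mass, delta_ppm=dppm))
        hits.sort(key=lambda h: (abs(h.delta_ppm), h.suspect))
        if hits:
            f.annotations.extend(hits)
            out[f.feature_id] = hits
    return out


def read_suspect_list(path: str | Path) -> list[SuspectEntry]:
    """Read a delimited suspect list with columns name, formula, neutral_mass."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"name"} - set(df.columns)
    if missing:
        raise FeatureTableError("suspect list missing 'name' column")
    entries = []
    for r in df.itertuples():
        formula = parse_formula(r.formula) if getattr(r, "formula", "") else None
        mass_text = getattr(r, "neutral_mass", "")
        mass = float(mass_text) if mass_text else None
        entries.append(SuspectEntry(name=r.name, formula=formula, neutral_mass=mass))
    return entries


# ---------------------------------------------------------------------------
# Workflow accounting and reports
# ---------------------------------------------------------------------------

def percent_reduction(n_before: int, n_after: int) -> float:
    """Percent of features removed by a workflow step, to one decimal.

    E.g. 2693 parent features reduced to 50 prioritized ones is a 98.1%
    reduction.
    """
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    if n_after < 0 or n_after > n_before:
        raise ValueError("n_after must be in [0, n_before]")
    return round_half_up(100.0 * (1.0 - n_after / n_before), 1)


def write_audit_report(
    results: Iterable[ZonePrioritization],
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the per-feature x per-rule audit (CSV) and surviving sets (JSON)."""
    rows = []
    summary: dict[str, dict] = {}
    for zp in results:
        key = zp.zone_id if zp.method is None else f"{zp.zone_id}/{zp.method}"
        summary[key] = {
            "zone_id": zp.zone_id,
            "method": zp.method,
            "n_tested": len(zp.audit),
            "n_surviving": len(zp.surviving),
            "surviving": sorted(zp.surviving),
        }
        for fid in sorted(zp.audit):
            for rule in RULE_NAMES:
                r = zp.audit[fid][rule]
                rows.append(
                    (zp.zone_id, zp.method or "", fid, rule, r.passed, "" if r.value is None else r.value)
                )
    pd.DataFrame(
        rows, columns=["zone_id", "method", "feature_id", "rule", "passed", "value"]
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
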