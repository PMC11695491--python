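"""The four-rule filter cascade, method intersection and suspect matching."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edascreen.chemmass import monoisotopic_mass, parse_formula
from edascreen.feature_model import FeatureTableError
from edascreen.prioritize import (
    PrioritizationConfig,
    SuspectEntry,
    ZonePrioritization,
    intersect_methods,
    percent_reduction,
    prioritize_zone,
    rule_blank,
    rule_fraction_ratio,
    rule_parent_abundance,
    rule_zone_exclusivity,
    suspect_match,
)

from conftest import (
    BLANK_IDS,
    FRAC_A_IDS,
    FRAC_B_IDS,
    PARENT_IDS,
    make_feature,
    make_table,
    triplicate,
)

CFG = PrioritizationConfig()


def test_config_invariants():
    with pytest.raises(ValueError):
        PrioritizationConfig(ratio_low=0.8, ratio_high=0.5)
    with pytest.raises(ValueError):
        PrioritizationConfig(blank_factor=0)
    with pytest.raises(ValueError):
        PrioritizationConfig(abundance_threshold=-1)


class TestParentAbundance:
    def test_real_peaks_above_threshold_pass(self):
        f = make_feature("f", areas=triplicate(PARENT_IDS, 3.9e7))
        r = rule_parent_abundance(f, PARENT_IDS, CFG)
        assert r.passed and r.value == pytest.approx(3.9e7)

    def test_boundary_is_strict(self):
        f = make_feature("f", areas=triplicate(PARENT_IDS, 1e6))
        assert not rule_parent_abundance(f, PARENT_IDS, CFG).passed

    def test_gap_filled_only_detections_fail(self):
        f = make_feature("f", areas=triplicate(PARENT_IDS, 5e6, gap=True))
        assert not rule_parent_abundance(f, PARENT_IDS, CFG).passed

    def test_no_parent_samples_is_an_error(self):
        with pytest.raises(FeatureTableError):
            rule_parent_abundance(make_feature("f"), [], CFG)


class TestFractionRatio:
    def _feature(self, ratio: float):
        areas = triplicate(PARENT_IDS, 1e7)
        areas.update(triplicate(FRAC_A_IDS, ratio * 1e7))
        return make_feature("f", areas=areas)

    @pytest.mark.parametrize("ratio,ok", [(0.38, True), (0.10, True), (0.75, True), (0.05, False), (0.80, False)])
    def test_window(self, ratio, ok):
        r = rule_fraction_ratio(self._feature(ratio), FRAC_A_IDS, PARENT_IDS, CFG)
        assert r.passed is ok
        assert r.value == pytest.approx(ratio)

    def test_relaxed_low_bound_admits_low_recovery(self):
        relaxed = PrioritizationConfig(ratio_low=0.05)
        assert rule_fraction_ratio(self._feature(0.05), FRAC_A_IDS, PARENT_IDS, relaxed).passed

    def test_zero_parent_mean_fails_with_no_ratio(self):
        f = make_feature("f", areas=triplicate(FRAC_A_IDS, 1e7))
        r = rule_fraction_ratio(f, FRAC_A_IDS, PARENT_IDS, CFG)
        assert not r.passed and r.value is None


class TestBlank:
    def _feature(self, frac: float, blank: float | None, blank_gap=False):
        areas = triplicate(FRAC_A_IDS, frac)
        if blank is not None:
            areas["blank_1"] = (blank, blank_gap)
        return make_feature("f", areas=areas)

    def test_twenty_fold_over_blank_passes(self):
        assert rule_blank(self._feature(2e7, 1e6), FRAC_A_IDS, BLANK_IDS, CFG).passed

    def test_five_fold_over_blank_fails(self):
        assert not rule_blank(self._feature(5e6, 1e6), FRAC_A_IDS, BLANK_IDS, CFG).passed

    def test_absent_from_blanks_passes_any_positive_fraction(self):
        assert rule_blank(self._feature(2e6, None), FRAC_A_IDS, BLANK_IDS, CFG).passed

    def test_gap_filled_blank_is_not_a_detection(self):
        assert rule_blank(self._feature(5e6, 1e6, blank_gap=True), FRAC_A_IDS, BLANK_IDS, CFG).passed

    def test_blank_has_no_abundance_floor(self):
        # "any peak detected" in a blank counts, however small
        assert not rule_blank(self._feature(5e4, 1e4), FRAC_A_IDS, BLANK_IDS, CFG).passed


class TestZoneExclusivity:
    def test_only_own_zone_passes(self):
        f = make_feature("f", areas=triplicate(FRAC_A_IDS, 1e7))
        assert rule_zone_exclusivity(f, "A", make_table([f]), CFG).passed

    def test_real_offzone_peak_fails(self):
        areas = triplicate(FRAC_A_IDS, 1e7)
        areas["frac_B_1"] = (2e6, False)
        f = make_feature("f", areas=areas)
        assert not rule_zone_exclusivity(f, "A", make_table([f]), CFG).passed

    def test_gap_filled_offzone_is_not_detected(self):
        areas = triplicate(FRAC_A_IDS, 1e7)
        areas["frac_B_1"] = (2e6, True)
        f = make_feature("f", areas=areas)
        assert rule_zone_exclusivity(f, "A", make_table([f]), CFG).passed

    def test_subthreshold_offzone_peak_tolerated_by_default(self):
        areas = triplicate(FRAC_A_IDS, 1e7)
        areas["frac_B_1"] = (5e5, False)
        f = make_feature("f", areas=areas)
        table = make_table([f])
        assert rule_zone_exclusivity(f, "A", table, CFG).passed
        strict = PrioritizationConfig(offzone_use_threshold=False)
        assert not rule_zone_exclusivity(f, "A", table, strict).passed


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def _toy_features():
    """20 features engineered to exercise every rule combination for zone A."""
    feats = []
    specs = {
        # name: (parent, parent_gap, fracA, blank, fracB)
        "pass_all": (1e7, False, 3.8e6, None, None),
        "low_parent": (5e5, False, 2e5, None, None),
        "parent_gap_only": (5e6, True, 2e6, None, None),
        "ratio_low": (1e7, False, 5e5, None, None),
        "ratio_high": (1e7, False, 8e6, None, None),
        "blank_heavy": (1e7, False, 3e6, 1e6, None),
        "blank_light": (1e7, False, 3e6, 1e4, None),
        "offzone_leak": (1e7, False, 3e6, None, 2e6),
        "offzone_sub": (1e7, False, 3e6, None, 5e5),
        "absent_in_zone": (1e7, False, None, None, 3e6),
    }
    for i, (name, (p, pgap, fa, bl, fb)) in enumerate(specs.items()):
        areas = triplicate(PARENT_IDS, p, gap=pgap)
        if fa is not None:
            areas.update(triplicate(FRAC_A_IDS, fa))
        if bl is not None:
            areas["blank_2"] = (bl, False)
        if fb is not None:
            areas["frac_B_3"] = (fb, False)
        feats.append(make_feature(name, mass=150.0 + 7 * i, areas=areas))
    # ten clean variations on pass_all at different ratios
    for k in range(10):
        ratio = 0.05 + 0.08 * k  # 0.05 .. 0.77
        areas = triplicate(PARENT_IDS, 2e7)
        areas.update(triplicate(FRAC_A_IDS, ratio * 2e7))
        feats.append(make_feature(f"sweep_{k}", mass=400.0 + 3 * k, areas=areas))
    return feats


def _oracle_surviving(table, zone, cfg):
    """Independent brute-force re-derivation of the cascade from raw areas."""
    parents = [s.sample_id for s in table.samples if s.role == "parent"]
    fracs = [s.sample_id for s in table.samples if s.role == "zone_fraction" and s.zone_id == zone]
    blanks = [s.sample_id for s in table.samples if s.role == "blank_fraction"]
    offzone = [
        s.sample_id
        for s in table.samples
        if s.role in ("zone_fraction", "off_zone_fraction") and s.zone_id not in (None, zone)
    ]
    out = set()
    for f in table.features:
        pvals = [m.area for sid, m in f.areas.items() if sid in parents and not m.gap_filled]
        pmean = sum(pvals) / len(pvals) if pvals else 0.0
        fvals = [m.area for sid, m in f.areas.items() if sid in fracs and not m.gap_filled]
        fmean = sum(fvals) / len(fvals) if fvals else 0.0
        bmax = max(
            (m.area for sid, m in f.areas.items() if sid in blanks and not m.gap_filled),
            default=0.0,
        )
        limit = cfg.abundance_threshold if cfg.offzone_use_threshold else 0.0
        r1 = bool(pvals) and pmean > cfg.abundance_threshold
        r2 = pmean > 0 and cfg.ratio_low <= fmean / pmean <= cfg.ratio_high
        r3 = fmean > 0 and fmean > cfg.blank_factor * bmax
        r4 = not any(
            not m.gap_filled and m.area > limit
            for sid, m in f.areas.items()
            if sid in offzone
        )
        if r1 and r2 and r3 and r4:
            out.add(f.feature_id)
    return out


def test_cascade_matches_bruteforce_on_toy_table():
    table = make_table(_toy_features())
    zp = prioritize_zone(table, "A", method="interface")
    assert zp.surviving == _oracle_surviving(table, "A", CFG)
    assert set(zp.audit) == {f.feature_id for f in table.features}  # audit covers all
    # spot checks forced by construction
    assert "pass_all" in zp.surviving
    for bad in ("low_parent", "parent_gap_only", "ratio_low", "ratio_high",
                "blank_heavy", "offzone_leak", "absent_in_zone"):
        assert bad not in zp.surviving, bad
    assert "blank_light" in zp.surviving and "offzone_sub" in zp.surviving


def test_cascade_is_order_independent_conjunction():
    """Applying rule subsets in any order yields the same conjunction."""
    table = make_table(_toy_features())
    zp = prioritize_zone(table, "A", method="interface")
    for perm in itertools.permutations(["parent_abundance", "fraction_ratio", "blank", "zone_exclusivity"]):
        surviving = {
            fid
            for fid in zp.audit
            if all(zp.audit[fid][rule].passed for rule in perm)
        }
        assert surviving == zp.surviving


def test_surviving_subset_of_parent_rule():
    table = make_table(_toy_features())
    zp = prioritize_zone(table, "A", method="interface")
    parent_pass = {fid for fid, rules in zp.audit.items() if rules["parent_abundance"].passed}
    assert zp.surviving <= parent_pass


def test_widening_config_is_monotone():
    table = make_table(_toy_features())
    base = prioritize_zone(table, "A", cfg=CFG).surviving
    wider = prioritize_zone(
        table, "A", cfg=PrioritizationConfig(ratio_low=0.05, ratio_high=0.9, blank_factor=5)
    ).surviving
    assert base <= wider


def test_empty_surviving_when_no_ratio_passes():
    areas = triplicate(PARENT_IDS, 1e7)
    areas.update(triplicate(FRAC_A_IDS, 1e5))  # ratio 0.01 for every feature
    table = make_table([make_feature("only", areas=areas)])
    assert prioritize_zone(table, "A").surviving == set()


def test_missing_zone_fractions_is_an_error():
    table = make_table([make_feature("f", areas=triplicate(PARENT_IDS, 1e7))])
    with pytest.raises(FeatureTableError, match="zone"):
        prioritize_zone(table, "Z")


# ---------------------------------------------------------------------------
# Method intersection
# ---------------------------------------------------------------------------

def _zp(zone, ids):
    return ZonePrioritization(zone_id=zone, method=None, surviving=set(ids), audit={})

def test_intersection_basics():
    a = _zp("D", {"x", "y"})
    assert intersect_methods(a, a) == {"x", "y"}
    assert intersect_methods(_zp("D", {"x"}), _zp("D", {"y"})) == set()
    with pytest.raises(ValueError):
        intersect_methods(_zp("C", {"x"}), _zp("D", {"x"}))


def test_intersection_of_32_and_24_with_13_common():
    common = {f"c{i}" for i in range(13)}
    a = _zp("D", common | {f"a{i}" for i in range(19)})  # 32 features
    b = _zp("D", common | {f"b{i}" for i in range(11)})  # 24 features
    assert len(a.surviving) == 32 and len(b.surviving) == 24
    assert intersect_methods(a, b) == common


# ---------------------------------------------------------------------------
# Suspect matching
# ---------------------------------------------------------------------------

def test_suspect_match_exact_and_boundary():
    cmit_mass = float(monoisotopic_mass(parse_formula("C4H4ClNOS")))
    feats = [
        make_feature("exact", mass=cmit_mass),
        make_feature("in_tol", mass=cmit_mass * (1 + 1.5e-6)),
        make_feature("out_tol", mass=cmit_mass * (1 + 3e-6)),
    ]
    table = make_table(feats)
    hits = suspect_match(table, [SuspectEntry("CMIT", parse_formula("C4H4ClNOS"))])
    assert set(hits) == {"exact", "in_tol"}
    assert hits["exact"][0].delta_ppm == pytest.approx(0.0, abs=1e-9)
    assert table.feature("exact").annotations  # annotations recorded
    wide = PrioritizationConfig(suspect_ppm_tol=5)
    hits5 = suspect_match(make_table([make_feature("out_tol", mass=cmit_mass * (1 + 3e-6))]),
                          [SuspectEntry("CMIT", parse_formula("C4H4ClNOS"))], wide)
    assert "out_tol" in hits5


def test_suspect_match_sorted_by_ppm_and_empty_list():
    f = make_feature("f", mass=200.0)
    table = make_table([f])
    suspects = [
        SuspectEntry("far", neutral_mass=200.0 * (1 + 1.8e-6)),
        SuspectEntry("near", neutral_mass=200.0 * (1 + 0.2e-6)),
    ]
    hits = suspect_match(table, suspects)
    assert [h.suspect for h in hits["f"]] == ["near", "far"]
    assert suspect_match(make_table([make_feature("g")]), []) == {}


def test_suspect_entry_mass_formula_consistency():
    with pytest.raises(ValueError):
        SuspectEntry("bad", parse_formula("C4H4ClNOS"), neutral_mass=148.9720)  # off by ~12 ppm
    SuspectEntry("good", parse_formula("C4H4ClNOS"), neutral_mass=148.970212)
    with pytest.raises(ValueError):
        SuspectEntry("nothing")


# ---------------------------------------------------------------------------
# Workflow accounting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "before,after,expected",
    [(2693, 50, 98.1), (2693, 20, 99.3), (1695, 14, 99.2), (100, 100, 0.0), (10, 0, 100.0)],
)
def test_percent_reduction(before, after, expected):
    assert percent_reduction(before, after) == expected


def test_percent_reduction_domain():
    with pytest.raises(ValueError):
        percent_reduction(0, 0)
    with pytest.raises(ValueError):
        percent_reduction(10, 11)
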