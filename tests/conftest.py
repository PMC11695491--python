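"""Shared builders for small in-memory studies used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from edascreen.chemmass import PROTON_MASS
from edascreen.feature_model import (
    AreaMeasurement,
    Feature,
    FeatureTable,
    SampleRecord,
)

# Canonical tiny study layout: triplicate parent, two zones (A and B) with
# triplicate interface fractions each, triplicate plate blanks.
STANDARD_SAMPLES = (
    [SampleRecord(f"parent_{r}", "parent", replicate=r) for r in (1, 2, 3)]
    + [
        SampleRecord(f"frac_A_{r}", "zone_fraction", zone_id="A", method="interface", replicate=r)
        for r in (1, 2, 3)
    ]
    + [
        SampleRecord(f"frac_B_{r}", "zone_fraction", zone_id="B", method="interface", replicate=r)
        for r in (1, 2, 3)
    ]
    + [SampleRecord(f"blank_{r}", "blank_fraction", replicate=r) for r in (1, 2, 3)]
)

PARENT_IDS = [f"parent_{r}" for r in (1, 2, 3)]
FRAC_A_IDS = [f"frac_A_{r}" for r in (1, 2, 3)]
FRAC_B_IDS = [f"frac_B_{r}" for r in (1, 2, 3)]
BLANK_IDS = [f"blank_{r}" for r in (1, 2, 3)]


def make_feature(
    feature_id: str,
    mass: float = 200.0,
    rt: float = 10.0,
    areas: dict[str, tuple[float, bool]] | None = None,
) -> Feature:
    """Feature with [M+H]+ m/z derived from the mass; areas as {sample: (area, gap)}."""
    return Feature(
        feature_id=feature_id,
        neutral_mass=mass,
        mz=mass + PROTON_MASS,
        adduct="[M+H]+",
        rt=rt,
        areas={sid: AreaMeasurement(a, g) for sid, (a, g) in (areas or {}).items()},
    )


def make_table(features: list[Feature], samples=None) -> FeatureTable:
    return FeatureTable(features=features, samples=list(samples or STANDARD_SAMPLES))


def triplicate(sample_ids, area: float, gap: bool = False) -> dict[str, tuple[float, bool]]:
    return {sid: (area, gap) for sid in sample_ids}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
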