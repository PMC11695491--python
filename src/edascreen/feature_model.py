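"""Data model and I/O for aligned non-target feature tables.

A *feature* is an aligned LC-HRMS signal — retention time, exact m/z and
(optionally) MS2 spectra — observed across parent-extract, fraction and
blank injections.  Tables are exchanged as long-format delimited text
(one row per feature x injection), the sample manifest as a second
delimited file, and MS2 spectra as MGF.

Peak areas are stored per injection replicate together with a gap-fill
flag: a gap-filled value was imputed during cross-sample alignment and
is *not* a genuine detection, which the prioritization filters must be
able to distinguish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .chemmass import ADDUCT_OFFSETS

__all__ = [
    "SampleRecord",
    "AreaMeasurement",
    "MS2Spectrum",
    "Feature",
    "FeatureTable",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "read_ms2",
    "write_ms2",
    "merge_feature_tables",
    "replicate_mean_area",
]

SAMPLE_ROLES = ("parent", "zone_fraction", "blank_fraction", "off_zone_fraction")

FEATURE_COLUMNS = [
    "feature_id",
    "neutral_mass",
    "mz",
    "adduct",
    "rt_min",
    "sample_id",
    "replicate",
    "area",
    "gap_filled",
]

MANIFEST_COLUMNS = ["sample_id", "role", "zone_id", "method", "replicate"]


class FeatureTableError(ValueError):
    """Malformed feature table or sample manifest."""


@dataclass(frozen=True)
class SampleRecord:
    """One measured injection and its role in the study design."""

    sample_id: str
    role: str  # parent | zone_fraction | blank_fraction | off_zone_fraction
    zone_id: str | None = None
    method: str | None = None  # interface | manual_methanol | manual_ethylacetate
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise FeatureTableError(f"unknown sample role {self.role!r} for {self.sample_id!r}")
        needs_zone = self.role in ("zone_fraction", "off_zone_fraction")
        if needs_zone and self.zone_id is None:
            raise FeatureTableError(f"sample {self.sample_id!r} with role {self.role!r} requires a zone_id")
        if not needs_zone and self.zone_id is not None:
            raise FeatureTableError(f"sample {self.sample_id!r} with role {self.role!r} must not carry a zone_id")
        if self.replicate < 1:
            raise FeatureTableError(f"replicate index must be >= 1 for {self.sample_id!r}")


@dataclass(frozen=True)
class AreaMeasurement:
    """Peak area of one feature in one injection; gap_filled marks imputation."""

    area: float
    gap_filled: bool = False

    def __post_init__(self) -> None:
        if self.area < 0:
            raise FeatureTableError(f"negative area: {self.area}")


@dataclass(frozen=True)
class MS2Spectrum:
    """Fragmentation spectrum: precursor m/z plus (fragment m/z, intensity) peaks."""

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple((float(m), float(i)) for m, i in self.peaks))
        mzs = [m for m, _ in self.peaks]
        if mzs != sorted(mzs):
            raise FeatureTableError("MS2 peaks must be sorted by fragment m/z")
        for m, inten in self.peaks:
            if inten < 0:
                raise FeatureTableError("negative MS2 intensity")
            if m > self.precursor_mz + 0.5:
                raise FeatureTableError(
                    f"fragment m/z {m} exceeds precursor {self.precursor_mz} by more than 0.5 Da"
                )

    @property
    def fragment_mzs(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)


@dataclass
class Feature:
    """One aligned non-target signal with per-injection areas."""

    feature_id: str
    neutral_mass: float
    mz: float
    adduct: str
    rt: float
    areas: dict[str, AreaMeasurement] = field(default_factory=dict)
    ms2: list[MS2Spectrum] = field(default_factory=list)
    annotations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise FeatureTableError(f"negative retention time for {self.feature_id!r}")
        if self.mz <= 0:
            raise FeatureTableError(f"non-positive m/z for {self.feature_id!r}")
        offset = ADDUCT_OFFSETS.get(self.adduct)
        if offset is not None:
            expected = self.neutral_mass + offset
            if abs(self.mz - expected) > 2e-6 * self.mz:
                raise FeatureTableError(
                    f"{self.feature_id!r}: m/z {self.mz} inconsistent with neutral mass "
                    f"{self.neutral_mass} + {self.adduct} offset (>2 ppm)"
                )

    def area_in(self, sample_id: str) -> AreaMeasurement | None:
        return self.areas.get(sample_id)


@dataclass
class FeatureTable:
    """Aligned features plus the sample manifest they refer to."""

    features: list[Feature] = field(default_factory=list)
    samples: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise FeatureTableError(f"duplicate sample_id(s): {dupes}")
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != len(fids):
            dupes = sorted({f for f in fids if fids.count(f) > 1})
            raise FeatureTableError(f"duplicate feature_id(s): {dupes}")
        known = set(sample_ids)
        for f in self.features:
            unknown = set(f.areas) - known
            if unknown:
                raise FeatureTableError(
                    f"feature {f.feature_id!r} references unknown sample(s): {sorted(unknown)}"
                )

    @property
    def sample_index(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def sample_ids(
        self,
        role: str | None = None,
        zone_id: str | None = None,
        method: str | None = None,
    ) -> list[str]:
        """Injection ids matching the given role / zone / elution method."""
        out = []
        for s in self.samples:
            if role is not None and s.role != role:
                continue
            if zone_id is not None and s.zone_id != zone_id:
                continue
            if method is not None and s.method != method:
                continue
            out.append(s.sample_id)
        return out


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".samples.csv") if path.suffix != ".csv" else path.with_name(
        path.stem + ".samples.csv"
    )


def write_feature_table(table: FeatureTable, path: str | Path, manifest_path: str | Path | None = None) -> None:
    """Write the long-format feature table and its sample manifest.

    Floats are written with shortest round-trip repr so that
    ``read_feature_table(write_feature_table(t))`` reproduces every field
    bit-exactly.
    """
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path is not None else _manifest_path(path)
    sidx = table.sample_index
    rows = []
    for f in table.features:
        for sample_id, meas in f.areas.items():
            rows.append(
                (
                    f.feature_id,
                    repr(f.neutral_mass),
                    repr(f.mz),
                    f.adduct,
                    repr(f.rt),
                    sample_id,
                    sidx[sample_id].replicate,
                    repr(meas.area),
                    "true" if meas.gap_filled else "false",
                )
            )
        if not f.areas:  # keep area-less features round-trippable
            rows.append(
                (f.feature_id, repr(f.neutral_mass), repr(f.mz), f.adduct, repr(f.rt), "", 0, "", "")
            )
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)
    mrows = [
        (s.sample_id, s.role, s.zone_id or "", s.method or "", s.replicate) for s in table.samples
    ]
    pd.DataFrame(mrows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)


def read_feature_table(path: str | Path, manifest_path: str | Path | None = None) -> FeatureTable:
    """Read a long-format feature table plus its sample manifest.

    Parse failures are reported with the offending row number; the
    resulting table is validated against all type invariants.
    """
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path is not None else _manifest_path(path)

    mdf = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(mdf.columns)
    if missing:
        raise FeatureTableError(f"sample manifest missing column(s): {sorted(missing)}")
    samples = [
        SampleRecord(
            sample_id=r.sample_id,
            role=r.role,
            zone_id=r.zone_id or None,
            method=r.method or None,
            replicate=int(r.replicate),
        )
        for r in mdf.itertuples()
    ]

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FeatureTableError(f"feature table missing column(s): {sorted(missing)}")

    features: dict[str, Feature] = {}
    for i, r in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            fid = r.feature_id
            if fid not in features:
                features[fid] = Feature(
                    feature_id=fid,
                    neutral_mass=float(r.neutral_mass),
                    mz=float(r.mz),
                    adduct=r.adduct,
                    rt=float(r.rt_min),
                )
            f = features[fid]
            if r.sample_id:
                if r.sample_id in f.areas:
                    raise FeatureTableError(
                        f"duplicate (feature, sample) row for {fid!r} / {r.sample_id!r}"
                    )
                f.areas[r.sample_id] = AreaMeasurement(
                    area=float(r.area), gap_filled=r.gap_filled.strip().lower() == "true"
                )
        except (ValueError, FeatureTableError) as exc:
            raise FeatureTableError(f"{path.name} row {i}: {exc}") from exc
    return FeatureTable(features=list(features.values()), samples=samples)


def write_ms2(table: FeatureTable, path: str | Path) -> None:
    """Write every feature's MS2 spectra to MGF (TITLE = feature_id)."""
    spectra = []
    for f in table.features:
        for k, spec in enumerate(f.ms2):
            spectra.append(
                {
                    "params": {
                        "title": f"{f.feature_id} scan={k}",
                        "pepmass": spec.precursor_mz,
                        "rtinseconds": f.rt * 60.0,
                    },
                    "m/z array": [m for m, _ in spec.peaks],
                    "intensity array": [i for _, i in spec.peaks],
                }
            )
    _mgf.write(spectra, str(path), file_mode="w")


def read_ms2(table: FeatureTable, path: str | Path) -> int:
    """Attach MGF spectra to the table's features in place.

    Returns the number of spectra attached; spectra whose TITLE does not
    resolve to a feature are ignored.
    """
    by_id = {f.feature_id: f for f in table.features}
    n = 0
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            fid = str(entry["params"]["title"]).split()[0]
            f = by_id.get(fid)
            if f is None:
                continue
            pep = entry["params"]["pepmass"]
            precursor = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            pairs = sorted(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            f.ms2.append(MS2Spectrum(precursor_mz=precursor, peaks=tuple(pairs)))
            n += 1
    return n


# ---------------------------------------------------------------------------
# Merging and replicate aggregation
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _within_ppm(m1: float, m2: float, ppm_tol: float) -> bool:
    # relative to the mean mass; symmetric in the arguments
    ref = 0.5 * (m1 + m2)
    return abs(m1 - m2) <= ppm_tol * 1e-6 * ref


def merge_feature_tables(
    tables: Sequence[FeatureTable],
    ppm_tol: float = 2.0,
    rt_tol: float = 0.2,
) -> FeatureTable:
    """Merge aligned tables by clustering features across tables.

    Features are linked when both |Δmass| <= ppm_tol (relative to the
    pair's mean mass) and |Δrt| <= rt_tol; merged features are the
    connected components of that link graph.  The representative mass
    and retention time of a cluster are the area-weighted means over its
    members, and per-sample areas are concatenated (sample namespaces of
    the input tables must be disjoint).
    """
    all_samples: list[SampleRecord] = []
    seen: set[str] = set()
    for t in tables:
        for s in t.samples:
            if s.sample_id in seen:
                raise FeatureTableError(f"sample namespaces overlap on {s.sample_id!r}")
            seen.add(s.sample_id)
            all_samples.append(s)

    feats = [f for t in tables for f in t.features]
    n = len(feats)
    order = sorted(range(n), key=lambda i: feats[i].neutral_mass)
    uf = _UnionFind(n)
    for a in range(n):
        i = order[a]
        mi = feats[i].neutral_mass
        for b in range(a + 1, n):
            j = order[b]
            mj = feats[j].neutral_mass
            if mj - mi > ppm_tol * 1e-6 * 0.5 * (mi + mj) + 1e-12 and not _within_ppm(mi, mj, ppm_tol):
                break  # masses are sorted; everything further is out of reach
            if _within_ppm(mi, mj, ppm_tol) and abs(feats[i].rt - feats[j].rt) <= rt_tol:
                uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)

    merged: list[Feature] = []
    for members in clusters.values():
        group = [feats[i] for i in members]
        group.sort(key=lambda f: f.feature_id)
        weights = [max(sum(m.area for m in f.areas.values() if not m.gap_filled), 0.0) for f in group]
        if not any(w > 0 for w in weights):
            weights = [1.0] * len(group)
        wsum = sum(weights)
        mass = sum(w * f.neutral_mass for w, f in zip(weights, group)) / wsum
        rt = sum(w * f.rt for w, f in zip(weights, group)) / wsum
        rep = group[0]
        areas: dict[str, AreaMeasurement] = {}
        ms2: list[MS2Spectrum] = []
        annotations: list = []
        for f in group:
            for sid, meas in f.areas.items():
                prev = areas.get(sid)
                if prev is None:
                    areas[sid] = meas
                else:
                    # two cluster members measured in the same injection are
                    # split parts of one peak: areas add, a genuine detection
                    # on either side makes the merged value genuine
                    areas[sid] = AreaMeasurement(
                        prev.area + meas.area, prev.gap_filled and meas.gap_filled
                    )
            ms2.extend(f.ms2)
            annotations.extend(f.annotations)
        offset = ADDUCT_OFFSETS.get(rep.adduct, rep.mz - rep.neutral_mass)
        merged.append(
            Feature(
                feature_id=rep.feature_id,
                neutral_mass=mass,
                mz=mass + offset,
                adduct=rep.adduct,
                rt=rt,
                areas=areas,
                ms2=ms2,
                annotations=annotations,
            )
        )
    merged.sort(key=lambda f: f.feature_id)
    return FeatureTable(features=merged, samples=all_samples)


def replicate_mean_area(
    feature: Feature,
    sample_ids: Iterable[str],
    exclude_gap_filled: bool = True,
) -> float:
    """Arithmetic mean peak area of a feature over an injection replicate group.

    Only replicates in which the feature is present (and, when
    ``exclude_gap_filled``, genuinely detected) enter the mean; a group
    with no qualifying replicate returns 0.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise FeatureTableError("empty replicate group")
    values = []
    for sid in sample_ids:
        meas = feature.areas.get(sid)
        if meas is None:
            continue
        if exclude_gap_filled and meas.gap_filled:
            continue
        values.append(meas.area)
    if not values:
        return 0.0
    return math.fsum(values) / len(values)
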