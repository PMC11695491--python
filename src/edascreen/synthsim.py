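"""Synthetic effect-directed-analysis studies with known ground truth.

No public raw data accompany the screening workflow this package
implements, so every pipeline stage is exercised against simulated
studies instead: a parent extract of log-normally abundant features, a
handful of HPTLC zones with partial, method-dependent recoveries
(interface elution recovers on the order of 10% of parent abundance,
manual silica scraping close to 40%), plate-blank background features,
injection triplicates with multiplicative noise, gap-filled
(imputation-only) entries, co-eluting in-source fragment clusters with
planted shared MS2 ions, spiked known genotoxicants, and molecular
fingerprints whose activity is determined by a planted bit rule.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemmass import ChemicalFormula, PROTON_MASS, monoisotopic_mass, parse_formula
from .feature_model import (
    AreaMeasurement,
    Feature,
    FeatureTable,
    MS2Spectrum,
    SampleRecord,
    write_feature_table,
    write_ms2,
)
from .genotox import EndpointDataset, Fingerprint, write_fingerprints
from .prioritize import SuspectEntry

__all__ = [
    "RecoveryModel",
    "SpikeSpec",
    "StudyConfig",
    "GroundTruth",
    "SyntheticStudy",
    "simulate_study",
    "simulate_endpoint_data",
    "write_study",
    "PLANTED_FRAGMENTS",
]

#: Default fragment ions planted into in-source cluster spectra.
PLANTED_FRAGMENTS = (85.0283, 99.0440, 127.0389)


@dataclass(frozen=True)
class RecoveryModel:
    """Distribution of fraction/parent recovery for one elution method."""

    kind: str  # "fixed" | "beta"
    value: float = 0.0  # fixed recovery
    a: float = 0.0  # beta shape parameters
    b: float = 0.0

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.value
        if self.kind == "beta":
            return float(np.clip(rng.beta(self.a, self.b), 1e-6, 1.0))
        raise ValueError(f"unknown recovery model kind {self.kind!r}")


@dataclass(frozen=True)
class SpikeSpec:
    """A known genotoxicant spiked into the parent extract."""

    name: str
    formula: ChemicalFormula
    zone_id: str
    recovery: float
    parent_area: float
    genotoxic: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.recovery <= 1):
            raise ValueError(f"spike {self.name!r}: recovery must be in (0, 1]")
        if self.parent_area <= 0:
            raise ValueError(f"spike {self.name!r}: parent_area must be positive")


def _default_spikes() -> tuple[SpikeSpec, ...]:
    # The two mock-study genotoxicants: an isothiazolinone biocide recovered
    # at ~38% (manual-scrape-like) and a nitroquinoline positive control at ~10%.
    return (
        SpikeSpec("CMIT", parse_formula("C4H4ClNOS"), zone_id="C", recovery=0.38, parent_area=5e7),
        SpikeSpec("4NQO", parse_formula("C9H6N2O3"), zone_id="B", recovery=0.10, parent_area=2e7),
    )


def _default_recovery_models() -> dict[str, RecoveryModel]:
    # Beta distributions with means 0.10 (interface elution) and 0.38
    # (manual scraping), moderately concentrated around those means.
    return {
        "interface": RecoveryModel("beta", a=4.0, b=36.0),
        "manual_methanol": RecoveryModel("beta", a=7.6, b=12.4),
        "manual_ethylacetate": RecoveryModel("beta", a=7.6, b=12.4),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Full specification of a synthetic study.

    Defaults emulate the one-dimensional mock study: 1695 parent-extract
    features, four bioactive zones, triplicate injections, interface
    elution, a 1e6-scale abundance regime in which a realistic minority
    of features falls below the picking threshold, and Tox21-scale
    endpoint datasets (5953 chemicals / 723 active for p53 activation;
    3057 / 257 for DT40 DNA damage).
    """

    n_matrix_features: int = 1695
    n_blank_features: int = 150
    spikes: tuple[SpikeSpec, ...] = field(default_factory=_default_spikes)
    zones: tuple[str, ...] = ("A", "B", "C", "D")
    methods: tuple[str, ...] = ("interface",)
    recovery_model: Mapping[str, RecoveryModel] = field(default_factory=_default_recovery_models)
    area_lognormal: tuple[float, float] = (6.8, 0.6)  # (mu, sigma) on log10 area
    triplicate_cv: float = 0.10
    gap_fill_prob: float = 0.5
    no_zone_prob: float = 0.3
    n_replicates: int = 3
    insource_clusters: tuple[tuple[int, int], ...] = ((5, 3), (2, 0))  # (size, n shared fragments)
    insource_rt_jitter: float = 0.02  # min; < half the default grouping rt tolerance
    fingerprint_length: int = 2048
    bit_density: float = 0.1
    planted_rule: tuple[int, ...] = (17, 421, 1337)
    label_noise: float = 0.05
    endpoints: tuple[tuple[str, int, int], ...] = (
        ("TOX21_p53_BLA", 5953, 723),
        ("TOX21_DT40_ratio", 3057, 257),
    )
    n_suspects: int = 378
    n_candidate_structures: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matrix_features < 0 or self.n_blank_features < 0:
            raise ValueError("feature counts must be >= 0")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.triplicate_cv < 0:
            raise ValueError("triplicate_cv must be >= 0")
        for s in self.spikes:
            if s.zone_id not in self.zones:
                raise ValueError(f"spike {s.name!r} assigned to unknown zone {s.zone_id!r}")
        for m in self.methods:
            if m not in self.recovery_model:
                raise ValueError(f"no recovery model for method {m!r}")
        if not self.planted_rule:
            raise ValueError("planted_rule must name at least one bit")
        if any(b < 0 or b >= self.fingerprint_length for b in self.planted_rule):
            raise ValueError("planted_rule bits out of fingerprint range")


@dataclass
class GroundTruth:
    """What the generator knows: truth for every emitted feature and structure."""

    features: dict[str, dict]  # feature_id -> {chemical_id, zone, is_spike, is_blank, insource_group}
    structure_activity: dict[str, bool]
    insource_groups: list[set[str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "structure_activity": self.structure_activity,
                "insource_groups": [sorted(g) for g in self.insource_groups],
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticStudy:
    config: StudyConfig
    table: FeatureTable
    fingerprints: dict[str, Fingerprint]  # feature_id -> predicted-from-MS2 stand-in fingerprint
    candidate_structures: dict[str, list[tuple[str, Fingerprint]]]  # feature_id -> structures
    suspects: list[SuspectEntry]
    endpoints: list[EndpointDataset]
    truth: GroundTruth


def _noise_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _random_fingerprint(
    rng: np.random.Generator, length: int, density: float
) -> Fingerprint:
    return Fingerprint((rng.random(length) < density).astype(np.uint8))


def simulate_endpoint_data(
    n_chemicals: int,
    active_fraction: float,
    planted_rule: Sequence[int],
    label_noise: float,
    seed: int,
    fingerprint_length: int = 2048,
    bit_density: float = 0.1,
    endpoint_name: str = "synthetic_endpoint",
) -> EndpointDataset:
    """Fingerprint/activity records whose truth is a planted OR-of-bits rule.

    A chemical's underlying activity is the OR of its planted-rule bits;
    the emitted label is that truth flipped with probability
    ``label_noise``.  The rule bits' activation probability is
    calibrated so that the *post-noise* class prior equals
    ``active_fraction`` in expectation (hence the emitted active count
    matches it to within binomial error).  Requires
    ``active_fraction > label_noise``.
    """
    if not (0 < active_fraction < 1):
        raise ValueError("active_fraction must be in (0, 1)")
    if not planted_rule:
        raise ValueError("planted_rule must name at least one bit")
    if active_fraction <= label_noise:
        raise ValueError("active_fraction must exceed label_noise")
    rng = np.random.default_rng(seed)
    k = len(planted_rule)
    # pre-noise rule prevalence r such that r(1-e) + (1-r)e = active_fraction
    r = (active_fraction - label_noise) / (1.0 - 2.0 * label_noise)
    p_rule_bit = 1.0 - (1.0 - r) ** (1.0 / k)

    X = (rng.random((n_chemicals, fingerprint_length)) < bit_density).astype(np.uint8)
    rule_idx = np.asarray(planted_rule)
    X[:, rule_idx] = (rng.random((n_chemicals, k)) < p_rule_bit).astype(np.uint8)
    truth = X[:, rule_idx].any(axis=1)
    flips = rng.random(n_chemicals) < label_noise
    labels = truth ^ flips
    ids = [f"{endpoint_name}_C{i:05d}" for i in range(n_chemicals)]
    return EndpointDataset(endpoint_name=endpoint_name, chemical_ids=ids, X=X, y=labels)


def simulate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study; see the module docstring."""
    rng = np.random.default_rng(cfg.seed)

    # --- sample manifest ----------------------------------------------------
    samples: list[SampleRecord] = []
    for r in range(1, cfg.n_replicates + 1):
        samples.append(SampleRecord(f"parent_{r}", "parent", replicate=r))
    for zone in cfg.zones:
        for method in cfg.methods:
            for r in range(1, cfg.n_replicates + 1):
                samples.append(
                    SampleRecord(
                        f"frac_{zone}_{method}_{r}",
                        "zone_fraction",
                        zone_id=zone,
                        method=method,
                        replicate=r,
                    )
                )
    for r in range(1, cfg.n_replicates + 1):
        samples.append(SampleRecord(f"blank_{r}", "blank_fraction", replicate=r))

    parent_ids = [s.sample_id for s in samples if s.role == "parent"]
    blank_ids = [s.sample_id for s in samples if s.role == "blank_fraction"]

    # --- matrix features ----------------------------------------------------
    n = cfg.n_matrix_features
    masses = rng.uniform(100.0, 800.0, n)
    rts = rng.uniform(1.0, 27.0, n)
    mu, sigma = cfg.area_lognormal
    parent_means = 10.0 ** rng.normal(mu, sigma, n)
    zone_draw = rng.random(n)
    zone_choice = rng.integers(0, len(cfg.zones), n)
    zones_of = [
        None if zone_draw[i] < cfg.no_zone_prob else cfg.zones[zone_choice[i]] for i in range(n)
    ]

    features: list[Feature] = []
    truth_features: dict[str, dict] = {}
    insource_groups: list[set[str]] = []

    # carve out in-source clusters from the front of the matrix features
    cluster_members: dict[int, tuple[int, int]] = {}  # feature idx -> (cluster idx, rank)
    cursor = 0
    for c_idx, (size, _) in enumerate(cfg.insource_clusters):
        for rank in range(size):
            cluster_members[cursor] = (c_idx, rank)
            cursor += 1
    if cursor > n:
        raise ValueError("insource_clusters larger than n_matrix_features")
    cluster_rt = rng.uniform(2.0, 26.0, len(cfg.insource_clusters))
    cluster_zone = [cfg.zones[int(z)] for z in rng.integers(0, len(cfg.zones), len(cfg.insource_clusters))]
    # distinct random extra fragments per cluster member
    extra_frag = rng.uniform(130.0, 180.0, (len(cluster_members) + 1, 2))

    def _matrix_feature(i: int) -> Feature:
        fid = f"M{i + 1:05d}"
        mass = masses[i]
        rt = rts[i]
        zone = zones_of[i]
        ms2: list[MS2Spectrum] = []
        chem_id = fid
        if i in cluster_members:
            c_idx, rank = cluster_members[i]
            size, n_shared = cfg.insource_clusters[c_idx]
            zone = cluster_zone[c_idx]
            mass = float(rng.uniform(200.0, 800.0))
            rt = float(cluster_rt[c_idx] + rng.uniform(-cfg.insource_rt_jitter, cfg.insource_rt_jitter))
            chem_id = f"CHEM_CLUSTER_{c_idx + 1}"
            if n_shared >= 1:
                frags = sorted(
                    list(PLANTED_FRAGMENTS[:n_shared]) + list(extra_frag[i])
                )
                ms2.append(
                    MS2Spectrum(
                        precursor_mz=mass + PROTON_MASS,
                        peaks=tuple((m, float(rng.uniform(50, 500))) for m in frags),
                    )
                )
            zones_of[i] = zone
        f = Feature(
            feature_id=fid,
            neutral_mass=float(mass),
            mz=float(mass) + PROTON_MASS,
            adduct="[M+H]+",
            rt=float(rt),
            areas={},
            ms2=ms2,
        )
        truth_features[fid] = {
            "chemical_id": chem_id,
            "zone": zone,
            "is_spike": False,
            "is_blank": False,
            "insource_group": cluster_members.get(i, (None,))[0],
        }
        return f

    for i in range(n):
        features.append(_matrix_feature(i))

    # precursor-in-fragments evidence for zero-shared clusters, and mass
    # ordering inside clusters so the representative is well defined
    by_cluster: dict[int, list[int]] = {}
    for i, (c_idx, _) in cluster_members.items():
        by_cluster.setdefault(c_idx, []).append(i)
    for c_idx, idxs in by_cluster.items():
        size, n_shared = cfg.insource_clusters[c_idx]
        insource_groups.append({features[i].feature_id for i in idxs})
        if n_shared == 0 and len(idxs) >= 2:
            ordered = sorted(idxs, key=lambda i: features[i].neutral_mass)
            parent_f = features[ordered[-1]]
            for child_i in ordered[:-1]:
                child = features[child_i]
                peaks = tuple(
                    sorted(
                        [(child.mz, 300.0)]
                        + [(float(m), 80.0) for m in extra_frag[child_i]]
                    )
                )
                parent_f.ms2.append(MS2Spectrum(precursor_mz=parent_f.mz, peaks=peaks))

    # --- blank-origin features ---------------------------------------------
    blank_masses = rng.uniform(100.0, 800.0, cfg.n_blank_features)
    blank_rts = rng.uniform(1.0, 27.0, cfg.n_blank_features)
    blank_means = 10.0 ** rng.normal(mu - 0.8, sigma, cfg.n_blank_features)
    for i in range(cfg.n_blank_features):
        fid = f"B{i + 1:05d}"
        features.append(
            Feature(
                feature_id=fid,
                neutral_mass=float(blank_masses[i]),
                mz=float(blank_masses[i]) + PROTON_MASS,
                adduct="[M+H]+",
                rt=float(blank_rts[i]),
            )
        )
        truth_features[fid] = {
            "chemical_id": fid,
            "zone": None,
            "is_spike": False,
            "is_blank": True,
            "insource_group": None,
        }

    # --- spikes --------------------------------------------------------------
    spike_rts = rng.uniform(2.0, 26.0, len(cfg.spikes))
    for k, spike in enumerate(cfg.spikes):
        fid = f"SPK_{spike.name}"
        mass = float(monoisotopic_mass(spike.formula))
        features.append(
            Feature(
                feature_id=fid,
                neutral_mass=mass,
                mz=mass + PROTON_MASS,
                adduct="[M+H]+",
                rt=float(spike_rts[k]),
            )
        )
        truth_features[fid] = {
            "chemical_id": fid,
            "zone": spike.zone_id,
            "is_spike": True,
            "is_blank": False,
            "insource_group": None,
        }

    # --- areas ----------------------------------------------------------------
    index_of = {f.feature_id: f for f in features}

    def _deposit(fid: str, sample_ids: Sequence[str], mean: float) -> None:
        factors = _noise_factors(rng, len(sample_ids), cfg.triplicate_cv)
        f = index_of[fid]
        for sid, fac in zip(sample_ids, factors):
            f.areas[sid] = AreaMeasurement(area=float(mean * fac), gap_filled=False)

    for i in range(n):
        fid = f"M{i + 1:05d}"
        _deposit(fid, parent_ids, parent_means[i])
        zone = zones_of[i]
        if zone is not None:
            for method in cfg.methods:
                rec = cfg.recovery_model[method].draw(rng)
                frac_ids = [f"frac_{zone}_{method}_{r}" for r in range(1, cfg.n_replicates + 1)]
                _deposit(fid, frac_ids, parent_means[i] * rec)
    for i in range(cfg.n_blank_features):
        _deposit(f"B{i + 1:05d}", blank_ids, blank_means[i])
    for spike in cfg.spikes:
        fid = f"SPK_{spike.name}"
        _deposit(fid, parent_ids, spike.parent_area)
        for method in cfg.methods:
            frac_ids = [
                f"frac_{spike.zone_id}_{method}_{r}" for r in range(1, cfg.n_replicates + 1)
            ]
            _deposit(fid, frac_ids, spike.parent_area * spike.recovery)

    # --- gap filling ----------------------------------------------------------
    if cfg.gap_fill_prob > 0:
        all_sample_ids = [s.sample_id for s in samples]
        gap_draw = rng.random((len(features), len(all_sample_ids)))
        gap_area = rng.uniform(1e4, 9e5, (len(features), len(all_sample_ids)))
        for fi, f in enumerate(features):
            for si, sid in enumerate(all_sample_ids):
                if sid not in f.areas and gap_draw[fi, si] < cfg.gap_fill_prob:
                    f.areas[sid] = AreaMeasurement(area=float(gap_area[fi, si]), gap_filled=True)

    table = FeatureTable(features=features, samples=samples)

    # --- fingerprints and candidate structures --------------------------------
    fingerprints: dict[str, Fingerprint] = {}
    candidate_structures: dict[str, list[tuple[str, Fingerprint]]] = {}
    structure_activity: dict[str, bool] = {}
    rule_idx = np.asarray(cfg.planted_rule)

    featured = [f"SPK_{s.name}" for s in cfg.spikes] + [
        fid for grp in insource_groups for fid in sorted(grp)
    ]
    genotoxic_of = {f"SPK_{s.name}": s.genotoxic for s in cfg.spikes}
    for fid in featured:
        fp = _random_fingerprint(rng, cfg.fingerprint_length, cfg.bit_density)
        bits = fp.bits.copy()
        if genotoxic_of.get(fid, False):
            bits[rule_idx] = 1
        else:
            bits[rule_idx] = 0
        fp = Fingerprint(bits)
        fingerprints[fid] = fp
        structs: list[tuple[str, Fingerprint]] = [(f"{fid}_TRUE", fp)]
        for k in range(cfg.n_candidate_structures - 1):
            sfp = _random_fingerprint(rng, cfg.fingerprint_length, cfg.bit_density)
            structs.append((f"{fid}_S{k + 1:03d}", sfp))
        candidate_structures[fid] = structs
        for sid, sfp in structs:
            structure_activity[sid] = bool(sfp.bits[rule_idx].any())

    # --- suspect list ----------------------------------------------------------
    suspects = [SuspectEntry(name=s.name, formula=s.formula) for s in cfg.spikes]
    n_decoys = max(0, cfg.n_suspects - len(suspects))
    decoy_masses = rng.uniform(100.0, 800.0, n_decoys)
    for i in range(n_decoys):
        suspects.append(SuspectEntry(name=f"suspect_{i + 1:04d}", neutral_mass=float(decoy_masses[i])))

    # --- endpoint datasets ------------------------------------------------------
    endpoint_datasets = []
    for e_idx, (name, n_chem, n_act) in enumerate(cfg.endpoints):
        endpoint_datasets.append(
            simulate_endpoint_data(
                n_chemicals=n_chem,
                active_fraction=n_act / n_chem,
                planted_rule=cfg.planted_rule,
                label_noise=cfg.label_noise,
                seed=int((cfg.seed * 1000003 + 7919 * (e_idx + 1)) % 2**31),
                fingerprint_length=cfg.fingerprint_length,
                bit_density=cfg.bit_density,
                endpoint_name=name,
            )
        )

    truth = GroundTruth(
        features=truth_features,
        structure_activity=structure_activity,
        insource_groups=insource_groups,
    )
    return SyntheticStudy(
        config=cfg,
        table=table,
        fingerprints=fingerprints,
        candidate_structures=candidate_structures,
        suspects=suspects,
        endpoints=endpoint_datasets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Study directory I/O (the file dialects of the downstream modules)
# ---------------------------------------------------------------------------

def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Emit a study directory in the pipeline's file dialects.

    features.csv / features.samples.csv, ms2.mgf, fingerprints.csv,
    candidates.csv, suspects.csv, endpoint_activity.csv plus one
    fingerprint file per endpoint, ground_truth.json and
    study_config.json.  Byte-identical for identical seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(study.table, outdir / "features.csv")
    write_ms2(study.table, outdir / "ms2.mgf")
    write_fingerprints(study.fingerprints, outdir / "fingerprints.csv")

    rows = []
    for fid, structs in study.candidate_structures.items():
        for sid, fp in structs:
            rows.append((fid, sid, fp.to_bitstring()))
    pd.DataFrame(rows, columns=["feature_id", "structure_id", "bitstring"]).to_csv(
        outdir / "candidates.csv", index=False
    )

    pd.DataFrame(
        [
            (s.name, s.formula.hill() if s.formula else "", repr(s.neutral_mass))
            for s in study.suspects
        ],
        columns=["name", "formula", "neutral_mass"],
    ).to_csv(outdir / "suspects.csv", index=False)

    act_rows = []
    for ds in study.endpoints:
        fps = {cid: Fingerprint(ds.X[i]) for i, cid in enumerate(ds.chemical_ids)}
        write_fingerprints(fps, outdir / f"endpoint_{ds.endpoint_name}_fingerprints.csv")
        for cid, y in zip(ds.chemical_ids, ds.y):
            act_rows.append((cid, ds.endpoint_name, "true" if y else "false"))
    pd.DataFrame(act_rows, columns=["chemical_id", "endpoint", "active"]).to_csv(
        outdir / "endpoint_activity.csv", index=False
    )

    (outdir / "ground_truth.json").write_text(study.truth.to_json())
    cfg_dict = asdict(study.config)
    cfg_dict["recovery_model"] = {k: asdict(v) for k, v in study.config.recovery_model.items()}
    (outdir / "study_config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True, default=str))
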