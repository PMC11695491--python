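"""Candidate-structure ranking and per-feature genotoxicity statistics.

For an unidentified feature, databases provide candidate structures
whose fingerprints can be compared with the fingerprint predicted from
the feature's MS2.  Candidates are ranked by fingerprint similarity
(Tanimoto/Jaccard over bits — a documented stand-in for proprietary
spectral-library scores; every statistic downstream depends only on the
rank order).  Per feature we then report how many candidates a
genotoxicity model calls active, overall and within the top decile of
the ranking, and order features by those statistics for follow-up.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemmass import round_half_up
from .feature_model import Feature, MS2Spectrum
from .genotox import EndpointPrediction, Fingerprint
from .insource import ChemicalGroup

__all__ = [
    "CandidateSet",
    "CandidateStats",
    "tanimoto",
    "rank_candidates",
    "top_decile_size",
    "candidate_stats",
    "stats_from_counts",
    "feature_priority_report",
    "load_reference_zone",
    "reference_zone_features",
]


@dataclass(frozen=True)
class CandidateSet:
    """Candidate structures for one feature, ranked by similarity (descending)."""

    feature_id: str
    candidates: tuple[tuple[str, Fingerprint, float], ...]  # (structure_id, fp, score)

    def __post_init__(self) -> None:
        scores = [s for _, _, s in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("candidate scores must be non-increasing")

    @property
    def structure_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.candidates]


@dataclass(frozen=True)
class CandidateStats:
    """Predicted-genotoxic counts over a ranked candidate list."""

    n_total: int
    n_active: int
    pct_active: float
    top_n: int
    top_active: int
    top_pct: float


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity of two bit vectors (1.0 for two empty vectors)."""
    if a.length != b.length:
        raise ValueError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    return inter / union


def rank_candidates(
    feature_id: str,
    feature_fp: Fingerprint,
    structures: Sequence[tuple[str, Fingerprint]],
) -> CandidateSet:
    """Rank candidate structures by fingerprint similarity to the feature.

    Ties are broken by structure_id lexicographically, which makes the
    ranking fully deterministic.
    """
    if not structures:
        raise ValueError("empty structure list")
    scored = sorted(
        ((sid, fp, tanimoto(feature_fp, fp)) for sid, fp in structures),
        key=lambda t: (-t[2], t[0]),
    )
    return CandidateSet(feature_id=feature_id, candidates=tuple(scored))


def top_decile_size(n_total: int) -> int:
    """Size of the top-10% prefix of a ranked list: round-half-up, minimum 1."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return max(1, (n_total + 5) // 10)


def stats_from_counts(n_total: int, n_active: int, top_active: int) -> CandidateStats:
    """Candidate statistics from pre-computed counts.

    Percentages are 100 x count ratios rounded half-up to one decimal;
    the top-decile denominator is :func:`top_decile_size`.
    """
    if not (0 <= n_active <= n_total):
        raise ValueError("need 0 <= n_active <= n_total")
    top_n = top_decile_size(n_total)
    if not (0 <= top_active <= top_n):
        raise ValueError("need 0 <= top_active <= top_decile_size(n_total)")
    return CandidateStats(
        n_total=n_total,
        n_active=n_active,
        pct_active=round_half_up(100.0 * n_active / n_total, 1),
        top_n=top_n,
        top_active=top_active,
        top_pct=round_half_up(100.0 * top_active / top_n, 1),
    )


def candidate_stats(cs: CandidateSet, active: Mapping[str, bool]) -> CandidateStats:
    """Predicted-genotoxic statistics over a ranked candidate set."""
    missing = [sid for sid in cs.structure_ids if sid not in active]
    if missing:
        raise KeyError(f"missing activity call for structure(s): {missing[:5]}")
    n_total = len(cs.candidates)
    if n_total == 0:
        raise ValueError("empty candidate set")
    n_active = sum(bool(active[sid]) for sid in cs.structure_ids)
    top_n = top_decile_size(n_total)
    top_active = sum(bool(active[sid]) for sid in cs.structure_ids[:top_n])
    return stats_from_counts(n_total, n_active, top_active)


def feature_priority_report(
    features: Mapping[str, Mapping],
    predictions: Mapping[str, EndpointPrediction],
    stats: Mapping[str, CandidateStats],
    groups: Sequence[ChemicalGroup] = (),
) -> pd.DataFrame:
    """Rank features for identification follow-up.

    The order encodes the screening logic: a feature whose own MS2
    fingerprint is called active in any endpoint outranks one that is
    not; then the share of predicted-genotoxic structures among the top
    decile, then over all candidates, then parent abundance; feature_id
    breaks any remaining tie so the order is total and deterministic.
    ``features`` maps feature_id to a metadata mapping that must carry
    ``parent_area`` (other keys are passed through to the report).
    """
    keys = set(features)
    if set(predictions) != keys or set(stats) != keys:
        raise KeyError("features, predictions and stats must share the same feature ids")
    report_columns = [
        "rank", "feature_id", "active_any", "active_endpoints", "n_candidates",
        "n_active_candidates", "pct_active", "top_n", "top_active", "top_pct",
        "group_id", "group_representative",
    ]
    if not keys:
        return pd.DataFrame(columns=report_columns)
    group_of: dict[str, str] = {}
    rep_of: dict[str, str] = {}
    for g in groups:
        for fid in g.member_feature_ids:
            group_of[fid] = g.group_id
            rep_of[fid] = g.representative

    rows = []
    for fid, meta in features.items():
        pred = predictions[fid]
        st = stats[fid]
        row = dict(meta)
        row.update(
            feature_id=fid,
            active_any=pred.active_any,
            active_endpoints=";".join(sorted(k for k, p in pred.probabilities.items() if p > 0.5)),
            n_candidates=st.n_total,
            n_active_candidates=st.n_active,
            pct_active=st.pct_active,
            top_n=st.top_n,
            top_active=st.top_active,
            top_pct=st.top_pct,
            group_id=group_of.get(fid, ""),
            group_representative=rep_of.get(fid, fid),
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["active_any", "top_pct", "pct_active", "parent_area", "feature_id"],
        ascending=[False, False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# Packaged reference dataset: 13 prioritized features of one bioactive zone
# (zone D of a printed-paperboard extract), used by the worked example and
# as a fixed oracle for the grouping / reporting layers.
# ---------------------------------------------------------------------------

#: MS2 fragment ions shared by the co-eluting in-source cluster in the
#: reference zone (also the synthetic generator's default planted fragments).
REFERENCE_SHARED_FRAGMENTS = (85.0283, 99.0440, 127.0389)


def load_reference_zone() -> pd.DataFrame:
    """The packaged reference table of 13 prioritized features for one zone."""
    with importlib.resources.files("edascreen.data").joinpath("zone_d_features.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"feature_id": str}, keep_default_na=False)
    return df


def reference_zone_features() -> list[Feature]:
    """Reference features as :class:`Feature` objects with their MS2 evidence.

    Co-eluting cluster members carry the shared fragment ions in their
    spectra; the precursor-as-fragment pair is reproduced by planting
    the lower-mass feature's ion m/z into the higher-mass feature's MS2.
    """
    df = load_reference_zone()
    feats: list[Feature] = []
    cluster_b = df[df.insource_cluster == "B"].sort_values("neutral_mass")
    child_mz = float(cluster_b.iloc[0].mz) if len(cluster_b) else None
    parent_id = str(cluster_b.iloc[-1].feature_id) if len(cluster_b) else None
    for r in df.itertuples():
        ms2: list[MS2Spectrum] = []
        if r.insource_cluster == "A":
            peaks = tuple((m, 100.0) for m in REFERENCE_SHARED_FRAGMENTS)
            ms2.append(MS2Spectrum(precursor_mz=float(r.mz), peaks=peaks))
        elif r.insource_cluster == "B" and str(r.feature_id) == parent_id:
            assert child_mz is not None
            peaks = tuple(sorted([(91.0542, 40.0), (child_mz, 100.0), (388.1754, 25.0)]))
            ms2.append(MS2Spectrum(precursor_mz=float(r.mz), peaks=peaks))
        feats.append(
            Feature(
                feature_id=str(r.feature_id),
                neutral_mass=float(r.neutral_mass),
                mz=float(r.mz),
                adduct="[M+H]+",
                rt=float(r.rt_min),
                ms2=ms2,
            )
        )
    return feats
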