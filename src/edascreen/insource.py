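"""Collapse in-source ionization artifacts into chemical groups.

Electrospray sources fragment a minority of intact ions before mass
analysis, so one chemical can surface as several aligned MS1 features
at the same retention time.  Two kinds of evidence link such features:
co-eluting features whose MS2 spectra share fragment ions, and a
feature whose [M+H]+ appears verbatim as an MS2 fragment of a
co-eluting higher-mass feature.  Linked features are grouped by
connected components; the highest-mass member represents the group as
the most plausible intact chemical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .feature_model import Feature, MS2Spectrum

__all__ = [
    "InsourceLink",
    "ChemicalGroup",
    "shared_fragments",
    "precursor_in_fragments",
    "group_insource",
    "write_groups_report",
]

DEFAULT_RT_TOL = 0.05  # min
DEFAULT_MZ_TOL = 0.005  # Da
DEFAULT_MIN_SHARED = 2


@dataclass(frozen=True)
class InsourceLink:
    """One pairwise piece of linkage evidence between co-eluting features."""

    feature_a: str
    feature_b: str
    evidence: str  # "shared_fragments" | "precursor_in_fragments"
    matched_mz: tuple[float, ...]


@dataclass(frozen=True)
class ChemicalGroup:
    """A set of features deduced to be one chemical."""

    group_id: str
    member_feature_ids: frozenset[str]
    representative: str  # member with the highest neutral mass


def shared_fragments(a: MS2Spectrum, b: MS2Spectrum, mz_tol: float = DEFAULT_MZ_TOL) -> list[float]:
    """Fragment m/z values common to two spectra.

    Fragments are paired greedily, closest pairs first, each fragment
    used at most once; the returned values are the midpoint m/z of each
    matched pair, sorted ascending.
    """
    if not a.peaks or not b.peaks:
        return []
    mza = a.fragment_mzs
    mzb = b.fragment_mzs
    pairs = [
        (abs(x - y), i, j)
        for i, x in enumerate(mza)
        for j, y in enumerate(mzb)
        if abs(x - y) <= mz_tol
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append(0.5 * (mza[i] + mzb[j]))
    return sorted(matched)


def precursor_in_fragments(
    parent_candidate: Feature, fragment_candidate: Feature, mz_tol: float = DEFAULT_MZ_TOL
) -> bool:
    """True when the candidate fragment's ion m/z occurs in the parent's MS2."""
    target = fragment_candidate.mz
    for spec in parent_candidate.ms2:
        for frag in spec.fragment_mzs:
            if abs(frag - target) <= mz_tol:
                return True
    return False


def _linked(
    fa: Feature, fb: Feature, rt_tol: float, mz_tol: float, min_shared: int
) -> InsourceLink | None:
    if abs(fa.rt - fb.rt) > rt_tol:
        return None
    best: list[float] = []
    for sa in fa.ms2:
        for sb in fb.ms2:
            m = shared_fragments(sa, sb, mz_tol)
            if len(m) > len(best):
                best = m
    if len(best) >= min_shared:
        return InsourceLink(fa.feature_id, fb.feature_id, "shared_fragments", tuple(best))
    for parent, child in ((fa, fb), (fb, fa)):
        if precursor_in_fragments(parent, child, mz_tol):
            return InsourceLink(
                parent.feature_id, child.feature_id, "precursor_in_fragments", (child.mz,)
            )
    return None


def group_insource(
    features: Sequence[Feature],
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> tuple[list[ChemicalGroup], list[InsourceLink]]:
    """Partition features into chemical groups via in-source linkage.

    Returns the groups (a partition of the input; singletons included)
    and the pairwise evidence edges.  Grouping accepts transitive
    closure: any chain of pairwise links makes one chemical.
    """
    if rt_tol <= 0 or mz_tol <= 0:
        raise ValueError("tolerances must be positive")
    feats = sorted(features, key=lambda f: f.feature_id)
    n = len(feats)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    links: list[InsourceLink] = []
    for i in range(n):
        for j in range(i + 1, n):
            link = _linked(feats[i], feats[j], rt_tol, mz_tol, min_shared)
            if link is not None:
                links.append(link)
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    components: dict[int, list[Feature]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(feats[i])

    groups = []
    for members in components.values():
        rep = max(members, key=lambda f: (f.neutral_mass, f.feature_id))
        groups.append(
            ChemicalGroup(
                group_id="",  # assigned after sorting for determinism
                member_feature_ids=frozenset(f.feature_id for f in members),
                representative=rep.feature_id,
            )
        )
    groups.sort(key=lambda g: min(g.member_feature_ids))
    groups = [
        ChemicalGroup(f"G{k + 1:03d}", g.member_feature_ids, g.representative)
        for k, g in enumerate(groups)
    ]
    return groups, links


def write_groups_report(
    groups: Sequence[ChemicalGroup], links: Sequence[InsourceLink], path: str | Path
) -> None:
    """Serialize chemical groups and their evidence edges to JSON."""
    payload = {
        "groups": [
            {
                "group_id": g.group_id,
                "members": sorted(g.member_feature_ids),
                "representative": g.representative,
            }
            for g in groups
        ],
        "links": [
            {
                "feature_a": l.feature_a,
                "feature_b": l.feature_b,
                "evidence": l.evidence,
                "matched_mz": list(l.matched_mz),
            }
            for l in links
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
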