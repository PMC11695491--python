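"""Fingerprint-based genotoxicity endpoint models.

Chemicals are represented as fixed-length binary molecular fingerprints
(substructure presence/absence bits).  For each genotoxicity endpoint —
p53 pathway activation, or DNA damage read out as differential
cytotoxicity of DNA-repair-deficient DT40 cell lines versus wild type —
a gradient-boosted tree classifier is trained on curated
chemical x fingerprint x activity records and then applied to the
fingerprints of unidentified screening features.  A feature counts as
potentially genotoxic when it is more likely than not (P > 0.5) active
in at least one endpoint model.

The DT40 DNA-damage endpoints are not raw assay calls: a chemical is
active when a repair-deficient line is at least ``sensitivity_threshold``
fold more sensitive (lower AC50) than the wild-type control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split

__all__ = [
    "Fingerprint",
    "EndpointDataset",
    "RatioActivityRule",
    "EndpointModel",
    "EndpointPrediction",
    "dt40_ratio_labels",
    "train_endpoint_model",
    "predict_probability",
    "classify_any_endpoint",
    "read_fingerprints",
    "write_fingerprints",
    "read_endpoint_records",
]

DEFAULT_FINGERPRINT_LENGTH = 2048
MODEL_SCHEMA_VERSION = 1

# Fixed shallow-tree settings: desk-scale, deterministic, no search.
XGB_PARAMS = dict(
    n_estimators=200,
    max_depth=3,
    learning_rate=0.2,
    tree_method="hist",
    n_jobs=1,
    eval_metric="logloss",
)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary molecular fingerprint."""

    bits: np.ndarray  # uint8 vector of 0/1

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("fingerprint must be a 1-D bit vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0 or 1")
        object.__setattr__(self, "bits", arr)

    @property
    def length(self) -> int:
        return int(self.bits.shape[0])

    @classmethod
    def from_bitstring(cls, s: str) -> "Fingerprint":
        if not s or set(s) - {"0", "1"}:
            raise ValueError("bitstring must be a non-empty string of 0/1")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Fingerprint) and np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


@dataclass
class EndpointDataset:
    """Chemicals x fingerprint bits x binary activity for one endpoint."""

    endpoint_name: str
    chemical_ids: list[str]
    X: np.ndarray  # (n_chemicals, fingerprint_length) uint8
    y: np.ndarray  # (n_chemicals,) bool

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=bool)
        if len(self.chemical_ids) != self.X.shape[0] or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("chemical_ids, X and y must have matching first dimension")
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise ValueError("duplicate chemical_id in endpoint dataset")

    @property
    def n_total(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_active(self) -> int:
        return int(self.y.sum())

    @property
    def fingerprint_length(self) -> int:
        return int(self.X.shape[1])

    @classmethod
    def from_records(
        cls, endpoint_name: str, records: Sequence[tuple[str, Fingerprint, bool]]
    ) -> "EndpointDataset":
        if not records:
            raise ValueError("empty endpoint dataset")
        lengths = {fp.length for _, fp, _ in records}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
        return cls(
            endpoint_name=endpoint_name,
            chemical_ids=[cid for cid, _, _ in records],
            X=np.stack([fp.bits for _, fp, _ in records]),
            y=np.array([a for _, _, a in records], dtype=bool),
        )


@dataclass(frozen=True)
class RatioActivityRule:
    """Mutant-vs-wild-type sensitivity fold-change defining DNA-damage activity."""

    sensitivity_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.sensitivity_threshold <= 1:
            raise ValueError("sensitivity_threshold must exceed 1")


def dt40_ratio_labels(
    ac50_mutant: Mapping[str, Mapping[str, float]] | Mapping[str, float],
    ac50_wt: Mapping[str, float],
    rule: RatioActivityRule = RatioActivityRule(),
) -> dict[str, bool]:
    """Activity labels from mutant/wild-type AC50 ratios.

    ``ac50_mutant`` is either one mutant line's chemical→AC50 map or a
    map of line name → such a map.  A chemical is active when, for at
    least one mutant line, wild-type AC50 / mutant AC50 >= the
    sensitivity threshold (the repair-deficient line dies at lower
    concentration).  Chemicals untested or inactive in every mutant
    line — or lacking a wild-type AC50 — are labelled inactive.
    """
    first = next(iter(ac50_mutant.values()), None)
    lines: list[Mapping[str, float]]
    if isinstance(first, Mapping):
        lines = list(ac50_mutant.values())  # type: ignore[arg-type]
    else:
        lines = [ac50_mutant]  # type: ignore[list-item]

    chemicals: set[str] = set(ac50_wt)
    for line in lines:
        chemicals.update(line)

    for name, value in ac50_wt.items():
        if value <= 0:
            raise ValueError(f"non-positive wild-type AC50 for {name!r}")
    labels: dict[str, bool] = {}
    for chem in sorted(chemicals):
        wt = ac50_wt.get(chem)
        active = False
        for line in lines:
            mut = line.get(chem)
            if mut is None:
                continue
            if mut <= 0:
                raise ValueError(f"non-positive mutant AC50 for {chem!r}")
            if wt is not None and wt / mut >= rule.sensitivity_threshold:
                active = True
        labels[chem] = active
    return labels


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class EndpointModel:
    """A trained endpoint classifier with its training metadata."""

    endpoint_name: str
    fingerprint_length: int
    seed: int
    metrics: dict[str, float]
    booster: xgb.Booster
    schema_version: int = MODEL_SCHEMA_VERSION

    def predict_probability(self, fp: Fingerprint) -> float:
        return predict_probability(self, fp)

    def feature_importances(self) -> np.ndarray:
        """Per-bit gain importance (zero for unused bits)."""
        gains = self.booster.get_score(importance_type="gain")
        out = np.zeros(self.fingerprint_length)
        for key, val in gains.items():
            out[int(key.lstrip("f"))] = val
        return out

    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "endpoint_name": self.endpoint_name,
            "fingerprint_length": self.fingerprint_length,
            "seed": self.seed,
            "metrics": self.metrics,
            "booster_json": self.booster.save_raw("json").decode(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EndpointModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {payload.get('schema_version')!r}")
        booster = xgb.Booster()
        booster.load_model(bytearray(payload["booster_json"].encode()))
        return cls(
            endpoint_name=payload["endpoint_name"],
            fingerprint_length=int(payload["fingerprint_length"]),
            seed=int(payload["seed"]),
            metrics=dict(payload["metrics"]),
            booster=booster,
        )


@dataclass(frozen=True)
class EndpointPrediction:
    """Per-endpoint activity probabilities for one feature."""

    feature_id: str
    probabilities: Mapping[str, float] = field(default_factory=dict)

    @property
    def active_any(self) -> bool:
        return classify_any_endpoint(self.probabilities)


def train_endpoint_model(
    dataset: EndpointDataset,
    seed: int,
    test_size: float = 0.15,
) -> tuple[EndpointModel, dict[str, float]]:
    """Train a gradient-boosted tree classifier on fingerprint bits.

    The data are split 0.85/0.15 stratified by class; class imbalance is
    handled by weighting positives n_inactive/n_active.  Returns the
    model and its held-out balanced accuracy, sensitivity and
    specificity.  Fully deterministic given the seed (single-threaded
    histogram trees).
    """
    if dataset.n_active == 0 or dataset.n_active == dataset.n_total:
        raise ValueError(f"endpoint {dataset.endpoint_name!r} has a single class")
    X_train, X_test, y_train, y_test = train_test_split(
        dataset.X,
        dataset.y,
        test_size=test_size,
        random_state=seed,
        stratify=dataset.y,
    )
    n_pos = int(y_train.sum())
    spw = (len(y_train) - n_pos) / n_pos
    clf = xgb.XGBClassifier(random_state=seed, scale_pos_weight=spw, **XGB_PARAMS)
    clf.fit(X_train, y_train.astype(int))
    y_pred = clf.predict(X_test).astype(bool)
    tn, fp, fn, tp = confusion_matrix(y_test, y_pred, labels=[False, True]).ravel()
    metrics = {
        "balanced_accuracy": float(balanced_accuracy_score(y_test, y_pred)),
        "sensitivity": float(tp / (tp + fn)) if tp + fn else float("nan"),
        "specificity": float(tn / (tn + fp)) if tn + fp else float("nan"),
        "n_train": float(len(y_train)),
        "n_test": float(len(y_test)),
    }
    model = EndpointModel(
        endpoint_name=dataset.endpoint_name,
        fingerprint_length=dataset.fingerprint_length,
        seed=seed,
        metrics=metrics,
        booster=clf.get_booster(),
    )
    return model, metrics


def predict_probability(model: EndpointModel, fp: Fingerprint) -> float:
    """Probability that the fingerprint is active in the model's endpoint."""
    if fp.length != model.fingerprint_length:
        raise ValueError(
            f"fingerprint length {fp.length} != model length {model.fingerprint_length}"
        )
    p = model.booster.inplace_predict(fp.bits.reshape(1, -1).astype(np.float32))
    return float(p[0])


def classify_any_endpoint(probs: Mapping[str, float]) -> bool:
    """More likely than not active in at least one endpoint (strict P > 0.5)."""
    if not probs:
        raise ValueError("no endpoint probabilities supplied")
    return max(probs.values()) > 0.5


# ---------------------------------------------------------------------------
# File dialects
# ---------------------------------------------------------------------------

def write_fingerprints(fps: Mapping[str, Fingerprint], path: str | Path) -> None:
    """Write a two-column delimited fingerprint file: id, bitstring."""
    df = pd.DataFrame(
        {"id": list(fps.keys()), "bitstring": [fp.to_bitstring() for fp in fps.values()]}
    )
    df.to_csv(path, index=False)


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if {"id", "bitstring"} - set(df.columns):
        raise ValueError("fingerprint file needs columns id, bitstring")
    return {r.id: Fingerprint.from_bitstring(r.bitstring) for r in df.itertuples()}


def read_endpoint_records(path: str | Path, fingerprints: Mapping[str, Fingerprint]) -> list[EndpointDataset]:
    """Read endpoint activity records (chemical_id, endpoint, active) into datasets."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if {"chemical_id", "endpoint", "active"} - set(df.columns):
        raise ValueError("endpoint file needs columns chemical_id, endpoint, active")
    datasets = []
    for endpoint, grp in df.groupby("endpoint", sort=True):
        records = [
            (r.chemical_id, fingerprints[r.chemical_id], r.active.strip().lower() in ("1", "true"))
            for r in grp.itertuples()
        ]
        datasets.append(EndpointDataset.from_records(str(endpoint), records))
    return datasets
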