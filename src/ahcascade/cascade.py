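"""The cascaded segment classifier: a 60-s screen gating a 10-s detector.

A 10-tree random forest classifies 60-s windows on a reduced six-feature set
(breath-drop counts, SpO2 dispersion, desaturation duration).  Only 10-s
windows contained in an AH-flagged 60-s window are passed to the second
stage, a 20-tree random forest on all 19 features; everything the screen
rejects is labeled N without invoking the second forest.  Class weights are
set to the inverse ratio of the training class counts to counter the strong
AH/N imbalance of whole-night data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES, REDUCED_FEATURES
from .preprocess import AH, N, UNKNOWN

N_TREES_60 = 10
N_TREES_20 = 20

__all__ = [
    "CascadeModel",
    "LabelSequence",
    "SchemaError",
    "train_cascade",
    "predict_60",
    "predict_cascade",
    "gate_mask",
    "crossvalidate",
    "save_model",
    "load_model",
]


class SchemaError(ValueError):
    """Raised when a feature table lacks the columns a model was trained on."""


@dataclass
class LabelSequence:
    """Predicted classes of consecutive 10-s segment start seconds.

    ``labels[i]`` is the class of the segment starting at
    ``start_offset_s + i`` seconds; UNKNOWN marks unusable segments.
    """

    labels: np.ndarray
    start_offset_s: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LabelSequence)
            and self.start_offset_s == other.start_offset_s
            and np.array_equal(self.labels, other.labels)
        )


@dataclass
class CascadeModel:
    """Both fitted forests plus everything needed to reproduce them."""

    detector60: RandomForestClassifier
    detector10: RandomForestClassifier
    class_weights_60: dict[str, float]
    class_weights_10: dict[str, float]
    gating_rule: str = "contain"  # or "overlap"
    random_seed: int = 0
    features_60: list[str] = field(default_factory=lambda: list(REDUCED_FEATURES))
    features_10: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    hyperparams: dict = field(default_factory=dict)


def _inverse_ratio_weights(labels: pd.Series) -> dict[str, float]:
    """Class weights proportional to inverse class counts, normalized to min 1."""
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"training labels contain a single class ({counts.index.tolist()}); "
            "both AH and N are required"
        )
    inv = {cls: 1.0 / n for cls, n in counts.items()}
    lo = min(inv.values())
    return {cls: w / lo for cls, w in inv.items()}


def _check_schema(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns {missing}")
    return table[columns].to_numpy(dtype=float)


def train_cascade(
    table_60: pd.DataFrame,
    table_10: pd.DataFrame,
    seed: int = 0,
    gating: str = "contain",
) -> CascadeModel:
    """Fit both forests on labeled feature tables (``label`` column, AH/N).

    The 60-s forest has 10 trees on the reduced feature set; the 10-s forest
    has 20 trees on all 19 features.  Tree hyperparameters beyond the counts
    are the classifier library's defaults, recorded on the model artifact.
    Training is reproducible given ``seed``.
    """
    if gating not in ("contain", "overlap"):
        raise ValueError(f"unknown gating rule {gating!r}")
    w60 = _inverse_ratio_weights(table_60["label"])
    w10 = _inverse_ratio_weights(table_10["label"])
    det60 = RandomForestClassifier(
        n_estimators=N_TREES_60, class_weight=w60, random_state=seed
    )
    det10 = RandomForestClassifier(
        n_estimators=N_TREES_20, class_weight=w10, random_state=seed + 1
    )
    det60.fit(_check_schema(table_60, REDUCED_FEATURES), table_60["label"].to_numpy())
    det10.fit(_check_schema(table_10, FEATURE_NAMES), table_10["label"].to_numpy())
    return CascadeModel(
        detector60=det60,
        detector10=det10,
        class_weights_60=w60,
        class_weights_10=w10,
        gating_rule=gating,
        random_seed=seed,
        hyperparams=det10.get_params(),
    )


def predict_60(model: CascadeModel, table_60: pd.DataFrame) -> np.ndarray:
    """Classes for each 60-s segment row of ``table_60`` (screening stage)."""
    return model.detector60.predict(_check_schema(table_60, model.features_60))


def gate_mask(
    ah60_starts: np.ndarray, n_starts_10: int, rule: str = "contain"
) -> np.ndarray:
    """Boolean mask over 10-s start seconds screened in by the 60-s stage.

    ``contain``: the 10-s window ``[t, t+10)`` must be fully inside some
    AH-flagged 60-s window ``[s, s+60)``, i.e. ``s ∈ [t−50, t]``.
    ``overlap``: any overlap suffices, i.e. ``s ∈ [t−59, t+9]``.
    """
    gate = np.zeros(n_starts_10, dtype=bool)
    if len(ah60_starts) == 0:
        return gate
    lo_off, hi_off = (0, 50) if rule == "contain" else (-9, 59)
    for s in np.asarray(ah60_starts, dtype=int):
        a = max(0, s + lo_off)
        b = min(n_starts_10, s + hi_off + 1)
        if b > a:
            gate[a:b] = True
    return gate


def predict_cascade(
    model: CascadeModel,
    table_60: pd.DataFrame,
    table_10: pd.DataFrame,
    n_starts_10: int | None = None,
) -> LabelSequence:
    """Full cascade prediction for one recording.

    Both tables must come from the same recording.  Unusable (absent) 10-s
    start seconds are UNKNOWN; gated-out seconds are N; only gated-in rows are
    sent to the 10-s forest.
    """
    recs = set(table_60.get("recording", pd.Series(dtype=object)).unique()) | set(
        table_10.get("recording", pd.Series(dtype=object)).unique()
    )
    if len(recs) > 1:
        raise ValueError(f"feature tables mix recordings: {sorted(recs)}")
    starts10 = table_10["start_s"].to_numpy(dtype=int)
    if n_starts_10 is None:
        n_starts_10 = int(starts10.max()) + 1 if len(starts10) else 0

    labels = np.full(n_starts_10, UNKNOWN, dtype=object)
    pred60 = predict_60(model, table_60)
    ah60 = table_60["start_s"].to_numpy(dtype=int)[pred60 == AH]
    gate = gate_mask(ah60, n_starts_10, model.gating_rule)

    labels[starts10] = N  # usable but not screened in
    gated_rows = gate[starts10]
    if gated_rows.any():
        sub = table_10.iloc[np.flatnonzero(gated_rows)]
        pred10 = model.detector10.predict(_check_schema(sub, model.features_10))
        labels[sub["start_s"].to_numpy(dtype=int)] = pred10
    return LabelSequence(labels=labels)


def _fold_assignment(n: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.zeros(n, dtype=int)
    folds[rng.permutation(n)[: n // 2]] = 1
    return folds


def crossvalidate(
    table_60: pd.DataFrame,
    table_10: pd.DataFrame,
    seed: int = 0,
    split: str = "segment",
    gating: str = "contain",
    n_starts_10: dict[str, int] | None = None,
) -> dict:
    """Twofold cross-validation over a multi-recording segment dataset.

    Each segment is predicted exactly once, by the fold model that did not
    train on it.  ``split="segment"`` divides segments at random, as the
    evaluation protocol does (overlapping windows then leak across folds —
    documented); ``split="subject"`` keeps each recording wholly inside one
    side of each fold.  Returns per-recording cascade :class:`LabelSequence`
    objects, pooled 10-s confusion counts, and the fold assignments.
    """
    if split not in ("segment", "subject"):
        raise ValueError(f"unknown split mode {split!r}")
    if min(len(table_60), len(table_10)) < 2:
        raise ValueError("need at least 2 segments per table for twofold CV")
    table_60 = table_60.reset_index(drop=True)
    table_10 = table_10.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    if split == "segment":
        f60 = _fold_assignment(len(table_60), rng)
        f10 = _fold_assignment(len(table_10), rng)
    else:
        subjects = sorted(
            set(table_60["recording"].unique()) | set(table_10["recording"].unique())
        )
        if len(subjects) < 2:
            raise ValueError("subject-level split needs >= 2 recordings")
        sf = dict(zip(subjects, _fold_assignment(len(subjects), rng)))
        f60 = table_60["recording"].map(sf).to_numpy()
        f10 = table_10["recording"].map(sf).to_numpy()

    pred60_all = np.empty(len(table_60), dtype=object)
    pred10_all = np.empty(len(table_10), dtype=object)
    for fold in (0, 1):
        model = train_cascade(
            table_60[f60 != fold], table_10[f10 != fold], seed=seed + fold, gating=gating
        )
        test60 = table_60[f60 == fold]
        test10 = table_10[f10 == fold]
        if len(test60):
            pred60_all[f60 == fold] = predict_60(model, test60)
        if len(test10):
            pred10_all[f10 == fold] = model.detector10.predict(
                _check_schema(test10, FEATURE_NAMES)
            )

    # Assemble per-recording gated label sequences from the pooled predictions.
    sequences: dict[str, LabelSequence] = {}
    raw10_sequences: dict[str, LabelSequence] = {}
    tp = fp = fn = tn = 0
    for rec_id in sorted(table_10["recording"].unique()):
        m60 = table_60["recording"] == rec_id
        m10 = (table_10["recording"] == rec_id).to_numpy()
        starts10 = table_10.loc[m10, "start_s"].to_numpy(dtype=int)
        n_starts = (
            (n_starts_10 or {}).get(rec_id)
            or (int(starts10.max()) + 1 if len(starts10) else 0)
        )
        ah60 = table_60.loc[m60.to_numpy() & (pred60_all == AH), "start_s"].to_numpy(int)
        gate = gate_mask(ah60, n_starts, gating)
        labels = np.full(n_starts, UNKNOWN, dtype=object)
        labels[starts10] = N
        gated = gate[starts10]
        labels[starts10[gated]] = pred10_all[m10][gated]
        sequences[rec_id] = LabelSequence(labels=labels)
        raw_labels = np.full(n_starts, UNKNOWN, dtype=object)
        raw_labels[starts10] = pred10_all[m10]
        raw10_sequences[rec_id] = LabelSequence(labels=raw_labels)

        ref = table_10.loc[m10, "label"].to_numpy()
        pred = labels[starts10]
        tp += int(np.sum((pred == AH) & (ref == AH)))
        fp += int(np.sum((pred == AH) & (ref == N)))
        fn += int(np.sum((pred == N) & (ref == AH)))
        tn += int(np.sum((pred == N) & (ref == N)))

    return {
        "sequences": sequences,
        "raw10_sequences": raw10_sequences,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "folds_60": f60,
        "folds_10": f10,
        "seed": seed,
        "split": split,
        "gating": gating,
    }


def save_model(model: CascadeModel, path) -> None:
    """Persist a trained cascade with a format version tag."""
    import joblib

    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> CascadeModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model artifact version: {payload.get('format_version')}")
    return payload["model"]
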