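"""Bagged decision-forest sleep stager with night-grouped cross-validation.

The classifier is an ensemble of 100 CART trees grown on bootstrap
resamples, splitting on Gini impurity with random feature subsets, and
stopping when a node is pure or holds fewer than ten observations
(scikit-learn's RandomForestClassifier realizes exactly this). On top
of the fitted trees, prediction is a per-tree plurality vote with ties
resolved toward the earlier stage in the fixed order W, N1, N2, N3, R.

Cross-validation folds are built per night, never splitting a night
across folds: patient-specific (PS) leave-one-night-out within each
patient, or pooled leave-one-night-out (LONO) across all patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureMatrix
from .io import STAGES, Hypnogram

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 100
    min_obs_to_split: int = 10
    features_per_split: int | str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_obs_to_split < 2:
            raise ValueError("min_obs_to_split must be >= 2")


@dataclass
class TrainedForest:
    model: RandomForestClassifier
    classes: tuple[str, ...]  # canonical stage order restricted to training
    feature_names: list[str]
    params: ForestParams

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedForest":
        return joblib.load(path)


@dataclass
class FoldSpec:
    """Night-level train/test partition; every night tests exactly once."""

    folds: list[tuple[tuple[Hashable, ...], tuple[Hashable, ...]]]
    scheme: str

    def __post_init__(self) -> None:
        tested: list[Hashable] = []
        for _, test in self.folds:
            tested.extend(test)
        if len(tested) != len(set(tested)):
            raise ValueError("a night appears in more than one test fold")


def make_folds(
    night_ids: Sequence[Hashable],
    patient_of: Mapping[Hashable, Hashable],
    scheme: str,
) -> FoldSpec:
    """Build PS or LONO cross-validation folds over nights.

    PS: one fold per night, training restricted to the same patient's
    other nights (every patient therefore needs at least two nights).
    LONO: one fold per night, training on all remaining nights pooled
    across patients.
    """
    scheme = scheme.upper()
    if scheme not in ("PS", "LONO"):
        raise ValueError(f"unknown scheme {scheme!r} (expected 'PS' or 'LONO')")
    night_ids = list(night_ids)
    folds = []
    if scheme == "LONO":
        for night in night_ids:
            train = tuple(n for n in night_ids if n != night)
            folds.append((train, (night,)))
    else:
        by_patient: dict[Hashable, list[Hashable]] = {}
        for n in night_ids:
            by_patient.setdefault(patient_of[n], []).append(n)
        for patient, nights in by_patient.items():
            if len(nights) < 2:
                raise ValueError(
                    f"patient {patient!r} has a single night; "
                    "patient-specific CV needs at least two"
                )
            for night in nights:
                train = tuple(n for n in nights if n != night)
                folds.append((train, (night,)))
    return FoldSpec(folds=folds, scheme=scheme)


def _valid_training_rows(features: FeatureMatrix, labels: Sequence[str]):
    if len(labels) != features.n_epochs:
        raise ValueError(
            f"{len(labels)} labels for {features.n_epochs} feature rows"
        )
    keep = features.epoch_valid
    X = features.values[keep]
    y = np.asarray(list(labels), dtype=object)[keep]
    return X, y


def train(
    features: FeatureMatrix,
    labels: Hypnogram | Sequence[str],
    params: ForestParams = ForestParams(),
) -> TrainedForest:
    """Fit the bagged forest on the valid epochs of a feature matrix."""
    labels = labels.stages if isinstance(labels, Hypnogram) else list(labels)
    X, y = _valid_training_rows(features, labels)
    if len(X) == 0:
        raise ValueError("no valid epochs to train on")
    present = set(y)
    if len(present) == 1:
        logger.warning(
            "training set contains a single class (%s); model is constant",
            next(iter(present)),
        )
    model = RandomForestClassifier(
        n_estimators=params.n_trees,
        criterion="gini",
        min_samples_split=params.min_obs_to_split,
        max_features=params.features_per_split,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    classes = tuple(c for c in STAGES if c in present)
    if not classes:  # wake/sleep or other alphabets
        classes = tuple(sorted(present))
    return TrainedForest(
        model=model,
        classes=classes,
        feature_names=list(features.feature_names),
        params=params,
    )


def plurality_vote(counts: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Winning class per row of a vote-count matrix.

    ``classes`` must be in the canonical tie-break order: on equal
    counts the earlier class wins (W before N1 before ... before R).
    """
    counts = np.asarray(counts)
    classes = np.asarray(list(classes), dtype=object)
    return classes[np.argmax(counts, axis=1)]


def predict(model: TrainedForest, features: FeatureMatrix) -> Hypnogram:
    """Plurality vote of the trees, one stage per epoch.

    Vote ties resolve to the stage earliest in (W, N1, N2, N3, R).
    Invalid epochs inherit the nearest preceding valid prediction
    (leading invalid epochs take the first valid one), logged.
    """
    if features.feature_names != model.feature_names:
        missing = [n for n in model.feature_names if n not in features.feature_names]
        extra = [n for n in features.feature_names if n not in model.feature_names]
        raise ValueError(
            f"feature columns do not match training order; "
            f"missing={missing[:5]}{'...' if len(missing) > 5 else ''}, "
            f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    valid = features.epoch_valid
    n = features.n_epochs
    stages = np.empty(n, dtype=object)
    if valid.any():
        X = features.values[valid]
        # Sub-estimators vote with indices into model.model.classes_;
        # re-order counts into the canonical stage order before argmax,
        # so np.argmax's first-wins rule realizes the stated tie-break.
        sk_classes = list(model.model.classes_)
        canon = [c for c in STAGES if c in sk_classes] or sorted(sk_classes)
        col_of = [sk_classes.index(c) for c in canon]
        votes = np.zeros((X.shape[0], len(sk_classes)), dtype=int)
        for tree in model.model.estimators_:
            idx = tree.predict(X).astype(int)
            np.add.at(votes, (np.arange(len(idx)), idx), 1)
        stages[valid] = plurality_vote(votes[:, col_of], canon)
    if not valid.all():
        if not valid.any():
            raise ValueError("no valid epochs to predict")
        logger.info(
            "%d invalid epoch(s) filled with the neighbouring valid prediction",
            int((~valid).sum()),
        )
        first_valid = int(np.flatnonzero(valid)[0])
        last = stages[first_valid]
        for k in range(n):
            if valid[k]:
                last = stages[k]
            else:
                stages[k] = last
    return Hypnogram(stages=list(stages))


def cross_validate(
    features_by_night: Mapping[Hashable, FeatureMatrix],
    labels_by_night: Mapping[Hashable, Hypnogram | Sequence[str]],
    folds: FoldSpec,
    params: ForestParams = ForestParams(),
) -> dict[Hashable, Hypnogram]:
    """Out-of-fold predictions for every night.

    Each night's hypnogram is predicted by a model that never saw that
    night; a leakage check asserts this for every fold at run time.
    """
    predictions: dict[Hashable, Hypnogram] = {}
    for train_nights, test_nights in folds.folds:
        overlap = set(train_nights) & set(test_nights)
        assert not overlap, f"fold leakage: nights {overlap} in both train and test"
        # canonical order: predictions depend on fold identity, not on
        # the order nights were listed in
        train_nights = sorted(train_nights, key=str)
        parts = [features_by_night[n] for n in train_nights]
        names = parts[0].feature_names
        stacked = FeatureMatrix(
            values=np.vstack([p.values for p in parts]),
            feature_names=names,
            epoch_valid=np.concatenate([p.epoch_valid for p in parts]),
        )
        labels: list[str] = []
        for night in train_nights:
            lb = labels_by_night[night]
            labels.extend(lb.stages if isinstance(lb, Hypnogram) else lb)
        model = train(stacked, labels, params)
        for night in test_nights:
            predictions[night] = predict(model, features_by_night[night])
    return predictions
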