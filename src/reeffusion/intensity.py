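"""Intensity-only baseline: how far do single-pixel colors get you?

Before bringing texture-aware networks to bear, the discriminatory value of
each spectral band is measured directly: the raw intensity of the annotated
pixel, for any subset of the five channels, feeds an RBF-kernel maximum-margin
classifier whose hyper-parameters (C and kernel width) are grid cross-validated
on the training set.  Accuracies are reported per channel subset for both the
10-category task and the coral-vs-other merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .datamodel import (
    LabelSet,
    PointAnnotation,
    RegisteredPair,
    merge_coral_other,
)

#: Channel names in stack order.
CHANNEL_NAMES: tuple[str, ...] = ("REF_R", "REF_G", "REF_B", "FLR_R", "FLR_G")

#: The channel subsets reported in the intensity analysis: each single
#: channel, the reflectance triplet, the fluorescence pair, and all five.
STANDARD_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("REF_R",),
    ("REF_G",),
    ("REF_B",),
    ("FLR_R",),
    ("FLR_G",),
    ("REF_R", "REF_G", "REF_B"),
    ("FLR_R", "FLR_G"),
    ("REF_R", "REF_G", "REF_B", "FLR_R", "FLR_G"),
)

#: Cross-validation grids for the RBF classifier, after the standard
#: grid-search protocol (exponential grids in C and kernel width).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-5, 16, 4))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-15, 4, 4))


@dataclass(frozen=True)
class ChannelSubset:
    """An ordered, duplicate-free subset of the five channels."""

    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channel subset must be nonempty")
        bad = set(self.channels) - set(CHANNEL_NAMES)
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in subset")

    @property
    def indices(self) -> list[int]:
        return [CHANNEL_NAMES.index(ch) for ch in self.channels]

    @property
    def name(self) -> str:
        return "+".join(self.channels)


def extract_intensities(
    pairs: Mapping[str, RegisteredPair],
    points: Sequence[PointAnnotation],
    subset: ChannelSubset,
    skip_invalid: bool = True,
) -> tuple[np.ndarray, list[PointAnnotation]]:
    """Single-pixel intensity features at each annotated location.

    Returns the (n, |subset|) feature matrix, columns in subset declaration
    order, together with the annotations actually used (points on pixels the
    fluorescence warp never covered are skipped with a warning).
    """
    import logging

    rows, used = [], []
    n_skipped = 0
    for p in points:
        pair = pairs[p.pair_id]
        if not pair.valid_mask[p.row, p.col]:
            if not skip_invalid:
                raise ValueError(f"{p.pair_id}: point on unregistered pixel")
            n_skipped += 1
            continue
        stacked = pair.stacked()
        rows.append(stacked[p.row, p.col, subset.indices])
        used.append(p)
    if n_skipped:
        logging.getLogger(__name__).warning(
            "skipped %d point(s) on unregistered pixels", n_skipped
        )
    return np.array(rows, dtype=np.float64), used


def train_intensity_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
):
    """RBF-kernel classifier with grid cross-validated (C, kernel width)."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    labels = list(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("intensity classifier requires at least 2 classes")
    folds = min(cv_folds, int(counts.min()))
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(c_grid), "gamma": list(gamma_grid)},
            cv=cv,
            n_jobs=1,
        )
        search.fit(features, labels)
        return search.best_estimator_
    return SVC(kernel="rbf", C=1.0, gamma="scale").fit(features, labels)


def evaluate_channel_subsets(
    train_pairs: Mapping[str, RegisteredPair],
    train_points: Sequence[PointAnnotation],
    test_pairs: Mapping[str, RegisteredPair],
    test_points: Sequence[PointAnnotation],
    subsets: Sequence[ChannelSubset] | None = None,
    labelset: LabelSet | None = None,
    seed: int = 0,
    **svm_kw,
) -> pd.DataFrame:
    """Per-subset mean ± SE of per-image test accuracy, 10-class and binary.

    One classifier is trained per subset and task on the training points; the
    accuracy aggregation (per image, then mean and standard error over images)
    matches the evaluation module's.
    """
    from .evaluation import per_image_accuracy, summarize_accuracy

    labelset = labelset or LabelSet()
    if subsets is None:
        subsets = [ChannelSubset(s) for s in STANDARD_SUBSETS]

    records = []
    for subset in subsets:
        x_train, pts_train = extract_intensities(train_pairs, train_points, subset)
        x_test, pts_test = extract_intensities(test_pairs, test_points, subset)
        y_train = [p.label for p in pts_train]
        y_test = [p.label for p in pts_test]
        test_images = [p.pair_id for p in pts_test]

        row: dict[str, object] = {"subset": subset.name}
        for task, (tr_labels, te_labels) in {
            "multiclass": (y_train, y_test),
            "binary": (
                merge_coral_other(y_train, labelset),
                merge_coral_other(y_test, labelset),
            ),
        }.items():
            clf = train_intensity_classifier(x_train, tr_labels, seed=seed, **svm_kw)
            pred = clf.predict(x_test)
            acc = per_image_accuracy(test_images, te_labels, list(pred))
            mean, se = summarize_accuracy(acc)
            row[f"{task}_accuracy"] = mean
            row[f"{task}_se"] = se
        records.append(row)
    return pd.DataFrame.from_records(records)
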