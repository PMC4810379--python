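"""Second-stage score fusion: the joint classifier.

After the per-modality networks are trained, every patch is propagated through
both, producing a 10-dimensional score vector per network.  The two vectors
are concatenated into a 20-dimensional joint score (reflectance scores first,
fluorescence scores second), which a linear maximum-margin classifier maps to
a label.  Because logits from separately trained networks live on
incommensurate scales, each joint dimension is standardized to zero mean and
unit variance using training-set statistics only; the SVM regularization
constant is chosen by cross-validation on the training set.

The per-sample hinge loss is scaled by 1/n so the fitted decision function is
invariant to duplicating the training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .cnn import PatchNetwork, predict_scores
from .datamodel import LabelSet
from .patching import PatchTensor, slice_modality

#: Cross-validation grid for the SVM regularization constant.
DEFAULT_C_GRID: tuple[float, ...] = tuple(10.0**k for k in range(-3, 4))


_MODALITY_BY_CHANNELS = {3: "ref", 2: "flr", 5: "five"}


def build_joint_features(
    net_ref: PatchNetwork,
    net_flr: PatchNetwork,
    patches: Sequence[PatchTensor],
) -> np.ndarray:
    """Concatenated per-modality scores: one 20-vector per (un-augmented) patch.

    Patches must be five-channel; each network sees exactly the channel slice
    matching its input width, and scores are concatenated in argument order
    (reflectance first in the canonical call).
    """
    halves = []
    for net in (net_ref, net_flr):
        modality = _MODALITY_BY_CHANNELS[net.spec.in_channels]
        halves.append(
            predict_scores(net, [slice_modality(p, modality) for p in patches])
        )
    return np.concatenate(halves, axis=1)


@dataclass
class FusionModel:
    """Fitted standardizer + linear SVM over joint score vectors."""

    pipeline: Pipeline
    labelset: LabelSet
    n_features: int
    best_c: float

    def decision_function(self, joint: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(self._check(joint))

    def predict(self, joint: np.ndarray) -> list[str]:
        idx = self.pipeline.predict(self._check(joint))
        return [self.labelset.labels[i] for i in idx]

    def _check(self, joint: np.ndarray) -> np.ndarray:
        joint = np.atleast_2d(np.asarray(joint, dtype=np.float64))
        if joint.shape[1] != self.n_features:
            raise ValueError(
                f"joint vectors must have {self.n_features} dimensions, "
                f"got {joint.shape[1]}"
            )
        return joint


def train_fusion(
    joint: np.ndarray,
    labels: Sequence[str],
    labelset: LabelSet | None = None,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> FusionModel:
    """Fit the linear one-vs-rest fusion classifier over standardized scores.

    The regularization constant is selected from ``c_grid`` by stratified
    cross-validation on the training data only.
    """
    labelset = labelset or LabelSet()
    joint = np.atleast_2d(np.asarray(joint, dtype=np.float64))
    y = labelset.to_indices(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("fusion training requires at least 2 classes")

    n = len(joint)

    def make_pipeline(c: float) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    LinearSVC(
                        C=c / n,  # mean (not summed) hinge: duplication-invariant
                        multi_class="ovr",
                        dual=False,
                        tol=1e-6,
                        max_iter=20000,
                    ),
                ),
            ]
        )

    folds = min(cv_folds, int(counts.min()))
    if folds >= 2 and len(c_grid) > 1:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            make_pipeline(1.0),
            {"svm__C": [c / n for c in c_grid]},
            cv=cv,
            n_jobs=1,
        )
        search.fit(joint, y)
        pipe = search.best_estimator_
        best_c = float(search.best_params_["svm__C"] * n)
    else:
        best_c = float(c_grid[len(c_grid) // 2])
        pipe = make_pipeline(best_c).fit(joint, y)

    return FusionModel(pipe, labelset, joint.shape[1], best_c)


def predict_fused(model: FusionModel, joint: np.ndarray) -> list[str]:
    """Deterministic label predictions for joint score vectors."""
    return model.predict(joint)
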