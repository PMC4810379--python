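"""End-to-end experiment orchestration.

The canonical experiment: split image pairs into train/test at the image
level, extract and augment training patches, train the three patch networks
(reflectance, fluorescence, five-channel), train the score-fusion classifier,
evaluate all four on the test set, and compare them with the paired
signed-rank protocol plus error-rate-reduction arithmetic.

The per-point prediction table (image, row, col, true, predicted, one score
column per class) is the interchange format between stages, so every stage is
independently testable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cnn, fusion, patching
from .datamodel import LabelSet, PointAnnotation, RegisteredPair
from .evaluation import (
    EvaluationReport,
    PairedComparison,
    build_report,
    error_reduction,
    wilcoxon_paired,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one full experiment run."""

    seed: int = 0
    train_fraction: float = 142 / 212  # the survey's 142/70 image-level split
    train_ids: tuple[str, ...] | None = None
    test_ids: tuple[str, ...] | None = None
    use_fluorescence: bool = True
    reduced_network: bool = True  # desk-scale filter counts (8/8/16)
    network_overrides: dict = field(default_factory=dict)
    score_mode: str = "logit"

    def network_spec(self, in_channels: int) -> cnn.NetworkSpec:
        kw = dict(self.network_overrides)
        kw["seed"] = kw.get("seed", self.seed)
        kw["score_mode"] = kw.get("score_mode", self.score_mode)
        if self.reduced_network:
            return cnn.NetworkSpec.reduced(in_channels, **kw)
        return cnn.NetworkSpec(in_channels=in_channels, **kw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Load a config from a YAML file of flat keys + nested sections."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("train_ids", "test_ids"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if "network_overrides" in raw and raw["network_overrides"] is None:
            raw["network_overrides"] = {}
        if "filters" in raw.get("network_overrides", {}):
            raw["network_overrides"]["filters"] = tuple(
                raw["network_overrides"]["filters"]
            )
        return cls(**raw)


def split_dataset(
    pair_ids: Sequence[str], config: ExperimentConfig
) -> tuple[list[str], list[str]]:
    """Seeded random image-level split into train and test ids."""
    ids = list(pair_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 pairs to split")
    if config.train_ids is not None or config.test_ids is not None:
        train = list(config.train_ids or [])
        test = list(config.test_ids or [id_ for id_ in ids if id_ not in set(train)])
        overlap = set(train) & set(test)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
        unknown = (set(train) | set(test)) - set(ids)
        if unknown:
            raise ValueError(f"unknown pair ids in split: {sorted(unknown)}")
    else:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(ids))
        n_train = int(round(config.train_fraction * len(ids)))
        train = [ids[i] for i in order[:n_train]]
        test = [ids[i] for i in order[n_train:]]
    if not train or not test:
        raise ValueError(
            f"degenerate split: {len(train)} train / {len(test)} test images"
        )
    logger.info("split: %d train / %d test images", len(train), len(test))
    return train, test


@dataclass
class ExperimentResult:
    """Reports and pairwise comparisons from one experiment run."""

    reports: dict[str, EvaluationReport]
    comparisons: dict[str, PairedComparison]
    error_reductions: dict[str, tuple[float, float]]
    predictions: dict[str, pd.DataFrame]
    train_ids: list[str]
    test_ids: list[str]
    config_digest: str
    seed: int
    networks: dict = field(default_factory=dict)
    fusion_model: object | None = None

    def summary(self) -> dict:
        """JSON-serializable summary (accuracies in percent)."""
        out: dict = {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "n_train_images": len(self.train_ids),
            "n_test_images": len(self.test_ids),
            "accuracy": {},
            "binary_accuracy": {},
            "comparisons": {},
            "error_reductions": {},
        }
        for name, rep in self.reports.items():
            out["accuracy"][name] = {
                "mean": 100 * rep.mean_accuracy,
                "se": 100 * rep.se_accuracy,
                "n": rep.n_images,
            }
            out["binary_accuracy"][name] = {
                "mean": 100 * rep.binary_mean,
                "se": 100 * rep.binary_se,
            }
        for name, cmp_ in self.comparisons.items():
            out["comparisons"][name] = {
                "p_value": cmp_.p_value,
                "statistic": cmp_.statistic,
                "n": cmp_.n,
                "method": cmp_.method,
            }
        for name, (absolute, relative) in self.error_reductions.items():
            out["error_reductions"][name] = {
                "absolute_pct": absolute,
                "relative_pct": relative,
            }
        return out


def predictions_frame(
    points: Sequence[PointAnnotation],
    predicted: Sequence[str],
    scores: np.ndarray,
    labelset: LabelSet,
) -> pd.DataFrame:
    """The per-point interchange table for one classifier."""
    df = pd.DataFrame(
        {
            "image": [p.pair_id for p in points],
            "row": [p.row for p in points],
            "col": [p.col for p in points],
            "true": [p.label for p in points],
            "predicted": list(predicted),
        }
    )
    for j, lab in enumerate(labelset.labels):
        df[f"score_{lab}"] = scores[:, j]
    return df


def report_from_frame(df: pd.DataFrame, labelset: LabelSet) -> EvaluationReport:
    scores = df[[f"score_{lab}" for lab in labelset.labels]].to_numpy()
    return build_report(
        df["image"].tolist(),
        df["true"].tolist(),
        df["predicted"].tolist(),
        scores,
        labelset,
    )


def run_experiment(
    pairs: Mapping[str, RegisteredPair],
    annotations: Sequence[PointAnnotation],
    config: ExperimentConfig,
    labelset: LabelSet | None = None,
) -> ExperimentResult:
    """Train and evaluate all classifiers under ``config``.

    Fully reproducible from config + seed.  With ``use_fluorescence=False``
    only the reflectance network is trained (degraded mode, logged loudly).
    """
    labelset = labelset or LabelSet()
    t0 = time.time()
    train_ids, test_ids = split_dataset(sorted(pairs), config)
    train_set, test_set = set(train_ids), set(test_ids)
    train_points = [a for a in annotations if a.pair_id in train_set]
    test_points = [a for a in annotations if a.pair_id in test_set]
    logger.info(
        "annotations: %d train (x8 augmented), %d test",
        len(train_points),
        len(test_points),
    )

    # five-channel patches; per-modality tensors are channel slices.  The 8x
    # dihedral training augmentation is expanded lazily inside the optimizer.
    train_plain = patching.extract_dataset(
        pairs, train_points, "five", augment_patches=False
    )
    test_patches = patching.extract_dataset(
        pairs, test_points, "five", augment_patches=False
    )
    # points on warp-invalid pixels were skipped; recover the surviving set
    test_used = [
        PointAnnotation(p.source[0], p.source[1], p.source[2], p.label)
        for p in test_patches
    ]
    logger.info("patch extraction done (%.1f s)", time.time() - t0)

    modalities = ["ref"] + (["flr", "five"] if config.use_fluorescence else [])
    if not config.use_fluorescence:
        logger.warning(
            "fluorescence data unavailable: degraded reflectance-only mode"
        )

    nets: dict[str, cnn.PatchNetwork] = {}
    reports: dict[str, EvaluationReport] = {}
    predictions: dict[str, pd.DataFrame] = {}
    for modality in modalities:
        t1 = time.time()
        spec = config.network_spec(patching.MODALITY_CHANNELS[modality])
        net = cnn.train_network(
            spec,
            [patching.slice_modality(p, modality) for p in train_plain],
            labelset,
            orbit_augment=True,
        )
        nets[modality] = net
        scores = cnn.predict_scores(
            net, [patching.slice_modality(p, modality) for p in test_patches]
        )
        pred = cnn.classify(scores, labelset)
        predictions[modality] = predictions_frame(test_used, pred, scores, labelset)
        reports[modality] = report_from_frame(predictions[modality], labelset)
        logger.info(
            "f_%s trained+evaluated in %.1f s (accuracy %.1f%%)",
            modality,
            time.time() - t1,
            100 * reports[modality].mean_accuracy,
        )

    comparisons: dict[str, PairedComparison] = {}
    error_reductions: dict[str, tuple[float, float]] = {}
    fuse = None
    if config.use_fluorescence:
        t1 = time.time()
        joint_train = fusion.build_joint_features(
            nets["ref"], nets["flr"], train_plain
        )
        fuse = fusion.train_fusion(
            joint_train, [p.label for p in train_plain], labelset, seed=config.seed
        )
        joint_test = fusion.build_joint_features(nets["ref"], nets["flr"], test_patches)
        joint_pred = fusion.predict_fused(fuse, joint_test)
        joint_scores = fuse.decision_function(joint_test)
        predictions["joint"] = predictions_frame(
            test_used, joint_pred, joint_scores, labelset
        )
        reports["joint"] = report_from_frame(predictions["joint"], labelset)
        logger.info(
            "f_joint trained+evaluated in %.1f s (accuracy %.1f%%)",
            time.time() - t1,
            100 * reports["joint"].mean_accuracy,
        )

        for a, b in [("joint", "ref"), ("joint", "flr"), ("five", "ref"), ("joint", "five")]:
            comparisons[f"{a}_vs_{b}"] = wilcoxon_paired(
                reports[a].per_image, reports[b].per_image
            )
        for a, b in [("ref", "joint"), ("flr", "joint"), ("ref", "five")]:
            error_reductions[f"{a}_to_{b}"] = error_reduction(
                100 * reports[a].mean_accuracy, 100 * reports[b].mean_accuracy
            )

    logger.info("experiment complete in %.1f s", time.time() - t0)
    return ExperimentResult(
        reports,
        comparisons,
        error_reductions,
        predictions,
        train_ids,
        test_ids,
        config.digest(),
        config.seed,
        networks=nets,
        fusion_model=fuse,
    )


def register_benchmark(pairs: Sequence) -> dict[str, RegisteredPair]:
    """Run the registration stage on synthetic pairs (fit + warp)."""
    from .registration import fit_affine, warp_to_reflectance

    out: dict[str, RegisteredPair] = {}
    for sp in pairs:
        transform, rmse = fit_affine(sp.correspondences)
        out[sp.pair_id] = warp_to_reflectance(
            sp.pair_id, sp.reflectance, sp.fluorescence_observed, transform
        )
        logger.debug("registered %s (RMSE %.2e px)", sp.pair_id, rmse)
    return out
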