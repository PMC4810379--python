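"""Core types for multi-modal benthic point-annotation data.

A survey station contributes a *registered pair*: a conventional strobed
reflectance photograph (RGB) and a wide-band fluorescence photograph from a
modified consumer camera whose blue channel is unusable (it overlaps the blue
excitation source), leaving a red channel (chlorophyll-a emission) and a green
channel (GFP emission).  Together the pair carries five informative channels.

Expert annotations are point-based: each of a fixed number of random pixel
locations per image is assigned one of ten benthic categories.  Percent cover
statistics and all classifiers in this package operate on these points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical 10-category benthic label set, in fixed order.  The first five are
#: the dominant hard-coral genera; ``other-hard-coral`` completes the coral
#: group.  ``Millepora`` is a hydrozoan (fire coral), not a hard coral.
DEFAULT_LABELS: tuple[str, ...] = (
    "Faviidae",
    "Stylophora",
    "Platygyra",
    "Acropora",
    "Pocillopora",
    "other-hard-coral",
    "Millepora",
    "bare-substrate",
    "other-invertebrates",
    "unknown",
)

#: Labels merged into the generic "coral" class for the binary task.
DEFAULT_CORAL_SUBSET: tuple[str, ...] = DEFAULT_LABELS[:6]

#: Label recorded by annotators but excluded from analysis (exceedingly rare).
EXCLUDED_LABEL = "macroalgae"

CORAL = "coral"
OTHER = "other"


@dataclass(frozen=True)
class LabelSet:
    """An ordered category list plus the subset counted as hard coral."""

    labels: tuple[str, ...] = DEFAULT_LABELS
    coral_subset: tuple[str, ...] = DEFAULT_CORAL_SUBSET

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        unknown = set(self.coral_subset) - set(self.labels)
        if unknown:
            raise ValueError(f"coral_subset entries not in labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label: {label!r}") from None

    def to_indices(self, labels: Iterable[str]) -> np.ndarray:
        return np.array([self.index(lab) for lab in labels], dtype=np.int64)

    def is_coral(self, label: str) -> bool:
        if label not in self:
            raise KeyError(f"unknown label: {label!r}")
        return label in self.coral_subset


@dataclass
class RegisteredPair:
    """A reflectance image and a fluorescence image on a common pixel grid.

    ``reflectance`` is H x W x 3 (R, G, B) and ``fluorescence`` H x W x 2
    (R, G); intensities are floats in [0, 1].  ``valid_mask`` marks pixels of
    the reflectance frame onto which the fluorescence image actually mapped
    during registration (False where the warp sampled outside its support).
    """

    pair_id: str
    reflectance: np.ndarray
    fluorescence: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        ref = np.asarray(self.reflectance, dtype=np.float64)
        flr = np.asarray(self.fluorescence, dtype=np.float64)
        if ref.ndim != 3 or ref.shape[2] != 3:
            raise ValueError(f"reflectance must be HxWx3, got {ref.shape}")
        if flr.ndim != 3 or flr.shape[2] != 2:
            raise ValueError(f"fluorescence must be HxWx2, got {flr.shape}")
        if ref.shape[:2] != flr.shape[:2]:
            raise ValueError(
                f"registered images must share a grid: {ref.shape[:2]} vs {flr.shape[:2]}"
            )
        self.reflectance = ref
        self.fluorescence = flr
        if self.valid_mask is None:
            self.valid_mask = np.ones(ref.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != ref.shape[:2]:
                raise ValueError("valid_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[:2]

    def stacked(self) -> np.ndarray:
        """Five-channel view: R_ref, G_ref, B_ref, R_flr, G_flr."""
        return np.concatenate([self.reflectance, self.fluorescence], axis=2)


@dataclass(frozen=True)
class PointAnnotation:
    """One expert label at one pixel of one registered pair (0-based row/col)."""

    pair_id: str
    row: int
    col: int
    label: str


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image and normalize intensities to [0, 1] floats."""
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


ANNOTATION_COLUMNS = ("image", "row", "col", "label")


def read_annotations(
    path: str | Path,
    labelset: LabelSet | None = None,
    bounds: dict[str, tuple[int, int]] | None = None,
) -> list[PointAnnotation]:
    """Read point annotations from a CoralNet-style export CSV.

    The CSV must have columns ``image,row,col,label``.  Rows labelled
    ``macroalgae`` are dropped (and counted in the log) per the exclusion rule;
    any other label outside the set is a hard error.  If ``bounds`` maps a
    pair id to (height, width), out-of-bounds points are hard errors.
    """
    labelset = labelset or LabelSet()
    df = pd.read_csv(path, dtype={"image": str, "label": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")

    annotations: list[PointAnnotation] = []
    n_excluded = 0
    for idx, rec in enumerate(df.itertuples(index=False)):
        label = rec.label
        if label == EXCLUDED_LABEL:
            n_excluded += 1
            continue
        if label not in labelset:
            raise ValueError(f"row {idx}: unknown label {label!r}")
        row, col = int(rec.row), int(rec.col)
        if row < 0 or col < 0:
            raise ValueError(f"row {idx}: negative coordinates ({row}, {col})")
        if bounds is not None and rec.image in bounds:
            h, w = bounds[rec.image]
            if row >= h or col >= w:
                raise ValueError(
                    f"row {idx}: point ({row}, {col}) outside {rec.image} ({h}x{w})"
                )
        annotations.append(PointAnnotation(rec.image, row, col, label))
    if n_excluded:
        logger.info("dropped %d %s annotation(s)", n_excluded, EXCLUDED_LABEL)
    return annotations


def write_annotations(path: str | Path, annotations: Sequence[PointAnnotation]) -> None:
    df = pd.DataFrame(
        [(a.pair_id, a.row, a.col, a.label) for a in annotations],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, index=False)


def merge_coral_other(
    labels: Iterable[str], labelset: LabelSet | None = None
) -> list[str]:
    """Collapse the 10-category labels to the binary coral-vs-other task.

    The five dominant genera plus ``other-hard-coral`` become ``coral``;
    everything else (including the hydrozoan ``Millepora`` and ``unknown``)
    becomes ``other``.
    """
    labelset = labelset or LabelSet()
    return [CORAL if labelset.is_coral(lab) else OTHER for lab in labels]
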