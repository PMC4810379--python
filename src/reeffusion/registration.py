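"""Landmark-based affine registration of fluorescence onto reflectance frames.

The two cameras were swapped on a fixed framer, so residual misregistration is
well modelled by a global affine warp.  A handful of corresponding points
(hand-clicked in the field data, exact in synthetic data) determine the warp by
linear least squares; the fluorescence image is then resampled onto the
reflectance grid, where the expert annotations live.

Coordinates are (row, col) throughout, 0-based, pixel centers on integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .datamodel import RegisteredPair


class DegenerateGeometryError(ValueError):
    """Fewer than 3 correspondences, or all correspondences collinear."""


@dataclass(frozen=True)
class CorrespondenceSet:
    """Matched landmark points: src in the fluorescence frame, dst in the
    reflectance frame."""

    pair_id: str
    src_points: np.ndarray  # (n, 2) rows of (row, col)
    dst_points: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.src_points, dtype=np.float64))
        dst = np.atleast_2d(np.asarray(self.dst_points, dtype=np.float64))
        if src.shape != dst.shape or src.shape[1] != 2:
            raise ValueError("src/dst must both be (n, 2) arrays")
        object.__setattr__(self, "src_points", src)
        object.__setattr__(self, "dst_points", dst)

    def __len__(self) -> int:
        return len(self.src_points)


@dataclass(frozen=True)
class AffineTransform:
    """x_dst = matrix @ x_src + offset, acting on (row, col) vectors."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        t = np.asarray(self.offset, dtype=np.float64).reshape(2)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateGeometryError("transform is singular")
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.offset + self.offset
        )

    @property
    def params(self) -> np.ndarray:
        """The 6 free parameters (matrix row-major, then offset)."""
        return np.concatenate([self.matrix.ravel(), self.offset])


def fit_affine(c: CorrespondenceSet) -> tuple[AffineTransform, float]:
    """Least-squares affine fit to correspondences; returns (transform, RMSE).

    Minimizes sum ||dst - (A src + t)||^2 over the 6 affine parameters.
    Requires at least 3 non-collinear correspondences.
    """
    n = len(c)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 correspondences, got {n}")
    src = c.src_points
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise DegenerateGeometryError("correspondence points are collinear")

    # design: [src_r, src_c, 1] -> solve for rows of [A | t]
    design = np.column_stack([src, np.ones(n)])
    coeffs, *_ = np.linalg.lstsq(design, c.dst_points, rcond=None)
    matrix = coeffs[:2, :].T
    offset = coeffs[2, :]
    transform = AffineTransform(matrix, offset)
    residuals = c.dst_points - transform.apply(src)
    rmse = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return transform, rmse


def warp_image(
    image: np.ndarray, transform: AffineTransform, output_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` under ``transform`` (src frame -> dst frame).

    Output pixel x is bilinearly sampled at transform^{-1}(x); samples falling
    outside the source support are zero-filled and marked False in the
    returned validity mask.
    """
    inv = transform.inverse()
    h, w = output_shape

    def _warp(channel: np.ndarray, cval: float) -> np.ndarray:
        return ndimage.affine_transform(
            channel,
            inv.matrix,
            offset=inv.offset,
            output_shape=(h, w),
            order=1,
            mode="constant",
            cval=cval,
        )

    if image.ndim == 2:
        warped = _warp(image, 0.0)
    else:
        warped = np.dstack([_warp(image[..., k], 0.0) for k in range(image.shape[2])])

    support = np.ones(image.shape[:2], dtype=np.float64)
    mask = _warp(support, 0.0) > 1.0 - 1e-9
    return warped, mask


def warp_to_reflectance(
    pair_id: str,
    reflectance: np.ndarray,
    fluorescence: np.ndarray,
    transform: AffineTransform,
) -> RegisteredPair:
    """Bring an unregistered fluorescence image into the reflectance frame.

    ``transform`` maps fluorescence coordinates to reflectance coordinates.
    """
    warped, mask = warp_image(fluorescence, transform, reflectance.shape[:2])
    return RegisteredPair(pair_id, reflectance, warped, valid_mask=mask)


CORRESPONDENCE_COLUMNS = ("pair_id", "src_row", "src_col", "dst_row", "dst_col")


def read_correspondences(path: str | Path) -> dict[str, CorrespondenceSet]:
    """Read landmark correspondences, one CSV row per clicked point pair."""
    df = pd.read_csv(path, dtype={"pair_id": str})
    missing = set(CORRESPONDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"correspondence CSV missing columns: {sorted(missing)}")
    out: dict[str, CorrespondenceSet] = {}
    for pair_id, grp in df.groupby("pair_id", sort=False):
        out[str(pair_id)] = CorrespondenceSet(
            str(pair_id),
            grp[["src_row", "src_col"]].to_numpy(dtype=np.float64),
            grp[["dst_row", "dst_col"]].to_numpy(dtype=np.float64),
        )
    return out


def write_correspondences(
    path: str | Path, sets: Sequence[CorrespondenceSet]
) -> None:
    rows = []
    for c in sets:
        for (sr, sc), (dr, dc) in zip(c.src_points, c.dst_points):
            rows.append((c.pair_id, sr, sc, dr, dc))
    pd.DataFrame(rows, columns=list(CORRESPONDENCE_COLUMNS)).to_csv(path, index=False)
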