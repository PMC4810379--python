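"""Patch extraction and augmentation around annotated points.

Each annotated point yields a 128 x 128 pixel patch centered on the point,
downsized to 32 x 32 by bilinear interpolation.  Training patches are expanded
to their 8-element dihedral orbit (rotations by 0/90/180/270 degrees, each
optionally mirrored) to prevent over-fitting; evaluation patches are never
augmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.transform import resize

from .datamodel import PointAnnotation, RegisteredPair

CROP_SIZE = 128
PATCH_SIZE = 32

Modality = Literal["ref", "flr", "five"]

#: Channel counts per modality; the five-channel stack order is
#: R_ref, G_ref, B_ref, R_flr, G_flr.
MODALITY_CHANNELS: dict[str, int] = {"ref": 3, "flr": 2, "five": 5}

#: Channel indices of each modality within the 5-channel stack.
MODALITY_SLICES: dict[str, slice] = {
    "ref": slice(0, 3),
    "flr": slice(3, 5),
    "five": slice(0, 5),
}

#: Dihedral-group element tags: rN = CCW rotation by N degrees, mN = mirror
#: about the vertical axis then rotate by N degrees.
D4_TAGS: tuple[str, ...] = ("r0", "r90", "r180", "r270", "m0", "m90", "m180", "m270")


class PointOnInvalidPixelError(ValueError):
    """Annotation sits on a pixel the fluorescence warp never covered."""


@dataclass
class PatchTensor:
    """A 32 x 32 x C patch with its provenance."""

    pixels: np.ndarray
    label: str
    source: tuple[str, int, int]
    augmentation_tag: str = "r0"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}xC, got {px.shape}")
        if px.shape[2] not in (2, 3, 5):
            raise ValueError(f"unsupported channel count {px.shape[2]}")
        self.pixels = px


def crop_patch(
    pair: RegisteredPair,
    point: PointAnnotation,
    modality: Modality = "five",
    size: int = CROP_SIZE,
) -> np.ndarray:
    """Crop a ``size`` x ``size`` patch centered on the annotated pixel.

    Borders are handled by reflection padding (mirror about the edge pixel).
    Raises :class:`PointOnInvalidPixelError` if the point lies on a pixel not
    covered by the registered fluorescence image.
    """
    h, w = pair.shape
    r, c = point.row, point.col
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"point ({r}, {c}) outside image {h}x{w}")
    if not pair.valid_mask[r, c]:
        raise PointOnInvalidPixelError(
            f"{point.pair_id}: point ({r}, {c}) on unregistered pixel"
        )
    image = pair.stacked()[:, :, MODALITY_SLICES[modality]]

    half = size // 2
    r0, c0 = r - half, c - half
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + size - h)
    pad_right = max(0, c0 + size - w)
    if pad_top or pad_left or pad_bottom or pad_right:
        image = np.pad(
            image,
            ((pad_top, pad_bottom), (pad_left, pad_right), (0, 0)),
            mode="reflect",
        )
        r0 += pad_top
        c0 += pad_left
    return image[r0 : r0 + size, c0 : c0 + size, :]


def resize_patch(patch: np.ndarray, out_size: int = PATCH_SIZE) -> np.ndarray:
    """Bilinearly downsample a 128 x 128 x C crop to 32 x 32 x C."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3 or patch.shape[:2] != (CROP_SIZE, CROP_SIZE):
        raise ValueError(f"expected {CROP_SIZE}x{CROP_SIZE}xC input, got {patch.shape}")
    return resize(
        patch,
        (out_size, out_size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def dihedral(patch: np.ndarray, tag: str) -> np.ndarray:
    """Apply one dihedral-group element (see :data:`D4_TAGS`) to a patch."""
    if tag not in D4_TAGS:
        raise ValueError(f"unknown dihedral tag {tag!r}")
    out = patch
    if tag.startswith("m"):
        out = out[:, ::-1, ...]  # mirror about the vertical axis
    k = int(tag[1:]) // 90
    return np.ascontiguousarray(np.rot90(out, k, axes=(0, 1)))


def augment(patch: PatchTensor) -> list[PatchTensor]:
    """The 8 dihedral-orbit members of a square patch, pixel-exact, tagged."""
    px = patch.pixels
    if px.shape[0] != px.shape[1]:
        raise ValueError("augmentation requires a square patch")
    return [
        PatchTensor(dihedral(px, tag), patch.label, patch.source, augmentation_tag=tag)
        for tag in D4_TAGS
    ]


def extract_patch(
    pair: RegisteredPair, point: PointAnnotation, modality: Modality = "five"
) -> PatchTensor:
    """Crop + resize one annotation into an evaluation-ready patch."""
    crop = crop_patch(pair, point, modality)
    return PatchTensor(resize_patch(crop), point.label, (point.pair_id, point.row, point.col))


def extract_dataset(
    pairs: dict[str, RegisteredPair],
    annotations: Sequence[PointAnnotation],
    modality: Modality = "five",
    augment_patches: bool = False,
    skip_invalid: bool = True,
) -> list[PatchTensor]:
    """Build a patch dataset from registered pairs and annotations.

    With ``augment_patches`` each of the N annotations yields its 8-element
    dihedral orbit (8N patches); otherwise one patch per annotation.  Points on
    warp-invalid pixels are skipped with a warning when ``skip_invalid``.
    """
    import logging

    out: list[PatchTensor] = []
    n_skipped = 0
    for point in annotations:
        pair = pairs[point.pair_id]
        try:
            patch = extract_patch(pair, point, modality)
        except PointOnInvalidPixelError:
            if not skip_invalid:
                raise
            n_skipped += 1
            continue
        if augment_patches:
            out.extend(augment(patch))
        else:
            out.append(patch)
    if n_skipped:
        logging.getLogger(__name__).warning(
            "skipped %d point(s) on unregistered pixels", n_skipped
        )
    return out


def slice_modality(patch: PatchTensor, modality: Modality) -> PatchTensor:
    """Channel-slice a five-channel patch down to one modality."""
    if patch.pixels.shape[2] != 5:
        raise ValueError("slice_modality requires a five-channel patch")
    return PatchTensor(
        patch.pixels[:, :, MODALITY_SLICES[modality]],
        patch.label,
        patch.source,
        patch.augmentation_tag,
    )


def stack_pixels(patches: Sequence[PatchTensor]) -> np.ndarray:
    """Stack patch pixels into an (N, C, H, W) float32 tensor."""
    return np.stack([p.pixels.transpose(2, 0, 1) for p in patches]).astype(np.float32)


def save_patch_dataset(directory, patches: Sequence[PatchTensor]) -> None:
    """Serialize patches as an array file plus an index CSV.

    ``patches.npz`` holds one (N, 32, 32, C) array; ``index.csv`` records the
    source point, label and augmentation tag of each row.
    """
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "patches.npz",
        pixels=np.stack([p.pixels for p in patches]).astype(np.float32),
    )
    pd.DataFrame(
        [(p.source[0], p.source[1], p.source[2], p.label, p.augmentation_tag)
         for p in patches],
        columns=["image", "row", "col", "label", "augmentation"],
    ).to_csv(directory / "index.csv", index=False)


def load_patch_dataset(directory) -> list[PatchTensor]:
    """Inverse of :func:`save_patch_dataset`."""
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    with np.load(directory / "patches.npz") as data:
        pixels = data["pixels"].astype(np.float64)
    index = pd.read_csv(directory / "index.csv", dtype={"image": str})
    if len(index) != len(pixels):
        raise ValueError("index.csv and patches.npz disagree on length")
    return [
        PatchTensor(
            px, rec.label, (rec.image, int(rec.row), int(rec.col)), rec.augmentation
        )
        for px, rec in zip(pixels, index.itertuples(index=False))
    ]
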