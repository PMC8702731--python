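"""Volume I/O and the preprocessing chain.

Reading/writing goes through SimpleITK (NIfTI ``.nii/.nii.gz`` and MetaImage
``.mha/.mhd``). SimpleITK's array view is (Z, Y, X), which maps directly onto
the package-wide (Z, H, W) convention; header spacing (x, y, z) is reversed
accordingly.

The preprocessing chain mirrors the study protocol: resample to isotropic
1 mm spacing, center-crop the working volume to (32, 96, 96) around the root
entry zone, min-max normalize to (0, 1); during training, random flip and a
small random affine (each with probability 0.5) are applied before
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import ImageVolume, LabelVolume

__all__ = [
    "read_volume", "write_volume", "resample_isotropic", "center_crop",
    "normalize01", "augment", "AugmentConfig", "AugmentLog", "preprocess",
]

logger = logging.getLogger(__name__)

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in SUPPORTED_EXTENSIONS):
        raise ValueError(
            f"unsupported volume extension on '{path.name}'; expected one of "
            f"{SUPPORTED_EXTENSIONS}"
        )


def read_volume(path: str | Path, as_labels: bool = False) -> ImageVolume | LabelVolume:
    """Read a 3D volume; ``as_labels`` validates and returns a LabelVolume.

    Label reads reject non-integer values and classes outside {0..3}.
    """
    path = Path(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (Z, Y, X)
    if arr.ndim != 3:
        raise ValueError(f"'{path.name}' is not a 3D volume (shape {arr.shape})")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if as_labels:
        return LabelVolume(arr, spacing_mm=spacing, origin_mm=origin)
    return ImageVolume(arr.astype(np.float32), spacing_mm=spacing, origin_mm=origin)


def write_volume(vol: ImageVolume | LabelVolume, path: str | Path) -> None:
    path = Path(path)
    _check_extension(path)
    arr = vol.values
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(reversed([float(s) for s in vol.spacing_mm])))
    img.SetOrigin(tuple(reversed([float(o) for o in vol.origin_mm])))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: ImageVolume | LabelVolume,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mode: str | None = None,
) -> ImageVolume | LabelVolume:
    """Resample to ``target_spacing``; output shape = round(shape * spacing / target).

    Images use linear interpolation, labels nearest-neighbour (so the class
    set is preserved). ``mode`` overrides the default choice.
    """
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    is_label = isinstance(vol, LabelVolume)
    if mode is None:
        mode = "nearest" if is_label else "linear"
    if mode not in ("nearest", "linear"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    spacing = np.asarray(vol.spacing_mm, dtype=np.float64)
    target = np.asarray(target_spacing, dtype=np.float64)
    out_shape = np.rint(np.asarray(vol.shape) * spacing / target).astype(int)
    out_shape = np.maximum(out_shape, 1)
    if tuple(out_shape) == vol.shape and np.allclose(spacing, target):
        return vol.with_values(vol.values.copy(), spacing_mm=tuple(target))
    zoom = out_shape / np.asarray(vol.shape, dtype=np.float64)
    order = 0 if mode == "nearest" else 1
    values = ndimage.zoom(
        vol.values.astype(np.float32 if not is_label else vol.values.dtype),
        zoom, order=order, mode="nearest", grid_mode=True,
    )
    # guard against rint edge cases in ndimage.zoom output size
    values = values[: out_shape[0], : out_shape[1], : out_shape[2]]
    return vol.with_values(values, spacing_mm=tuple(target))


def center_crop(
    vol: ImageVolume | LabelVolume,
    size: tuple[int, int, int] = (32, 96, 96),
) -> ImageVolume | LabelVolume:
    """Center-crop (lower-index-biased on odd margins); zero-pad smaller inputs."""
    size = tuple(int(s) for s in size)
    values = vol.values
    pads = []
    for ax in range(3):
        deficit = size[ax] - values.shape[ax]
        if deficit > 0:
            before = deficit // 2
            pads.append((before, deficit - before))
        else:
            pads.append((0, 0))
    if any(p != (0, 0) for p in pads):
        logger.info("center_crop: padding input %s to reach %s", vol.shape, size)
        values = np.pad(values, pads)
    starts = [(values.shape[ax] - size[ax]) // 2 for ax in range(3)]
    out = values[
        starts[0]:starts[0] + size[0],
        starts[1]:starts[1] + size[1],
        starts[2]:starts[2] + size[2],
    ].copy()
    return vol.with_values(out)


def normalize01(vol: ImageVolume) -> ImageVolume:
    """Per-volume min-max normalization to (0, 1); constant volumes map to 0."""
    v = vol.values.astype(np.float32)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return vol.with_values(np.zeros_like(v))
    return vol.with_values((v - vmin) / (vmax - vmin))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Bounds for the random spatial augmentation.

    Flip and affine are each applied with probability 0.5. The affine is a
    small in-plane rotation, isotropic scale and per-axis translation.
    """

    flip_prob: float = 0.5
    affine_prob: float = 0.5
    max_rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_translation_vox: float = 5.0


@dataclass
class AugmentLog:
    flipped: bool = False
    flip_axis: int | None = None
    affined: bool = False
    rotation_deg: float = 0.0
    scale: float = 1.0
    translation_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)


def augment(
    img: ImageVolume,
    lab: LabelVolume,
    seed: int,
    cfg: AugmentConfig | None = None,
    return_log: bool = False,
):
    """Apply one random flip/affine draw identically to an image/label pair.

    The image is interpolated linearly, the label with nearest-neighbour, so
    no new classes are introduced. Fully deterministic given ``seed``.
    """
    if cfg is None:
        cfg = AugmentConfig()
    if img.shape != lab.shape:
        raise ValueError(f"image/label grids differ: {img.shape} vs {lab.shape}")
    rng = np.random.default_rng(seed)
    ivals = img.values
    lvals = lab.values
    log = AugmentLog()

    if rng.random() < cfg.flip_prob:
        axis = int(rng.integers(0, 3))
        ivals = np.flip(ivals, axis=axis).copy()
        lvals = np.flip(lvals, axis=axis).copy()
        log.flipped, log.flip_axis = True, axis

    if rng.random() < cfg.affine_prob:
        angle = float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
        scale = float(rng.uniform(*cfg.scale_range))
        shift = rng.uniform(-cfg.max_translation_vox, cfg.max_translation_vox, size=3)
        theta = np.deg2rad(angle)
        # in-plane (H, W) rotation; Z untouched by the rotation
        rot = np.array([
            [1.0, 0.0, 0.0],
            [0.0, np.cos(theta), -np.sin(theta)],
            [0.0, np.sin(theta), np.cos(theta)],
        ])
        mat = rot / scale
        center = (np.asarray(ivals.shape) - 1) / 2.0
        offset = center - mat @ (center + shift)
        ivals = ndimage.affine_transform(
            ivals.astype(np.float32), mat, offset=offset, order=1, mode="constant",
            cval=float(ivals.min()),
        )
        lvals = ndimage.affine_transform(
            lvals, mat, offset=offset, order=0, mode="constant", cval=0,
        )
        log.affined = True
        log.rotation_deg, log.scale = angle, scale
        log.translation_vox = tuple(float(s) for s in shift)

    out_img = img.with_values(ivals)
    out_lab = lab.with_values(lvals)
    if return_log:
        return out_img, out_lab, log
    return out_img, out_lab


def preprocess(
    img: ImageVolume,
    lab: LabelVolume | None = None,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    crop_size: tuple[int, int, int] = (32, 96, 96),
    normalize: bool = True,
):
    """Resample -> center-crop (-> normalize) an image and optional label."""
    img = resample_isotropic(img, target_spacing)
    img = center_crop(img, crop_size)
    if normalize:
        img = normalize01(img)
    if lab is None:
        return img
    lab = resample_isotropic(lab, target_spacing)
    lab = center_crop(lab, crop_size)
    return img, lab
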