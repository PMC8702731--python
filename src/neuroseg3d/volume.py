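"""In-memory containers for 3D medical volumes.

All arrays use (Z, H, W) axis order -- slices first -- and physical
coordinates place voxel centers at ``(index + 0.5) * spacing + origin``.
Spacing and origin follow the same (Z, H, W) ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Segmentation classes, in label order.
CLASS_NAMES = ("background", "brainstem", "cerebrovasculature", "trigeminal_nerve")
#: Short per-class codes used in reports (Table-style layout).
CLASS_CODES = ("BG", "BS", "CV", "TN")
NUM_CLASSES = 4

Triple = tuple[float, float, float]


@dataclass
class ImageVolume:
    """A scalar 3D intensity grid with voxel-spacing metadata.

    Parameters
    ----------
    values
        3D float array in (Z, H, W) order. Intensity units are arbitrary.
    spacing_mm
        Strictly positive voxel spacing per axis, millimetres, (Z, H, W).
    origin_mm
        Physical position of the corner of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: Triple = (1.0, 1.0, 1.0)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **meta) -> "ImageVolume":
        return replace(self, values=values, **meta)


@dataclass
class LabelVolume:
    """An integer 3D class grid over {0..3} paired with an :class:`ImageVolume`.

    Classes: 0=background, 1=brainstem, 2=cerebrovasculature, 3=trigeminal nerve.
    """

    values: np.ndarray
    spacing_mm: Triple = (1.0, 1.0, 1.0)
    origin_mm: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.round(arr)
            if not np.allclose(arr, rounded, atol=1e-6, equal_nan=False):
                raise ValueError("label volume contains non-integer values")
            arr = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(arr), np.arange(NUM_CLASSES))
        if bad.size:
            raise ValueError(
                f"label volume contains classes outside {{0..{NUM_CLASSES - 1}}}: {bad.tolist()}"
            )
        self.values = arr.astype(np.int16, copy=False)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def class_counts(self) -> dict[str, int]:
        """Voxel count per class, keyed by class name."""
        return {
            name: int(np.count_nonzero(self.values == i))
            for i, name in enumerate(CLASS_NAMES)
        }

    def with_values(self, values: np.ndarray, **meta) -> "LabelVolume":
        return replace(self, values=values, **meta)


def one_hot(labels: np.ndarray, num_classes: int = NUM_CLASSES) -> np.ndarray:
    """One-hot encode an integer label grid to (*grid, C) float32."""
    return np.eye(num_classes, dtype=np.float32)[np.asarray(labels, dtype=np.int64)]


def check_aligned(a, b) -> None:
    if a.shape != b.shape:
        raise ValueError(f"volume grids differ: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm, atol=1e-6):
        raise ValueError(f"voxel spacings differ: {a.spacing_mm} vs {b.spacing_mm}")
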