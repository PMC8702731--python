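"""Synthetic neurovascular phantoms.

The real study data (50 clinical MRA volumes of the trigeminal root entry
zone) is private, so this module generates image/label pairs that reproduce
its *structural* character on a configurable grid:

* a large, compact, mid-intensity brainstem (an ellipsoid, several percent
  of the volume),
* sparse bright tubular cerebrovasculature (polyline tubes),
* a tiny trigeminal nerve: a thin tube lying almost in-plane so that it
  appears in roughly 3 consecutive axial slices and occupies well under 1%
  of the voxels — the class imbalance that motivates the weighted loss,
* optionally a vessel diverted to pass within one voxel of the nerve
  midpoint (neurovascular-contact geometry).

Axis order is (Z, H, W); physical voxel centers sit at
``(index + 0.5) * spacing``. Intensities are arbitrary units; contrast
levels are free parameters of the spec, not claims about real MRA tissue
statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import ImageVolume, LabelVolume

__all__ = [
    "TubeSpec", "EllipsoidSpec", "PhantomSpec",
    "rasterize_tube", "rasterize_ellipsoid", "generate_phantom", "make_dataset",
]


@dataclass
class TubeSpec:
    """A tube swept along a polyline of physical-mm control points.

    ``radius_mm`` may be a scalar or one radius per control point (linear
    taper along each segment).
    """

    centerline: list[tuple[float, float, float]]
    radius_mm: float | list[float]
    intensity_mean: float = 150.0
    intensity_std: float = 5.0
    name: str = "tube"

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError(f"tube '{self.name}': centerline needs >= 2 points in 3D")
        if np.all(np.ptp(pts, axis=0) == 0):
            raise ValueError(f"tube '{self.name}': degenerate centerline (all points identical)")
        for a, b in zip(pts[:-1], pts[1:]):
            if np.allclose(a, b):
                raise ValueError(f"tube '{self.name}': consecutive control points identical")
        radii = self.radii
        if np.any(radii <= 0):
            raise ValueError(f"tube '{self.name}': radius must be positive")

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.centerline, dtype=np.float64)

    @property
    def radii(self) -> np.ndarray:
        r = np.asarray(self.radius_mm, dtype=np.float64)
        if r.ndim == 0:
            return np.full(len(self.centerline), float(r))
        if r.shape != (len(self.centerline),):
            raise ValueError(f"tube '{self.name}': need one radius per control point")
        return r


@dataclass
class EllipsoidSpec:
    """Axis-aligned ellipsoid in physical mm, used for the brainstem."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    intensity_mean: float = 110.0
    intensity_std: float = 6.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("ellipsoid semi-axes must be positive")


@dataclass
class PhantomSpec:
    """Full parametric description of one phantom volume."""

    grid_shape: tuple[int, int, int] = (32, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brainstem: EllipsoidSpec | None = None
    vessels: list[TubeSpec] = field(default_factory=list)
    nerve: TubeSpec | None = None
    background_mean: float = 60.0
    background_std: float = 5.0
    noise_sigma: float = 10.0
    contact: bool = False
    contact_distance_mm: float = 1.0
    max_nerve_slices: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        for part in self._foreground_parts():
            if part.intensity_mean <= self.background_mean:
                raise ValueError(
                    "foreground tissues must be brighter than background "
                    f"(got {part.intensity_mean} <= {self.background_mean})"
                )

    def _foreground_parts(self):
        parts = []
        if self.brainstem is not None:
            parts.append(self.brainstem)
        parts.extend(self.vessels)
        if self.nerve is not None:
            parts.append(self.nerve)
        return parts

    # -- canonical geometry -------------------------------------------------
    @classmethod
    def default(cls, grid_shape: tuple[int, int, int] = (32, 96, 96),
                seed: int = 0, contact: bool = False) -> "PhantomSpec":
        """The canonical phantom, optionally scaled to a smaller grid.

        Geometry is defined on the (32, 96, 96) working grid (the study's
        96 x 96 x 32 center crop at 1 mm spacing) and scaled proportionally
        for other grids; tube radii are floored at ~1 voxel so structures
        never vanish, and the nerve radius is kept fixed so its axial extent
        stays at ~3 slices.
        """
        sz, sh, sw = (grid_shape[0] / 32.0, grid_shape[1] / 96.0, grid_shape[2] / 96.0)

        def pt(z, h, w):
            return (z * sz, h * sh, w * sw)

        def rad(r):
            return max(1.2, r * min(sh, sw))

        zc = 16.0 * sz  # mid-stack
        brainstem = EllipsoidSpec(
            center_mm=pt(16, 48, 46),
            semi_axes_mm=(max(2.5, 14 * sz), max(4.0, 22 * sh), max(4.0, 16 * sw)),
            intensity_mean=110.0, intensity_std=6.0,
        )
        vessels = [
            TubeSpec([pt(2, 20, 48), pt(30, 24, 48)], rad(2.0),
                     intensity_mean=200.0, intensity_std=8.0, name="basilar"),
            TubeSpec([pt(16, 30, 48), pt(18, 40, 70), pt(22, 50, 88)], rad(1.6),
                     intensity_mean=200.0, intensity_std=8.0, name="sca_left"),
            TubeSpec([pt(14, 30, 46), pt(16, 40, 26), pt(20, 48, 8)], rad(1.6),
                     intensity_mean=200.0, intensity_std=8.0, name="sca_right"),
        ]
        # Nerve: in-plane tube at the mid-slice; radius 1.2 mm on a 1 mm grid
        # covers 3 consecutive axial slices.
        nerve_z = zc + 0.5
        nerve = TubeSpec(
            [(nerve_z, 40 * sh, 58 * sw), (nerve_z, 36 * sh, 72 * sw)],
            1.2, intensity_mean=140.0, intensity_std=5.0, name="trigeminal",
        )
        spec = cls(grid_shape=tuple(int(g) for g in grid_shape),
                   brainstem=brainstem, vessels=vessels, nerve=nerve,
                   seed=seed, contact=contact)
        if contact:
            spec = spec.with_contact()
        return spec

    def with_contact(self) -> "PhantomSpec":
        """Divert one vessel to pass within ``contact_distance_mm`` of the
        nerve midpoint (neurovascular-compression-like geometry)."""
        if self.nerve is None or not self.vessels:
            raise ValueError("contact geometry needs both a nerve and a vessel")
        pts = self.nerve.points
        mid = pts[len(pts) // 2] if len(pts) > 2 else pts.mean(axis=0)
        touch = (mid[0] + 0.8 * self.contact_distance_mm, mid[1], mid[2])
        vessel = self.vessels[-1]
        new_line = [tuple(p) for p in vessel.points[:-1]] + [touch, tuple(vessel.points[-1])]
        radius = vessel.radius_mm
        if not np.isscalar(radius):
            # keep one radius per control point: reuse the tail radius
            radius = [float(r) for r in vessel.radii[:-1]] + [float(vessel.radii[-1])] * 2
        name = vessel.name.removesuffix("_contact") + "_contact"
        new_vessel = dataclasses.replace(vessel, centerline=new_line,
                                         radius_mm=radius, name=name)
        vessels = self.vessels[:-1] + [new_vessel]
        return dataclasses.replace(self, vessels=vessels, contact=True)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _voxel_centers_1d(n: int, spacing: float) -> np.ndarray:
    return (np.arange(n, dtype=np.float64) + 0.5) * spacing


def rasterize_ellipsoid(ell: EllipsoidSpec, grid_shape, spacing) -> np.ndarray:
    zz = _voxel_centers_1d(grid_shape[0], spacing[0])
    hh = _voxel_centers_1d(grid_shape[1], spacing[1])
    ww = _voxel_centers_1d(grid_shape[2], spacing[2])
    cz, ch, cw = ell.center_mm
    az, ah, aw = ell.semi_axes_mm
    q = (((zz - cz) / az) ** 2)[:, None, None] \
        + (((hh - ch) / ah) ** 2)[None, :, None] \
        + (((ww - cw) / aw) ** 2)[None, None, :]
    return q <= 1.0


def rasterize_tube(tube: TubeSpec, grid_shape, spacing) -> np.ndarray:
    """Binary mask of voxels whose physical centers lie within the tube.

    A voxel is foreground iff the distance from its center to the nearest
    centerline *segment* (point-to-segment, not point-to-vertex) is at most
    the (possibly tapered) radius. Evaluation is restricted to each
    segment's bounding box expanded by its radius, which is exact: voxels
    outside every expanded box cannot be within radius of any segment.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = np.asarray(spacing, dtype=np.float64)
    if any(g <= 0 for g in grid_shape):
        raise ValueError("grid must be nonempty")
    pts = tube.points
    radii = tube.radii
    max_extent = min(g * s for g, s in zip(grid_shape, spacing))
    if radii.max() >= max_extent / 2.0:
        raise ValueError(
            f"tube '{tube.name}': radius {radii.max()} exceeds half the smallest "
            f"grid extent ({max_extent / 2.0})"
        )
    mask = np.zeros(grid_shape, dtype=bool)
    for (p1, p2), (r1, r2) in zip(zip(pts[:-1], pts[1:]), zip(radii[:-1], radii[1:])):
        rmax = max(r1, r2)
        lo = np.minimum(p1, p2) - rmax
        hi = np.maximum(p1, p2) + rmax
        # voxel index ranges whose centers may fall inside the expanded box
        i0 = np.maximum(np.floor(lo / spacing - 0.5).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil(hi / spacing - 0.5).astype(int) + 2,
                        np.asarray(grid_shape))
        if np.any(i0 >= i1):
            continue
        axes = [
            _voxel_centers_1d(grid_shape[d], spacing[d])[i0[d]:i1[d]]
            for d in range(3)
        ]
        cz, ch, cw = np.meshgrid(*axes, indexing="ij")
        c = np.stack([cz, ch, cw], axis=-1)  # (..., 3)
        d = p2 - p1
        seg_len2 = float(d @ d)
        rel = c - p1
        t = np.clip((rel @ d) / seg_len2, 0.0, 1.0)
        proj = p1 + t[..., None] * d
        dist2 = np.sum((c - proj) ** 2, axis=-1)
        r_here = r1 + t * (r2 - r1)
        sub = dist2 <= r_here ** 2
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= sub
    return mask


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Render a phantom spec into a paired image/label volume.

    Label precedence at overlaps: nerve > vessel > brainstem > background.
    The image is each class's mean plus per-tissue Gaussian texture plus
    global additive Gaussian noise; the same seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(g) for g in spec.grid_shape)
    spacing = spec.spacing_mm

    label = np.zeros(shape, dtype=np.int16)
    image = spec.background_mean + spec.background_std * rng.standard_normal(shape)

    def paint(mask, cls, mean, std):
        label[mask] = cls
        n = int(mask.sum())
        if n:
            image[mask] = mean + std * rng.standard_normal(n)

    if spec.brainstem is not None:
        bs = rasterize_ellipsoid(spec.brainstem, shape, spacing)
        paint(bs, 1, spec.brainstem.intensity_mean, spec.brainstem.intensity_std)
    for vessel in spec.vessels:
        vm = rasterize_tube(vessel, shape, spacing)
        paint(vm, 2, vessel.intensity_mean, vessel.intensity_std)
    if spec.nerve is not None:
        nm = rasterize_tube(spec.nerve, shape, spacing)
        z_extent = int(np.count_nonzero(nm.any(axis=(1, 2))))
        if z_extent > spec.max_nerve_slices:
            raise ValueError(
                f"nerve '{spec.nerve.name}' spans {z_extent} axial slices "
                f"(limit {spec.max_nerve_slices})"
            )
        paint(nm, 3, spec.nerve.intensity_mean, spec.nerve.intensity_std)

    if spec.noise_sigma > 0:
        image = image + spec.noise_sigma * rng.standard_normal(shape)

    img = ImageVolume(image.astype(np.float32), spacing_mm=spacing)
    lab = LabelVolume(label, spacing_mm=spacing)
    return img, lab


def _jitter_spec(base: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Perturb geometry/intensity so a cohort has subject-like variability."""

    def jit_tube(tube: TubeSpec, z_sigma: float) -> TubeSpec:
        pts = tube.points.copy()
        pts[:, 0] += rng.normal(0.0, z_sigma, len(pts))
        pts[:, 1:] += rng.normal(0.0, 1.5, (len(pts), 2))
        radii = tube.radii * rng.uniform(0.9, 1.1)
        return dataclasses.replace(
            tube,
            centerline=[tuple(p) for p in pts],
            radius_mm=[float(r) for r in radii],
            intensity_mean=tube.intensity_mean + rng.normal(0.0, 4.0),
        )

    brainstem = base.brainstem
    if brainstem is not None:
        brainstem = dataclasses.replace(
            brainstem,
            center_mm=tuple(np.asarray(brainstem.center_mm) + rng.normal(0.0, 1.5, 3)),
            semi_axes_mm=tuple(np.asarray(brainstem.semi_axes_mm) * rng.uniform(0.92, 1.08, 3)),
            intensity_mean=brainstem.intensity_mean + rng.normal(0.0, 4.0),
        )
    vessels = [jit_tube(v, z_sigma=1.0) for v in base.vessels]
    # the nerve keeps a near-constant axial coordinate so it still spans ~3 slices
    nerve = jit_tube(base.nerve, z_sigma=0.15) if base.nerve is not None else None
    spec = dataclasses.replace(base, brainstem=brainstem, vessels=vessels,
                               nerve=nerve, seed=seed, contact=False)
    if base.contact:
        spec = spec.with_contact()
    return spec


def make_dataset(
    n: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[ImageVolume, LabelVolume, PhantomSpec]], dict]:
    """Generate a cohort of ``n`` jittered phantoms plus a manifest.

    Returns the in-memory pairs and the manifest dict; when ``out_dir`` is
    given, also writes ``caseXXX_img.nii.gz`` / ``caseXXX_lab.nii.gz`` pairs
    and ``manifest.json``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_spec is None:
        base_spec = PhantomSpec.default()
    rng = np.random.default_rng(seed)
    cases = []
    manifest: dict = {"seed": int(seed), "n": int(n), "grid_shape": list(base_spec.grid_shape),
                      "spacing_mm": list(base_spec.spacing_mm), "cases": []}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(20):
            jrng = np.random.default_rng(case_seed + attempt)
            spec = _jitter_spec(base_spec, jrng, seed=case_seed)
            try:
                img, lab = generate_phantom(spec)
                break
            except ValueError:
                continue  # rare: jitter pushed the nerve over the slice limit
        else:  # pragma: no cover
            raise RuntimeError("could not jitter a valid phantom in 20 attempts")
        case_id = f"case{i:03d}"
        entry = {"id": case_id, "seed": case_seed, "class_counts": lab.class_counts()}
        if out_path is not None:
            from . import io as vio
            img_file, lab_file = f"{case_id}_img.nii.gz", f"{case_id}_lab.nii.gz"
            vio.write_volume(img, out_path / img_file)
            vio.write_volume(lab, out_path / lab_file)
            entry["img"] = img_file
            entry["lab"] = lab_file
        manifest["cases"].append(entry)
        cases.append((img, lab, spec))
    if out_path is not None:
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cases, manifest
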