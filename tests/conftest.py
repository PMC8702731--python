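"""Shared fixtures: phantoms, oracles, and one session-scoped overfit run."""

from __future__ import annotations

import numpy as np
import pytest

import neuroseg3d as ns

#: Reduced grid used for CPU training runs (in-plane halved, same slice count
#: character); chosen once for runtime, documented in docs/methods.md.
TRAIN_GRID = (16, 48, 48)


@pytest.fixture(scope="session")
def default_phantom():
    """One canonical full-size phantom pair (32, 96, 96)."""
    return ns.generate_phantom(ns.PhantomSpec.default(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """One reduced-grid phantom pair for fast tests."""
    return ns.generate_phantom(ns.PhantomSpec.default(grid_shape=TRAIN_GRID, seed=5))


@pytest.fixture(scope="session")
def overfit_run():
    """Width-8 full cascade overfitted on 2 reduced-grid phantoms.

    Shared by the learning-capacity checks; training stops as soon as the
    training brainstem DSC reaches 0.8 (capped at 300 iterations).
    """
    spec = ns.PhantomSpec.default(grid_shape=TRAIN_GRID)
    raw, _ = ns.make_dataset(2, base_spec=spec, seed=11)
    cases = [(img, lab) for img, lab, _ in raw]
    cfg = ns.TrainConfig(max_iterations=300, batch_size=1, eval_every=10,
                         augment=False, seed=3, target_train_dsc=0.8,
                         target_class=1)
    net_cfg = ns.NetConfig(base_width=8, depth=2, refiner_width=8, refiner_depth=2)
    result = ns.train(cases, None, cfg=cfg, net_cfg=net_cfg)
    return result, cases


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the fast-path code they check)
# ---------------------------------------------------------------------------

def brute_force_tube_mask(tube, grid_shape, spacing):
    """Exhaustive per-voxel point-to-segment rasterization."""
    pts = np.asarray(tube.centerline, dtype=np.float64)
    radii = np.asarray(tube.radius_mm, dtype=np.float64)
    if radii.ndim == 0:
        radii = np.full(len(pts), float(radii))
    mask = np.zeros(grid_shape, dtype=bool)
    for idx in np.ndindex(*grid_shape):
        c = (np.asarray(idx, dtype=np.float64) + 0.5) * np.asarray(spacing)
        inside = False
        for (p1, p2), (r1, r2) in zip(zip(pts[:-1], pts[1:]),
                                      zip(radii[:-1], radii[1:])):
            d = p2 - p1
            t = np.clip(((c - p1) @ d) / float(d @ d), 0.0, 1.0)
            dist2 = float(np.sum((c - (p1 + t * d)) ** 2))
            if dist2 <= (r1 + t * (r2 - r1)) ** 2:
                inside = True
                break
        mask[idx] = inside
    return mask


def brute_force_surface(mask):
    """Foreground voxels with >= 1 background 6-neighbour (border = background)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        z, h, w = idx
        for dz, dh, dw in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, nh, nw = z + dz, h + dh, w + dw
            if not (0 <= nz < mask.shape[0] and 0 <= nh < mask.shape[1]
                    and 0 <= nw < mask.shape[2]):
                out[z, h, w] = True
                break
            if not mask[nz, nh, nw]:
                out[z, h, w] = True
                break
    return out


def brute_force_hd_asd(pred, gt, spacing=(1.0, 1.0, 1.0)):
    """Exhaustive pairwise surface distances -> (HD, ASD)."""
    sp = np.argwhere(brute_force_surface(pred)) * np.asarray(spacing)
    sg = np.argwhere(brute_force_surface(gt)) * np.asarray(spacing)
    d2 = ((sp[:, None, :] - sg[None, :, :]) ** 2).sum(-1)
    d = np.sqrt(d2)
    d_pg = d.min(axis=1)
    d_gp = d.min(axis=0)
    hd = max(d_pg.max(), d_gp.max())
    asd = 0.5 * (d_pg.mean() + d_gp.mean())
    return float(hd), float(asd)
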