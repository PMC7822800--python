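"""Synthetic head phantom generation.

The generated anatomy is a set of nested ellipsoids: air background, a
soft-tissue scalp, a cranial bone shell, and a brain interior, with a few
seeded adipose pockets embedded in the scalp.  Shell thicknesses scale with
the phantom size so that the same recipe works from 32 voxels in-plane up.
After rasterization the bone shell is explicitly closed along every grid
axis: with coarse axial spacing the thin cranial cap can fall between slice
centres, so any brain-containing voxel column is capped with bone where the
continuous shell failed to rasterize.  This keeps the vault watertight,
which matters for attenuation realism and is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np

from .materials import DEFAULT_LABELS
from .volume import LabelVolume

__all__ = ["make_head_phantom", "AIR", "SOFT", "ADIPOSE", "BONE", "BRAIN"]

AIR = DEFAULT_LABELS["air"]
SOFT = DEFAULT_LABELS["soft_tissue"]
ADIPOSE = DEFAULT_LABELS["adipose"]
BONE = DEFAULT_LABELS["bone"]
BRAIN = DEFAULT_LABELS["brain"]

# fractions of the outer (scalp) semi-axes: scalp ~0.07 a, cranial bone
# ~0.085 a thick (5-7 mm on an adult-sized head)
_BONE_OUTER_FRAC = 0.93
_BRAIN_FRAC = 0.795


def make_head_phantom(
    n_xy: int,
    n_z: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0),
    seed: int = 0,
    n_adipose: int = 3,
) -> LabelVolume:
    """Generate a head-like label volume of ``n_xy x n_xy x n_z`` voxels.

    Deterministic for a fixed seed; the seed only jitters the adipose
    pockets.  The volume is centred on the world origin.
    """
    if n_xy < 32:
        raise ValueError(f"n_xy must be >= 32 to fit all tissue shells, got {n_xy}")
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    sx, sy, sz = (float(s) for s in spacing)

    origin = (-n_xy * sx / 2.0, -n_xy * sy / 2.0, -n_z * sz / 2.0)
    vol = LabelVolume(np.zeros((n_z, n_xy, n_xy), dtype=np.int16),
                      (sx, sy, sz), origin)
    X, Y, Z = vol.voxel_centers()

    a = 0.46 * n_xy * sx  # scalp semi-axes, mm
    b = 0.38 * n_xy * sy
    c = 0.5 * n_z * sz
    if _BRAIN_FRAC * min(a / sx, b / sy) < 2.0:
        raise ValueError("grid too small to fit scalp, bone shell and brain")

    def inside(fr_xy: float, fr_z: float = None) -> np.ndarray:
        fz = fr_xy if fr_z is None else fr_z
        return (X / (fr_xy * a)) ** 2 + (Y / (fr_xy * b)) ** 2 + (Z / (fz * c)) ** 2 < 1.0

    labels = vol.labels
    labels[inside(1.0)] = SOFT
    labels[inside(_BONE_OUTER_FRAC)] = BONE
    labels[inside(_BRAIN_FRAC)] = BRAIN

    # adipose pockets carved out of the scalp, jittered but reproducible;
    # restricting the blob to soft tissue keeps the bone shell intact
    rng = np.random.default_rng(seed)
    soft = labels == SOFT
    for _ in range(n_adipose):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.92, 0.96)
        cx, cy = rad * a * np.cos(ang), rad * b * np.sin(ang)
        cz = rng.uniform(-0.4, 0.4) * c
        r_mm = rng.uniform(1.5, 3.0) * max(sx, sy)
        blob = ((X - cx) ** 2 + (Y - cy) ** 2 + ((Z - cz) * sx / sz) ** 2
                < r_mm ** 2)
        labels[blob & soft] = ADIPOSE

    _close_bone_shell(labels)
    return vol


def _close_bone_shell(labels: np.ndarray) -> None:
    """Cap every brain run with bone along all six grid directions."""
    for axis in range(3):
        moved = np.moveaxis(labels, axis, 0)
        n = moved.shape[0]
        brain = moved == BRAIN
        any_brain = brain.any(axis=0)
        if not any_brain.any():
            continue
        idx = np.arange(n).reshape(-1, 1, 1)
        first = np.where(any_brain, np.where(brain, idx, n).min(axis=0), -1)
        last = np.where(any_brain, np.where(brain, idx, -1).max(axis=0), n)
        for caps, valid in ((first - 1, first > 0), (last + 1, last < n - 1)):
            cap_idx = np.clip(caps, 0, n - 1)
            sel = valid & any_brain
            jj, kk = np.nonzero(sel)
            moved[cap_idx[jj, kk], jj, kk] = np.where(
                moved[cap_idx[jj, kk], jj, kk] == BRAIN, BRAIN, BONE
            )
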