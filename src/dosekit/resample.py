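"""Down-sampling and guided-filter super-resolution of dose volumes.

All 2-D operations act slice-wise on axial planes: the phantom's axial
spacing is coarse to begin with, so only the in-plane resolution is traded
against simulation speed.  Two down-sampling operators are provided:

* fraction-of-mass (FoM): the mass-weighted mean of each ``s x s`` in-plane
  window, which conserves the mass-weighted total of the field exactly;
* statistical mode: each window is replaced by its most frequent tissue
  label, so the dominant tissue stays exactly represented.

Reconstruction works in the fluence domain.  Under charged-particle
equilibrium, dose D = psi * (muen/rho) with psi the photon energy fluence.
Dividing the coarse dose by the coarse absorption map gives a smooth coarse
fluence; after nearest-neighbour up-sampling, an edge-aware guided filter
(guidance: the high-resolution absorption map) both denoises and sharpens
it, and multiplying back by the high-resolution absorption map restores the
dose with tissue detail reinstated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import BeamSetup
from .materials import MaterialLibrary, absorption_map, labels_to_density
from .transport import DoseResult, simulate
from .volume import LabelVolume, ScalarVolume

__all__ = [
    "DownsampleSpec",
    "downsample_fom",
    "downsample_mode",
    "radius_from_scale",
    "guided_filter_2d",
    "upsample_dose",
    "reconstruct_from_simulation",
]


def radius_from_scale(s: int) -> int:
    """Guided-filter radius r(s): nearest integer of s/2 (half rounds up), plus 1."""
    if s < 1:
        raise ValueError("window size s must be >= 1")
    return int(np.floor(0.5 * s + 0.5)) + 1


@dataclass
class DownsampleSpec:
    """Parameters of one down-sample/up-sample pass.

    ``eps`` is the guided-filter ridge regularizer on the raw guidance scale;
    ``None`` selects ``(0.01 * range(guidance))**2`` at filter time.
    """

    s: int
    method: str = "mode"
    radius: int | None = None
    eps: float | None = None

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.method not in ("mode", "fom"):
            raise ValueError(f"method must be 'mode' or 'fom', got {self.method!r}")
        if self.radius is None:
            self.radius = radius_from_scale(self.s)
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be positive")


def _window_edges(n: int, s: int) -> np.ndarray:
    """Window start indices; a trailing partial window keeps its actual size."""
    return np.arange(0, n, s)


def _coarse_grid(vol, s: int):
    sx, sy, sz = vol.spacing
    return (sx * s, sy * s, sz), vol.origin


def downsample_fom(values: ScalarVolume, density: ScalarVolume, s: int) -> ScalarVolume:
    """Fraction-of-mass down-sampling: per in-plane window the mass-weighted
    mean ``sum(m_x f_x) / sum(m_x)`` with ``m_x = V * rho_x``; the axial
    dimension is untouched."""
    if not values.same_grid(density):
        raise ValueError("values and density must share one grid")
    if s == 1:
        return values.with_values(values.values.copy())
    v = values.values
    rho = density.values
    ey = _window_edges(v.shape[1], s)
    ex = _window_edges(v.shape[2], s)
    mass = rho  # voxel volume V is constant on the grid and cancels
    num = np.add.reduceat(np.add.reduceat(v * mass, ey, axis=1), ex, axis=2)
    den = np.add.reduceat(np.add.reduceat(mass, ey, axis=1), ex, axis=2)
    cnt = np.add.reduceat(np.add.reduceat(np.ones_like(v), ey, axis=1), ex, axis=2)
    out = np.empty_like(num)
    zero = den <= 0
    if np.any(zero):
        warnings.warn("all-zero-mass window(s); falling back to unweighted mean",
                      stacklevel=2)
        plain = np.add.reduceat(np.add.reduceat(v, ey, axis=1), ex, axis=2) / cnt
        out[zero] = plain[zero]
    np.divide(num, den, out=out, where=~zero)
    spacing, origin = _coarse_grid(values, s)
    return ScalarVolume(out, spacing, origin)


def downsample_mode(labels: LabelVolume, s: int,
                    lib: MaterialLibrary | None = None) -> LabelVolume:
    """Statistical-mode down-sampling of a label volume (in-plane windows).

    Ties break deterministically: highest mass density first (when a library
    is supplied), then lowest label id.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if s == 1:
        return labels.with_labels(labels.labels.copy())
    arr = labels.labels
    nz, ny, nx = arr.shape
    ey = _window_edges(ny, s)
    ex = _window_edges(nx, s)
    present = labels.present_labels()
    n_lab = int(present.max()) + 1
    density = np.zeros(n_lab)
    if lib is not None:
        for lab in present:
            density[lab] = lib[int(lab)].density

    # per-window label histogram via one-hot reduceat
    counts = np.zeros((n_lab, nz, ey.size, ex.size), dtype=np.int64)
    for lab in present:
        onehot = (arr == lab).astype(np.int64)
        counts[lab] = np.add.reduceat(np.add.reduceat(onehot, ey, axis=1), ex, axis=2)
    # lexicographic argmax over (count, density, -label): counts dominate,
    # then higher density, then lower label id
    key = (counts[present].astype(np.float64) * 1e6
           + density[present][:, None, None, None] * 1e2
           + (n_lab - present)[:, None, None, None].astype(np.float64))
    best = present[np.argmax(key, axis=0)]
    spacing, origin = _coarse_grid(labels, s)
    return LabelVolume(best.astype(arr.dtype), spacing, origin)


def _box_sum(img: np.ndarray, r: int) -> np.ndarray:
    """Sum over (2r+1)^2 windows clipped at the image border (valid area)."""
    n, m = img.shape
    c = np.zeros((n + 1, m + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=c[1:, 1:])
    i = np.arange(n)
    j = np.arange(m)
    lo_i = np.clip(i - r, 0, n)
    hi_i = np.clip(i + r + 1, 0, n)
    lo_j = np.clip(j - r, 0, m)
    hi_j = np.clip(j + r + 1, 0, m)
    return (c[np.ix_(hi_i, hi_j)] - c[np.ix_(lo_i, hi_j)]
            - c[np.ix_(hi_i, lo_j)] + c[np.ix_(lo_i, lo_j)])


def _box_mean(img: np.ndarray, r: int, cnt: np.ndarray) -> np.ndarray:
    return _box_sum(img, r) / cnt


def guided_filter_2d(guide: np.ndarray, src: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Edge-preserving guided filter (local linear model a*guide + b).

    Box windows of radius ``r`` use shrunken (valid-area) normalization at
    the image border.  ``eps`` is the ridge regularizer on the local
    variance of the guide.
    """
    guide = np.asarray(guide, float)
    src = np.asarray(src, float)
    if guide.shape != src.shape or guide.ndim != 2:
        raise ValueError("guide and src must be equal-shape 2-D images")
    if not (np.all(np.isfinite(guide)) and np.all(np.isfinite(src))):
        raise ValueError("guided filter inputs must be finite")
    if r < 1:
        raise ValueError("radius must be >= 1")
    cnt = _box_sum(np.ones_like(guide), r)
    mean_i = _box_mean(guide, r, cnt)
    mean_p = _box_mean(src, r, cnt)
    corr_ip = _box_mean(guide * src, r, cnt)
    corr_ii = _box_mean(guide * guide, r, cnt)
    var_i = corr_ii - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + eps)
    b = mean_p - a * mean_i
    mean_a = _box_mean(a, r, cnt)
    mean_b = _box_mean(b, r, cnt)
    return mean_a * guide + mean_b


def _nn_upsample_slice(coarse: np.ndarray, hr_shape: tuple[int, int], s: int) -> np.ndarray:
    """Replicate each coarse pixel over its originating window partition."""
    ny, nx = hr_shape
    wy = np.diff(np.append(_window_edges(ny, s), ny))
    wx = np.diff(np.append(_window_edges(nx, s), nx))
    return np.repeat(np.repeat(coarse, wy, axis=0), wx, axis=1)


def upsample_dose(
    coarse_dose: ScalarVolume,
    guidance_hr: ScalarVolume,
    guidance_lr: ScalarVolume,
    spec: DownsampleSpec,
) -> ScalarVolume:
    """Fluence-domain guided-filter super-resolution of a coarse dose volume.

    Slice-wise: coarse fluence = coarse_dose / guidance_lr, nearest-neighbour
    up-sampling to the high-resolution grid, guided filtering against
    ``guidance_hr`` with radius ``spec.radius``, then multiplication by
    ``guidance_hr``.  Guidance values are floored at the smallest positive
    guidance value so the division never hits zero (the fluence relation
    only holds in matter); negative filter output is clamped to zero.
    """
    s = spec.s
    nz, ny, nx = guidance_hr.shape
    cz, cy, cx = coarse_dose.shape
    if cz != nz:
        raise ValueError("coarse and high-resolution grids must share slices")
    if (cy, cx) != (len(_window_edges(ny, s)), len(_window_edges(nx, s))):
        raise ValueError("coarse grid shape does not match the window partition")
    if coarse_dose.shape != guidance_lr.shape:
        raise ValueError("guidance_lr must live on the coarse grid")

    g_hr = guidance_hr.values
    g_lr = guidance_lr.values
    positive = g_hr[g_hr > 0]
    if positive.size == 0:
        raise ValueError("guidance map has no positive values")
    floor = min(positive.min(), g_lr[g_lr > 0].min() if np.any(g_lr > 0) else np.inf)
    g_lr = np.maximum(g_lr, floor)
    g_hr_f = np.maximum(g_hr, floor)

    eps = spec.eps
    if eps is None:
        rng = float(g_hr.max() - g_hr.min())
        eps = (0.01 * rng) ** 2 if rng > 0 else 1e-12

    out = np.empty((nz, ny, nx))
    for k in range(nz):
        psi = coarse_dose.values[k] / g_lr[k]
        psi_hr = _nn_upsample_slice(psi, (ny, nx), s)
        psi_f = guided_filter_2d(g_hr_f[k], psi_hr, spec.radius, eps)
        out[k] = psi_f * g_hr_f[k]
    np.clip(out, 0.0, None, out=out)
    return ScalarVolume(out, guidance_hr.spacing, guidance_hr.origin)


def reconstruct_from_simulation(
    labels_hr: LabelVolume,
    lib: MaterialLibrary,
    setup: BeamSetup,
    spec: DownsampleSpec,
    n_histories: int,
    seed: int = 0,
    n_batches: int = 10,
) -> tuple[ScalarVolume, DoseResult]:
    """Mode-downsample the phantom, simulate on the coarse grid, and
    reconstruct the high-resolution dose; returns (reconstruction, coarse
    simulation result)."""
    labels_lr = downsample_mode(labels_hr, spec.s, lib)
    result = simulate(labels_lr, lib, setup, n_histories,
                      seed=seed, n_batches=n_batches)
    guidance_hr = absorption_map(labels_hr, lib, setup.spectrum)
    guidance_lr = absorption_map(labels_lr, lib, setup.spectrum)
    recon = upsample_dose(result.total_dose, guidance_hr, guidance_lr, spec)
    return recon, result
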