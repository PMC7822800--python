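"""Imaging geometry: SE(3) poses, C-arm beam setup, collimation, X-ray spectra.

World frame: the phantom's longitudinal (axial stacking) axis is ``z``.  At a
primary angle of 0 deg (posteroanterior view) the source sits on the negative
``y`` side of the isocenter and the central ray points along ``+y``; positive
primary angles rotate the source about ``+z`` (90 deg = lateral view).  The
C-arm secondary and table angles are fixed at zero: only the primary angle is
parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Pose",
    "Spectrum",
    "BeamSetup",
    "source_pose",
    "beam_contains",
    "beam_mask",
    "reference_point",
    "load_spectrum",
    "make_analytic_spectrum",
    "sample_spectrum_energy",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Pose:
    """Rigid transform: ``p_world = rotation @ p_local + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "Pose") -> "Pose":
        """self after other: ``(self @ other)(p) = self(other(p))``."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)

    __matmul__ = compose

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return p @ self.rotation.T + self.translation


@dataclass
class Spectrum:
    """Discrete X-ray spectrum: photon-fluence weights per energy bin."""

    energies: np.ndarray  # keV, strictly increasing
    weights: np.ndarray  # relative photon fluence, normalized to sum 1
    kvp: float  # peak tube voltage, kV

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, float)
        self.weights = np.asarray(self.weights, float)
        if self.energies.ndim != 1 or self.energies.size == 0:
            raise ValueError("spectrum needs at least one energy bin")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("spectrum energies must be strictly increasing")
        if np.any(self.weights < 0) or self.weights.shape != self.energies.shape:
            raise ValueError("weights must be non-negative, one per energy")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total fluence")
        self.weights = self.weights / total
        if self.energies[-1] > self.kvp + 1e-9:
            raise ValueError(
                f"maximum energy {self.energies[-1]:.3g} keV exceeds kVp {self.kvp:.3g}"
            )

    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)


@dataclass
class BeamSetup:
    """C-arm cone-beam configuration.

    ``opening_phi``/``opening_theta`` are half-opening angles (deg) from the
    central ray to the field edge along the two detector axes; collimation is
    a rectangular pyramid matching a flat detector.
    """

    primary_angle: float  # deg
    sod: float  # source-to-isocenter distance, mm
    sid: float  # source-to-image distance, mm
    opening_phi: float  # deg, in-plane (world x at 0 deg)
    opening_theta: float  # deg, axial (world z)
    spectrum: Spectrum
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, float).reshape(3)
        if not 0 < self.sod < self.sid:
            raise ValueError(f"require 0 < SOD < SID, got SOD={self.sod}, SID={self.sid}")
        for name, ang in (("opening_phi", self.opening_phi),
                          ("opening_theta", self.opening_theta)):
            if not 0 < ang < 45:
                raise ValueError(f"{name} must be in (0, 45) deg, got {ang}")


def source_pose(setup: BeamSetup) -> Pose:
    """Pose of the X-ray source.

    The pose's local ``z`` axis is the central ray (pointing at the
    isocenter), local ``x`` is the in-plane detector axis, local ``y`` the
    axial one; the translation is the source position.
    """
    a = np.deg2rad(setup.primary_angle)
    Rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                   [np.sin(a), np.cos(a), 0.0],
                   [0.0, 0.0, 1.0]])
    ray = Rz @ np.array([0.0, 1.0, 0.0])  # central ray direction
    x_axis = Rz @ np.array([1.0, 0.0, 0.0])
    y_axis = np.array([0.0, 0.0, -1.0])  # right-handed: x cross y = ray
    R = np.column_stack([x_axis, y_axis, ray])
    src = setup.isocenter - setup.sod * ray
    return Pose(R, src)


def beam_contains(setup: BeamSetup, point) -> bool:
    """True iff the ray source -> point lies inside the collimation pyramid."""
    return bool(_beam_contains_many(setup, np.asarray(point, float).reshape(1, 3))[0])


def _beam_contains_many(setup: BeamSetup, points: np.ndarray) -> np.ndarray:
    pose = source_pose(setup)
    local = (points - pose.translation) @ pose.rotation  # R^T (p - src)
    z = local[:, 2]
    if np.any(np.linalg.norm(local, axis=1) < 1e-12):
        raise ValueError("point coincides with the X-ray source")
    tan_phi = np.tan(np.deg2rad(setup.opening_phi))
    tan_theta = np.tan(np.deg2rad(setup.opening_theta))
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = (z > 0) & (np.abs(local[:, 0]) <= tan_phi * z) \
            & (np.abs(local[:, 1]) <= tan_theta * z)
    return inside


def beam_mask(setup: BeamSetup, volume) -> np.ndarray:
    """Boolean (nz, ny, nx) mask of voxel centres inside the beam pyramid."""
    X, Y, Z = volume.voxel_centers()
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return _beam_contains_many(setup, pts).reshape(X.shape)


def reference_point(setup: BeamSetup, offset_mm: float = 150.0) -> np.ndarray:
    """Interventional reference point: on the central ray, ``offset_mm``
    upstream of the isocenter (IEC convention: 15 cm toward the source)."""
    if offset_mm >= setup.sod:
        raise ValueError(f"reference offset {offset_mm} mm must be < SOD {setup.sod} mm")
    pose = source_pose(setup)
    ray = pose.rotation[:, 2]
    return setup.isocenter - offset_mm * ray


def load_spectrum(path: str | Path, kvp: float | None = None) -> Spectrum:
    """Read a two-column spectrum CSV (``energy_keV, relative_fluence``)."""
    df = pd.read_csv(path)
    required = {"energy_keV", "relative_fluence"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectrum CSV must have columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    e = df["energy_keV"].to_numpy(float)
    w = df["relative_fluence"].to_numpy(float)
    if kvp is None:
        kvp = float(np.ceil(e.max()))
    return Spectrum(e, w, kvp)


def make_analytic_spectrum(
    kvp: float,
    filtration_mm: float = 0.0,
    filtration_material: str = "copper",
    inherent_al_mm: float = 2.3,
    step_kev: float = 1.0,
) -> Spectrum:
    """Analytic tungsten-anode spectrum: Kramers bremsstrahlung shape
    (photon fluence proportional to (kVp - E)/E) hardened by 2.3 mm
    aluminum-equivalent inherent filtration plus optional added filtration.

    An acknowledged approximation of measured/Boone-model spectra: no
    characteristic tungsten lines, no anode self-filtration detail.
    """
    from .materials import build_material_library  # local import, avoids cycle

    if not 40 <= kvp <= 150:
        raise ValueError(f"kvp must be in [40, 150], got {kvp}")
    lib = build_material_library()
    try:
        filt = lib.by_name(filtration_material)
    except KeyError:
        raise ValueError(f"unknown filtration material '{filtration_material}'")
    al = lib.by_name("aluminum")

    energies = np.arange(6.0, kvp + 0.5 * step_kev, step_kev)
    w = (kvp - energies) / energies
    w = np.clip(w, 0.0, None)
    w *= np.exp(-al.mu_rho_at(energies) * al.density * inherent_al_mm / 10.0)
    if filtration_mm > 0:
        w *= np.exp(-filt.mu_rho_at(energies) * filt.density * filtration_mm / 10.0)
    # drop numerically empty bins at the soft end
    keep = w > w.max() * 1e-9
    first = int(np.argmax(keep))
    return Spectrum(energies[first:], w[first:], kvp)


def sample_spectrum_energy(spectrum: Spectrum, rng: np.random.Generator,
                           size: int | None = None) -> np.ndarray | float:
    """Draw photon energies (keV) with probability proportional to the weights."""
    idx = np.searchsorted(spectrum.cdf(), rng.random(size), side="right")
    idx = np.minimum(idx, spectrum.energies.size - 1)
    e = spectrum.energies[idx]
    return float(e) if size is None else e
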