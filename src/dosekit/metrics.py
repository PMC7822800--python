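"""Dosimetric evaluation: error metrics, organ dose summaries, point probes.

Doses are intensive (per mass), so percentage errors and 2-sigma agreement
flags are invariant under any common unit change (mGy vs Gy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .volume import LabelVolume, ScalarVolume

__all__ = [
    "MeasurementSet",
    "mape",
    "error_map",
    "slice_organ_dose",
    "sample_dose_at_points",
    "compare_measurements",
    "ComparisonReport",
]


@dataclass
class MeasurementSet:
    """Point-dose measurements (e.g. MOSFET probes): id, world position (mm),
    mean dose and standard deviation (mGy) over ``n_repeats`` acquisitions."""

    ids: list[str]
    positions_mm: np.ndarray  # (n, 3) world x, y, z
    mean_dose: np.ndarray  # mGy
    sigma: np.ndarray  # mGy
    n_repeats: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.positions_mm = np.asarray(self.positions_mm, float).reshape(-1, 3)
        self.mean_dose = np.asarray(self.mean_dose, float)
        self.sigma = np.asarray(self.sigma, float)
        self.n_repeats = np.asarray(self.n_repeats, int)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("measurement ids must be unique")
        if not all(arr.shape[0] == n for arr in
                   (self.positions_mm, self.mean_dose, self.sigma, self.n_repeats)):
            raise ValueError("measurement fields must have one entry per point")
        if not np.all(np.isfinite(self.positions_mm)):
            raise ValueError("positions must be finite")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementSet":
        df = pd.read_csv(path)
        required = ["id", "x_mm", "y_mm", "z_mm", "dose_mGy", "sigma_mGy", "n_repeats"]
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"measurement CSV missing columns {sorted(missing)}")
        return cls(
            ids=df["id"].tolist(),
            positions_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            mean_dose=df["dose_mGy"].to_numpy(float),
            sigma=df["sigma_mGy"].to_numpy(float),
            n_repeats=df["n_repeats"].to_numpy(int),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "id": self.ids,
            "x_mm": self.positions_mm[:, 0],
            "y_mm": self.positions_mm[:, 1],
            "z_mm": self.positions_mm[:, 2],
            "dose_mGy": self.mean_dose,
            "sigma_mGy": self.sigma,
            "n_repeats": self.n_repeats,
        }).to_csv(path, index=False)


def _resolve_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    if isinstance(mask, LabelVolume):
        return mask.labels.astype(bool)
    m = np.asarray(mask)
    if m.shape != shape:
        raise ValueError("mask shape does not match the volumes")
    return m.astype(bool)


def mape(estimate: ScalarVolume, reference: ScalarVolume, mask=None) -> float:
    """Mean absolute percentage error over masked voxels, percent."""
    if not estimate.same_grid(reference):
        raise ValueError("estimate and reference must share one grid")
    m = _resolve_mask(mask, reference.shape)
    if not m.any():
        raise ValueError("mask selects no voxels")
    ref = reference.values[m]
    if np.any(ref <= 0):
        raise ValueError("reference must be positive within the mask")
    est = estimate.values[m]
    return float(np.mean(np.abs(est - ref) / ref) * 100.0)


def error_map(estimate: ScalarVolume, reference: ScalarVolume):
    """Voxelwise absolute percentage error and a validity mask.

    Returns ``(map, valid)``: the map is zero where the reference is zero,
    and those voxels are flagged False in ``valid``.
    """
    if not estimate.same_grid(reference):
        raise ValueError("estimate and reference must share one grid")
    ref = reference.values
    valid = ref > 0
    out = np.zeros_like(ref)
    np.divide(np.abs(estimate.values - ref), ref, out=out, where=valid)
    return estimate.with_values(out * 100.0), valid


def slice_organ_dose(
    dose: ScalarVolume,
    labels: LabelVolume,
    organ_label: int,
    density: ScalarVolume | None = None,
) -> pd.Series:
    """Per-axial-slice organ-equivalent dose (mGy), averaged over the organ's
    voxels in each slice.

    Averaging is mass-weighted; with no density map the organ is assumed
    uniform, in which case mass and voxel-count weighting coincide.  The
    radiation weighting factor is 1 (photons), so equivalent dose equals
    absorbed dose.
    """
    if not dose.same_grid(labels):
        raise ValueError("dose and labels must share one grid")
    organ = labels.labels == int(organ_label)
    if not organ.any():
        warnings.warn(f"organ label {organ_label} absent from the volume",
                      stacklevel=2)
        return pd.Series(dtype=float, name="organ_dose_mGy")
    w = np.ones_like(dose.values) if density is None else density.values
    vals = {}
    for k in range(dose.shape[0]):
        sel = organ[k]
        if sel.any():
            vals[k] = float(np.average(dose.values[k][sel], weights=w[k][sel]))
    return pd.Series(vals, name="organ_dose_mGy")


def sample_dose_at_points(dose: ScalarVolume, points: MeasurementSet) -> np.ndarray:
    """Trilinear interpolation of the dose volume at the probe positions (mGy)."""
    sx, sy, sz = dose.spacing
    ox, oy, oz = dose.origin
    p = points.positions_mm
    # fractional voxel-centre coordinates, array order (z, y, x)
    fi = (p[:, 0] - ox) / sx - 0.5
    fj = (p[:, 1] - oy) / sy - 0.5
    fk = (p[:, 2] - oz) / sz - 0.5
    nz, ny, nx = dose.shape
    for name, f, n in (("x", fi, nx), ("y", fj, ny), ("z", fk, nz)):
        bad = (f < 0) | (f > n - 1)
        if np.any(bad):
            culprit = points.ids[int(np.argmax(bad))]
            raise ValueError(
                f"measurement point '{culprit}' lies outside the dose grid "
                f"(axis {name})"
            )
    coords = np.vstack([fk, fj, fi])
    return map_coordinates(dose.values, coords, order=1, mode="nearest")


@dataclass
class ComparisonReport:
    """Per-point simulation/measurement comparison plus a MAPE summary."""

    points: pd.DataFrame
    mean_abs_percentage_error: float

    def to_dict(self) -> dict:
        return {
            "points": self.points.to_dict(orient="records"),
            "mean_abs_percentage_error": self.mean_abs_percentage_error,
        }


def compare_measurements(simulated: np.ndarray, measured: MeasurementSet) -> ComparisonReport:
    """Compare simulated point doses against measurements.

    Per point: absolute error, percentage error, and whether the simulation
    lies inside the measurement's 2-sigma confidence interval.
    """
    simulated = np.asarray(simulated, float)
    if simulated.shape[0] != len(measured.ids):
        raise ValueError("one simulated value per measurement point required")
    abs_err = np.abs(simulated - measured.mean_dose)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_err = 100.0 * abs_err / measured.mean_dose
    within = abs_err <= 2.0 * measured.sigma
    df = pd.DataFrame({
        "id": measured.ids,
        "measured_mGy": measured.mean_dose,
        "simulated_mGy": simulated,
        "abs_error_mGy": abs_err,
        "pct_error": pct_err,
        "within_2sigma": within,
    })
    return ComparisonReport(df, float(np.mean(pct_err)))
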