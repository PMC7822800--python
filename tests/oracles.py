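"""Independent brute-force oracles used by the test suite.

Everything here is deliberately slow and simple: direct loops and closed
forms that do not share code paths with the package's vectorized
implementations.
"""

import numpy as np

from dosekit import Material, MaterialLibrary


def box_mean_valid(img: np.ndarray, r: int) -> np.ndarray:
    """Border-shrunken box mean by explicit loops."""
    n, m = img.shape
    out = np.empty_like(img, dtype=float)
    for i in range(n):
        for j in range(m):
            w = img[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1]
            out[i, j] = w.mean()
    return out


def guided_filter_bruteforce(I: np.ndarray, p: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Per-pixel windowed ridge regression, then coefficient averaging."""
    n, m = I.shape
    a = np.empty((n, m))
    b = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            wi = I[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1].ravel()
            wp = p[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1].ravel()
            mi, mp = wi.mean(), wp.mean()
            cov = (wi * wp).mean() - mi * mp
            var = (wi * wi).mean() - mi * mi
            a[i, j] = cov / (var + eps)
            b[i, j] = mp - a[i, j] * mi
    return box_mean_valid(a, r) * I + box_mean_valid(b, r)


def mape_loop(est: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> float:
    total = 0.0
    count = 0
    for e, rr, m in zip(est.ravel(), ref.ravel(), mask.ravel()):
        if m:
            total += abs(e - rr) / rr * 100.0
            count += 1
    return total / count


def organ_dose_loop(dose: np.ndarray, labels: np.ndarray, organ: int) -> dict:
    out = {}
    for k in range(dose.shape[0]):
        vals = [dose[k, j, i]
                for j in range(dose.shape[1])
                for i in range(dose.shape[2])
                if labels[k, j, i] == organ]
        if vals:
            out[k] = sum(vals) / len(vals)
    return out


def spectrum_weighted_coefficient_loop(material, spectrum, kind: str) -> float:
    num = den = 0.0
    for e, w in zip(spectrum.energies, spectrum.weights):
        c = (material.mu_rho_at(e) if kind == "attenuation"
             else material.muen_rho_at(e))
        num += w * e * c
        den += w * e
    return num / den


def absorption_only_library(lib: MaterialLibrary) -> MaterialLibrary:
    """Clone a library with every interaction forced photoelectric.

    Useful for analytic transport checks: every interaction absorbs the
    photon fully, so deposits follow the Beer-Lambert first-interaction law
    with the unchanged total attenuation.
    """
    mats = {}
    for lab, m in lib.materials.items():
        f = np.zeros((m.energy_grid.size, 3))
        f[:, 0] = 1.0
        mats[lab] = Material(m.name, m.density, m.energy_grid,
                             m.mu_rho, m.mu_rho.copy(), f)
    return MaterialLibrary(mats)


def expected_first_interaction_deposits(mu_per_voxel_mm: np.ndarray,
                                        widths_mm: np.ndarray,
                                        energy_kev: float) -> np.ndarray:
    """Closed-form expected energy deposit per voxel for a pencil beam
    through a heterogeneous voxel column, when every interaction absorbs
    the photon (per emitted photon, keV)."""
    tau_in = np.concatenate([[0.0], np.cumsum(mu_per_voxel_mm * widths_mm)])
    return energy_kev * (np.exp(-tau_in[:-1]) - np.exp(-tau_in[1:]))
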