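"""Monte Carlo photon transport on voxel phantoms.

Physics model (kerma approximation, adequate in the diagnostic energy range):

* free flight by Woodcock delta-tracking against the volume's majorant
  linear attenuation, evaluated at the photon's current energy;
* photoelectric absorption deposits the full photon energy locally;
* Compton scattering samples the Klein-Nishina distribution by Kahn's
  rejection method and deposits the recoil-electron energy locally;
* Rayleigh scattering changes direction only (Thomson angular shape, no
  form factors);
* photons are "primary" until their first Compton/Rayleigh event, after
  which their deposits count as scatter dose;
* photons below a low-energy cutoff (default 5 keV) are absorbed locally;
  secondary electrons, characteristic X-rays and bremsstrahlung are not
  transported.

Free-in-air collision kerma is scored at the interventional reference point
with a track-length estimator over a 1 cm^3 spherical air cell placed on the
central ray upstream of the phantom; only the unattenuated pre-phantom part
of each primary track contributes.

Randomness is counter-based: each history seeds its own generator from
(seed, history index), so splitting a run into batches does not change any
photon's random stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .geometry import BeamSetup, beam_mask, reference_point, source_pose
from .materials import MaterialLibrary, labels_to_density
from .volume import LabelVolume, ScalarVolume

__all__ = ["DoseResult", "simulate", "estimate_uncertainty", "scale_to_air_kerma"]

KEV_TO_MGY_G = 1.602176634e-10  # 1 keV/g in mGy
_EGRID_MIN = 5.0
_EGRID_MAX = 150.0
_EGRID_STEP = 0.25
# radius of a 1 cm^3 sphere, mm
_REF_CELL_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

U64 = np.uint64


@dataclass
class DoseResult:
    """Output of one simulation run.

    Dose grids are absolute mGy for the simulated ``n_histories`` (scale with
    :func:`scale_to_air_kerma` to match a measured air kerma).
    ``batch_doses`` stacks the per-batch total-dose grids used for the
    batch-variance uncertainty estimate.
    """

    primary_dose: ScalarVolume
    scatter_dose: ScalarVolume
    n_histories: int
    batch_doses: np.ndarray  # (n_batches, nz, ny, nx), mGy
    ref_point_air_kerma: float  # mGy
    seed: int
    energy_emitted_kev: float
    energy_escaped_kev: float
    energy_deposited_kev: float

    def __post_init__(self) -> None:
        if self.n_histories <= 0:
            raise ValueError("n_histories must be positive")
        if np.any(self.primary_dose.values < 0) or np.any(self.scatter_dose.values < 0):
            raise ValueError("dose grids must be non-negative")

    @property
    def total_dose(self) -> ScalarVolume:
        return self.primary_dose.with_values(
            self.primary_dose.values + self.scatter_dose.values
        )


# ----------------------------------------------------------------- RNG core


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = (x + U64(0x9E3779B97F4A7C15)) & U64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _rand(s):
    s ^= s >> U64(12)
    s ^= (s << U64(25)) & U64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> U64(27)
    u = ((s * U64(0x2545F4914F6CDD1D)) >> U64(11)) * (1.0 / 9007199254740992.0)
    if u <= 0.0:
        u = 5e-324
    return s, u


@njit(cache=True, inline="always")
def _interp(table, e):
    x = (e - _EGRID_MIN) / _EGRID_STEP
    n = table.shape[0]
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(dz) < 0.999999:
        den = np.sqrt(1.0 - dz * dz)
        ux, uy, uz = dx * dz / den, dy * dz / den, -den
        vx, vy = -dy / den, dx / den
        nx = dx * cost + sint * (cosp * ux + sinp * vx)
        ny = dy * cost + sint * (cosp * uy + sinp * vy)
        nz = dz * cost + sint * cosp * uz
    else:
        sign = 1.0 if dz > 0 else -1.0
        nx = sint * cosp
        ny = sint * sinp
        nz = sign * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _kahn_compton(s, e_kev):
    """Klein-Nishina sampling (Kahn's rejection): returns (state, E', cos theta)."""
    a = e_kev / 510.99895
    while True:
        s, u1 = _rand(s)
        s, u2 = _rand(s)
        s, u3 = _rand(s)
        if u1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            eta = 1.0 + 2.0 * a * u2
            if u3 <= 4.0 * (eta - 1.0) / (eta * eta):
                return s, e_kev / eta, 1.0 - (eta - 1.0) / a
        else:
            eta = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * u2)
            cost = 1.0 - (eta - 1.0) / a
            if u3 <= 0.5 * (cost * cost + 1.0 / eta):
                return s, e_kev / eta, cost


@njit(cache=True, inline="always")
def _thomson_cost(s):
    while True:
        s, u = _rand(s)
        mu = 2.0 * u - 1.0
        s, v = _rand(s)
        if v <= 0.5 * (1.0 + mu * mu):
            return s, mu


@njit(cache=True, inline="always")
def _aabb(px, py, pz, dx, dy, dz, lox, loy, loz, hix, hiy, hiz):
    tmin = -1e30
    tmax = 1e30
    for k in range(3):
        if k == 0:
            p, d, lo, hi = px, dx, lox, hix
        elif k == 1:
            p, d, lo, hi = py, dy, loy, hiy
        else:
            p, d, lo, hi = pz, dz, loz, hiz
        if abs(d) < 1e-12:
            if p < lo or p > hi:
                return False, 0.0, 0.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
    if tmax <= max(tmin, 0.0):
        return False, 0.0, 0.0
    return True, max(tmin, 0.0), tmax


@njit(cache=True)
def _run_histories(
    labels, ox, oy, oz, sx, sy, sz,
    mu_mm, p_photo, p_compton, maj_mm, muen_air,
    sp_e, sp_cdf,
    srcx, srcy, srcz, rot, tan_phi, tan_theta,
    refx, refy, refz, ref_r,
    e_cut, h0, h1, seed,
    edep_p, edep_s,
):
    nz, ny, nx = labels.shape
    lox, loy, loz = ox, oy, oz
    hix = ox + nx * sx
    hiy = oy + ny * sy
    hiz = oz + nz * sz
    emitted = 0.0
    escaped = 0.0
    kerma_raw = 0.0

    for h in range(h0, h1):
        s = _splitmix64(U64(seed) * U64(0x9E3779B97F4A7C15) ^ U64(h))
        if s == U64(0):
            s = U64(0x853C49E6748FEA9B)

        # --- source: energy and collimated direction
        s, u = _rand(s)
        m = sp_cdf.shape[0]
        lo = 0
        hi = m - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if sp_cdf[mid] < u:
                lo = mid + 1
            else:
                hi = mid
        e = sp_e[lo]
        emitted += e

        s, u = _rand(s)
        bx = tan_phi * (2.0 * u - 1.0)
        s, u = _rand(s)
        by = tan_theta * (2.0 * u - 1.0)
        bn = np.sqrt(bx * bx + by * by + 1.0)
        bx, by, bz = bx / bn, by / bn, 1.0 / bn
        dx = rot[0, 0] * bx + rot[0, 1] * by + rot[0, 2] * bz
        dy = rot[1, 0] * bx + rot[1, 1] * by + rot[1, 2] * bz
        dz = rot[2, 0] * bx + rot[2, 1] * by + rot[2, 2] * bz

        px, py, pz = srcx, srcy, srcz
        hit, t_in, t_out = _aabb(px, py, pz, dx, dy, dz,
                                 lox, loy, loz, hix, hiy, hiz)

        # --- reference-point kerma: unattenuated pre-phantom track length
        t_limit = t_in if hit else 1e30
        ocx, ocy, ocz = px - refx, py - refy, pz - refz
        b = ocx * dx + ocy * dy + ocz * dz
        cq = ocx * ocx + ocy * ocy + ocz * ocz - ref_r * ref_r
        disc = b * b - cq
        if disc > 0.0:
            sq = np.sqrt(disc)
            ta = max(-b - sq, 0.0)
            tb = min(-b + sq, t_limit)
            if tb > ta:
                kerma_raw += e * (tb - ta) * _interp(muen_air, e)

        if not hit:
            escaped += e
            continue

        t = t_in
        primary = True
        alive = True
        while alive:
            mmaj = _interp(maj_mm, e)
            s, u = _rand(s)
            t += -np.log(u) / mmaj
            if t >= t_out:
                escaped += e
                break
            qx = px + t * dx
            qy = py + t * dy
            qz = pz + t * dz
            i = int((qx - ox) / sx)
            j = int((qy - oy) / sy)
            k = int((qz - oz) / sz)
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                escaped += e
                break
            lab = labels[k, j, i]
            mu = _interp(mu_mm[lab], e)
            s, u = _rand(s)
            if u * mmaj >= mu:
                continue  # fictitious interaction

            s, u = _rand(s)
            fp = _interp(p_photo[lab], e)
            fc = _interp(p_compton[lab], e)
            if u < fp:
                # photoelectric: local full absorption
                if primary:
                    edep_p[k, j, i] += e
                else:
                    edep_s[k, j, i] += e
                alive = False
            elif u < fp + fc:
                s, e_new, cost = _kahn_compton(s, e)
                de = e - e_new
                if primary:
                    edep_p[k, j, i] += de
                else:
                    edep_s[k, j, i] += de
                primary = False
                if e_new < e_cut:
                    edep_s[k, j, i] += e_new
                    alive = False
                else:
                    e = e_new
                    s, u = _rand(s)
                    dx, dy, dz = _rotate(dx, dy, dz, cost, 2.0 * np.pi * u)
                    px, py, pz = qx, qy, qz
                    hit, t_in2, t_out = _aabb(px, py, pz, dx, dy, dz,
                                              lox, loy, loz, hix, hiy, hiz)
                    if not hit:
                        escaped += e
                        alive = False
                    t = 0.0
            else:
                # Rayleigh: elastic, direction change only
                primary = False
                s, cost = _thomson_cost(s)
                s, u = _rand(s)
                dx, dy, dz = _rotate(dx, dy, dz, cost, 2.0 * np.pi * u)
                px, py, pz = qx, qy, qz
                hit, t_in2, t_out = _aabb(px, py, pz, dx, dy, dz,
                                          lox, loy, loz, hix, hiy, hiz)
                if not hit:
                    escaped += e
                    alive = False
                t = 0.0

    return emitted, escaped, kerma_raw


# ------------------------------------------------------------------ driver


def _material_tables(labels: LabelVolume, lib: MaterialLibrary):
    """Per-label attenuation and interaction tables on the transport grid."""
    egrid = np.arange(_EGRID_MIN, _EGRID_MAX + 0.5 * _EGRID_STEP, _EGRID_STEP)
    present = [int(v) for v in labels.present_labels()]
    n_lab = max(present) + 1
    mu_mm = np.zeros((n_lab, egrid.size))
    p_photo = np.zeros((n_lab, egrid.size))
    p_compton = np.zeros((n_lab, egrid.size))
    for lab in present:
        mat = lib[lab]
        mu_mm[lab] = mat.mu_rho_at(egrid) * mat.density / 10.0  # 1/mm
        f = mat.fractions_at(egrid)
        p_photo[lab] = f[:, 0]
        p_compton[lab] = f[:, 1]
    maj_mm = mu_mm[present].max(axis=0)
    if np.any(maj_mm <= 0):
        raise ValueError("majorant attenuation must be positive everywhere")
    air = lib.by_name("air")
    muen_air = air.muen_rho_at(egrid)
    return egrid, mu_mm, p_photo, p_compton, maj_mm, muen_air


def simulate(
    labels: LabelVolume,
    lib: MaterialLibrary,
    setup: BeamSetup,
    n_histories: int,
    seed: int = 0,
    n_batches: int = 10,
    energy_cutoff_kev: float = 5.0,
    reference_offset_mm: float = 150.0,
) -> DoseResult:
    """Run the photon transport and score primary/scatter dose (mGy).

    Reproducible bit-for-bit for fixed inputs and seed.  ``n_batches``
    partitions the histories into contiguous index ranges whose per-batch
    dose grids feed :func:`estimate_uncertainty`.
    """
    if n_histories < n_batches:
        raise ValueError("n_histories must be >= n_batches")
    spectrum = setup.spectrum
    if spectrum.energies[0] < _EGRID_MIN or spectrum.energies[-1] > _EGRID_MAX:
        raise ValueError(
            f"spectrum must lie within the transport energy grid "
            f"[{_EGRID_MIN}, {_EGRID_MAX}] keV"
        )

    in_beam = beam_mask(setup, labels)
    air_label = lib.label_for("air")
    if not np.any(in_beam & (labels.labels != air_label)):
        warnings.warn("beam does not intersect the phantom body; "
                      "patient dose will be zero", stacklevel=2)

    _, mu_mm, p_photo, p_compton, maj_mm, muen_air = _material_tables(labels, lib)
    pose = source_pose(setup)
    refp = reference_point(setup, reference_offset_mm)
    sp_e = spectrum.energies.astype(np.float64)
    sp_cdf = spectrum.cdf().astype(np.float64)
    lab_arr = np.ascontiguousarray(labels.labels.astype(np.int16))
    ox, oy, oz = labels.origin
    sx, sy, sz = labels.spacing

    nz, ny, nx = labels.shape
    batch_edges = np.linspace(0, n_histories, n_batches + 1).astype(np.int64)
    rho = labels_to_density(labels, lib).values
    mass_g = rho * labels.voxel_volume_cm3

    edep_p_total = np.zeros((nz, ny, nx))
    edep_s_total = np.zeros((nz, ny, nx))
    batch_doses = np.empty((n_batches, nz, ny, nx), dtype=np.float32)
    emitted = escaped = kerma_raw = 0.0
    for b in range(n_batches):
        edep_p = np.zeros((nz, ny, nx))
        edep_s = np.zeros((nz, ny, nx))
        em, es, kr = _run_histories(
            lab_arr, ox, oy, oz, sx, sy, sz,
            mu_mm, p_photo, p_compton, maj_mm, muen_air,
            sp_e, sp_cdf,
            pose.translation[0], pose.translation[1], pose.translation[2],
            pose.rotation,
            np.tan(np.deg2rad(setup.opening_phi)),
            np.tan(np.deg2rad(setup.opening_theta)),
            refp[0], refp[1], refp[2], _REF_CELL_RADIUS_MM,
            energy_cutoff_kev,
            int(batch_edges[b]), int(batch_edges[b + 1]), seed,
            edep_p, edep_s,
        )
        emitted += em
        escaped += es
        kerma_raw += kr
        edep_p_total += edep_p
        edep_s_total += edep_s
        batch_doses[b] = ((edep_p + edep_s) * KEV_TO_MGY_G / mass_g).astype(np.float32)

    primary = ScalarVolume(edep_p_total * KEV_TO_MGY_G / mass_g,
                           labels.spacing, labels.origin)
    scatter = ScalarVolume(edep_s_total * KEV_TO_MGY_G / mass_g,
                           labels.spacing, labels.origin)
    # track-length kerma over the 1 cm^3 cell: keV*mm*(cm^2/g) -> mGy
    kerma_mgy = kerma_raw * 0.1 * KEV_TO_MGY_G / 1.0
    return DoseResult(
        primary_dose=primary,
        scatter_dose=scatter,
        n_histories=n_histories,
        batch_doses=batch_doses,
        ref_point_air_kerma=float(kerma_mgy),
        seed=seed,
        energy_emitted_kev=float(emitted),
        energy_escaped_kev=float(escaped),
        energy_deposited_kev=float(edep_p_total.sum() + edep_s_total.sum()),
    )


def estimate_uncertainty(result: DoseResult) -> ScalarVolume:
    """Voxelwise relative 2-sigma uncertainty (percent) of the mean dose,
    from batch-to-batch variance; voxels with no dose are flagged as 100 %."""
    b = result.batch_doses.astype(np.float64)
    n = b.shape[0]
    if n < 2:
        raise ValueError("uncertainty estimation requires at least two batches")
    mean = b.mean(axis=0)
    var = b.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 200.0 * np.sqrt(var / n) / mean
    rel[~np.isfinite(rel) | (mean <= 0)] = 100.0
    return ScalarVolume(rel, result.primary_dose.spacing, result.primary_dose.origin)


def scale_to_air_kerma(result: DoseResult, measured_kair_mgy: float) -> DoseResult:
    """Scale all dose grids by measured/simulated reference-point air kerma."""
    if result.ref_point_air_kerma <= 0:
        raise ValueError("simulated reference-point air kerma is zero; cannot scale")
    f = measured_kair_mgy / result.ref_point_air_kerma
    return replace(
        result,
        primary_dose=result.primary_dose.with_values(result.primary_dose.values * f),
        scatter_dose=result.scatter_dose.with_values(result.scatter_dose.values * f),
        batch_doses=result.batch_doses * np.float32(f),
        ref_point_air_kerma=float(measured_kair_mgy),
    )
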