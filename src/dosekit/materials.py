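"""Material data model: densities, photon interaction coefficients, guidance maps.

The packaged tables (``dosekit/data/materials``) hold, per material, the mass
attenuation coefficient mu/rho, the mass-energy absorption coefficient
muen/rho, and the relative shares of photoelectric, Compton and Rayleigh
interactions on a log-spaced 5-150 keV grid.  Between grid points the
coefficients are interpolated linearly in log-log space, which tracks the
smooth power-law behaviour of photon cross sections in the diagnostic range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .volume import LabelVolume, ScalarVolume

__all__ = [
    "Material",
    "MaterialLibrary",
    "build_material_library",
    "labels_to_density",
    "spectrum_averaged_coefficient",
    "absorption_map",
]

# default label ids used by the synthetic phantom and the pipeline
DEFAULT_LABELS = {
    "air": 0,
    "soft_tissue": 1,
    "adipose": 2,
    "bone": 3,
    "brain": 4,
    "lung": 5,
    "water": 6,
    "aluminum": 7,
    "copper": 8,
}


@dataclass
class Material:
    """One tissue/material: bulk density plus energy-resolved coefficients.

    ``interaction_fractions`` has shape ``(n_energies, 3)`` with columns
    (photoelectric, Compton, Rayleigh); each row sums to one.
    """

    name: str
    density: float  # g/cm^3
    energy_grid: np.ndarray  # keV, strictly increasing
    mu_rho: np.ndarray  # cm^2/g
    muen_rho: np.ndarray  # cm^2/g
    interaction_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, float)
        self.mu_rho = np.asarray(self.mu_rho, float)
        self.muen_rho = np.asarray(self.muen_rho, float)
        self.interaction_fractions = np.asarray(self.interaction_fractions, float)
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError(f"{self.name}: energy grid must be strictly increasing")
        if np.any(self.muen_rho > self.mu_rho * (1 + 1e-12)):
            raise ValueError(f"{self.name}: muen/rho exceeds mu/rho")
        f = self.interaction_fractions
        if f.shape != (self.energy_grid.size, 3):
            raise ValueError(f"{self.name}: interaction_fractions shape mismatch")
        if np.any(f < 0) or not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: interaction fractions must be a per-energy simplex")

    def _interp_loglog(self, table: np.ndarray, energies_kev) -> np.ndarray:
        e = np.asarray(energies_kev, float)
        if np.any(e < self.energy_grid[0]) or np.any(e > self.energy_grid[-1]):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{self.energy_grid[0]:.3g}, {self.energy_grid[-1]:.3g}] keV "
                f"for material '{self.name}' (no extrapolation)"
            )
        return np.exp(np.interp(np.log(e), np.log(self.energy_grid), np.log(table)))

    def mu_rho_at(self, energies_kev) -> np.ndarray:
        """Mass attenuation coefficient, cm^2/g."""
        return self._interp_loglog(self.mu_rho, energies_kev)

    def muen_rho_at(self, energies_kev) -> np.ndarray:
        """Mass-energy absorption coefficient, cm^2/g."""
        return self._interp_loglog(self.muen_rho, energies_kev)

    def fractions_at(self, energies_kev) -> np.ndarray:
        """Interaction-type probabilities (photo, Compton, Rayleigh), shape (n, 3)."""
        e = np.asarray(energies_kev, float)
        cols = [
            np.interp(e, self.energy_grid, self.interaction_fractions[:, i])
            for i in range(3)
        ]
        f = np.stack(cols, axis=-1)
        return f / f.sum(axis=-1, keepdims=True)


@dataclass
class MaterialLibrary:
    """Mapping from integer tissue label to :class:`Material`."""

    materials: dict[int, Material] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "air" not in {m.name for m in self.materials.values()}:
            raise ValueError("material library must contain an 'air' entry")

    def __getitem__(self, label: int) -> Material:
        try:
            return self.materials[int(label)]
        except KeyError:
            raise KeyError(f"unknown tissue label {int(label)}") from None

    def __contains__(self, label: int) -> bool:
        return int(label) in self.materials

    @property
    def labels(self) -> list[int]:
        return sorted(self.materials)

    def label_for(self, name: str) -> int:
        for lab, mat in self.materials.items():
            if mat.name == name:
                return lab
        raise KeyError(f"no material named '{name}'")

    def by_name(self, name: str) -> Material:
        return self.materials[self.label_for(name)]


def build_material_library() -> MaterialLibrary:
    """Load the packaged tissue tables into a library with default label ids.

    Provides at least air, soft tissue, adipose, bone, brain, lung and water
    (plus aluminum and copper for beam filtration).
    """
    pkg = resources.files("dosekit.data") / "materials"
    try:
        manifest = json.loads((pkg / "manifest.json").read_text())
    except (FileNotFoundError, json.JSONDecodeError) as exc:
        raise RuntimeError(f"embedded material manifest unreadable: {exc}") from exc

    materials: dict[int, Material] = {}
    for name, label in DEFAULT_LABELS.items():
        if name not in manifest:
            raise RuntimeError(f"embedded material table missing entry '{name}'")
        try:
            raw = np.genfromtxt(
                (pkg / f"{name}.csv").open("r"), delimiter=",", names=True
            )
        except (FileNotFoundError, ValueError) as exc:
            raise RuntimeError(f"embedded table for '{name}' unreadable: {exc}") from exc
        fractions = np.column_stack(
            [raw["f_photo"], raw["f_compton"], raw["f_rayleigh"]]
        )
        materials[label] = Material(
            name=name,
            density=float(manifest[name]["density_g_cm3"]),
            energy_grid=raw["energy_keV"],
            mu_rho=raw["mu_rho"],
            muen_rho=raw["muen_rho"],
            interaction_fractions=fractions,
        )
    return MaterialLibrary(materials)


def labels_to_density(labels: LabelVolume, lib: MaterialLibrary) -> ScalarVolume:
    """Voxelwise mass-density map (g/cm^3) on the same grid as ``labels``."""
    present = labels.present_labels()
    lut_size = int(present.max()) + 1
    lut = np.full(lut_size, np.nan)
    for lab in present:
        lut[lab] = lib[int(lab)].density  # KeyError names the label
    rho = lut[labels.labels]
    return ScalarVolume(rho, labels.spacing, labels.origin)


def spectrum_averaged_coefficient(material: Material, spectrum, kind: str) -> float:
    """Energy-fluence-weighted mean coefficient over a spectrum, cm^2/g.

    The weight of each spectral bin is photon fluence times photon energy,
    i.e. the bin's share of the beam's energy fluence, matching the
    energy-fluence formulation of the kerma relation D = psi * (muen/rho).
    """
    if kind == "attenuation":
        coef = material.mu_rho_at(spectrum.energies)
    elif kind == "absorption":
        coef = material.muen_rho_at(spectrum.energies)
    else:
        raise ValueError(f"kind must be 'attenuation' or 'absorption', got {kind!r}")
    w = spectrum.weights * spectrum.energies
    return float(np.sum(w * coef) / np.sum(w))


def absorption_map(labels: LabelVolume, lib: MaterialLibrary, spectrum) -> ScalarVolume:
    """Voxelwise spectrum-averaged muen/rho map: the guidance image for
    guided-filter dose reconstruction."""
    present = labels.present_labels()
    lut = np.full(int(present.max()) + 1, np.nan)
    for lab in present:
        lut[lab] = spectrum_averaged_coefficient(lib[int(lab)], spectrum, "absorption")
    return ScalarVolume(lut[labels.labels], labels.spacing, labels.origin)
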