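"""Generate the packaged tabulated X-ray spectra under src/dosekit/data/spectra/.

Each CSV is produced by the package's analytic tungsten-anode model
(Kramers bremsstrahlung, 2.3 mm Al inherent filtration, optional Cu
pre-filtration) so the shipped tables and the analytic fallback agree.

Run from the repository root:  python scripts/build_spectra.py
"""

from pathlib import Path

import numpy as np

from dosekit.geometry import make_analytic_spectrum

SPECTRA = [
    (70.0, 0.0, "tungsten_70kvp.csv"),
    (90.0, 0.0, "tungsten_90kvp.csv"),
    (120.0, 0.9, "tungsten_120kvp_0.9mmcu.csv"),
]


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "src" / "dosekit" / "data" / "spectra"
    out_dir.mkdir(parents=True, exist_ok=True)
    for kvp, cu, name in SPECTRA:
        sp = make_analytic_spectrum(kvp, filtration_mm=cu)
        rows = np.column_stack([sp.energies, sp.weights])
        np.savetxt(out_dir / name, rows, delimiter=",", fmt="%.8g",
                   header="energy_keV,relative_fluence", comments="")
        print(f"{name}: {sp.energies.size} bins, mean {sp.mean_energy():.1f} keV")


if __name__ == "__main__":
    main()
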