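"""Regenerate the packaged mass-attenuation tables.

The tables split the total mass attenuation coefficient (cm^2/g) into
photoelectric, incoherent (Compton) and coherent (Rayleigh) partials on a
1 keV grid from 10 to 100 keV:

* incoherent: exact Klein-Nishina total cross section per free electron
  multiplied by the electron density N_A * (Z/A) of the material;
* photoelectric: power law C * (Z_eff/7.42)^3.8 * (30/E)^3.6 anchored to
  water (0.090 cm^2/g at 30 keV);
* coherent: power law C * (Z_eff/7.42)^1.9 * (30/E)^1.9 anchored to water
  (0.032 cm^2/g at 30 keV).

See src/cbctscatter/data/README.md for the calibration rationale.
"""

from pathlib import Path

import numpy as np

R_E_CM = 2.8179403262e-13          # classical electron radius, cm
N_A = 6.02214076e23
MEC2_KEV = 510.99895               # electron rest energy, keV

# name -> (Z/A, effective Z)
MATERIALS = {
    "air": (0.49919, 7.64),
    "soft_tissue": (0.55509, 7.42),
    "bone": (0.52130, 13.8),
    "aluminum": (0.48181, 13.0),
}

WATER_ZEFF = 7.42
PE_ANCHOR = 0.090      # water photoelectric mass coefficient at 30 keV, cm^2/g
PE_Z_EXP = 3.8
PE_E_EXP = 3.6
COH_ANCHOR = 0.032     # water coherent mass coefficient at 30 keV, cm^2/g
COH_Z_EXP = 1.9
COH_E_EXP = 1.9


def klein_nishina_total(energy_kev):
    """Total Klein-Nishina cross section per electron (cm^2)."""
    a = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a)
                             - np.log1p(2.0 * a) / a)
    t2 = np.log1p(2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    return 2.0 * np.pi * R_E_CM**2 * (t1 + t2 - t3)


def build_table(z_over_a, z_eff, energies):
    mu_compton = klein_nishina_total(energies) * N_A * z_over_a
    mu_pe = PE_ANCHOR * (z_eff / WATER_ZEFF) ** PE_Z_EXP * (30.0 / energies) ** PE_E_EXP
    mu_rayleigh = COH_ANCHOR * (z_eff / WATER_ZEFF) ** COH_Z_EXP * (30.0 / energies) ** COH_E_EXP
    return mu_pe, mu_compton, mu_rayleigh


def main():
    out_dir = Path(__file__).resolve().parents[1] / "src" / "cbctscatter" / "data" / "attenuation"
    out_dir.mkdir(parents=True, exist_ok=True)
    energies = np.arange(10.0, 101.0)
    for name, (z_over_a, z_eff) in MATERIALS.items():
        mu_pe, mu_co, mu_ra = build_table(z_over_a, z_eff, energies)
        path = out_dir / f"{name}.txt"
        with path.open("w") as fh:
            fh.write("# mass attenuation coefficients (cm^2/g)\n")
            fh.write(f"# material: {name}  Z/A={z_over_a}  Z_eff={z_eff}\n")
            fh.write("# energy_keV mu_pe mu_compton mu_rayleigh\n")
            for e, pe, co, ra in zip(energies, mu_pe, mu_co, mu_ra):
                fh.write(f"{e:.1f} {pe:.6e} {co:.6e} {ra:.6e}\n")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
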