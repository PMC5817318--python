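# Packaged attenuation data

Mass attenuation coefficient tables for the four transport materials
(air, soft tissue, bone, aluminum) on a 1 keV grid from 10 to 100 keV,
split into photoelectric, incoherent (Compton) and coherent (Rayleigh)
partials, units cm^2/g.

Format: whitespace-separated text, `#` comment header, columns
`energy_keV mu_pe mu_compton mu_rayleigh`.

## Provenance

The tables are generated by `scripts/make_attenuation_tables.py` from a
parametric cross-section model, so the package is fully self-contained:

* **Incoherent** — exact total Klein-Nishina cross section per free
  electron times the material electron density `N_A * (Z/A)`. Electron
  binding (incoherent scattering function) is neglected, consistent with
  the free-electron Compton model used by the transport code.
* **Photoelectric** — `0.090 * (Z_eff/7.42)^3.8 * (30 keV/E)^3.6` cm^2/g,
  anchored so water reproduces commonly tabulated values to ~10–20% over
  10–100 keV (4.7 at 10 keV, 0.090 at 30 keV, 0.0074 at 60 keV).
* **Coherent** — `0.032 * (Z_eff/7.42)^1.9 * (30 keV/E)^1.9` cm^2/g,
  anchored to water at 30 keV.

`Z/A` values are the standard elemental-composition averages (air 0.4992,
water 0.5551, cortical-bone equivalent 0.5213, aluminum 0.4818); effective
Z values are the usual photoelectric-weighted ones (7.64, 7.42, 13.8, 13.0).

These tables are a smooth, edge-free approximation adequate for the
diagnostic band used here; they are **not** a substitute-accuracy copy of
any evaluated nuclear data library. The total coefficient is defined as
the exact sum of the three partials at every grid energy.
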