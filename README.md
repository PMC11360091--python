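# ssaxs

Data reduction for **spectral small-angle X-ray scattering (sSAXS)** with 2D
spectroscopic photon-counting detectors.

In sSAXS a polychromatic pencil beam irradiates the sample and a pixellated
energy-resolving detector (HEXITEC-class CdTe, e.g. 80 × 80 pixels × 200 energy
bins) records, per pixel, a histogram of scattered-photon energies. Because
every pixel sees a known scattering angle 2θ from the system geometry and every
count carries its photon energy E, each recorded count maps to a momentum
transfer

    q = 4π E sin θ / hc,        θ = 2θ / 2,    hc = 1.24 keV·nm

and a powder reflection with lattice spacing d appears as a Debye–Scherrer ring
at q = 2π/d. This package reduces the raw 3D count array
(energy bin × row × column) into:

- **1D scattering patterns** — counts binned in q, separately per user-defined
  energy window, with optional background subtraction;
- **2D detector images** — per-pixel counts summed over an energy window;
- **2D scattering maps** — for raster scans, each position scored by the
  area under the peak (AUP) in a chosen q-range and placed into the scan grid.

A forward simulator generates synthetic detector frames containing Gaussian
rings at specified q under a chosen source spectrum with Poisson noise, so the
whole chain can be validated against known ground truth.

## Worked example

Simulate a caffeine-like powder measurement (rings at 8.4 and 18.6 nm⁻¹, flat
30–45 keV spectrum, SDD 250 mm, 0.25 mm pitch, beam center just off one
corner), then reduce it into three 5 keV energy windows:

```yaml
# sim.yaml
geometry:
  sdd_mm: 250.0
  beam_center: [-2.0, -2.0]
  pixel_pitch_mm: 0.25
  n_rows: 80
  n_cols: 80
energy_axis: {n_bins: 200, bin_width_keV: 1.0, offset_keV: 0.0}
spectrum: {flat: [30, 45]}
rings:
  - {q_peak: 8.4, sigma_q: 0.15, intensity: 20000}
  - {q_peak: 18.6, sigma_q: 0.15, intensity: 12000}
background_rate: 0.01
```

```console
$ ssaxs simulate --config sim.yaml --seed 42 --out caffeine_like.h5
wrote caffeine_like.h5: 45046 counts (expected 44800.0)
$ ssaxs reduce --frame caffeine_like.h5 --config sim.yaml \
      --bin-start 30 --bin-end 45 --energy-window 5 --out-prefix demo
wrote 6 files with prefix demo
```

Each window yields a pattern CSV (`q_nm_inv,counts`) and a detector-image CSV.
The pattern maxima sit within one 0.1 nm⁻¹ bin of the injected rings:

```
w30-35  argmax q = 8.35   total = 9963
w35-40  argmax q = 8.45   total = 10736
w40-45  argmax q = 18.55  total = 12456
```

Note the physics in the numbers: the 18.6 nm⁻¹ ring is kinematically out of
reach of the detector at the lowest energies and becomes the dominant feature
only in the 40–45 keV window — higher q is covered as the energy increases.

For a raster scan, `ssaxs simulate-scan` writes one frame per grid cell and
`ssaxs map --scan-dir ... --rows R --cols C --aup-min 7 --aup-max 9 ...`
assembles the AUP map (here 7–9 nm⁻¹, the first caffeine reflection); cell
values rank-order with the simulated ring intensities.

The same operations are available as a library
(`ssaxs.reduce_to_pattern`, `ssaxs.build_scan_map`, `ssaxs.simulate_frame`, …)
for scripted analysis.

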