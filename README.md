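# barcodemc

Monte Carlo assessment of fully insertable, optically interrogated glucose
biosensors ("barcode" implants) in layered skin.

A grain-of-rice hydrogel implant carrying alternating luminescent assay
domains — an oxygen-quenched phosphorescence-lifetime assay and a
FRET competitive-binding assay — is inserted a few millimetres under the
skin and read transdermally: an LED on the surface excites the implant, and
a colocated fiber-coupled photodiode collects the returning luminescence.
Whether any photons make it back above the noise floor depends on tissue
scattering and absorption, endogenous autofluorescence, skin tone, implant
depth and the skin-safety limit on illumination.  `barcodemc` answers that
question by simulation, for engineers designing such sensors.

## What it computes

* **Voxelized photon transport** through a three-layer forearm model
  (epidermis / dermis / subcutis, 0.010 / 0.15 / 0.24 cm) with an embedded
  barcode implant: hop–drop–spin random walk with Henyey–Greenstein
  scattering (g = 0.90), continuous track-length absorption, Russian
  roulette, an LED source (0.40 × 0.40 cm top-hat, truncated-Lambertian
  far field of half-width π/8) and a fiber detector (NA 0.4, ⌀ 0.17 cm).
* **A two-stage luminescence cascade**: one excitation run fixes where
  light is absorbed in a luminescent domain; per-bin emission runs (80
  bins by default) are scaled by the modified quantum yield
  mΦ_bin = Φ·Em(bin)/ΣEm and by the power-yield factor λ_ex/λ_em.
* **Assay post-processing**: Stern–Volmer quenching I₀/I = τ₀/τ =
  1 + K_SV·[O₂], time-gated decay collection, the ratiometric FRET
  combination
  FI_D = FLRD_D·(1 − SO·E·ConA·MT·κ²),
  FI_A = FLRD_A·(ε_D/ε_A)·SO·E·ConA·κ²,
  and the additively combined directly excited Cy7 component of the
  far-red assay.
* **Tissue autofluorescence** from FAD, collagen, vitamin A and melanin at
  450 and 680 nm excitation.
* **Detectability**: conversion to watts at the skin-safe source power
  (2 kW/m² × 0.16 cm² = 32 mW) and comparison against a photodiode's
  minimum detectable power P_min = NEP·√BW·S(λ)/S_max.
* **Studies**: photon-count convergence, implant-depth sweeps and
  epidermal melanosome-fraction sweeps (0.03 / 0.23 / 0.43 ≈ Fitzpatrick
  tones I / IV / VI).

All randomness is counter-based: a run is bit-reproducible from its seed,
independent of batching.

## Worked example

```python
from barcodemc import (SourceSpec, propagate, fluence_at_depth,
                       absorbed_fraction_report)
from barcodemc.studies import barcode_grid

grid = barcode_grid(680)                 # three layers + barcode implant
src = SourceSpec(wavelength=680.0)       # 680 nm LED, 32 mW bookkeeping
res = propagate(grid, src, n_photons=100_000, seed=3)

print(f"absorbed anywhere: {res.absorbed_total:.3f}")
print(f"BMAP domains:      {absorbed_fraction_report(res, grid, 'phosphor')}")
print(f"fluence at 0.2 cm: {fluence_at_depth(res, 0.20):.2f} /cm^2 per W")
```

prints (seed 3, 1e5 photons):

```
absorbed anywhere: 0.182
BMAP domains:      {'fraction_of_incident': 0.0549..., 'fraction_of_absorbed': 0.3016..., 'total_absorbed': 0.1822...}
fluence at 0.2 cm: 1.54 /cm^2 per W
```

Read: 18.2% of the incident 680 nm light is absorbed somewhere in the
domain; the two BMAP phosphor domains capture 5.5% of the incident light
(30% of everything absorbed), and the fluence 2 mm deep under the beam is
1.54 cm⁻² per watt of source power — the implant is well lit at 680 nm.
The same call at 450 nm shows the visible-spectrum assay capturing only
~2×10⁻⁵ of the incident light, which is why the far-red barcode is the
viable design.

A command-line interface mirrors the library
(`barcodemc run-excitation|run-fluorescence|run-assay|autofluorescence|
sweep-depth|sweep-melanin|converge|power-report`, each accepting
`--config/--seed/--photons/--out/--fast`).

## Layout

| module | contents |
| --- | --- |
| `optics` | chromophore-mixture skin properties, Table-style fluorophore registry, property files |
| `geometry` | layer stack, barcode implant, voxel grid |
| `transport` | the numba transport kernel, source/detector models, tallies |
| `fluorescence` | emission-bin plans, modified quantum yield, the cascade |
| `assays` | Stern–Volmer, time gating, FRET combination, melanin Φ arithmetic |
| `autofluorescence` | endogenous fluorophore layer models |
| `detectability` | MPE power, NEP-based minimum detectable power, margins |
| `studies` | convergence, depth and melanosome sweeps, reports |
| `config` / `cli` | YAML run configs, synthetic spectra, result I/O, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
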