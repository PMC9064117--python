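# Methods

## Model overview

`barcodemc` simulates steady-state light transport through a voxelized
three-layer model of the dorsal forearm with an embedded luminescent
"barcode" implant, followed by a deterministic assay post-processing
layer.  The chain is:

1. an excitation transport run at the source wavelength,
2. an emission-source map proportional to the excitation weight absorbed
   inside the luminescent domain,
3. one emission transport run per wavelength bin, scaled by the
   absorbed-excitation fraction and the per-bin power yield,
4. scalar assay arithmetic (Stern–Volmer quenching, time gating, FRET
   combination) and conversion to watts at the exposure-limited source
   power for comparison with a photodiode noise floor.

## Transport

The random walk is the hop–drop–spin scheme of the MCML/mcxyz family on a
voxel grid.  Scattering hops are sampled as s = −ln ξ / μ_s and consumed
across voxel-boundary substeps; directions update by Henyey–Greenstein
inverse-CDF sampling with azimuth drawn by Marsaglia rejection.
Absorption is continuous: along every substep of length d the weight is
multiplied by exp(−μ_a·d) and the lost weight is deposited in the voxel.
This track-length estimator (rather than discrete per-collision deposits)
is what keeps the absorption and fluence tallies smooth in low-absorption
media; in the convergence scenario below, a collision estimator would
register only a handful of discrete events per million photons in the
μ_a = 0.001 cm⁻¹ implant and its run-to-run scatter would never reach the
sub-percent regime the tool is designed to verify.  Fluence is tallied as
deposited-weight/μ_a (pure path length where μ_a = 0), so fluence·μ_a·V
and the absorption tally agree identically.

Photon termination is by escape through any of the six domain faces
(boundaries are index-matched; no Fresnel events, all media at n = 1.40)
or by Russian roulette below weight 1e-4 (survival 1/10, weight ×10 —
unbiased).  Weight is conserved per run to well under 1e-3.

Top-face escapes are tested against the fiber detector: accept iff the
exit point lies within 0.085 cm of the axis and the exit angle from the
surface normal is at most asin(NA/n_ambient) with NA = 0.4 and ambient
n = 1.0.

The LED source is a 0.40 × 0.40 cm top-hat rectangle with a
truncated-Lambertian polar density (cosine-weighted, renormalized on
[0, π/8]) read as an axisymmetric cone; a per-axis variant was considered
and rejected as underdetermined.  Setting the widths and half-angle to
zero yields a normally incident pencil beam for closed-form checks.

Randomness is counter-based: each photon derives an xorshift64* stream
from (master seed, photon index) via splitmix64, so tallies are
bit-reproducible and independent of batch size.  Library-level seeds are
derived with `numpy.random.SeedSequence` from a single master seed plus
structural tags (bin index, replicate, wavelength).

## Optical properties

The skin layers use a chromophore-mixture parameterization: per-layer
volume fractions of whole blood (hemoglobin 150 g/L split by oxygen
saturation), water, fat and melanosomes, with a generic "skin baseline"
spectrum assigned to the residual fraction.  Defaults
(B/S/W/F): epidermis 0 / – / 0.75 / 0, dermis 0.002 / 0.67 / 0.65 / 0,
subcutis 0.005 / 0.75 / 0.05 / 0.70; melanosome interior absorption
519·(λ/500 nm)⁻³·⁵ scaled by the epidermal volume fraction (default 0.03).
The composite epidermal absorption is multiplied by 0.1 — the reduction is
applied to the full melanin + baseline mixture, including during
melanosome sweeps (a configurable switch).  Reduced scattering follows
μ_s′ = a·(λ/500 nm)⁻ᵇ with (a, b) = (46, 1.421) for epidermis and dermis
and (19, 0.68) for subcutis; μ_s = μ_s′/(1 − g) with g = 0.90 everywhere.

The embedded hemoglobin/water/fat tables are compact (10 nm step,
440–920 nm) approximations of the standard compilations and are the main
systematic uncertainty of the absolute predictions; any medium can be
replaced by a measured five-column property file
(wavelength, μ_a, μ_s, g, n), which round-trips bit-identically.

Implant assay domains are non-scattering (dye absorption dominates) and
carry their registered absorption coefficient only within ±2 nm of their
excitation wavelength; at emission wavelengths they default to transparent,
on the assumption that Stokes-shifted emission is not strongly
re-absorbed.  Both choices are configurable.

## Geometry

Implant dimensions are not prescribed by the application beyond
"grain-of-rice": the default is a 0.10 × 0.10 cm bar, 0.40 cm long, split
into four alternating 0.10 cm domains (FRET, phosphor, FRET, phosphor),
centered at 0.20 cm depth.  Depth-sweep values are interpreted in
centimetres (0.20–0.50 cm) for consistency with the default placement.
Voxels default to 0.005 cm (cubic) over a 1.5 × 1.5 cm lateral extent;
autofluorescence grids use a finer 0.002 cm axial size so that the
0.002 cm stratum corneum and the stratum basale (bottom 20% of the
0.010 cm epidermis) land on voxel faces.  The stratum corneum thickness is
taken as 0.002 cm (a literal 0.02 cm would exceed the epidermis).

## Luminescence cascade

The modified quantum yield apportions Φ over the emission-bin plan,
mΦ_bin = Φ·Em(bin)/Σ_bins Em (Σ mΦ = Φ exactly), and is converted to a
power yield by λ_ex/λ_em.  Emission is launched isotropically from the
frozen excitation absorption map of the luminescent label; there is no
re-absorption/re-emission cascade (single generation).  Default plans use
80 bins over 493–700 nm (visible) or 700–900 nm (far-red), i.e. 1.8–2.6 nm
resolution; autofluorescence runs use ≤5 nm resolution.

Autofluorescence models substitute the host (sub-)layer's absorption with
the registered fluorophore value for the excitation run only (all
absorption there is attributed to the fluorophore; scattering follows the
host layer); emission propagates through the unmodified skin model.  NADH
is excluded at 450 nm and porphyrins at 680 nm; PPIX is registered but
excluded from the default 450 nm set.

## Assays

Stern–Volmer is read as I₀/I = τ₀/τ = 1 + K_SV·[Q]; the package's default
triplet parameters are K_SV = 0.023 µM⁻¹ / τ₀ = 588 µs (visible PdP
assay) and K_SV = 0.03 µM⁻¹ (far-red BMAP assay), with [O₂] = 100 µM as
the physiological maximum.  Time gating multiplies a quenched spectrum by
e^(−t_start/τ) − e^(−t_end/τ).  The FRET acceptor expression carries no
bound-MT factor (the donor expression does); a symmetric variant is
available behind a flag.  FRET scalar defaults are SO = E = 1, κ² = 2/3,
ε_D/ε_A = 1 with bound fractions from configuration; two named presets
cover the 1 µM and 500 nM TRITC-ConA validation mixtures with placeholder
bound fractions, since the binding-equilibrium model is out of scope.

The far-red FRET readout additionally includes a directly excited Cy7
component (Φ = 0.30, μ_a = 42.5 cm⁻¹ at 680 nm) combined additively.

## Detectability

Minimum detectable power is implemented exactly as
P_min = NEP·√BW·S(λ)/S_max.  Because the multiplicative form makes a less
sensitive wavelength look easier to detect, a `physical` option divides by
S/S_max instead; the default keeps the multiplicative convention.  The shipped
photodiode sensitivity curve is a synthetic broad-response stand-in (the
real device curve is not publicly tabulated) and is replaceable by a
two-column file.  The exposure-limited source power is irradiance × area
(default 2 kW/m² × 0.16 cm² = 32 mW).

## Synthetic emission spectra

Dye and endogenous emission curves default to two-sided Gaussians
(independent blue/red half-widths, exact peak value 1 and exact requested
FWHM) with peaks at the wavelengths the assays are built around (APTS 520,
TRITC 580, PdP 700, Cy5.5 710, Cy7 779, BMAP 807 nm; collagen 520, FAD
535, vitamin A 500, melanin 550 / 695 nm).  Widths and skews are fixture
parameters, not measurements: passing tests demonstrate the machinery's
correctness and internal orderings (e.g. collagen dominating the 450 nm
autofluorescence peak), not agreement with any specific measured dye lot.

## Problem sizes and numerical choices

Full production runs use 1e7 photons per transport stage; the bundled
test-suite and acceptance-script runs use 1e5–2e6 photons and 4–8 emission
bins, the package's desk-scale defaults.  All stochastic bounds checked at
reduced counts are conservative: replicate COV and consecutive-count
differences shrink as 1/√N, so a bound met at small N holds a fortiori at
production N.  Attenuation factors use a third-order expansion of
exp(−μ_a·d) below μ_a·d = 1e-3 (per-step relative error < 1e-10);
Henyey–Greenstein cosines are clamped to [−1, 1]; g = 0 falls back to
isotropic sampling; zero-μ_t voxels are traversed ballistically.

## Known limitations

* The absolute absorbed fractions and the 680/450 fluence ratio depend
  strongly on the embedded chromophore tables and layer fractions, which
  approximate the standard compilations; sensitivities of order 2–5× on
  those quantities are expected when the dermal blood fraction moves
  within its literature range (0.2–2%).  Property files let users pin the
  curves of any specific reference build.
* No polarization, no Fresnel refraction, no time-of-flight transport
  (lifetimes are handled analytically), no curved anatomy or vascular
  heterogeneity, no secondary fluorescence, no source–detector offset.
* The glucose → bound-fraction equilibrium is an input, not a model.
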