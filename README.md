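# shgflux

Label-free second-harmonic (SH) imaging can watch individual Ca²⁺ ions cross
a lipid bilayer: SH emission is forbidden in centrosymmetric media, so a
charged giant unilamellar vesicle (GUV) lights up at its equator only while
its two leaflets are hydrated asymmetrically. Adding CaCl₂ to the outside
breaks the symmetry (Ca²⁺ binds the outer anionic headgroups and reorients
interfacial water); as ions passively translocate, symmetry — and darkness —
returns. The per-angle exponential decay time τ(θ) of the ring intensity is
therefore a spatially resolved measurement of membrane permeation.

`shgflux` is a tested, fully synthetic-data-driven reimplementation of that
measurement chain for scientists who want to analyze (or stress-test analyses
of) SH GUV time-lapse data:

* **`shgflux.synthetic`** — movie generator with known ground truth: a ring of
  radius R with Gaussian radial cross-section (PSF FWHM 0.4 µm),
  cos²(θ−θ_pol) polarization modulation, micrometre-scale rim domains via a
  correlated lognormal τ(θ) field, per-angle exponential intensity decay,
  and an EM-CCD noise model (Poisson shot noise × gain, Gaussian read noise,
  background offset, frame-correlated illumination flicker).
* **`shgflux.analysis`** — ring detection, polar transform with radial band
  integration, cos²θ normalization restricted to a 120° acceptance window
  per lobe, partition of the valid arcs into 25 ROIs, weighted
  exponential fits `I(t) = A·exp(−t/τ) + b`, decay-constant maps, integrated
  traces and noise-floor crossing times.
* **`shgflux.kinetics`** — bound-ion counts `N = σ·4πR²/q`, per-ion
  translocation times `τ_eff/N`, permeability coefficients
  `P = (N/τ_eff)/(4πR²·c·N_A)`, single-pore permeability `p = flux/(c·N_A)`,
  Grahame surface potentials, and competitive Ca²⁺-binding equilibria
  (membrane vs indicator dye).
* **`shgflux.energetics`** — a parametric pore free-energy surrogate G(ξ) on
  a normalized defect-connectivity coordinate (flat membrane at ξ = 0.2,
  open pore at ξ ≈ 0.95) with transmembrane-voltage tilt, plus Kramers
  rates, exact 1-D mean-first-passage integrals and an overdamped Langevin
  oracle.
* **`shgflux.pipeline`** — reproducible simulate → analyze → kinetics →
  energetics runs with a checksummed manifest, and a `shgflux` CLI.

The numbered scripts under `analysis/` are narrative drivers that exercise
the library end to end and write their tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_movies.py
python analysis/02_decay_mapping.py
```

prints, for the mono-unsaturated (DOPC:DOPA) vesicle:

```
detected ring: center 31.48,31.50 px, R = 9.98 um
decay map: 25/25 ROIs with finite tau, tau 5.9-9.5 min (ratio 1.61, mean 7.6 min)
integrated trace crosses the noise floor at t = 960 s
```

The detected geometry matches the generated vesicle (R = 10 µm at the frame
center); every ROI yields a finite decay constant inside the ground-truth
4–13 min range; and the integrated SH intensity becomes indistinguishable
from the measured noise floor within ~16 min of salt addition. Running
`analysis/03_composition_comparison.py` adds the composition phenomenology —
a ~10× slower mean τ with cholesterol, 96–100 % of ROIs flagged “no decay”
for the branched (DPhPC:DPhPA) and poly-unsaturated (SLPC:SLPA) membranes,
and a ~3× spatial spread of τ along the rim of replicate vesicles — and
`analysis/04`/`05` convert the map into per-ion translocation times
(tens of µs), permeability coefficients (~10⁻⁹–10⁻¹⁰ cm/s at 5 mM),
the ~10⁻¹² cm³/s single-pore permeability, and the pore-barrier ordering
DOPC < DOPC:Chol < DPhPC under voltage tilt.

Each quantity comes straight from the code; rerunning with the same seeds
reproduces the numbers exactly.

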