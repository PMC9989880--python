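# Methods

## Physical picture and model

A charged GUV in electrolyte emits second-harmonic light from oriented
interfacial water. With identical leaflets the interface is centrosymmetric
and dark; Ca²⁺ bound to the *outer* leaflet orients water on one side only
and the equatorial section appears as a bright ring. SH intensity is
proportional to the *square* of the net oriented-water amplitude, so if the
leaflet asymmetry Γ(θ, t) relaxes exponentially the measured intensity decays
with time constant τ(θ) and the amplitude with 2τ(θ). Throughout the package
presets parameterize the **intensity** decay time, the quantity an
experimenter fits; the stored asymmetry is the square root of the intensity
envelope.

The angular intensity modulation cos²(θ − θ_pol) comes from the projection of
the optical field onto the membrane interface; the radial cross-section of
the ring is the microscope PSF (Gaussian, FWHM 0.4 µm by default).

## Synthetic data generator

The generator emulates a time-lapse acquisition (default 30 frames, 60 s
period, 5 s accumulation, 64×64 px at 0.4 µm/px, R = 10 µm) with ground
truth attached. Features and defaults, with reasons:

* **τ(θ) field** — log τ is a stationary Gaussian field on the circle
  (FFT-smoothed white noise) with correlation length set by the rim-domain
  scale (2 µm at a 10 µm reference radius, i.e. ~11°; bright/dark domains of
  1.5–3 µm are the observed scale), min–max rescaled in log space so
  max(τ)/min(τ) is *exactly* the preset heterogeneity. Lognormality keeps
  τ > 0. Defaults: threefold heterogeneity with geometric-mean base
  √(240·780) ≈ 433 s, so the field spans ≈ 4–13 min — the range of published
  single-ROI fits. The cholesterol preset multiplies the base by 10 (the
  reported average slowdown); the branched (DPhPC:DPhPA) and
  poly-unsaturated (SLPC:SLPA) presets are infinite-τ (no translocation).
* **Noise model** — expected crest signal 450 counts (90 counts/s × 5 s)
  over a 100-count background with 3-count read noise: per-pixel crest SNR
  ≈ 19 with EM gain 1. Counts are `gain·Poisson(signal/gain) + N(0, read) +
  background`, clipped at zero. In addition each frame's *signal* is
  multiplied by a global illumination factor with 2 % RMS
  (`flicker_rel_sd`): wide-field SH intensity scales as the square of the
  fundamental power, so a ~1 % pulse-energy fluctuation appears as ~2 %
  frame-correlated scatter. This term, not camera noise, dominates the
  variance of the *integrated* single-GUV trace (which averages over ~10³
  pixels) and is what makes a decayed trace indistinguishable from noise at
  a few percent of its initial level — without it the synthetic integrated
  trace would be ~50× cleaner than real single-vesicle traces and would
  never "vanish" on the observed timescale while τ runs to 13 min.
* **Seeding** — one integer seed; every draw site derives a child generator
  from (seed, tag path) via SeedSequence, so sub-operations are
  order-independent and movies are bit-reproducible.

What the generator does **not** emulate: vesicle drift and shape
fluctuations, domain rearrangement over time (τ(θ) is static), multi-GUV
fields, depth-of-focus effects, nonlinear wave propagation and phase
matching, intensifier fixed-pattern noise. Passing tests therefore
demonstrate correctness of the *measurement chain* under the stated
phenomenology, not robustness to every instrumental artifact of real data.

## Measurement chain

* **Ring detection** maximizes the mean bilinearly interpolated intensity on
  a circle: centroid + radial-profile initialization, Nelder–Mead
  refinement. A ring must exceed the background by 5 robust σ (median/MAD)
  or a no-ring error is raised. The radial integration band half-width
  defaults to 2× the PSF FWHM.
* **Polar transform** integrates the interpolated image over
  r ∈ [R − band, R + band] with the polar area element r dr (0.25 px steps),
  so profile × bin width conserves the band-integrated intensity (verified
  to 2 %).
* **cos² normalization and masking** divides by cos²(θ − θ_pol) and keeps
  two arcs of ±60° around the polarization-aligned lobes (120° acceptance
  per lobe); bins with cos² < 0.05 are additionally masked so the
  normalization never amplifies noise by more than 20×. Masked bins are
  excluded from every downstream statistic (verified by perturbation).
* **ROIs** — the valid arcs are partitioned into 25 contiguous equal-angle
  ROIs (largest-remainder allocation across arcs, never spanning a masked
  region). Whether the published 25 ROIs covered one lobe or both is not
  stated; both the count and the partition policy are configurable.
* **Traces** — per-frame background (median outside r > R + 3·band) is
  subtracted by default, then ROI traces are sums of normalized valid bins.
  Raw and t = 0-normalized integrated traces are both written, since it is
  unknown whether published integrated traces were normalized.
* **Decay fits** — weighted least squares of `A·exp(−t/τ) + b` with
  Poisson-motivated weights, variance floored at 2 % of the trace maximum
  (integrated, normalized intensities are not raw counts; without the floor,
  near-zero tail points dominate χ² and destabilize slow-τ fits).
  Log-linear-regression initialization, bounded restarts (×0.3, ×3, ×10 on
  τ₀). `no_decay` is flagged when the fitted relative amplitude
  A/(A+b) < 0.1 or τ exceeds 50× the observation span; the baseline is
  fitted, not pinned to the noise floor, for robustness to background drift.
  Under 5 % multiplicative noise (30 points / 30 min) the estimator is
  median-unbiased to < 1 %; the per-replicate spread is set by information
  content, with Cramér–Rao relative sd 2.6 %/4.0 %/6.6 % at τ = 4/9/13 min,
  so individual fits at the slow end scatter beyond 5 % no matter the
  estimator.
* **Noise floor** — the quantitative analogue of the dashed noise-level
  line on an integrated-trace plot: the maximum of (i) a camera floor,
  the identical band integration run on a signal-free control circle at
  0.5 R (mean + 3 σ over frames, scaled by the ring-radius ratio), and
  (ii) an illumination floor, 3× the detrended per-frame relative scatter
  of the trace (median absolute deviation of point/3-frame-running-mean,
  which is insensitive to a smooth decay) times the initial intensity.
  Crossing time is the first timestamp where the 3-frame running mean dips
  to the floor; a trace that never does is censored.

## Translocation kinetics

With headgroup charge density σ = 1 mC/m² and R = 10 µm, the outer leaflet
binds N = σ·4πR²/q ions — q = 2e if each Ca²⁺ neutralizes two unit charges
(`divalent_2e`, default 3.9×10⁶ ions) or q = e per binding site
(`monovalent_site_e`, 7.8×10⁶). Per-ion translocation time is τ_eff/N; for
the fastest published ROI (τ = 240 s) this gives 31–61 µs depending on
convention, bracketing the published 22–30 µs — the published arithmetic is
not reproducible exactly under either convention, so the convention is an
explicit user choice recorded in every result. The permeability coefficient
P = (N/τ_eff)/(4πR²·c·N_A) at the experimental c = 5 mM is then
4×10⁻¹⁰–9×10⁻¹⁰ cm/s, about an order of magnitude below the published
~10⁻⁸ cm/s — that printed value does not follow from the printed σ, R, τ
and c under any convention we could construct, and the package reports what
the formula gives. τ_eff defaults to the intensity decay time of the
integrated trace; an option converts to the amplitude time (2τ).

Electrostatics: the Grahame relation is solved for ψ₀ by bracketed Brent
iteration to 10⁻⁹ V (T = 298.15 K, ε_r = 78.4; concentrations treated as
activities). Dye competition solves the coupled 1:1 equilibria for free
Ca²⁺ by monotone root finding; with membrane K_D in the 10⁻⁸–10⁻¹¹ M range
against a 325 nM indicator dye, under 1 % of Ca²⁺ ends up on the dye — the
quantitative form of the negative indicator-dye result.

## Pore energetics surrogate

G(ξ) = G₀(ξ) − q_eff·F·|V|·s(ξ) on a normalized defect-connectivity
coordinate: G₀ is a raised-cosine well (ξ = 0.2) → crest (ξ = 0.7) →
metastable open plateau (ξ = 0.95, at 40 % of the barrier); s(ξ) is a
smoothstep from flat to open state (capacitive energy release grows with
defect connectivity). Default barriers 30/45/60 kJ/mol for
DOPC / DOPC:Chol / DPhPC with q_eff 0.5/0.3/0.3 e encode only the published
*ordering* and DOPC's stronger voltage sensitivity; absolute heights are
configuration, not claims. The ordering and the monotone barrier decrease
hold over the full 0–600 mV range used in constant-potential simulations.

Rates: the Kramers closed form uses local quadratic fits of well and barrier
curvature (fallback to the exact integral, flagged, below 1 kT); the exact
MFPT double integral (reflecting at ξ = 0, absorbing at the open state) is
always attached as reference. The Langevin oracle is Euler–Maruyama with a
step bounded by ≤ 0.5 kT drift energy and ≤ 0.025 diffusive step, recorded
in the result metadata. Validation runs on a matched double-parabola profile
(`double_parabola_pmf`), where the harmonic assumptions hold exactly and the
closed form agrees with the integral to ~2 % across 2–12 kT; on the smooth
raised-cosine composition profiles the closed form runs 13–21 % high
(anharmonicity plus post-barrier travel), which is expected behavior of the
approximation, not an implementation defect. Langevin replica counts taper
from 400 (low barriers) to 48 (12 kT) to keep the validation suite within
minutes; agreement is asserted at 3 standard errors.

Open-pore lifetimes and pore densities are not measurable here, so
macroscopic permeability is exposed as P = duty·p_pore/area together with
the inverse diagnostic (duty cycle required for a target P): with
p_pore ≈ 1.1×10⁻¹² cm³/s and a 10 µm GUV, P = 10⁻⁸ cm/s needs a duty cycle
of ~0.1 pore-equivalents — a useful consistency scale, not an assertion.

## Problem sizes and reproducibility

Default study sizes — 64×64 px movies, 30 frames (120 for the cholesterol
pair, whose slow decay needs a 2 h window), 25 ROIs, 200-replicate fit
calibrations, 5 replicate vesicles for population statements (the
experimental protocol observed ≥ 10 vesicles per condition) — were chosen so
every analysis is exactly reproducible from one integer seed and runs on a
laptop in minutes. Reported decay constants are in seconds internally and
minutes in displays.

## Known limitations

* The τ(θ) field is static; real rim domains fluctuate on second scales.
* Detection assumes a single, centered, non-drifting vesicle.
* The kinetics layer treats concentrations as activities and ignores
  chloride co-transport and binding-site saturation dynamics.
* The energetics module is a surrogate: it reproduces orderings and
  monotonicities, never absolute free energies or absolute opening rates.
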