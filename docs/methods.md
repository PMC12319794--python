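# Methods

`vasim` simulates steady-state gradient-echo (GE) and spin-echo (SE) BOLD
signal formation across cortical depth at 7 T from an explicit 3D vascular
network. This note documents the model, its assumptions, the numerical
choices, and what the synthetic inputs do and do not represent.

## Signal model

The voxel signal of each cortical lamina is the sum of an extravascular
(EV) term and two intravascular (IV) terms:

    S(t) = S_EV(t) + S_aIV(t) + S_vIV(t)

- **EV:** `S_EV(t) = (1 − bCBVa − bCBVv) · |A(t)| · exp(−t/T2₀⁽*⁾)`, where
  `|A(t)|` is the Monte-Carlo ensemble attenuation of diffusing tissue
  water and `T2₀* = 28.57 ms` (GE) / `T2₀ = 48.30 ms` (SE) are cortical
  grey-matter constants at 7 T. Only the macrovascular blood volume is
  subtracted from the water pool — the microvessel volume is deliberately
  retained in the EV weight, matching the reference formulation; a
  `subtract_micro=True` mode exists for sensitivity analysis.
- **IV:** `bCBV · exp(−t/T2_blood)` per compartment. Venous blood T2
  depends on oxygen saturation through an empirical 7 T lookup
  (GE 4.41→9.68 ms and SE 5.75→44.33 ms over SO₂ 50→90 %); arteries use
  the fixed 95 %-saturation values (9.87 / 49.67 ms). The microvascular IV
  contribution is null by assumption (capillary blood relaxation at 7 T is
  poorly characterized and its volume share is small).

The per-lamina metrics are the relative rate change
`ΔR2⁽*⁾ = (R2_state/R2_tissue − 1)·100`, with `R2_state` from a degree-one
fit to `ln S(t)` over `[0, TE]`, and the relative signal change
`ΔBOLD = (S(TE)/exp(−TE/T2₀⁽*⁾) − 1)·100`. Both are referenced to the
pure-tissue baseline, so `ΔBOLD` is negative (blood presence plus
dephasing cost signal) and rises toward zero as venous SO₂ increases;
statements like "GE peaks at X %" refer to the amplitude `|ΔBOLD|`, and
all GE-vs-SE orderings in the tests are amplitude comparisons.

### Physiology

Per-compartment oxygen saturation: arteries 95 %, veins one of fifteen
values 50–92 % (step 3), microvessels the arterio-venous midpoint
`SO2art − (SO2art − SO2vein)/2`. Vessel-size-dependent hematocrit from the
systemic value: arteries ×0.90, microvessels ×0.70, veins ×1.20 (the venous
surplus models red-cell stalling in venules). Defaults: systemic Hct 45 %,
sweep 35–55 % in steps of 2.5.

The venous-T2 tables stop at the 90 % column while the saturation list
extends to 92 %; the lookup interpolates monotone rates `R2 = 1/T2` with a
shape-preserving (PCHIP) spline and extends the last 0.90→0.92 step
*linearly* with the endpoint derivative — the cubic tail itself is not
monotone and would make venous T2 non-increasing near 92 %.

## Frequency field

Each vessel segment perturbs the field as an infinite paramagnetic
cylinder, evaluated only over the segment's axial extent:

    δω(r) = ½ · γ · B0 · Δχ · (R/r)² · cos 2θ · sin²ψ,
    Δχ = 4π·0.276·10⁻⁶ · Hct(R) · (1 − SO2)

with γ = 267.5×10⁶ rad s⁻¹ T⁻¹, B0 = 7 T along +z (normal to the pial
surface), ψ the axis-to-B0 angle and θ the azimuth between the radial
vector and the in-plane B0 projection. Offsets are accumulated in angular
units (rad/s) so phase integrates directly in radians; a `hz` mode divides
by 2π for sensitivity analysis. The voxel field is the superposition of
all segments on a regular grid (default 1 µm for oracle work, 3 µm for
laminar runs) together with an inside-vessel mask.

Numerical choices:

- **Axial truncation.** The per-segment expression is evaluated only where
  the field point's axial projection falls within the segment ± one radius
  (end effects neglected; curved vessels are polyline-subdivided upstream).
- **Cutoff.** Contributions beyond `r > √1000·R ≈ 31.6 R` (where the field
  falls to 10⁻³ of the wall value) are skipped; `cutoff_rel=None` gives the
  exact summation used by the oracle tests.
- **In-plane periodicity.** For laminar runs the eight in-plane periodic
  images of every segment are included so the field is consistent with the
  periodically wrapped random walk.
- **Linearity shortcut.** The field is linear in each segment's Δχ, which
  within a compartment is the common scalar `4π·0.276e-6·Hct_c·(1−SO2_c)`.
  Per-compartment unit fields ("field basis") are therefore precomputed
  once and any oxygenation/hematocrit state is a 3-weight linear
  combination — and, because trajectories depend only on the vessel mask,
  the per-spin phase of *every* state in a sweep is obtained from the same
  random walk by re-weighting per-compartment phase integrals.

## Monte-Carlo dephasing

Extravascular walkers take isotropic Gaussian steps with per-axis standard
deviation `√(2·D·dt)` (D = 1 µm²/ms, dt = 0.025 ms) and accrue phase
`φ += δω(x)·dt` with trilinear field interpolation. Rules:

- Steps landing inside a vessel (nearest-node mask test) are rejected and
  redrawn, up to 10 attempts, after which the walker stays in place for
  that step — the vascular network is impermeable.
- x/y exits wrap periodically, preserving phase.
- A walker touching the pial (z ≤ 0) or white-matter (z ≥ L) face
  invalidates its whole path; a fresh walker is simulated in its place.
  Restarts draw a *new* extravascular starting position within the same
  lamina slab (up to 100 path attempts): restarting from the original
  position never terminates for walkers seeded within ~1 µm of a face,
  while lamina-local redraws preserve per-lamina walker counts. Phantom
  runs (no cortical faces) use fully periodic boundaries instead.
- SE negates all accumulated phase at TE/2; GE reads free precession.
  Trajectories are sequence-independent, so one pass yields both readouts
  (GE truncated at its own TE).
- Lamina attribution is by initial position — walkers cross laminae during
  the walk, and the starting slab is the only unambiguous choice.
- RNG streams are counter-seeded per walker (and per restart), making
  results independent of execution order.

`A(t) = ⟨e^{−iφ(t)}⟩` is recorded per lamina on a subsampled time axis
(default every 8th step, 0.2 ms); phase is always integrated at the full
dt. The *magnitude* |A| enters the EV term (a global phase carries no
signal information at readout).

Desk-scale defaults are 10⁵ spins; the reference full-scale condition (20
repetitions × 5·10⁷ spins on ~mm³ two-photon vascular models) is
cluster-scale and is not run here. Statistical errors shrink as
`1/√(n_reps·n_spins)`; at 10⁵ spins the per-lamina attenuation noise is
~3·10⁻³, small against the percent-level laminar effects analyzed.

## Synthetic vasculature

Two generators provide inputs with the statistical structure the analysis
assumes, not anatomically faithful reconstructions:

- **Cylinder phantoms:** mono-sized cylinders with uniform random centers
  and orientations, added until a target volume fraction (analytic
  `Σ πR²L / V`; overlaps uncorrected, consistent with how baseline CBV is
  defined for vectorized data). Cylinder length is capped at 8 R and the
  box scales as 22 R so even a 100 µm phantom holds ≥ ~8 cylinders — full
  box-chords at large radii would leave one or two cylinders and an
  unusable orientation variance.
- **Cortical voxel:** ~0.6–1 mm² in plane, 1 mm deep (the lower end of the
  1–1.75 mm range of the source reconstructions; 16 laminae of 62.5 µm).
  Two pial veins (R 11–14 µm) span the plane, six pial arteries are
  250 µm surface stubs, giving the 3:1 artery:vein trunk ratio observed in
  humans; penetrating trunks descend with tapering radius and lateral
  jitter; a capillary bed of 50–100 µm segments (radius ~N(3, 0.5) µm,
  mild depth-axis orientation bias, density decaying to 0.7× at depth)
  fills the microvessel budget up to a 1.5 % total CBV. The generator
  enforces: top-250 µm CBV above the deeper mean (top lamina ~3.5 %,
  deeper ~1.3 %), total CBV within 20 % of target, determinism per seed.

What passing tests on these inputs show: the *biophysics* — vessel-size
regimes, GE/SE contrast, laminar ordering, hematocrit scaling — behaves
correctly. What they do not show: quantitative agreement with any real
angioarchitecture; the synthetic capillary bed has no true topology (no
connectivity, no flow), macrovascular branching is schematic, and absolute
slopes/amplitudes depend on the CBV distribution of the particular
network.

## Statistics

Response slopes (ΔR2⁽*⁾ or ΔBOLD versus venous SO₂ as a fraction, or
versus systemic hematocrit in percentage points) are ordinary
least-squares fits to laminar-group means. The central estimate is the
mean of per-repetition slopes and the 95 % CI is the t interval across
repetitions; pairwise slope comparisons use a two-sided Welch test on the
repetition slopes (guarded for degenerate zero-variance samples). The CI
machinery is calibration-tested: over 1000 synthetic trials with Gaussian
noise the interval covers an injected slope at the nominal ~95 %.

## Problem sizes used by the test suite and acceptance script

Chosen so the whole pipeline runs on a single core in minutes: cortical
voxel 600 µm × 600 µm × 1 mm at 3 µm grid spacing, 8 venous SO₂ levels
(50–92 % step 6), 2 repetitions × 5·10⁴ spins per state (shared across all
states of a sweep via the phase-basis trick); hematocrit sweep at 9 levels
and SO₂ 62 %; phantom regime sweep radii 1–100 µm at 2 % volume fraction,
1.5 T, 5 repetitions × 2·10⁴ spins; static-dephasing cross-check with one
100 µm cylinder at 10⁵ spins against a dense 2D quadrature of the exact
dipole field.

## Known limitations

- No EPI readout/k-space encoding effects, no CSF compartment, no
  transmembrane water exchange, no flow or dynamic CBF/CBV/CMRO₂ — the
  model is steady-state with an instantaneous readout.
- B0 is fixed normal to the pial surface; orientation dependence is out of
  scope.
- The vessel mask is resolved at the field-grid spacing, so walls are
  accurate to ~half a grid cell; sub-micron wall interactions at the
  smallest capillary radii require the finer phantom grids (0.5 µm).
- Overlapping vessels double-count volume in both CBV and the mask; the
  source data convention is the same and the effect is ≪ 1 % of CBV.
- The near-face invalidation rule slightly biases sampling within a
  diffusion length (~10 µm at SE TE) of the pial and white-matter faces.
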