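# Methods

This note documents the models implemented in `pchkit`, the conventions and
defaults chosen where several were defensible, and what the synthetic-data
generator does and does not emulate.

## Observation profile and brightness conventions

The detection profile is an ideal 3D Gaussian,
B(r) = exp(−2(x²+y²)/w0² − 2z²/z0²), normalized to 1 at the focus. All
lengths are micrometres, so volumes in μm³ equal femtolitres. Two integrals
recur:

- V_psf = ∫B dV = (π/2)^{3/2} w0² z0 — the profile-integrated volume;
- γ₂ = ∫B² dV / ∫B dV = 2^{−3/2} — the shape factor relating Mandel's Q to
  brightness (Q_molecular = γ₂·ε_bin for a single species).

**Brightness** ε is the detected count rate of one molecule at the focus
(cpsm). **Particle number** N is referenced to V_ref = V_psf. This pair is
the unique convention under which the mean count rate of a sample is
exactly ε·N, so a fit conserves intensity (ε_app·N_app = measured count
rate) and protomer concentrations ε_app·N_app/ε₁ follow without shape
factors. It also means the dye-calibrated "observation volume"
V = N/(C·N_A) returned by the pipeline equals V_ref: for a pure 3D-Gaussian
model the full count distribution depends on (concentration, ε) only, so
the fitted N is proportional to whatever reference volume the model uses,
and the calibrated volume reports that convention. Relative brightnesses —
the biological readout — are independent of the convention.

The default geometry is constructed from the calibrated volume rather than
from nominal beam parameters: `PSFGeometry.from_observation_volume(1.02,
aspect_ratio=4)` gives w0 ≈ 0.51 μm, z0 ≈ 2.02 μm, typical of a one-photon
confocal spot with a ~1 Airy-unit pinhole.

## Single-particle distribution and quadrature

For one particle uniform in V_ref,
p⁽¹⁾(k) = (1/V_ref)∫ Poisson(k; ε_bin B(r)) dV for k ≥ 1, with the closure
mass at k = 0. Using the volume-shell decomposition of the Gaussian (the
volume enclosed by B = e^{−t} is ∝ t^{3/2}) the integral becomes
∫₀^∞ √t · Poisson(k; ε_bin e^{−t}) dt, and the substitution t = s² removes
the square-root endpoint singularity, leaving a smooth integrand evaluated
with 400-point Gauss–Legendre quadrature on [0, √(ln ε_bin + 37)]. The
result is verified against the exact first moment
(mean = ε_bin·V_psf/V_ref) at 10⁻¹⁰ tolerance on every call; both first and
second factorial moments agree with closed forms to ~10⁻¹⁴ in tests.

For ε_bin > 1 the k ≥ 1 mass can exceed 1 when V_ref = V_psf (the
"single-particle distribution" is then not a distribution). The compound
population model is exactly invariant under (V_ref, N) → (rV_ref, rN), so
the mixture builder rescales with r = max(1, 2ε_bin) internally;
`single_particle_pch` raises with the required volume if called standalone
in that regime.

## Population histogram, mixtures, dead time

An open volume with Poisson-distributed particle number is a compound
Poisson: the probability generating function is exp(N(G₁(s) − 1)), and
species multiply generating functions. This is evaluated by FFT on a
support chosen so the neglected tail mass is < 10⁻¹² (auto-doubling k_max).

Detector dead time enters as a first-order per-bin count-loss transform:
each photon in a bin with k true counts is independently lost with
probability (k−1)·τ_d·f_s. For a Poisson source this reproduces
Q = −2Iτ_d to first order, i.e. exactly the linear model used to calibrate
the detector, and is applied both in the forward model (as a transform
matrix on the pmf) and in the simulator (as binomial thinning). The
approximation is valid for I·τ_d ≪ 1 — at 15 ns and ≤ 2×10⁶ counts/s the
loss is ≤ 3 %. Afterpulsing (each detected photon spawning a secondary with
probability p_a) is simulated and calibrated (intercept of the Q line,
p_a = intercept/2) but deliberately excluded from the fitted model, where
its effect is negligible at realistic p_a.

## Fitting

`fit_pch` minimizes the Pearson chi-square between observed and expected
bin frequencies. Tail bins are pooled so every pooled bin has expected
count ≥ 5; the pooling pattern is frozen from the initial-guess expected
distribution so the objective is continuous and the fit deterministic.
Optimization is trust-region least squares over log-parameters (positivity
without active bounds). Initialization follows the method of moments: the
dead-time-corrected Q gives ε_bin = Q/γ₂ and the mean gives N; three fixed
alternative starts (ε halved/doubled/quadrupled, N compensated) guard
against a poor moment estimate. The reduced chi-square uses
dof = pooled bins − 1 − 2·(number of species). Two-species fits share the
same machinery; they are exposed but the pipeline follows the two-state
*algebraic* route (below), as multi-species PCH decompositions need far
more photons than a 30-s trace provides.

## From brightness to biology

- **Fluorescence probability**: a tandem dimer against its monomer gives
  ε₂/ε₁ = 1 + p_f (intensity-weighted statistics of Binomial(2, p_f) lit
  labels), so p_f = ratio − 1 (0.7 for a HaloTag-JF646-like label).
- **Labeling correction**: ε_corrected = 1 + (ε_norm − 1)/p_f when
  ε_norm > 1, else ε_norm unchanged. With the generator's label statistics
  this correction exactly restores the ideal two-state curve for any
  mixture (shown in tests), not only for pure populations.
- **Two-state inversion**: with ideal ratios ε₂/ε₁ = 2 and ε₄/ε₁ = 4, the
  apparent relative brightness is (3x+1)/(x+1) (dimer) or (15x+1)/(3x+1)
  (tetramer); the closed-form inverse round-trips to 10⁻¹². Relative
  brightness slightly below 1 clips to x = 0 with a warning (measurement
  noise); above the pure-oligomer value it raises, since that indicates
  movement artifacts or higher-order species, not a valid fraction.
- **Per-cell aggregation**: mean and sample (n−1) SD over ≥ 3 spots, spots
  beyond 1.5σ dropped, mean recomputed once. The exclusion is a single
  pass — iterated trimming can cascade on the small spot counts involved.
- **Protomer concentration**: N₁ = ε_app·N_app/ε₁ protomers in the
  calibrated volume, divided by the labeling efficiency (default 0.7) to
  count unlabeled protein; computed on raw brightnesses before any
  normalization. Per-cell concentrations average the spots surviving the
  brightness exclusion.

## Kinetics

Dissociation: B(t) = A·e^(−t/τ) + C by nonlinear least squares
(`scipy.optimize.curve_fit`), initial guesses A = B(0)−B(end), C = B(end),
τ = range/3, bounds A∈[0,10], C∈[0,5], τ∈(0,10·range]; τ½ = ln2·τ;
R² = 1 − SS_res/SS_tot. Degenerate inputs (constant series, amplitude
collapsing, parameter at a bound) are flagged, not raised. Note that an
exponentially relaxing oligomer *fraction* pushed through the two-state map
is not exactly exponential in brightness; fitting brightness-space data
with a single exponential (as practice does) carries a small model bias
that grows with the initial fraction, while inverting to fraction space
first recovers the lifetime exactly — both behaviors are tested.

Photobleaching: frames 3–25 of a 50-frame series are retained by default,
renormalized so the first retained frame is 1 at t = 0, and fit to
I = e^(−kt) with k ≥ 0 (rising traces clip to 0 with a warning). Rates are
compared across fluorophores via E_C = P_λ·ϵ_λ. The acquisition-time bias
on oligomerization is 1 − e^(−ln2·t_acq/τ½): a 30-s read-out with a 4–9 min
half-life loses 3.8–8.3 % of the oligomer.

## Synthetic data

The snapshot generator draws, per bin, a Poisson particle number per
species, uniform positions, and Poisson counts with mean
Σ lit-labels·(ε/f_s)·B(r). An n-subunit species with per-label fluorescence
probability p_f is expanded into independent Poisson sub-populations with
fixed lit-label counts (exact by Poisson splitting) — this reproduces
ε_n/ε₁ = 1 + (n−1)p_f automatically. Particles are simulated explicitly
only where B ≥ 10⁻³; the remaining box contributes a Poisson background
with the exact (erf-based) mean. The neglected excess variance of that far
field biases Q by O(ε_bin·10⁻³·far-fraction) ≈ 10⁻⁶ — far below sampling
error anywhere in the tests. The box spans 8 beam waists laterally and 8
axial waists axially (profile truncation < 10⁻³, enforced).

The Brownian generator moves particles by Euler–Maruyama steps of SD
√(2DΔt) per axis with periodic boundaries, warning when a step exceeds
w0/2. Each trace holds its Poisson-drawn particle number fixed, so a
*single* trace's marginal is conditioned on that draw; pooling independent
traces restores the open-volume statistics exactly, which is how the
snapshot/diffusion equivalence is tested. Intensity drift multiplies the
rate by (1 + drift_slope·t/duration). D defaults to 25 μm²/s (a small
cytoplasmic protein); one-bin statistics are independent of it.

Kinetics/labeling tables add homoscedastic Gaussian noise (no noise model
is implied by averaged fluorescence readouts; this is the simplest honest
choice). The default labeling rate is 0.6 h⁻¹, which reaches 95 % of
plateau — the operational equilibrium definition used by the labeling
calibration — at 5.0 h, consistent with staining protocols that equilibrate
within 6 h.

What the generator does **not** emulate: photon-timestamp (sub-bin)
detector physics, triplet blinking, cell movement other than linear drift,
autofluorescence background, or scanning acquisitions. Passing tests
therefore validate the estimators under the stated photophysical model,
not robustness to every live-cell artifact; the QC stage (drift screening,
segment selection) is the automated surrogate for manual trajectory
inspection and cannot capture everything a human would reject.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seed and configuration give
bit-identical traces. Validation sizes were chosen to keep the full suite
around six minutes on one core while leaving large statistical margins:
Monte-Carlo/semi-analytic agreement at 10⁶ draws per configuration;
brightness/number recovery on 30-s, 20-kHz traces (6×10⁵ bins); the
dark/light population benchmark with 5 cells × 3 spots × 5-s traces per
condition at 30–80 nM. Measured recovery errors (≈1 % on ε and N, ±0.05 fL
on the volume, < 5 % on concentrations) sit several-fold inside the
tolerances asserted.

## Known limitations

- The first-order dead-time model saturates at high count rates
  (k·τ_d·f_s → 1); the simulator raises rather than extrapolate.
- The ideal 3D-Gaussian profile carries no out-of-focus correction;
  absolute ε may differ from instrument software using other shape
  conventions by a fixed factor, leaving relative brightness unaffected.
- Two-state inversion assumes exactly two species with ideal 2× or 4×
  brightness ratios after labeling correction; intermediate stoichiometries
  fold into an effective fraction.
- Single-exponential kinetics only; multi-exponential decays are flagged
  through residual structure (low R²) rather than modeled.
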