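# pchkit

Photon counting histogram (PCH) analysis for quantifying protein
oligomerization in living cells.

Single-point fluorescence fluctuation spectroscopy (FFS) parks a confocal
spot in a cell and records detected photons in short time bins (typically
20 kHz for 10–30 s). The histogram of counts per bin encodes two molecular
quantities: the **molecular brightness** ε (detected counts·s⁻¹·molecule⁻¹)
and the mean **particle number** N in the observation volume. Because a
homo-n-mer carries n labels, its brightness is ~n× that of the monomer —
brightness is a direct stoichiometry readout. `pchkit` implements the full
pipeline used to turn raw binned photon counts into oligomeric states and
absolute protomer concentrations for photoactivatable proteins (LOV domains,
cryptochromes) labeled with fluorescent proteins or HaloTag dyes:

- a semi-analytic PCH forward model for a 3D-Gaussian observation profile
  with first-order detector dead time, and a chi-square fitter for
  (ε_app, N_app);
- detector calibration from Mandel's Q of a constant source,
  Q = 2p_a − 2Iτ_d, and observation-volume calibration V = N/(C·N_A) from a
  dye of known concentration;
- conversion of fitted brightness into biology: per-cell aggregation with a
  1.5σ spot exclusion, labeling correction
  ε_corrected = 1 + (ε_norm − 1)/p_f, two-state monomer–dimer
  ((3x+1)/(x+1)) and monomer–tetramer ((15x+1)/(3x+1)) inversion, and
  protomer concentrations via ε_app·N_app = ε₁N₁;
- exponential kinetics: dissociation fits B(t) = A·e^(−t/τ) + C with
  τ½ = ln2·τ, and photobleaching fits I(t) = e^(−kt) compared across
  fluorophores via E_C = P_λ·ϵ_λ;
- a Monte-Carlo photon-stream simulator (independent snapshots or Brownian
  dynamics) with species mixtures, per-label fluorescence probability,
  detector dead time/afterpulsing and slow drift — every stage of the
  pipeline is testable against known ground truth without a microscope.

## The model in brief

A single particle uniformly distributed in a reference volume V_ref
produces counts

p⁽¹⁾(k) = (1/V_ref) ∫ Poisson(k; ε_bin·B(r)) dV,  B(r) = exp(−2(x²+y²)/w0² − 2z²/z0²),

and an open volume with Poisson-distributed particle number N is the
compound-Poisson mixture of convolution powers of p⁽¹⁾; mixtures multiply
generating functions. With ε the focal count rate and N referenced to
V_ref = ∫B dV, the fit conserves intensity exactly: ε_app·N_app equals the
measured count rate, which is what makes protomer concentrations
ε_app·N_app/ε₁ well defined. A fitted single-species model applied to a
mixture returns the intensity-weighted brightness
ε_app = (ε₁²N₁ + ε₂²N₂)/(ε₁N₁ + ε₂N₂).

## Worked example

Simulate a 10-s, 20-kHz acquisition of a 20 nM dye solution
(ε = 20,000 cpsm, 15 ns dead time), fit its PCH, and calibrate the
observation volume:

```sh
$ pchkit simulate --seed 7 --duration 10 --brightness 20000 --mean-count 3195 --out dye.csv
wrote 200000 bins, mean rate 244761.9 counts/s
$ pchkit fit-pch dye.csv --out dyefit.json
eps_app = 20012.6 cpsm, N_app = 12.277, reduced chi2 = 0.62, converged = True
$ pchkit calibrate-volume dyefit.json --concentration-nm 20 --out vol.json
V = 1.019 fL
```

The fit recovers the simulated brightness to 0.1 % and finds ~12.3
molecules in the observation volume; 12.28 particles at 20 nM is a 1.02 fL
confocal volume, and the calibration returns 1.019 fL. A brightness decay
after switching off the activating light fits the dissociation model:

```sh
$ pchkit kinetics decay.csv --out decayfit.json
tau = 12.013 min, half-life = 8.33 min, R2 = 0.9930
```

(the example `decay.csv` was generated with lifetime 12.594 min and 3 %
noise; the fitted half-life ln2·τ ≈ 8.3 min estimates the true 8.73 min).

In Python, the same algebra is one call each:

```python
>>> from pchkit import oligomer_fraction, correct_relative_brightness
>>> correct_relative_brightness(1.7, 1.0, p_f=0.7).value   # labeling correction
2.0
>>> oligomer_fraction(1.3, n_oligomer=2)                   # dimer fraction
0.17647058823529413
```

A corrected relative brightness of 1.3 under the monomer–dimer model means
18 % of particles are dimers.

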