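# Methods

`libsquant` quantifies the mass fraction of an adulterant (HFCS F55, HFCS
F90 or rape honey) mixed into acacia honey from laser-induced breakdown
spectra, using peak-intensity variables, partial least squares regression
and three variable-selection schemes. Because no measured spectra ship
with the package, a simulator generates physically structured stand-ins
for the full campaign; every stage downstream of the simulator works
identically on measured data supplied as CSV.

## Variables: emission-line peak intensities

The variable set is a fixed library of 43 emission lines between 247.88
and 859.49 nm, covering C, Si, Mg, Ca, Na, K, N, H(α), O, the CN violet
bands and four unassigned lines. For each line the model variable is the
*observed peak intensity*: the maximum spectral value on grid points
within ±0.25 nm of the nominal wavelength (`peak_extraction`). There is no
baseline subtraction, continuum removal or line-shape fitting — the raw
observed height is the variable. The half-window default of 0.25 nm keeps
the Na I 589.03/589.64 nm and K I 766.57/769.97 nm doublets in separate
windows while tolerating a few grid steps of wavelength mismatch. Note
that a handful of library pairs sit closer than the window (e.g.
822.28/822.43 nm), so those two variables share blended signal — exactly
as they would on an echelle instrument at this resolution.

## Regression model

Predictors are autoscaled: each column is mean-centred and divided by its
standard deviation with the n−1 denominator (the chemometrics
convention). The response y (adulterant fraction, 0–1) is centred but not
variance-scaled; with a single response the regression slope absorbs its
scale. A zero-variance predictor is an error at fit time, by design — it
indicates a degenerate variable, and the univariate screen flags such
lines instead.

The PLS1 model is computed with de Jong's SIMPLS: the cross-product
s = Xᵀy is repeatedly deflated against an orthonormal basis of the
X-loadings; each factor's weight vector is the current deflated s, its
score is normalised, and the regression vector is b = R q. Scores are
orthogonal by construction, and for a single response SIMPLS predictions
coincide with NIPALS PLS1 — the test suite checks both properties against
an independent NIPALS implementation and, at full rank, against ordinary
least squares.

The number of latent variables A is chosen by random 10-fold
cross-validation: folds are a seeded random partition into near-equal
parts, each fold's model (including its autoscaler — no leakage from
held-out samples) is refit on the remaining folds, and A minimises the
pooled RMSECV over 1..A_max (default 10), ties to the smaller A. If a
fold cannot support A_max factors the scan is capped with a warning.

Performance is summarised by the Pearson correlation r and RMSE between
predicted and actual fractions on the calibration, cross-validation and
external prediction sets. Reports render RMSE in percent; r is kept
signed internally and reported as a magnitude in univariate tables.

## Variable selection

All three schemes operate on the 63-sample calibration set; the reduced
model's LV count is re-chosen by CV after subsetting.

* **VIP** — computed from the full-variable model at its CV-chosen LV
  count: VIP_j = √(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a) with
  SS_a = q_a²·t_aᵀt_a, satisfying Σ_j VIP_j² = p exactly; variables with
  VIP > 1 are kept.
* **SR** — target projection: X is projected onto b/‖b‖, and SR_j is the
  ratio of explained to residual sum of squares of column j under that
  rank-one reconstruction. The cutoff is the upper-5 % F quantile with
  (n−2, n−3) degrees of freedom — 1.532 at n = 63. A variable with zero
  residual yields SR = +∞ and is always selected (with a warning).
* **GA** — binary chromosomes (one gene per line), fitness = −RMSECV of a
  PLSR on the chromosome's variables with the LV count chosen by an inner
  5-fold CV. Tournament selection (size 2), single-point crossover
  (p = 0.5), per-gene mutation (p = 0.01), elitism of 1, population 30,
  100 generations. Five independent seeded runs each contribute their best
  chromosome; the final mask keeps variables included in ≥ 60 % of runs,
  and the inclusion frequencies are the scores. An all-zero chromosome
  receives −∞ fitness. Fitness values are memoised per chromosome within
  a run. These hyperparameters are conventional for GA-PLS at p ≈ 43 and
  are all overridable via the study config.

## The simulator

`synthetic_data` emulates the measurement campaign, not the plasma: each
endmember is a vector of non-negative per-line amplitudes, a binary
mixture at adulterant fraction f has amplitudes (1−f)·pure + f·adulterant,
and a noiseless spectrum is a constant baseline (default 1 a.u.) plus one
Gaussian peak per line (height = amplitude, FWHM 0.30 nm) on a uniform
0.05 nm grid over 240–860 nm (12,401 points). The FWHM/grid pair resolves
the Na doublet while keeping arrays desk-sized. A measurement averages 100
simulated shots: the mean of n i.i.d. additive N(0, σ_shot) noises is
N(0, σ_shot/√n) per pixel and is drawn in one step; the averaged spectrum
is then clipped at zero.

Endmember amplitude structure (defaults; all ranges configurable):

| group | acacia | rape | HFCS F55 | HFCS F90 |
|---|---|---|---|---|
| Mg, Ca, K | base U(40,70) | ×U(0.6,0.8) | 0 | 0 |
| Na | U(70,90) | U(20,30) | U(2,5) | U(2,5) |
| C, CN | base U(20,50) | ×U(0.95,1.05) | ×U(1.04,1.10) | ×U(1.18,1.32) |
| H, O, N | base U(20,50) | ×U(0.97,1.03) | ×U(0.97,1.03) | ×U(1.10,1.20) |
| Si, Unknown | base U(10,30) | ×U(0.99,1.01) | ×U(0.99,1.01) | ×U(0.99,1.01) |

This encodes the qualitative elemental picture of the real samples:
mineral emissions present only in honeys, Na markedly stronger in acacia
than rape, organics present everywhere with F90 departing further from
acacia than F55 (so the F90 series is the easier univariate problem), and
the Si/unassigned lines essentially uninformative. Every line carries at
least ±1 % endmember-to-endmember jitter so that no peak-table column is
exactly constant even in noiseless runs — autoscaling would otherwise
reject it. The default per-shot noise SD of 20 a.u. (≈ 2 a.u. after
100-shot averaging, against mineral-line contrasts of roughly 10–80 a.u.)
produces a univariate-r spread across line groups comparable to a real
campaign: strong mineral lines near r ≈ 0.95+, weak-contrast organics in
mid-range, inert lines near zero.

What the simulator deliberately omits: plasma physics (Saha–Boltzmann
level populations, self-absorption), matrix effects beyond linear mixing,
wavelength drift, a structured continuum, and heteroscedastic or
correlated noise. Passing tests therefore demonstrate the correctness of
the chemometric machinery and its behaviour under controlled
signal-to-noise, not instrument-level realism; absolute r/RMSE values on
real spectra will differ.

The mixing design is fixed by the study: 21 calibration levels at 5 %
spacing (0–100 %) and 13 prediction levels at 8 % spacing (0–96 %), three
replicates each — 63 calibration and 39 prediction samples per adulterant.

## Randomness and determinism

Every stochastic component (amplitude draws, shot noise, CV folds, GA)
consumes seeds derived from a single master seed through a fixed
counter-style fan-out (`SeedSequence([master, *path])`, truncated to
31 bits). Branches are tagged by adulterant index and stage, so adding a
method or replicate never shifts the randomness of existing branches, and
a full study run is bit-reproducible from its master seed.

## Numerical choices and degenerate inputs

* Rank deficiency before the requested factor count raises an error
  naming the achievable rank (strict mode); inside CV the factorization
  is instead truncated and the largest achievable model stands in for
  higher counts.
* RMSECV ties choose the smaller A (guarding against overfitting);
  RMSE uses the n denominator throughout.
* Negative post-averaging intensities are clipped to zero.
* CSV writers use repr-shortest floats and a fixed column order, so a
  write is byte-deterministic and a read round-trips to 1e−12 relative;
  readers validate header monotonicity and name the offending row/column
  on malformed input.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full default study (3 adulterants × 4
methods on 63 + 39 samples with the GA settings above, ≈ half a minute).
Orchestration unit tests use a reduced GA (population 10–20, a few dozen
generations, 2–3 runs) — selection pressure, not search exhaustiveness,
is what those tests exercise. Monte-Carlo checks (noise-ladder
monotonicity, planted-variable recovery) use 10 seeds each.

## Known limitations

* Window-max extraction on blended line pairs (< 0.5 nm apart) makes a
  few variables piecewise-affine in the mixing fraction, so an exactly
  rank-one calibration matrix is only obtained from amplitude-level data;
  rendered noiseless studies are still recovered to RMSE < 1e−6 by the
  CV-chosen models.
* The GA is a stochastic search; only its seeded reproducibility and its
  recovery of planted predictors are guaranteed by tests, not global
  optimality.
* Univariate r/RMSE and Table-style model metrics depend on the simulator's
  amplitude and noise configuration; they characterise the pipeline, not
  any specific instrument.
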