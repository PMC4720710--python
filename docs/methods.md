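# Methods

## Forward model and dictionaries

A uniformly sampled signal g (N samples, default 96 hourly samples = 4
days) is modelled as g = H f + ε on a fixed grid of candidate periods
(default: integer periods 8–32 h, the circadian domain at 1-h precision).
Two dictionary conventions are provided:

* **summed** (default for the synthetic benchmark): one column per period,
  entries cos(2πt/p) + sin(2πt/p).  Each component is then a sinusoid of
  fixed phase π/4 and signed amplitude f_j; the PC vector has M entries and
  the amplitude spectrum is |f_j|.  On the default grids this 96×25 matrix
  has 2-norm condition number 56,798,802,860 — the ill-conditioning that
  motivates the Bayesian treatment.
* **split**: separate cosine and sine blocks (N×2M), so each period carries
  a free amplitude and phase; amplitudes are √(a_j²+b_j²).  This is the
  default wherever the component phases are unknown, i.e. for real
  recordings (`stability_scan`, the CLI raw-series path).

Columns are not normalised; any fixed column scaling would change the
conditioning number, which is itself a reported quantity.  The time origin
is t₁ = 0; a different origin only moves coefficient mass between the
cos/sin blocks, not the amplitudes.

## Hierarchical model

Sparsity of f is encoded by a Student's-t prior expressed as an infinite
Gaussian scale mixture: f_j | v_fj ~ N(0, v_fj) with v_fj ~ IG(α_f0, β_f0)
per coefficient.  The noise is non-stationary: ε_i | v_εi ~ N(0, v_εi) with
v_εi ~ IG(α_ε0, β_ε0) per sample.  All four constants default to the
non-informative value 0.001 (`IGHyperparameters`), so the variances are
data-driven; note that β₀ also acts as a floor on the inverse-gamma scales
and hence as a cap (α₀+½)/β₀ ≈ 500 on any expected precision.

### JMAP

Alternate optimisation of the joint negative log-posterior
L(f, v_ε, v_f): a weighted-ridge SPD solve for f (Cholesky, never an
explicit inverse), then closed-form conditional maximisers
v̂_εi = (β_ε0 + r_i²/2)/(α_ε0 + 3/2) and v̂_fj = (β_f0 + f_j²/2)/(α_f0 + 3/2).
Each block update minimises L exactly, so L is non-increasing per sweep
(asserted in tests).  The iteration converges to a *local* optimum whose
quality varies strongly with the noise realization; this instability is a
property of the method, reproduced and tested, not a defect of the
implementation.

### Posterior mean via variational Bayes

The posterior is approximated by a separable law minimising the KL
divergence.  Shape parameters are constant (α₀ + ½); expected precisions
are inverse-gamma inverse moments α/β.

*Partial separability* keeps a full normal factor for f:
Σ = (HᵀV̂_ε⁻¹H + V̂_f⁻¹)⁻¹, f̂ = Σ HᵀV̂_ε⁻¹ g, noise scales
β_εi = β_ε0 + ½[H_iΣH_iᵀ + r_i²], prior scales β_fj = β_f0 + ½(f̂_j² + Σ_jj).

*Full separability* factorises every coordinate.  The mean update is a
Gauss–Seidel sweep in ascending period order (each coordinate sees the
already-updated predecessors — the sequential reading of the coordinate
expectations; fixed order for determinism), var_j = 1/(‖V̂_ε^{1/2}H_j‖² + v̂_fj⁻¹).
The noise-scale update uses the diagonal-covariance quadratic term
Σ_j H_ij² var_j + r_i²; the variant without the square and the covariance
term that can be written down from the coordinate derivation is
dimensionally inconsistent and can go negative, so the squared form is
used throughout.

Initialisation for both schemes: all inverse-gamma factors at (α₀, β₀),
i.e. unit expected precisions; update order f → noise factors → prior
factors.

### Stopping

Relative change ‖f⁽ᵏ⁺¹⁾−f⁽ᵏ⁾‖/‖f⁽ᵏ⁾‖ < 1e-6, with a sweep cap of 200 for
JMAP and VBA-partial.  The full-separability scheme gets a cap of 5000:
one coordinate sweep moves f far less than one joint solve, and with the
strong correlation between adjacent-period columns the scheme needs on the
order of 2000 sweeps to reach its fixed point (each sweep is only O(N·K)).
Hitting the cap returns the current state with `converged=False` rather
than raising.

### Gaussian baselines

The comparison estimators tie all coefficients to a single shared variance
(stationary Gaussian prior, not sparsity-enforcing), with the same
per-sample noise treatment.  JMAP form: v̂_f = (β_f0 + ½Σ_j f_j²)/(α_f0 + 1 + K/2);
VBA form: a pooled IG factor with shape α_f0 + K/2 and scale
β_f0 + ½Σ_j(f̂_j² + Σ_jj).  With variances frozen both reduce to
ridge/Tikhonov solutions.  Their role is comparative: dense spectra and
larger PC errors than the sparse model on matched data (tested).

## Synthetic benchmark

`benchmark_experiment` generates the study conditions: 96 hourly samples,
summed-basis dictionary on the 8–32 h grid, sparse PC vector with peaks at
11, 15 and 23 h — unit amplitudes at 11 and 15 h, amplitude 2 at 23 h,
phases zero (the peak heights are a package default; only their ratios
matter, as the SNR fixes the overall noise scale).  Noise is i.i.d.
Gaussian rescaled so the *realized* ratio 10·log₁₀(‖g₀‖²/‖ε‖²) equals the
requested level (5/10/15 dB) exactly, making every experiment reproducible
from its seed.

What the generator does *not* emulate: non-Gaussian and autocorrelated
noise, trends and transients of real activity recordings, missing data,
and components off the integer period grid.  Passing the synthetic checks
therefore shows correct recovery under the model's own assumptions, not
performance guarantees on arbitrary recordings.

## Measured behaviour and known limitations

All error levels below are δx = ‖x−x̂‖²/‖x‖² at 5 dB on the benchmark
unless stated otherwise.

* JMAP: δg₀ typically ≈ 0.05, δf ranging roughly 0.03–0.3 across noise
  realizations with occasional much larger failures — the documented
  local-minimum instability.
* VBA (both schemes) from the non-informative cold start converges to
  fixed points with δf ≈ 0.03–0.25 (partial) and sometimes far worse
  (full).  Good fixed points with δf ≈ 0.01–0.1 exist — warm-starting
  either scheme at the truth reaches them — but the cold start often lands
  in basins where some per-sample noise variances collapse toward the
  β_ε0 floor and absorb signal.  A stationary (pooled) noise variance
  removes this failure mode entirely (δf 0.01–0.07 from the cold start);
  the per-sample model is kept because it is the model, and the pooled
  variant informs the Gaussian-baseline construction only.
* At 15 dB the partial scheme recovers the support cleanly: the three
  largest amplitudes are the true peaks and every spurious amplitude is at
  least 5× below the smallest true peak.  Partial and full separability
  agree at isolated peaks to a few percent; at the 23-h peak, whose
  neighbouring columns are strongly correlated, the coordinate-wise
  factorisation is biased and agreement is only ~10%.
* A 96-h window of an off-grid-phase sinusoid leaves a ±1 grid-step
  ambiguity in the dominant period, so moving-window scans of a 23-h
  rhythm may report 22–24 h in individual windows — still strictly more
  informative than the FFT, which is locked to 24 h on such windows.

## Preprocessing and stability scan

Real series are aggregated to hourly samples (mean by default, sum by
flag), zero-meaned and scaled so max|value| = 10; normalisation is applied
once to the full segment of interest, then 4-day windows (shift 1 day) are
cut.  The scan runs the chosen estimator per window, recording the
amplitude spectrum and the in-band dominant period (ties broken toward the
smaller period); a failing window (e.g. all zeros) yields a NaN row and
the scan continues.

## Degenerate inputs and numerics

Zero signals are rejected where an SNR or a relative error would be
undefined; the dictionary build rejects empty or non-monotone grids; the
SPD solves raise on indefinite systems (possible only with non-positive
variances, which are themselves rejected).  Posterior covariance is
obtained from the Cholesky factor of the precision matrix; its positive
definiteness is asserted in tests at every stage.
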