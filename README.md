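# pcbayes

Sparse Bayesian estimation of the periodic-component (PC) vector of short
biomedical time series, built for chronobiology: recordings of a few days
(locomotor activity, gene-expression bioluminescence) in which the dominant
rhythm sits near 24 h and must be located with 1-hour precision.

## The problem

A periodogram of a T-hour record only represents periods T/k.  On a 4-day
(96 h) record the representable periods inside the circadian domain
(8–32 h) are 8, 8.73, 9.6, 10.67, 12, 13.71, 16, 19.2, 24 and 32 h — there
is *nothing* between 19.2 and 32 h except 24 h, so a true 23-h rhythm is
reported at 24 h.  Separating 23, 24 and 25 h by Fourier analysis alone
would need 575 days of recording.

`pcbayes` instead poses the estimation as a linear inverse problem.  With a
dictionary H whose columns are sinusoids on a fixed period grid
(one column per integer period 8..32 h),

    g = H f + ε,

the PC vector f is sparse — a handful of biological rhythms — and H is
severely ill-conditioned (cond(H) ≈ 5.7·10¹⁰ for the default 96×25
dictionary), so the prior does the work.  Both f and the noise are given
normal–inverse-gamma (Student's-t, infinite Gaussian scale mixture)
hierarchies

    f_j | v_fj ~ N(0, v_fj),      v_fj ~ IG(α_f0, β_f0),
    ε_i | v_εi ~ N(0, v_εi),      v_εi ~ IG(α_ε0, β_ε0),

with non-informative constants (0.001).  The unknowns (f, v_ε, v_f) are
estimated by

* **JMAP** — joint maximum a posteriori by alternate optimisation
  (`run_jmap`),
* **PM via VBA, partial separability** — posterior mean under a mean-field
  approximation that keeps a full multivariate-normal factor for f
  (`run_vba_partial`),
* **PM via VBA, full separability** — every coordinate factorised;
  Gauss–Seidel coordinate updates (`run_vba_full`),

with FFT (`fft_period_spectrum`) and Gaussian-prior (`gaussian_jmap`,
`gaussian_pm`) baselines, a synthetic-experiment generator
(`benchmark_experiment`), preprocessing for real recordings (`preprocess`)
and a moving-window dominant-period stability scan (`stability_scan`).

Performance is measured as δx = ‖x − x̂‖²/‖x‖² on the PC vector (δf), the
noiseless signal (δg₀) and the data (δg).

## Worked example

`examples/simulate_and_estimate.py` generates the 4-day benchmark: a sparse
PC vector with peaks at 11, 15 and 23 h (23 h dominant), noise at a
realized 5-dB SNR, then runs every estimator:

```
dictionary: (96, 25), cond(H) = 56,798,802,860
realized SNR: 5.0 dB

method                    delta_f  delta_g0  dominant
JMAP (sparse)              0.0915    0.0531      23 h
VBA partial (sparse)       0.1181    0.0862      23 h
VBA full (sparse)          0.8031    0.2507      22 h
JMAP (Gaussian prior)      0.4510    0.0631      11 h
PM (Gaussian prior)        0.5621    0.1547      11 h
```

The sparse-prior estimators place the dominant period at (or next to) the
true 23 h — a value the FFT cannot even represent on this record — while
the Gaussian-prior baselines spread energy across the whole grid and miss
the dominant rhythm.  `examples/stability_scan.py` runs the moving-window
analysis on a week-long 23-h rhythm: the FFT reports 24 h in all four
4-day windows; the sparse estimator tracks 23 h to within one grid step.

A thin CLI wraps the same operations:

```sh
pcbayes simulate --snr-db 5 --seed 1 --out exp.csv
pcbayes estimate exp.csv --method vba-partial --out result.json
pcbayes window-scan series.csv --method vba-partial --out scan
```

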