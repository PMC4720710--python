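"""Generate the 4-day benchmark experiment and compare all estimators.

The true PC vector has peaks at 11, 15 and 23 h (23 h dominant); noise is
added at a realized 5-dB SNR.  For each method the script prints the
relative errors delta_f (PC vector), delta_g0 (noiseless signal) and the
estimated dominant period.  Small delta values with a 23-h dominant period
mean the sparse prior recovered the spectral content the FFT cannot see.
"""

import numpy as np

from pcbayes import (
    amplitude_spectrum,
    benchmark_experiment,
    condition_number,
    dominant_period,
    gaussian_jmap,
    gaussian_pm,
    l2_relative_error,
    run_jmap,
    run_vba_full,
    run_vba_partial,
)

exp = benchmark_experiment(snr_db=5.0, seed=0)
print(f"dictionary: {exp.dictionary.matrix.shape}, cond(H) = {condition_number(exp.dictionary):,.0f}")
realized = 10 * np.log10(np.sum(exp.g0**2) / np.sum(exp.noise**2))
print(f"realized SNR: {realized:.1f} dB\n")

runners = {
    "JMAP (sparse)": lambda: run_jmap(exp.g, exp.dictionary).f,
    "VBA partial (sparse)": lambda: run_vba_partial(exp.g, exp.dictionary).f_mean,
    "VBA full (sparse)": lambda: run_vba_full(exp.g, exp.dictionary).f_mean,
    "JMAP (Gaussian prior)": lambda: gaussian_jmap(exp.g, exp.dictionary).f,
    "PM (Gaussian prior)": lambda: gaussian_pm(exp.g, exp.dictionary).f_mean,
}

print(f"{'method':24s} {'delta_f':>8s} {'delta_g0':>9s} {'dominant':>9s}")
for name, run in runners.items():
    f_hat = run()
    df = l2_relative_error(exp.f_true.coefficients, f_hat.coefficients)
    dg0 = l2_relative_error(exp.g0, exp.dictionary.matrix @ f_hat.coefficients)
    dom = dominant_period(exp.dictionary.period_grid.periods, amplitude_spectrum(f_hat))
    print(f"{name:24s} {df:8.4f} {dg0:9.4f} {dom:7.0f} h")
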