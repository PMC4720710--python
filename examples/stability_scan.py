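"""Moving-window dominant-period stability of a week-long recording.

A synthetic 7-day hourly activity trace with a 23-h rhythm stands in for a
locomotor-activity recording.  After the standard preprocessing (hourly,
zero-mean, normalised to [-10, 10]) the series is cut into 4-day windows
shifted by one day; each window is analysed with the sparse Bayesian
estimator and with the FFT.  The FFT reports 24 h in every window (the only
representable period near 24 on a 96-h grid), while the sparse estimator
tracks the true 23-h rhythm to within one 1-h grid step.
"""

import numpy as np

from pcbayes import moving_windows, preprocess, stability_scan

rng = np.random.default_rng(42)
t = np.arange(7 * 24.0)
raw = 3.0 * np.cos(2 * np.pi * t / 23.0) + 0.5 * rng.standard_normal(t.size)

hourly = preprocess(raw, step_hours=1.0)
windows = moving_windows(hourly, window_days=4, shift_days=1)
print(f"{windows.source_length_days}-day series -> {len(windows.windows)} windows\n")

for method in ("vba-partial", "fft"):
    scan = stability_scan(windows, method)
    doms = ", ".join(f"{p:g} h" for p in scan.dominant)
    print(f"{method:12s} dominant period per window: {doms}")
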