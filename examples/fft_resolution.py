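"""Why a periodogram cannot resolve circadian periods on a 4-day record.

The DFT of a T-hour record only represents periods T/k.  This script prints
the representable circadian periods of a 96-h record, the neighbours of
24 h, the record length needed to separate 23/24/25 h, and where the FFT
places a pure 23-h component.
"""

import numpy as np

from pcbayes import (
    dominant_period,
    fft_neighbor_periods,
    fft_period_spectrum,
    minimal_record_length,
)

periods, _ = fft_period_spectrum(np.zeros(96), step=1.0)
in_band = periods[(periods >= 8) & (periods <= 32)]
print("Representable periods of a 96-h record inside 8-32 h:")
print("  " + ", ".join(f"{p:.2f}" for p in sorted(in_band)))

below, above = fft_neighbor_periods(24.0, 96.0)
print(f"Neighbours of 24 h on the 96-h grid: {below:g} h and {above:g} h")
print("  -> every component between those values is attributed to 24 h.")

hours = minimal_record_length({23, 24, 25})
print(f"Separating 23/24/25 h needs {hours} h = {hours // 24} days of recording.")

t = np.arange(96.0)
grid, amps = fft_period_spectrum(np.cos(2 * np.pi * t / 23.0), step=1.0)
print(f"A pure 23-h cosine over 96 h peaks at {dominant_period(grid, amps):g} h via FFT.")
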