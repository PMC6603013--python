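"""2D correlation spectroscopy of a concentration-perturbed series.

A 12-band compound measured at six concentrations (0.2-10 in volume
percent) gives a synchronous map whose diagonal carries one autopeak per
responding band; the suitability screen shows how small concentration spans
drown the autopeaks in instrument noise.
"""

import numpy as np

from nirassign import autopeaks, concentration_suitability, correlate
from nirassign.synthetic import (make_magnolol_analog,
                                 simulate_concentration_series)

mag = make_magnolol_analog()
concs = (0.2, 0.4, 0.6, 9.6, 9.8, 10.0)
series = simulate_concentration_series(mag, concs)
result = correlate(series, stride=4)
peaks = autopeaks(result)
print(f"noiseless series: {len(peaks)} autopeaks at",
      [f"{p.position_nm:.0f}" for p in peaks], "nm")

grid = np.arange(1100.0, 2500.5, 1.0)


def builder(c, noise_sd, seed):
    return simulate_concentration_series(mag, c, grid, noise_sd, seed)


base = np.array(concs)
sets = [list(base * s) for s in (0.25, 1.0, 4.0)]
table = concentration_suitability(builder, sets, noise_sd=1.9, seed=0,
                                  expected_bands=12, window=None, stride=4)
print("\nsuitability under noise (sd 1.9 AU):")
print(table.to_string(index=False))
print("\nLarger concentration spans raise the signal variance on the "
      "diagonal; only sufficiently wide series recover all 12 bands.")
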