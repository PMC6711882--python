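"""Estimate ERP components trial by trial with Mexican-hat template matching.

Embeds a known P3 (peak 450 ms, breadth 400 ms, amplitude 4 uV) in a noisy
epoch, scans Mexican-hat templates over a lag x scale grid, and reads the
component's amplitude/latency/breadth off the cross-covariance extreme.
"""

import numpy as np

from mweeg import synth
from mweeg.containers import default_time_axis
from mweeg.sterp import detect_component, mexican_hat, wavelet_cross_covariance

time_ms = default_time_axis()
rng = np.random.default_rng(0)

true_amp, true_lat, true_scale = 4.0, 450.0, 400.0
signal = true_amp * mexican_hat((time_ms - true_lat) / true_scale)
signal += synth.pink_noise(time_ms.shape, exponent=0.0, sd=1.0, rng=rng)

s_grid = np.geomspace(200, 1400, 32)  # candidate breadths, ms
wmap = wavelet_cross_covariance(signal, time_ms, s_grid)
feat = detect_component(wmap, (250.0, 600.0), polarity=+1, component="P3")

print(f"embedded:  peak {true_lat:.0f} ms, breadth {true_scale:.0f} ms")
print(f"detected:  peak {feat.lag_ms:.0f} ms, breadth {feat.scale_ms:.0f} ms, "
      f"W = {feat.amplitude:.1f} ({feat.found})")
print("-> W scales linearly with the embedded amplitude; the extreme's "
      "coordinates give single-trial latency and width without any averaging")
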