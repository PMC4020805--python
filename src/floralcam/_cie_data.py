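"""CIE daylight-series component data.

Standard colorimetric tables at 10 nm spacing, 300-830 nm: the mean daylight
component S0 and the first two characteristic vectors S1, S2 used to
synthesise daylight spectral power distributions for a given correlated
colour temperature.
"""

import numpy as np

CIE_S_WAVELENGTHS_NM = np.arange(300.0, 831.0, 10.0)

# columns: S0, S1, S2
CIE_S_COMPONENTS = np.array([
    [0.04, 0.02, 0.00],
    [6.00, 4.50, 2.00],
    [29.60, 22.40, 4.00],
    [55.30, 42.00, 8.50],
    [57.30, 40.60, 7.80],
    [61.80, 41.60, 6.70],
    [61.50, 38.00, 5.30],
    [68.80, 42.40, 6.10],
    [63.40, 38.50, 3.00],
    [65.80, 35.00, 1.20],
    [94.80, 43.40, -1.10],
    [104.80, 46.30, -0.50],
    [105.90, 43.90, -0.70],
    [96.80, 37.10, -1.20],
    [113.90, 36.70, -2.60],
    [125.60, 35.90, -2.90],
    [125.50, 32.60, -2.80],
    [121.30, 27.90, -2.60],
    [121.30, 24.30, -2.60],
    [113.50, 20.10, -1.80],
    [113.10, 16.20, -1.50],
    [110.80, 13.20, -1.30],
    [106.50, 8.60, -1.20],
    [108.80, 6.10, -1.00],
    [105.30, 4.20, -0.50],
    [104.40, 1.90, -0.30],
    [100.00, 0.00, 0.00],
    [96.00, -1.60, 0.20],
    [95.10, -3.50, 0.50],
    [89.10, -3.50, 2.10],
    [90.50, -5.80, 3.20],
    [90.30, -7.20, 4.10],
    [88.40, -8.60, 4.70],
    [84.00, -9.50, 5.10],
    [85.10, -10.90, 6.70],
    [81.90, -10.70, 7.30],
    [82.60, -12.00, 8.60],
    [84.90, -14.00, 9.80],
    [81.30, -13.60, 10.20],
    [71.90, -12.00, 8.30],
    [74.30, -13.30, 9.60],
    [76.40, -12.90, 8.50],
    [63.30, -10.60, 7.00],
    [71.70, -11.60, 7.60],
    [77.00, -12.20, 8.00],
    [65.20, -10.20, 6.70],
    [47.70, -7.80, 5.20],
    [68.60, -11.20, 7.40],
    [65.00, -10.40, 6.80],
    [66.00, -10.60, 7.00],
    [61.00, -9.70, 6.40],
    [53.30, -8.30, 5.50],
    [58.90, -9.30, 6.10],
    [61.90, -9.80, 6.50],
])

assert CIE_S_COMPONENTS.shape == (CIE_S_WAVELENGTHS_NM.size, 3)
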