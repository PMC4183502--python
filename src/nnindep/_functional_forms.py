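"""Frozen functional forms for the benchmark dependencies.

The constants follow the noise-benchmark script of Simon & Tibshirani
(centered quadratic/cubic, sine of period 0.5 on the unit interval, fourth
root, binary step, unit circle).  They are collected here, once, so that every
part of the package — sampling, grid densities, MI calibration — uses the
identical shapes.
"""

from __future__ import annotations

import numpy as np

FUNCTIONAL_KINDS = (
    "linear",
    "quadratic",
    "cubic",
    "sine_p05",
    "fourth_root",
    "step",
)

#: y = f(x) on x in [0, 1]
FUNCTIONS = {
    "linear": lambda x: x,
    "quadratic": lambda x: 4.0 * (x - 0.5) ** 2,
    "cubic": lambda x: 128.0 * (x - 1 / 3) ** 3
    - 48.0 * (x - 1 / 3) ** 2
    - 12.0 * (x - 1 / 3),
    "sine_p05": lambda x: np.sin(4.0 * np.pi * x),
    "fourth_root": lambda x: x ** 0.25,
    "step": lambda x: (x > 0.5).astype(float),
}

#: circle: (cos theta, sin theta), theta ~ U(0, 2 pi), radius 1
CIRCLE_RADIUS = 1.0

ALL_KINDS = FUNCTIONAL_KINDS + ("circle", "patchwork")
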