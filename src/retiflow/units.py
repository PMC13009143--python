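"""Centralized unit conventions and conversions.

Internal units are fixed across the package: velocity in mm/s, volume
rate in uL/min, stroke volume in nL, diameter in um, frequency in Hz,
spectral moments in Hz^2. All conversions live here so no module carries
its own constants.
"""

import numpy as np

#: 1 uL/min expressed in nL/s (1000 nL per uL, 60 s per min).
NL_PER_S_PER_UL_MIN = 1000.0 / 60.0


def flow_ul_min(mean_velocity_mm_s, area_um2):
    """Volume rate through a cross-section.

    Q = v_bar * A with v in mm/s and A in um^2:
    v[mm/s] * 1e-3 [m/s] * A[um^2] * 1e-12 [m^2] = v*A*1e-15 m^3/s
    = v*A*1e-15 * 1e9 [uL/s] * 60 = v*A*6e-5 uL/min.
    """
    return np.asarray(mean_velocity_mm_s) * np.asarray(area_um2) * 6e-5


def circular_area_um2(diameter_um):
    """Lumen area assuming a circular cross-section, um^2."""
    d = np.asarray(diameter_um, dtype=float)
    return np.pi * (d / 2.0) ** 2


def ul_min_s_to_nl(q_times_t):
    """Convert an integral of (uL/min) over seconds to nL."""
    return np.asarray(q_times_t) * NL_PER_S_PER_UL_MIN
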