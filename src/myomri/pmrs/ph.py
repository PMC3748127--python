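"""Intracellular pH from the Pi-PCr chemical-shift difference.

Henderson-Hasselbalch calibration of the inorganic-phosphate resonance:
pH = pKa + log10((d - d_min) / (d_max - d)) with pKa = 6.75 and the acid and
base shift limits d_min = 3.27, d_max = 5.69 ppm.
"""

from __future__ import annotations

import math

from .priors import PH_DELTA_MAX_PPM, PH_DELTA_MIN_PPM, PH_PKA


def compute_phi(
    delta_pi_ppm: float,
    pka: float = PH_PKA,
    delta_min: float = PH_DELTA_MIN_PPM,
    delta_max: float = PH_DELTA_MAX_PPM,
) -> float:
    """pH from the Pi chemical shift (ppm relative to PCr)."""
    if not (delta_min < delta_pi_ppm < delta_max):
        raise ValueError(
            f"Pi shift {delta_pi_ppm} ppm outside open interval "
            f"({delta_min}, {delta_max})"
        )
    return pka + math.log10((delta_pi_ppm - delta_min) / (delta_max - delta_pi_ppm))


def delta_for_ph(
    ph: float,
    pka: float = PH_PKA,
    delta_min: float = PH_DELTA_MIN_PPM,
    delta_max: float = PH_DELTA_MAX_PPM,
) -> float:
    """Inverse calibration: Pi shift (ppm) that a given pH produces."""
    r = 10.0 ** (ph - pka)
    return (delta_min + delta_max * r) / (1.0 + r)
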