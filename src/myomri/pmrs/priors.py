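"""Spectral prior knowledge for in vivo skeletal-muscle 31P spectra.

Chemical shifts are quoted in ppm relative to phosphocreatine (PCr = 0).
Standard literature values are used: Pi near +4.8 ppm (pH dependent),
gamma-ATP -2.48, alpha-ATP -7.52, beta-ATP -16.26 ppm; ATP doublets are 1:1
and the beta-ATP triplet 1:2:1 with J = 16.5 Hz.  The spectrometer frequency
defaults to 81.08 MHz (31P at 4.7 T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

SPECTROMETER_MHZ = 81.08  # 31P Larmor frequency at 4.7 T; Hz per ppm
J_ATP_HZ = 16.5

PCR_PPM = 0.0
PI_NOMINAL_PPM = 4.8
GATP_PPM = -2.48
AATP_PPM = -7.52
BATP_PPM = -16.26

# Henderson-Hasselbalch calibration of the Pi-PCr chemical shift
PH_PKA = 6.75
PH_DELTA_MIN_PPM = 3.27  # acid-limit Pi shift
PH_DELTA_MAX_PPM = 5.69  # base-limit Pi shift


@dataclass(frozen=True)
class Multiplet:
    """One resonance group: J-coupled components at fixed amplitude ratios.

    ``offsets_hz`` are component positions about the group centre; ``ratios``
    are the fixed internal amplitude fractions (they sum to 1), so the group
    amplitude parameter is the total area of the multiplet.
    """

    name: str
    nominal_ppm: float
    offsets_hz: Tuple[float, ...] = (0.0,)
    ratios: Tuple[float, ...] = (1.0,)
    damping_init_hz: float = 15.0
    ppm_window: float = 0.2  # search window about the nominal shift


def default_peaks(j_hz: float = J_ATP_HZ) -> Dict[str, Multiplet]:
    """PCr + Pi singlets, gamma/alpha-ATP doublets, beta-ATP triplet."""
    return {
        "PCr": Multiplet("PCr", PCR_PPM, damping_init_hz=10.0, ppm_window=0.2),
        "Pi": Multiplet("Pi", PI_NOMINAL_PPM, damping_init_hz=15.0, ppm_window=1.2),
        "gATP": Multiplet(
            "gATP", GATP_PPM, (-j_hz / 2, j_hz / 2), (0.5, 0.5), 25.0, 0.2
        ),
        "aATP": Multiplet(
            "aATP", AATP_PPM, (-j_hz / 2, j_hz / 2), (0.5, 0.5), 25.0, 0.2
        ),
        "bATP": Multiplet(
            "bATP", BATP_PPM, (-j_hz, 0.0, j_hz), (0.25, 0.5, 0.25), 25.0, 0.2
        ),
    }


@dataclass(frozen=True)
class PriorKnowledge:
    """Peak table plus acquisition constants used by the time-domain fitter."""

    peaks: Dict[str, Multiplet] = field(default_factory=default_peaks)
    spectrometer_mhz: float = SPECTROMETER_MHZ

    def ppm_to_hz(self, ppm: float) -> float:
        return ppm * self.spectrometer_mhz

    def hz_to_ppm(self, hz: float) -> float:
        return hz / self.spectrometer_mhz
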