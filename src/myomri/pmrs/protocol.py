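"""Dynamic 31P acquisition protocol: rest/stimulation/recovery FID binning.

The standard protocol acquires one fully relaxed spectrum (12 accumulations,
TR 20 s), then 256 FIDs at TR 1.875 s (64 rest + 192 stimulation) and 512
recovery FIDs.  FIDs are summed coherently into bins: 64 rest -> 1 bin, the
stimulation FIDs by packets of 32 (-> 6 bins of ~60 s), and the recovery
FIDs by packets of 32, then 64, then one packet of 96 (-> 7 + 3 + 1 bins),
18 protocol bins in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

SWEEP_WIDTH_HZ = 8000.0
N_POINTS = 2048


class MrsProtocol(BaseModel):
    """Bin structure of the rest/stimulation/recovery acquisition."""

    tr_s: float = Field(default=1.875, gt=0)
    rest_relaxed_acquisitions: int = Field(default=12, gt=0)
    rest_relaxed_tr_s: float = Field(default=20.0, gt=0)
    rest_fids: int = 64
    stim_fids: int = 192
    stim_packet: int = 32
    recovery_layout: Tuple[Tuple[int, int], ...] = ((224, 32), (192, 64), (96, 96))
    sweep_width_hz: float = SWEEP_WIDTH_HZ
    n_points: int = N_POINTS

    @model_validator(mode="after")
    def _divisible(self) -> "MrsProtocol":
        if self.stim_fids % self.stim_packet:
            raise ValueError("stimulation packet size must divide the FID count")
        for total, packet in self.recovery_layout:
            if total % packet:
                raise ValueError(
                    f"recovery packet {packet} does not divide its block of {total}"
                )
        return self

    @property
    def recovery_fids(self) -> int:
        return sum(total for total, _ in self.recovery_layout)

    @property
    def total_fids(self) -> int:
        return self.rest_fids + self.stim_fids + self.recovery_fids

    @property
    def stim_start_s(self) -> float:
        return self.rest_fids * self.tr_s

    @property
    def recovery_start_s(self) -> float:
        return (self.rest_fids + self.stim_fids) * self.tr_s

    def bin_layout(self) -> List[Tuple[str, int]]:
        """(phase, FIDs-per-bin) for each protocol bin in acquisition order."""
        layout: List[Tuple[str, int]] = [("rest", self.rest_fids)]
        layout += [("stim", self.stim_packet)] * (self.stim_fids // self.stim_packet)
        for total, packet in self.recovery_layout:
            layout += [("recovery", packet)] * (total // packet)
        return layout

    @property
    def n_bins(self) -> int:
        return len(self.bin_layout())


@dataclass
class SpectrumSeries:
    """Binned complex FIDs with timing metadata.

    ``fids`` has shape (n_bins, n_points); ``fully_relaxed`` is the separate
    long-TR rest spectrum used for the PCr/ATP ratio.
    """

    fids: np.ndarray
    bin_phase: List[str]
    bin_start_s: np.ndarray
    bin_width_s: np.ndarray
    n_summed: np.ndarray
    sweep_width_hz: float = SWEEP_WIDTH_HZ
    spectrometer_mhz: float = 81.08
    fully_relaxed: Optional[np.ndarray] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mids = self.bin_mid_s
        if np.any(np.diff(mids) <= 0):
            raise ValueError("bin timestamps must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.fids.shape[0]

    @property
    def n_points(self) -> int:
        return self.fids.shape[1]

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sweep_width_hz

    @property
    def time_axis_s(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_s

    @property
    def bin_mid_s(self) -> np.ndarray:
        return self.bin_start_s + self.bin_width_s / 2.0


def bin_fids(raw_fids: np.ndarray, protocol: MrsProtocol) -> SpectrumSeries:
    """Sum raw FIDs coherently into protocol bins.

    ``raw_fids`` must contain exactly the protocol's FID count in acquisition
    order (rest, stimulation, recovery), shape (n_fids, n_points).
    """
    raw_fids = np.asarray(raw_fids)
    expected = protocol.total_fids
    if raw_fids.ndim != 2 or raw_fids.shape[0] != expected:
        raise ValueError(
            f"expected {expected} FIDs "
            f"({protocol.rest_fids} rest + {protocol.stim_fids} stim + "
            f"{protocol.recovery_fids} recovery), got shape {raw_fids.shape}"
        )
    layout = protocol.bin_layout()
    fids = np.empty((len(layout), raw_fids.shape[1]), dtype=complex)
    phases: List[str] = []
    starts = np.empty(len(layout))
    widths = np.empty(len(layout))
    counts = np.empty(len(layout), dtype=int)
    idx = 0
    for b, (phase, n) in enumerate(layout):
        fids[b] = raw_fids[idx : idx + n].sum(axis=0)
        phases.append(phase)
        starts[b] = idx * protocol.tr_s
        widths[b] = n * protocol.tr_s
        counts[b] = n
        idx += n
    return SpectrumSeries(
        fids=fids,
        bin_phase=phases,
        bin_start_s=starts,
        bin_width_s=widths,
        n_summed=counts,
        sweep_width_hz=protocol.sweep_width_hz,
    )
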