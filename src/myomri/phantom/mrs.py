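"""Dynamic 31P-MRS signal generator.

Metabolite kinetics during a rest/stimulation/recovery protocol:

* PCr is 100 % at rest, falls monoexponentially toward an end-of-stimulation
  plateau during stimulation, and recovers monoexponentially with time
  constant ``tau_recovery_s`` (the tau-PCr the analysis estimates).
* Pi mirrors PCr exactly (PCr + Pi is conserved), starting from a resting
  Pi pool expressed relative to resting PCr.
* pH ramps linearly from ``ph_rest`` to ``ph_end`` during stimulation and
  relaxes back exponentially during recovery; the Pi resonance moves along
  the Henderson-Hasselbalch calibration accordingly.

Each protocol bin synthesizes a 2048-point complex FID (8 kHz sweep) whose
component amplitudes are the kinetic model averaged analytically over the
bin's acquisition window, scaled by the number of summed FIDs.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ..pmrs.ph import delta_for_ph
from ..pmrs.priors import PriorKnowledge
from ..pmrs.protocol import MrsProtocol, SpectrumSeries


class MrsKinetics(BaseModel):
    """Ground-truth metabolic kinetics for the stimulation protocol.

    Amplitudes are in percent of resting PCr (PCr rest = 100).  The resting
    Pi pool defaults to 10 % of resting PCr; ATP amplitudes are constant at
    100 / ``pcr_atp_ratio`` so the fully relaxed spectrum carries the target
    PCr:beta-ATP area ratio.
    """

    pcr_end_stim_pct: float = Field(default=55.0, gt=0, le=100)
    tau_deplete_s: float = Field(default=60.0, gt=0)
    tau_recovery_s: float = Field(default=148.0, gt=0)
    ph_rest: float = 7.06
    ph_end: float = 6.80
    pi_rest_pct: float = Field(default=10.0, gt=0)
    pcr_atp_ratio: float = Field(default=3.5, gt=0)
    noise_sigma: float = Field(default=0.0, ge=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _sane(self) -> "MrsKinetics":
        if self.ph_end > self.ph_rest:
            raise ValueError("stimulation must not alkalinize: ph_end <= ph_rest")
        return self

    # --- truth time courses -------------------------------------------------

    def pcr_pct(self, t_s: np.ndarray, protocol: MrsProtocol) -> np.ndarray:
        """Instantaneous PCr (% of rest) at protocol time t."""
        t = np.asarray(t_s, dtype=float)
        t0, t1 = protocol.stim_start_s, protocol.recovery_start_s
        out = np.full(t.shape, 100.0)
        stim = (t >= t0) & (t < t1)
        end = self.pcr_end_stim_pct
        out[stim] = end + (100.0 - end) * np.exp(-(t[stim] - t0) / self.tau_deplete_s)
        rec = t >= t1
        pcr_t1 = end + (100.0 - end) * np.exp(-(t1 - t0) / self.tau_deplete_s)
        out[rec] = 100.0 - (100.0 - pcr_t1) * np.exp(
            -(t[rec] - t1) / self.tau_recovery_s
        )
        return out

    def pi_pct(self, t_s: np.ndarray, protocol: MrsProtocol) -> np.ndarray:
        """Pi in the same units (% of resting PCr); conservation with PCr."""
        return self.pi_rest_pct + (100.0 - self.pcr_pct(t_s, protocol))

    def ph(self, t_s: np.ndarray, protocol: MrsProtocol) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        t0, t1 = protocol.stim_start_s, protocol.recovery_start_s
        out = np.full(t.shape, self.ph_rest)
        stim = (t >= t0) & (t < t1)
        frac = (t[stim] - t0) / (t1 - t0)
        out[stim] = self.ph_rest + (self.ph_end - self.ph_rest) * frac
        rec = t >= t1
        out[rec] = self.ph_rest + (self.ph_end - self.ph_rest) * np.exp(
            -(t[rec] - t1) / self.tau_recovery_s
        )
        return out

    def _mean_over(self, fn, start: float, width: float, protocol: MrsProtocol) -> float:
        """Average of a kinetic time course over one bin window.

        Bins never straddle phase boundaries, and within a phase every time
        course is constant + exponential (or linear for stimulation pH), so a
        fine trapezoid on the closed-form course is exact to well below the
        fitting noise floor; 256 nodes keep it under 1e-6 relative.
        """
        ts = np.linspace(start, start + width, 257)
        return float(np.trapezoid(fn(ts, protocol), ts) / width)


def synthesize_fid(
    amplitudes: Dict[str, float],
    pi_delta_ppm: float,
    prior: PriorKnowledge,
    n_points: int,
    sweep_width_hz: float,
    dampings_hz: Optional[Dict[str, float]] = None,
    phase_rad: float = 0.0,
) -> np.ndarray:
    """Sum-of-damped-sinusoids FID for the given multiplet amplitudes.

    ``amplitudes`` are total multiplet areas (time-domain t=0 amplitudes);
    internal multiplet ratios and J-splittings come from the prior table.
    The Pi group is placed at ``pi_delta_ppm`` instead of its nominal shift.
    """
    t = np.arange(n_points) / sweep_width_hz
    fid = np.zeros(n_points, dtype=complex)
    for name, amp in amplitudes.items():
        if amp == 0:
            continue
        pk = prior.peaks[name]
        ppm = pi_delta_ppm if name == "Pi" else pk.nominal_ppm
        f0 = prior.ppm_to_hz(ppm)
        d = (dampings_hz or {}).get(name, pk.damping_init_hz)
        for off, ratio in zip(pk.offsets_hz, pk.ratios):
            fid += (
                amp
                * ratio
                * np.exp(-d * t)
                * np.exp(1j * (2 * np.pi * (f0 + off) * t + phase_rad))
            )
    return fid


# generator-side linewidths; deliberately not identical to the fitter's
# initial guesses so recovery is a genuine fit
TRUE_DAMPINGS_HZ = {"PCr": 9.0, "Pi": 14.0, "gATP": 24.0, "aATP": 26.0, "bATP": 28.0}


def simulate_mrs_series(
    kin: MrsKinetics,
    protocol: Optional[MrsProtocol] = None,
    prior: Optional[PriorKnowledge] = None,
) -> SpectrumSeries:
    """Simulate the binned dynamic series plus the fully relaxed rest spectrum.

    Noise: independent complex Gaussian per point per bin with sigma
    ``kin.noise_sigma`` on the single-FID amplitude scale (bins are stored as
    coherent sums, so bin noise scales with sqrt(n) while bin signal scales
    with n, exactly as summing noisy raw FIDs would give).
    """
    protocol = protocol or MrsProtocol()
    prior = prior or PriorKnowledge()
    rng = np.random.default_rng(kin.rng_seed)
    layout = protocol.bin_layout()
    atp = 100.0 / kin.pcr_atp_ratio

    fids = np.empty((len(layout), protocol.n_points), dtype=complex)
    phases, starts, widths, counts = [], [], [], []
    idx = 0
    for phase, n in layout:
        start = idx * protocol.tr_s
        width = n * protocol.tr_s
        pcr = kin._mean_over(kin.pcr_pct, start, width, protocol)
        pi = kin._mean_over(kin.pi_pct, start, width, protocol)
        ph = kin._mean_over(kin.ph, start, width, protocol)
        amps = {"PCr": pcr, "Pi": pi, "gATP": atp, "aATP": atp, "bATP": atp}
        fid = synthesize_fid(
            amps,
            delta_for_ph(ph),
            prior,
            protocol.n_points,
            protocol.sweep_width_hz,
            TRUE_DAMPINGS_HZ,
        )
        noise = kin.noise_sigma * np.sqrt(n) * (
            rng.standard_normal(protocol.n_points)
            + 1j * rng.standard_normal(protocol.n_points)
        )
        fids[len(phases)] = n * fid + noise
        phases.append(phase)
        starts.append(start)
        widths.append(width)
        counts.append(n)
        idx += n

    relaxed_amps = {
        "PCr": 100.0,
        "Pi": kin.pi_rest_pct,
        "gATP": atp,
        "aATP": atp,
        "bATP": atp,
    }
    relaxed = protocol.rest_relaxed_acquisitions * synthesize_fid(
        relaxed_amps,
        delta_for_ph(kin.ph_rest),
        prior,
        protocol.n_points,
        protocol.sweep_width_hz,
        TRUE_DAMPINGS_HZ,
    )
    relaxed = relaxed + kin.noise_sigma * np.sqrt(
        protocol.rest_relaxed_acquisitions
    ) * (
        rng.standard_normal(protocol.n_points)
        + 1j * rng.standard_normal(protocol.n_points)
    )

    return SpectrumSeries(
        fids=fids,
        bin_phase=phases,
        bin_start_s=np.array(starts),
        bin_width_s=np.array(widths),
        n_summed=np.array(counts),
        sweep_width_hz=protocol.sweep_width_hz,
        spectrometer_mhz=prior.spectrometer_mhz,
        fully_relaxed=relaxed,
        meta={"kinetics": kin.model_dump(), "protocol": protocol.model_dump()},
    )
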