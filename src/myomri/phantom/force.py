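"""Evoked-force signal generator: force-frequency and fatigue protocols.

Tetani are modelled as a saturating exponential rise during the stimulus
train, F(t) = F_plateau (1 - exp(-k t)), followed by monoexponential
relaxation from the peak, F_peak exp(-t / relax_tau_s).  The maximum rate of
force development is therefore F_plateau * k at train onset, and the
half-relaxation time is relax_tau_s * ln 2.  Twitches in the fatigue
protocol are scaled copies of the same pulse shape with their own (much
faster) time constants; their amplitudes follow a configurable decline
schedule (default: exponential decline to a plateau).

Per-train plateau force follows a Hill force-frequency curve
F(f) = F_max f^n / (f^n + f50^n), which is what the analysis module fits
back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator

DEFAULT_FREQUENCIES_HZ = (1.0, 10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0, 120.0, 150.0)


class ForceProtocolSpec(BaseModel):
    """Stimulation protocol plus ground-truth waveform parameters."""

    mode: Literal["force_frequency", "fatigue"] = "force_frequency"
    frequencies_hz: Tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    train_duration_s: float = Field(default=0.75, gt=0)
    rest_interval_s: float = Field(default=30.0, gt=0)
    fatigue_duration_s: float = Field(default=360.0, gt=0)
    fatigue_rate_hz: float = Field(default=1.7, gt=0)

    f_max_mN: float = Field(default=300.0, gt=0)
    hill_f50_hz: float = Field(default=40.0, gt=0)
    hill_n: float = Field(default=3.0, gt=0)
    rise_rate_k_per_s: float = Field(default=10.5, gt=0)
    relax_tau_s: float = Field(default=0.262 / math.log(2), gt=0)

    twitch_amplitude_mN: float = Field(default=60.0, gt=0)
    twitch_rise_s: float = Field(default=0.02, gt=0)
    twitch_relax_tau_s: float = Field(default=0.04, gt=0)
    fatigue_plateau_frac: float = Field(default=0.5, gt=0, le=1.0)
    fatigue_tau_s: float = Field(default=60.0, gt=0)
    fatigue_schedule: Optional[Tuple[float, ...]] = None  # per-15 s-bin factors

    sample_rate_hz: float = Field(default=10000.0, ge=1000.0)
    noise_sigma: float = Field(default=0.0, ge=0)
    rng_seed: int = 0

    @field_validator("frequencies_hz")
    @classmethod
    def _increasing(cls, v):
        arr = np.asarray(v)
        if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        return v

    def hill_force(self, f_hz: float) -> float:
        fn = f_hz**self.hill_n
        return self.f_max_mN * fn / (fn + self.hill_f50_hz**self.hill_n)

    def twitch_decline(self, t_s: float) -> float:
        """Relative twitch amplitude at fatigue-protocol time t."""
        if self.fatigue_schedule is not None:
            b = min(int(t_s // 15.0), len(self.fatigue_schedule) - 1)
            return self.fatigue_schedule[b]
        p = self.fatigue_plateau_frac
        return p + (1.0 - p) * math.exp(-t_s / self.fatigue_tau_s)


@dataclass
class ForceRecording:
    """Sampled force trace plus the stimulation schedule that produced it."""

    t_s: np.ndarray
    force_mN: np.ndarray
    schedule: Dict
    sample_rate_hz: float
    mode: str
    meta: Dict = field(default_factory=dict)


def _add_pulse(
    force: np.ndarray,
    t: np.ndarray,
    start_s: float,
    contract_s: float,
    amplitude: float,
    k_per_s: float,
    relax_tau_s: float,
    window_s: float,
) -> None:
    """Add one rise-then-relax pulse onto the trace in place."""
    sr = 1.0 / (t[1] - t[0])
    i0 = int(round(start_s * sr))
    i1 = min(int(round((start_s + contract_s) * sr)), t.size)
    i2 = min(int(round((start_s + contract_s + window_s) * sr)), t.size)
    if i0 >= t.size:
        return
    tr = t[i0:i1] - start_s
    force[i0:i1] += amplitude * (1.0 - np.exp(-k_per_s * tr))
    peak = amplitude * (1.0 - math.exp(-k_per_s * contract_s))
    td = t[i1:i2] - (start_s + contract_s)
    force[i1:i2] += peak * np.exp(-td / relax_tau_s)


def simulate_force_protocol(spec: ForceProtocolSpec) -> ForceRecording:
    """Simulate one full protocol run (all trains, or the 6-min twitch bout)."""
    rng = np.random.default_rng(spec.rng_seed)
    sr = spec.sample_rate_hz

    if spec.mode == "force_frequency":
        period = spec.train_duration_s + spec.rest_interval_s
        total_s = period * len(spec.frequencies_hz)
        n = int(round(total_s * sr))
        t = np.arange(n) / sr
        force = np.zeros(n)
        trains: List[Dict] = []
        for j, f in enumerate(spec.frequencies_hz):
            start = j * period
            n_pulses = int(math.floor(spec.train_duration_s * f)) + 1
            pulses = [start + i / f for i in range(n_pulses)]
            pulses = [p for p in pulses if p < start + spec.train_duration_s]
            _add_pulse(
                force,
                t,
                start,
                spec.train_duration_s,
                spec.hill_force(f),
                spec.rise_rate_k_per_s,
                spec.relax_tau_s,
                window_s=8.0 * spec.relax_tau_s,
            )
            trains.append(
                {
                    "frequency_hz": f,
                    "start_s": start,
                    "end_s": start + spec.train_duration_s,
                    "pulse_times_s": pulses,
                }
            )
        schedule = {"mode": spec.mode, "trains": trains}
    elif spec.mode == "fatigue":
        total_s = spec.fatigue_duration_s + 1.0
        n = int(round(total_s * sr))
        t = np.arange(n) / sr
        force = np.zeros(n)
        n_twitch = int(round(spec.fatigue_duration_s * spec.fatigue_rate_hz))
        k_tw = 5.0 / spec.twitch_rise_s  # ~99% of amplitude reached by end of rise
        times = []
        for i in range(n_twitch):
            ts = i / spec.fatigue_rate_hz
            amp = spec.twitch_amplitude_mN * spec.twitch_decline(ts)
            _add_pulse(
                force,
                t,
                ts,
                spec.twitch_rise_s,
                amp,
                k_tw,
                spec.twitch_relax_tau_s,
                window_s=8.0 * spec.twitch_relax_tau_s,
            )
            times.append(ts)
        schedule = {
            "mode": spec.mode,
            "twitch_times_s": times,
            "rate_hz": spec.fatigue_rate_hz,
            "duration_s": spec.fatigue_duration_s,
        }
    else:  # pragma: no cover - pydantic restricts the literal
        raise ValueError(f"unknown mode {spec.mode!r}")

    if spec.noise_sigma > 0:
        force = force + spec.noise_sigma * rng.standard_normal(force.shape)
    return ForceRecording(
        t_s=t,
        force_mN=force,
        schedule=schedule,
        sample_rate_hz=sr,
        mode=spec.mode,
        meta={"spec": spec.model_dump()},
    )
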