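"""Evoked-force analysis: train metrics, Hill force-frequency fit, fatigue.

Per stimulation train the analysis reports the baseline-subtracted isometric
peak force, the maximum rate of force development (centred-difference
derivative after light smoothing), and the half-relaxation time, i.e. the
time for force to fall from its post-train peak to 50 % of the decline
toward baseline.  Peak forces across frequencies are fitted to the Hill
force-frequency relation

    F(f) = F_max f^n / (f^n + f50^n)

with free exponent n and zero offset, so F(f50) = F_max / 2 by definition.
The 6-min twitch fatigue protocol is summarized as per-twitch peaks averaged
over consecutive 15-s bins, optionally normalized by muscle volume
(specific force, mN/mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .phantom.force import ForceRecording


@dataclass
class TrainMetrics:
    frequency_hz: float
    peak_force_mN: float
    max_dfdt_mN_per_ms: float
    half_relaxation_ms: float
    baseline_mN: float


@dataclass
class ForceFrequencyFit:
    f_max_mN: float
    f50_hz: float
    hill_exponent: float
    residual_rms: float
    peaks: pd.DataFrame  # frequency_hz, peak_force_mN
    converged: bool = True
    message: str = ""

    def force_at(self, f_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(f_hz, dtype=float)
        fn = f**self.hill_exponent
        return self.f_max_mN * fn / (fn + self.f50_hz**self.hill_exponent)

    def relative_curve(self, reference_hz: float = 150.0) -> pd.DataFrame:
        """Peak forces as a percentage of the force at the reference frequency."""
        ref = float(self.force_at(np.array([reference_hz]))[0])
        out = self.peaks.copy()
        out["relative_pct"] = 100.0 * out.peak_force_mN / ref
        return out


@dataclass
class FatigueSummary:
    bin_means_mN: np.ndarray
    bin_means_specific: Optional[np.ndarray]
    n_bins: int
    twitch_peaks_mN: np.ndarray
    twitch_times_s: np.ndarray


def _smooth(force: np.ndarray, sr_hz: float, window_ms: float) -> np.ndarray:
    w = max(int(round(window_ms * 1e-3 * sr_hz)), 1)
    if w <= 1:
        return force
    kernel = np.ones(w) / w
    return np.convolve(force, kernel, mode="same")


def train_metrics(
    recording: ForceRecording,
    train: Dict,
    baseline_ms: float = 50.0,
    smooth_ms: float = 1.0,
    hrt_smooth_ms: float = 5.0,
    deriv_window_ms: float = 21.0,
) -> TrainMetrics:
    """Analyze one stimulation train given its schedule entry.

    ``train`` is one element of ``recording.schedule['trains']`` (needs
    ``start_s``, ``end_s``, ``frequency_hz``, nonempty ``pulse_times_s``).
    The rate of force development uses a local-cubic (Savitzky-Golay)
    derivative over ``deriv_window_ms``: a plain centred difference amplifies
    sampling noise by the sample rate, while a cubic window tracks the
    curvature of the force onset where dF/dt peaks.
    """
    if not train.get("pulse_times_s"):
        raise ValueError("train window contains no stimuli")
    sr = recording.sample_rate_hz
    t, f = recording.t_s, recording.force_mN
    i_start = int(round(train["start_s"] * sr))
    i_end = int(round(train["end_s"] * sr))
    # analysis window runs to the next train (or end of trace)
    i_stop = min(int(round((train["end_s"] + 20.0) * sr)), t.size)

    i_base0 = max(i_start - int(round(baseline_ms * 1e-3 * sr)), 0)
    baseline = float(np.median(f[i_base0:i_start])) if i_start > i_base0 else 0.0

    fs = _smooth(f[i_start:i_stop], sr, smooth_ms) - baseline
    peak = float(fs[: i_end - i_start + int(0.05 * sr)].max())

    # the relaxation reference is the force maximum after the LAST stimulus:
    # on a noisy plateau a global argmax can land anywhere in the train.  The
    # half-relaxation is measured on a more heavily smoothed copy so the peak
    # estimate does not ride a noise spike (which would shift the crossing).
    fr = _smooth(f[i_start:i_stop], sr, hrt_smooth_ms) - baseline
    last_pulse = max(train["pulse_times_s"])
    j_last = max(int(round((last_pulse - train["start_s"]) * sr)), 0)
    j_hi = min(i_end - i_start + int(0.05 * sr), fr.size)
    rel0 = j_last + int(np.argmax(fr[j_last:j_hi]))

    w = max(int(round(deriv_window_ms * 1e-3 * sr)) // 2 * 2 + 1, 5)
    j0 = max(i_start - w, 0)
    dfdt = savgol_filter(f[j0:i_stop], w, 3, deriv=1, delta=1.0 / sr)  # mN/s
    dfdt = dfdt[i_start - j0 :]
    max_dfdt = float(dfdt[: max(rel0, 1)].max()) if rel0 > 0 else float(dfdt[0])

    # half-relaxation: from the post-train maximum down to 50% of the decline
    target = 0.5 * fr[rel0]
    below = np.nonzero(fr[rel0:] <= target)[0]
    if below.size == 0:
        hrt_ms = np.nan
    else:
        j = below[0]
        # linear interpolation between the straddling samples
        y1, y2 = fr[rel0 + j - 1], fr[rel0 + j]
        frac = (y1 - target) / (y1 - y2) if y2 != y1 else 0.0
        hrt_ms = (j - 1 + frac) / sr * 1e3
    return TrainMetrics(
        frequency_hz=float(train["frequency_hz"]),
        peak_force_mN=peak,
        max_dfdt_mN_per_ms=max_dfdt * 1e-3,
        half_relaxation_ms=float(hrt_ms),
        baseline_mN=baseline,
    )


def analyze_all_trains(recording: ForceRecording, **kwargs) -> pd.DataFrame:
    """Train metrics for every train in a force-frequency recording."""
    if "trains" not in recording.schedule:
        raise ValueError("recording carries no train schedule")
    rows = [
        vars(train_metrics(recording, tr, **kwargs))
        for tr in recording.schedule["trains"]
    ]
    return pd.DataFrame(rows)


def fit_force_frequency(
    frequencies_hz: Sequence[float], peaks_mN: Sequence[float]
) -> ForceFrequencyFit:
    """Fit the Hill force-frequency relation to per-train peak forces."""
    f = np.asarray(frequencies_hz, dtype=float)
    y = np.asarray(peaks_mN, dtype=float)
    if f.size < 4 or np.unique(f).size < 4:
        raise ValueError("need at least 4 distinct stimulation frequencies")
    table = pd.DataFrame({"frequency_hz": f, "peak_force_mN": y})
    if y.max() - y.min() < 1e-9 * max(abs(y.max()), 1.0):
        return ForceFrequencyFit(
            f_max_mN=float(y.mean()), f50_hz=np.nan, hill_exponent=np.nan,
            residual_rms=0.0, peaks=table, converged=False,
            message="flat force-frequency data",
        )

    def hill(ff, fmax, f50, n):
        fn = ff**n
        return fmax * fn / (fn + f50**n)

    p0 = (float(y.max()), float(np.median(f)), 2.0)
    try:
        popt, _ = curve_fit(
            hill, f, y, p0=p0,
            bounds=([0.0, f.min() * 0.1, 0.2], [np.inf, f.max() * 10.0, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return ForceFrequencyFit(
            f_max_mN=np.nan, f50_hz=np.nan, hill_exponent=np.nan,
            residual_rms=np.nan, peaks=table, converged=False, message=str(exc),
        )
    resid = y - hill(f, *popt)
    return ForceFrequencyFit(
        f_max_mN=float(popt[0]),
        f50_hz=float(popt[1]),
        hill_exponent=float(popt[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        peaks=table,
    )


def fatigue_summary(
    recording: ForceRecording,
    volume_mm3: Optional[float] = None,
    bin_s: float = 15.0,
    baseline_ms: float = 50.0,
) -> FatigueSummary:
    """Per-twitch peaks averaged over consecutive 15-s stimulation bins.

    Twitch peaks are the maxima of the baseline-subtracted trace between
    consecutive scheduled stimuli; bin membership follows the stimulus time.
    """
    sched = recording.schedule
    if "twitch_times_s" not in sched:
        raise ValueError("recording carries no twitch stimulation schedule")
    times = np.asarray(sched["twitch_times_s"], dtype=float)
    sr = recording.sample_rate_hz
    f = recording.force_mN
    i0 = int(round(times[0] * sr))
    b0 = max(i0 - int(round(baseline_ms * 1e-3 * sr)), 0)
    baseline = float(np.median(f[b0:i0])) if i0 > b0 else 0.0

    interval = 1.0 / sched.get("rate_hz", 1.0 / np.median(np.diff(times)))
    peaks = np.empty(times.size)
    for k, ts in enumerate(times):
        j0 = int(round(ts * sr))
        j1 = min(int(round((ts + interval) * sr)), f.size)
        peaks[k] = f[j0:j1].max() - baseline

    duration = float(sched.get("duration_s", times[-1] + interval))
    n_bins = int(np.floor(duration / bin_s))
    bins = np.minimum((times // bin_s).astype(int), n_bins - 1)
    means = np.array([peaks[bins == b].mean() for b in range(n_bins)])
    specific = None
    if volume_mm3 is not None:
        specific = specific_force(means, volume_mm3)
    return FatigueSummary(
        bin_means_mN=means,
        bin_means_specific=specific,
        n_bins=n_bins,
        twitch_peaks_mN=peaks,
        twitch_times_s=times,
    )


def specific_force(force_mN, volume_mm3: float):
    """Force normalized by hindlimb muscle volume (mN/mm^3); elementwise."""
    if volume_mm3 <= 0:
        raise ValueError("muscle volume must be positive")
    return np.asarray(force_mN, dtype=float) / volume_mm3
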