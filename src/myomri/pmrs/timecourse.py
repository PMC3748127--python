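"""Metabolite time courses and PCr recovery kinetics.

PCr and Pi are expressed as percent of their rest-bin amplitudes; pHi is
computed per bin from the fitted Pi-PCr shift; the resting PCr/ATP ratio
comes from the fully relaxed spectrum (PCr area over beta-ATP area).  The
post-stimulation PCr recovery is fitted with the monoexponential
PCr(t) = PCr_end - dPCr exp(-(t - t0)/tau), whose time constant tau-PCr
indexes muscle oxidative capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fitting import SpectrumFit, fit_spectrum
from .ph import compute_phi
from .priors import PH_DELTA_MAX_PPM, PH_DELTA_MIN_PPM, PriorKnowledge
from .protocol import SpectrumSeries


@dataclass
class RecoveryFit:
    """Monoexponential PCr recovery fit; flagged rather than raised on failure."""

    tau_s: float
    asymptote_pct: float
    delta_pct: float
    converged: bool
    message: str = ""
    residual_rms: float = np.nan


@dataclass
class MetaboliteTimeCourse:
    """Tidy per-bin table plus rest-spectrum summary quantities."""

    table: pd.DataFrame  # bin, t_s, phase, pcr_pct, pi_pct, phi
    pcr_atp_ratio: float
    recovery: Optional[RecoveryFit] = None
    fits: List[SpectrumFit] = field(default_factory=list, repr=False)


def pcr_atp_from_fit(fit: SpectrumFit) -> float:
    """Resting PCr/ATP ratio from the fully relaxed spectrum (beta-ATP area)."""
    return fit.amplitude("PCr") / fit.amplitude("bATP")


def build_time_course(
    series: SpectrumSeries,
    fits: Optional[Sequence[SpectrumFit]] = None,
    relaxed_fit: Optional[SpectrumFit] = None,
    prior: Optional[PriorKnowledge] = None,
    fit_recovery: bool = True,
    rng_seed: int = 0,
) -> MetaboliteTimeCourse:
    """Quantify every bin and assemble the normalized time course.

    Spectra are fitted here unless precomputed fits are supplied.  The first
    rest bin defines the 100 % level for PCr; Pi is normalized by the same
    factor scaled to its own resting amplitude, so the conserved PCr + Pi sum
    is visible in the table.  pHi is reported only where the fitted Pi shift
    falls inside the calibration's open interval.
    """
    prior = prior or PriorKnowledge()
    if fits is None:
        fits = [
            fit_spectrum(series.fids[b], series.sweep_width_hz, prior,
                         rng_seed=rng_seed + b)
            for b in range(series.n_bins)
        ]
    fits = list(fits)
    if len(fits) != series.n_bins:
        raise ValueError("need one spectral fit per bin")
    rest_idx = [i for i, ph in enumerate(series.bin_phase) if ph == "rest"]
    if not rest_idx or not fits[rest_idx[0]].converged:
        raise ValueError("missing or failed rest-bin fit; cannot normalize")
    rest = fits[rest_idx[0]]
    # bins are coherent sums of different packet sizes; convert amplitudes to
    # per-FID units before normalizing to the rest bin
    n_rest = series.n_summed[rest_idx[0]]
    pcr_rest = rest.amplitude("PCr") / n_rest
    pi_rest = rest.amplitude("Pi") / n_rest

    rows = []
    for b, fit in enumerate(fits):
        if fit.converged:
            pcr = 100.0 * fit.amplitude("PCr") / series.n_summed[b] / pcr_rest
            pi = 100.0 * fit.amplitude("Pi") / series.n_summed[b] / pi_rest
            delta = fit.delta_pi_ppm
            phi = (
                compute_phi(delta)
                if PH_DELTA_MIN_PPM < delta < PH_DELTA_MAX_PPM
                else np.nan
            )
        else:
            pcr = pi = phi = np.nan
        rows.append(
            {
                "bin": b,
                "t_s": series.bin_mid_s[b],
                "phase": series.bin_phase[b],
                "pcr_pct": pcr,
                "pi_pct": pi,
                "phi": phi,
            }
        )
    table = pd.DataFrame(rows)

    if relaxed_fit is None and series.fully_relaxed is not None:
        relaxed_fit = fit_spectrum(
            series.fully_relaxed, series.sweep_width_hz, prior, rng_seed=rng_seed + 99
        )
    pcr_atp = pcr_atp_from_fit(relaxed_fit) if (
        relaxed_fit is not None and relaxed_fit.converged
    ) else np.nan

    recovery = None
    if fit_recovery:
        rec = table[table.phase == "recovery"].dropna(subset=["pcr_pct"])
        t0 = float(
            series.bin_start_s[min(i for i, p in enumerate(series.bin_phase)
                                   if p == "recovery")]
        )
        recovery = fit_pcr_recovery(
            rec.t_s.to_numpy(), rec.pcr_pct.to_numpy(), t0=t0
        )
    return MetaboliteTimeCourse(
        table=table, pcr_atp_ratio=pcr_atp, recovery=recovery, fits=fits
    )


def fit_pcr_recovery(
    t_s: np.ndarray, pcr_pct: np.ndarray, t0: float = 0.0
) -> RecoveryFit:
    """Least-squares monoexponential recovery fit over the recovery bins.

    Requires at least 4 recovery points.  A flat course (no depletion left to
    recover) makes tau unidentifiable and is flagged, not raised.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(pcr_pct, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 recovery bins to fit tau")
    span = y.max() - y.min()
    if span < 1e-6 * max(abs(y.mean()), 1.0):
        return RecoveryFit(np.nan, float(y.mean()), 0.0, False,
                           "flat recovery: tau unidentifiable")

    def model(tt, end, delta, tau):
        return end - delta * np.exp(-(tt - t0) / tau)

    p0 = (float(y[-1]), float(max(y[-1] - y[0], 1e-3)), float((t[-1] - t0) / 3.0))
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return RecoveryFit(np.nan, np.nan, np.nan, False, str(exc))
    resid = y - model(t, *popt)
    return RecoveryFit(
        tau_s=float(popt[2]),
        asymptote_pct=float(popt[0]),
        delta_pct=float(popt[1]),
        converged=True,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
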