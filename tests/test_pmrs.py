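"""31P-MRS: binning, prior-knowledge fitting, pH calibration, recovery kinetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from myomri.phantom import MrsKinetics, simulate_mrs_series, synthesize_fid
from myomri.phantom.mrs import TRUE_DAMPINGS_HZ
from myomri.pmrs import (
    MrsProtocol,
    PriorKnowledge,
    bin_fids,
    build_time_course,
    compute_phi,
    delta_for_ph,
    fit_pcr_recovery,
    fit_spectrum,
    pcr_atp_from_fit,
)

SWEEP = 8000.0


def rest_amplitudes(pcr_atp=3.5):
    atp = 100.0 / pcr_atp
    return {"PCr": 100.0, "Pi": 10.0, "gATP": atp, "aATP": atp, "bATP": atp}


class TestBinning:
    def test_layout_is_18_bins_conserving_768_fids(self):
        prot = MrsProtocol()
        layout = prot.bin_layout()
        assert len(layout) == 18
        assert sum(n for _, n in layout) == 768 == prot.total_fids
        phases = [p for p, _ in layout]
        assert phases.count("rest") == 1
        assert phases.count("stim") == 6
        assert phases.count("recovery") == 11

    def test_coherent_sum_scales_with_packet_size(self):
        prot = MrsProtocol()
        fid = np.exp(1j * np.linspace(0, 4, 64))
        raw = np.tile(fid, (768, 1))
        series = bin_fids(raw, prot)
        np.testing.assert_allclose(series.fids[0], 64 * fid, rtol=1e-12)
        assert list(series.n_summed[:8]) == [64, 32, 32, 32, 32, 32, 32, 32]

    def test_stim_bin_width_is_60_seconds(self):
        prot = MrsProtocol()
        series = bin_fids(np.ones((768, 8), complex), prot)
        stim = [i for i, p in enumerate(series.bin_phase) if p == "stim"]
        np.testing.assert_allclose(series.bin_width_s[stim], 32 * 1.875)
        assert 32 * 1.875 == 60.0

    def test_recovery_bin_widths_follow_packet_layout(self):
        series = bin_fids(np.ones((768, 8), complex), MrsProtocol())
        rec = [i for i, p in enumerate(series.bin_phase) if p == "recovery"]
        widths = series.bin_width_s[rec]
        np.testing.assert_allclose(widths, [60] * 7 + [120] * 3 + [180])

    def test_wrong_fid_count_rejected_with_layout(self):
        with pytest.raises(ValueError, match="expected 768 FIDs"):
            bin_fids(np.ones((700, 8), complex), MrsProtocol())


class TestFitSpectrum:
    def test_single_damped_sinusoid_recovered_exactly(self):
        prior = PriorKnowledge()
        t = np.arange(2048) / SWEEP
        fid = 100.0 * np.exp(-10.0 * t)  # PCr at 0 ppm, damping 10 Hz
        fit = fit_spectrum(fid.astype(complex), SWEEP, prior, restarts=1)
        assert fit.converged
        pcr = fit.peaks["PCr"]
        assert pcr.amplitude == pytest.approx(100.0, abs=1e-4)
        assert pcr.damping_hz == pytest.approx(10.0, abs=1e-4)
        assert abs(pcr.frequency_hz) < 1e-4

    def test_rest_spectrum_pcr_atp_recovered_noiseless(self):
        prior = PriorKnowledge()
        fid = synthesize_fid(rest_amplitudes(3.5), delta_for_ph(7.06), prior,
                             2048, SWEEP, TRUE_DAMPINGS_HZ)
        fit = fit_spectrum(fid, SWEEP, prior, restarts=1)
        assert pcr_atp_from_fit(fit) == pytest.approx(3.5, rel=1e-4)

    def test_two_peak_amplitudes_match_grid_search_oracle(self):
        """Brute force: dense amplitude grid at known frequencies/dampings."""
        prior = PriorKnowledge()
        t = np.arange(2048) / SWEEP
        # PCr at 0 Hz and Pi ~30 Hz away: overlap resolved by the fitter
        f_pi = 30.0
        fid = (80.0 * np.exp(-10 * t)
               + 40.0 * np.exp(-14 * t) * np.exp(2j * np.pi * f_pi * t))
        prior_small = PriorKnowledge(
            peaks={k: v for k, v in prior.peaks.items() if k in ("PCr", "Pi")}
        )
        # widen nothing: place Pi window around its true position
        from myomri.pmrs.priors import Multiplet
        prior_small.peaks["Pi"] = Multiplet("Pi", f_pi / prior.spectrometer_mhz,
                                            damping_init_hz=14.0, ppm_window=0.3)
        fit = fit_spectrum(fid, SWEEP, prior_small, restarts=1)

        grid = np.linspace(20, 120, 401)
        b1 = np.exp(-10 * t)
        b2 = np.exp(-14 * t) * np.exp(2j * np.pi * f_pi * t)
        best, best_err = None, np.inf
        for a1 in grid:
            resid = fid - a1 * b1
            # optimal a2 given a1 (linear projection)
            a2 = np.real(np.vdot(b2, resid)) / np.real(np.vdot(b2, b2))
            err = np.linalg.norm(resid - a2 * b2)
            if err < best_err:
                best, best_err = (a1, a2), err
        assert fit.peaks["PCr"].amplitude == pytest.approx(best[0], rel=0.01)
        assert fit.peaks["Pi"].amplitude == pytest.approx(best[1], rel=0.01)

    def test_noisy_pcr_atp_within_three_percent(self, rng):
        """SNR 50 (PCr FID amplitude / per-point noise sigma)."""
        prior = PriorKnowledge()
        fid = synthesize_fid(rest_amplitudes(3.5), delta_for_ph(7.06), prior,
                             2048, SWEEP, TRUE_DAMPINGS_HZ)
        noisy = fid + 2.0 * (rng.standard_normal(2048)
                             + 1j * rng.standard_normal(2048))
        fit = fit_spectrum(noisy, SWEEP, prior, rng_seed=1)
        assert pcr_atp_from_fit(fit) == pytest.approx(3.5, rel=0.03)

    def test_residuals_white_on_simulated_spectra(self):
        """Ljung-Box portmanteau on fit residuals over several seeds."""
        from statsmodels.stats.diagnostic import acorr_ljungbox

        prior = PriorKnowledge()
        fid0 = synthesize_fid(rest_amplitudes(), delta_for_ph(7.0), prior,
                              2048, SWEEP, TRUE_DAMPINGS_HZ)
        rejected = 0
        n_seeds = 8
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            noisy = fid0 + 2.0 * (r.standard_normal(2048)
                                  + 1j * r.standard_normal(2048))
            fit = fit_spectrum(noisy, SWEEP, prior, rng_seed=seed)
            resid = (noisy - fit.model_fid).real
            p = acorr_ljungbox(resid, lags=[20]).lb_pvalue.iloc[0]
            rejected += p < 0.05
        assert rejected <= 2  # ~5% nominal rate; allow sampling slack

    def test_zero_fid_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            fit_spectrum(np.zeros(64, complex), SWEEP)


class TestPhCalibration:
    def test_midpoint_shift_gives_pka(self):
        assert compute_phi(4.48) == pytest.approx(6.75)

    def test_closed_form_value(self):
        assert compute_phi(4.60) == pytest.approx(6.8365, abs=5e-4)

    def test_round_trip_at_resting_ph(self):
        assert compute_phi(delta_for_ph(7.06)) == pytest.approx(7.06, abs=1e-12)

    def test_shift_outside_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_phi(3.27)
        with pytest.raises(ValueError):
            compute_phi(5.70)

    @given(st.floats(min_value=6.4, max_value=7.4))
    def test_inverse_is_exact_over_physiological_range(self, ph):
        assert compute_phi(delta_for_ph(ph)) == pytest.approx(ph, abs=1e-12)

    def test_calibration_strictly_monotonic(self):
        deltas = np.linspace(3.28, 5.68, 200)
        phs = [compute_phi(d) for d in deltas]
        assert np.all(np.diff(phs) > 0)


@pytest.fixture(scope="module")
def noiseless_tc():
    kin = MrsKinetics(tau_recovery_s=159.0, rng_seed=0)
    series = simulate_mrs_series(kin)
    return kin, build_time_course(series, rng_seed=0)


class TestTimeCourse:
    def test_rest_bin_normalized_to_100(self, noiseless_tc):
        _, tc = noiseless_tc
        rest = tc.table[tc.table.phase == "rest"]
        assert rest.pcr_pct.iloc[0] == pytest.approx(100.0, abs=1e-6)
        assert rest.pi_pct.iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_end_stim_pcr_matches_generator_truth(self, noiseless_tc):
        kin, tc = noiseless_tc
        prot = MrsProtocol()
        last_stim = tc.table[tc.table.phase == "stim"].iloc[-1]
        expected = kin._mean_over(
            kin.pcr_pct, prot.stim_start_s + 5 * 60.0, 60.0, prot
        )
        assert last_stim.pcr_pct == pytest.approx(expected, rel=1e-3)

    def test_pi_mirrors_pcr_with_conserved_sum(self, noiseless_tc):
        kin, tc = noiseless_tc
        # convert Pi back to absolute units (% of resting PCr) and check sum
        pi_abs = tc.table.pi_pct * kin.pi_rest_pct / 100.0
        total = tc.table.pcr_pct + pi_abs
        np.testing.assert_allclose(total, 100.0 + kin.pi_rest_pct, rtol=1e-3)

    def test_phi_tracks_stimulation_acidosis(self, noiseless_tc):
        kin, tc = noiseless_tc
        assert tc.table.phi.iloc[0] == pytest.approx(kin.ph_rest, abs=5e-3)
        assert tc.table.phi.min() < kin.ph_rest - 0.1

    def test_pcr_atp_from_fully_relaxed_spectrum(self, noiseless_tc):
        _, tc = noiseless_tc
        assert tc.pcr_atp_ratio == pytest.approx(3.5, rel=1e-3)

    def test_tau_recovered_from_full_pipeline(self, noiseless_tc):
        _, tc = noiseless_tc
        assert tc.recovery.converged
        assert tc.recovery.tau_s == pytest.approx(159.0, rel=0.01)


class TestRecoveryFit:
    def recovery_midpoints(self):
        prot = MrsProtocol()
        starts, idx = [], 0
        for ph, n in prot.bin_layout():
            starts.append((ph, idx * prot.tr_s, n * prot.tr_s))
            idx += n
        return (np.array([s + w / 2 for p, s, w in starts if p == "recovery"]),
                prot.recovery_start_s)

    def test_noiseless_exponential_tau_exact(self):
        mids, t0 = self.recovery_midpoints()
        y = 100.0 - 45.0 * np.exp(-(mids - t0) / 159.0)
        fit = fit_pcr_recovery(mids, y, t0=t0)
        assert fit.converged
        assert fit.tau_s == pytest.approx(159.0, rel=1e-9)
        assert fit.asymptote_pct == pytest.approx(100.0, rel=1e-9)

    def test_flat_recovery_flagged_unidentifiable(self):
        mids, t0 = self.recovery_midpoints()
        fit = fit_pcr_recovery(mids, np.full(mids.size, 80.0), t0=t0)
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_pcr_recovery(np.arange(3.0), np.arange(3.0), t0=0.0)

    def test_noisy_tau_matches_grid_search_oracle(self):
        """50 seeds at 2% noise: mean tau within 5% of truth and within 1%
        of a brute-force tau-grid oracle (end/delta solved linearly)."""
        mids, t0 = self.recovery_midpoints()
        truth = 100.0 - 45.0 * np.exp(-(mids - t0) / 159.0)
        taus, oracle_taus = [], []
        grid = np.linspace(60.0, 400.0, 1200)
        for seed in range(50):
            r = np.random.default_rng(seed)
            y = truth * (1 + 0.02 * r.standard_normal(mids.size))
            taus.append(fit_pcr_recovery(mids, y, t0=t0).tau_s)
            best, best_err = None, np.inf
            for tau in grid:
                x = np.exp(-(mids - t0) / tau)
                a = np.column_stack([np.ones_like(x), -x])
                coef, res, *_ = np.linalg.lstsq(a, y, rcond=None)
                err = np.linalg.norm(y - a @ coef)
                if err < best_err:
                    best, best_err = tau, err
            oracle_taus.append(best)
        assert np.mean(taus) == pytest.approx(159.0, rel=0.05)
        assert np.mean(taus) == pytest.approx(np.mean(oracle_taus), rel=0.01)
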