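"""Phantom construction and simulator signal models against closed forms."""

import math

import numpy as np
import pytest

from myomri.phantom import (
    ANTERIOR_LABEL,
    POSTERIOR_LABEL,
    Compartment,
    Ellipse,
    ForceProtocolSpec,
    MrsKinetics,
    PhantomSpec,
    build_phantom,
    mouse_hindlimb_spec,
    simulate_dixon,
    simulate_dwi,
    simulate_force_protocol,
    simulate_mrs_series,
    simulate_multiecho_t2,
)
from myomri.phantom.build import components_to_tensor, tensor_from_eigensystem
from myomri.pmrs import MrsProtocol


def single_ellipse_spec(**comp_kwargs):
    comp = Compartment(
        label=1,
        name="muscle",
        geometry=Ellipse(semi_axes_mm=comp_kwargs.pop("semi_axes_mm", (4.0, 3.0))),
        **comp_kwargs,
    )
    return PhantomSpec(grid=(128, 128, 3), compartments=[comp], rng_seed=0)


class TestBuildPhantom:
    def test_voxel_volume_matches_fov_and_matrix(self):
        spec = mouse_hindlimb_spec("WT")
        dx, dy, dz = spec.voxel_dims_mm
        assert dx == dy == pytest.approx(20.0 / 128)
        assert dx * dy * dz == pytest.approx(0.0244, abs=5e-5)

    def test_zero_fat_everywhere_gives_zero_truth_map(self):
        gt = build_phantom(single_ellipse_spec(fat_fraction=0.0))
        assert np.all(gt.fat_fraction == 0.0)

    def test_posterior_truth_t2_is_group_value(self, gt_tg):
        roi = gt_tg.mask(POSTERIOR_LABEL)
        assert roi.any()
        assert np.all(gt_tg.t2_ms[roi] == 19.8)

    def test_overlapping_compartments_error_names_voxel(self):
        a = Compartment(label=1, name="a", geometry=Ellipse(semi_axes_mm=(4, 3)))
        b = Compartment(label=2, name="b", geometry=Ellipse(semi_axes_mm=(3, 2)))
        spec = PhantomSpec(grid=(64, 64, 1), compartments=[a, b], rng_seed=0)
        with pytest.raises(ValueError, match=r"overlaps .* at voxel \(\d+, \d+, \d+\)"):
            build_phantom(spec)

    def test_rasterized_area_close_to_analytic_ellipse(self):
        gt = build_phantom(single_ellipse_spec(semi_axes_mm=(4.0, 3.0)))
        dx, dy, _ = gt.voxel_dims_mm
        area = gt.mask(1)[:, :, 0].sum() * dx * dy
        # tolerance: one voxel-width band around the perimeter (~ Ramanujan)
        a, b = 4.0, 3.0
        perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
        assert abs(area - math.pi * a * b) < perim * dx

    def test_tensor_truth_is_spd_with_requested_eigenvalues(self):
        d = tensor_from_eigensystem((1.95, 1.45, 1.07), (1, 1, 0))
        evs = np.linalg.eigvalsh(d)[::-1]
        np.testing.assert_allclose(evs, (1.95, 1.45, 1.07), atol=1e-12)
        assert np.allclose(d, d.T)

    def test_determinism_identical_spec_and_seed(self, gt_wt):
        a = simulate_dixon(gt_wt, noise_sigma=0.01, rng_seed=42)
        b = simulate_dixon(gt_wt, noise_sigma=0.01, rng_seed=42)
        assert np.array_equal(a.data, b.data)


class TestDixonSimulator:
    def test_pure_water_voxel_equal_magnitudes(self, gt_wt):
        gt = build_phantom(single_ellipse_spec(fat_fraction=0.0, b0_offset_hz=13.0))
        vol = simulate_dixon(gt)
        m = gt.mask(1)
        mags = np.abs(vol.data[m])
        np.testing.assert_allclose(mags[:, 0], mags[:, 1], rtol=1e-12)
        np.testing.assert_allclose(mags[:, 0], mags[:, 2], rtol=1e-12)

    def test_half_fat_voxel_cancels_on_opposed_echo(self):
        gt = build_phantom(single_ellipse_spec(fat_fraction=0.5, b0_offset_hz=0.0))
        vol = simulate_dixon(gt)
        assert np.abs(vol.data[gt.mask(1), 1]).max() < 1e-12

    def test_opposed_magnitude_is_water_minus_fat(self):
        # W=80, F=20 in arbitrary units -> opposed-echo magnitude 60
        gt = build_phantom(
            single_ellipse_spec(fat_fraction=0.2, proton_density=100.0)
        )
        vol = simulate_dixon(gt)
        m = gt.mask(1)
        np.testing.assert_allclose(np.abs(vol.data[m, 1]), 60.0, rtol=1e-12)
        np.testing.assert_allclose(np.abs(vol.data[m, 0]), 100.0, rtol=1e-12)

    def test_unknown_phase_scheme_rejected(self, gt_wt):
        with pytest.raises(ValueError, match="unknown phase label"):
            simulate_dixon(gt_wt, phase_scheme=("in", "quadrature", "in"))


class TestT2Simulator:
    def test_noiseless_decay_matches_closed_form(self):
        gt = build_phantom(single_ellipse_spec(t2_ms=18.8))
        vol = simulate_multiecho_t2(gt, echo_times_ms=(8.0,))
        m = gt.mask(1)
        np.testing.assert_allclose(
            vol.data[m, 0], math.exp(-8.0 / 18.8), rtol=1e-12
        )
        assert vol.data[m, 0][0] == pytest.approx(0.6534, abs=1e-4)

    def test_te_to_zero_returns_s0(self):
        gt = build_phantom(single_ellipse_spec(proton_density=2.5))
        vol = simulate_multiecho_t2(gt, echo_times_ms=(1e-9,))
        np.testing.assert_allclose(vol.data[gt.mask(1), 0], 2.5, rtol=1e-9)

    def test_noiseless_signal_exactly_monoexponential(self):
        gt = build_phantom(single_ellipse_spec(t2_ms=21.0))
        vol = simulate_multiecho_t2(gt)
        m = gt.mask(1)
        tes = np.array(vol.echo_times_ms)
        expected = np.broadcast_to(np.exp(-tes / 21.0), vol.data[m].shape)
        np.testing.assert_allclose(vol.data[m], expected, rtol=1e-12)


class TestDwiSimulator:
    def test_b0_image_equals_s0(self, gt_wt):
        dwi = simulate_dwi(gt_wt)
        np.testing.assert_allclose(dwi.data[..., 0], gt_wt.proton_density)

    def test_isotropic_tensor_gives_direction_independent_signal(self):
        gt = build_phantom(
            single_ellipse_spec(tensor_eigenvalues_um2_per_ms=(1.5, 1.5, 1.5))
        )
        dwi = simulate_dwi(gt)
        m = gt.mask(1)
        sig = dwi.data[m][:, 1:]
        np.testing.assert_allclose(sig, np.broadcast_to(sig[:, :1], sig.shape),
                                   rtol=1e-12)

    def test_attenuation_matches_stejskal_tanner_closed_form(self):
        gt = build_phantom(
            single_ellipse_spec(
                tensor_eigenvalues_um2_per_ms=(1.95, 1.45, 1.07),
                principal_axis=(1.0, 0.0, 0.0),
            )
        )
        dwi = simulate_dwi(gt, directions=np.array([[1.0, 0.0, 0.0]]))
        m = gt.mask(1)
        # b=450, lambda1=1.95e-3 -> exp(-0.8775) = 0.4158
        np.testing.assert_allclose(
            dwi.data[m, 1], math.exp(-450 * 1.95e-3), rtol=1e-12
        )
        assert dwi.data[m, 1][0] == pytest.approx(0.4158, abs=1e-4)

    def test_non_unit_direction_rejected(self, gt_wt):
        with pytest.raises(ValueError, match="unit-norm"):
            simulate_dwi(gt_wt, directions=np.array([[1.0, 1.0, 0.0]]))


class TestMrsSimulator:
    def test_rest_bin_amplitude_is_100_percent(self):
        kin = MrsKinetics(rng_seed=0)
        prot = MrsProtocol()
        assert kin.pcr_pct(np.array([0.0, 60.0, 119.0]), prot) == pytest.approx(100.0)

    def test_pcr_plus_pi_conserved_at_all_times(self):
        kin = MrsKinetics(rng_seed=0)
        prot = MrsProtocol()
        t = np.linspace(0, 1440, 2000)
        total = kin.pcr_pct(t, prot) + kin.pi_pct(t, prot)
        np.testing.assert_allclose(total, 100.0 + kin.pi_rest_pct, rtol=1e-12)

    def test_bin_amplitudes_match_quadrature_oracle(self):
        """Analytic bin averages agree with dense numerical integration."""
        from scipy.integrate import quad

        kin = MrsKinetics(rng_seed=0)
        prot = MrsProtocol()
        idx = 0
        for phase, n in prot.bin_layout():
            start, width = idx * prot.tr_s, n * prot.tr_s
            idx += n
            expected = (
                quad(
                    lambda tt: kin.pcr_pct(np.array([tt]), prot)[0],
                    start,
                    start + width,
                    limit=400,
                )[0]
                / width
            )
            got = kin._mean_over(kin.pcr_pct, start, width, prot)
            assert got == pytest.approx(expected, rel=1e-3)

    def test_series_has_protocol_layout_and_relaxed_spectrum(self):
        series = simulate_mrs_series(MrsKinetics(rng_seed=1))
        assert series.n_bins == 18
        assert series.bin_phase.count("rest") == 1
        assert series.bin_phase.count("stim") == 6
        assert series.bin_phase.count("recovery") == 11
        assert series.fully_relaxed is not None
        assert np.all(np.diff(series.bin_mid_s) > 0)


class TestForceSimulator:
    def test_rise_slope_closed_form(self):
        # k chosen as target_slope / plateau force reproduces that slope
        spec = ForceProtocolSpec(rng_seed=0)
        plateau = spec.hill_force(150.0)
        k = 3.15e3 / plateau
        spec = ForceProtocolSpec(rng_seed=0, rise_rate_k_per_s=k)
        rec = simulate_force_protocol(spec)
        tr = rec.schedule["trains"][-1]
        sr = rec.sample_rate_hz
        i0 = int(tr["start_s"] * sr)
        slope = np.diff(rec.force_mN[i0 : i0 + 3]).max() * sr  # mN/s
        assert slope * 1e-3 == pytest.approx(3.15, rel=0.01)

    def test_half_relaxation_equals_tau_log2(self):
        spec = ForceProtocolSpec(rng_seed=0)
        rec = simulate_force_protocol(spec)
        tr = rec.schedule["trains"][-1]
        sr = rec.sample_rate_hz
        i_end = int(tr["end_s"] * sr)
        peak = rec.force_mN[i_end]
        after = rec.force_mN[i_end:]
        cross = np.argmax(after <= peak / 2)
        hrt_s = cross / sr
        assert hrt_s == pytest.approx(spec.relax_tau_s * math.log(2), rel=5e-3)

    def test_fatigue_schedule_has_612_events(self):
        rec = simulate_force_protocol(ForceProtocolSpec(mode="fatigue", rng_seed=0))
        assert len(rec.schedule["twitch_times_s"]) == 612

    def test_train_pulse_counts_follow_frequency(self):
        rec = simulate_force_protocol(ForceProtocolSpec(rng_seed=0))
        for tr in rec.schedule["trains"]:
            n = len(tr["pulse_times_s"])
            assert n == int(np.ceil(tr["frequency_hz"] * 0.75))
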