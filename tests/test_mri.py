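"""Round-trip and property tests for the MRI quantification chain."""

import numpy as np
import pytest

from sonoperm.mri import (
    AslModelParams,
    SusceptibilityConstants,
    fit_t1,
    gd_enhancement,
    inversion_efficiency,
    quantify_adc,
    quantify_bvf,
    quantify_cbf,
)
from sonoperm.simulate import (
    DwiParams,
    IrParams,
    Phantom,
    fibonacci_directions,
    simulate_mri,
)


class TestT1Fit:
    def test_noiseless_voxel_recovered_to_0p1_percent(self):
        tis = np.asarray(IrParams().tis)
        t1_true, m0_true, kappa = 1.5, 100.0, 1.0
        sig = np.abs(m0_true * (1 - 2 * kappa * np.exp(-tis / t1_true)))
        fit = fit_t1(sig[:, None, None, None], tis)
        assert fit.t1[0, 0, 0] == pytest.approx(t1_true, rel=1e-3)
        assert fit.m0[0, 0, 0] == pytest.approx(m0_true, rel=1e-3)
        assert fit.kappa[0, 0, 0] == pytest.approx(kappa, rel=1e-3)

    def test_constant_series_flagged_nonconverged(self):
        tis = np.asarray(IrParams().tis)
        sig = np.full((tis.size, 1, 1, 1), 5.0)
        fit = fit_t1(sig, tis)
        assert not fit.converged[0, 0, 0]
        assert np.isnan(fit.t1[0, 0, 0])

    def test_noisy_recovery_median_error_below_3_percent(self, rng):
        tis = np.asarray(IrParams().tis)
        n = 10_000
        t1_true = rng.uniform(0.8, 2.5, n)
        m0_true = 100.0
        sig = np.abs(m0_true * (1 - 2 * np.exp(-tis[:, None] / t1_true[None, :])))
        noisy = np.hypot(sig + rng.normal(0, 2.0, sig.shape), rng.normal(0, 2.0, sig.shape))
        fit = fit_t1(noisy.reshape(tis.size, n, 1, 1), tis)
        err = np.abs(fit.t1.reshape(n) / t1_true - 1)
        assert np.nanmedian(err) < 0.03

    def test_needs_three_tis(self):
        with pytest.raises(ValueError):
            fit_t1(np.zeros((2, 1, 1, 1)), [0.1, 1.0])


class TestInversionEfficiency:
    def test_perfect_inversion(self):
        c = np.full((4, 4), 10.0)
        assert inversion_efficiency(c, -c, np.ones((4, 4), bool)) == pytest.approx(1.0)

    def test_no_inversion_raises(self):
        c = np.full((4, 4), 10.0)
        with pytest.raises(ValueError):
            inversion_efficiency(c, c.copy(), np.ones((4, 4), bool))

    def test_round_trip_with_noise(self, default_phantom):
        asl = simulate_mri(default_phantom, "pcasl", noise_sd=1.0, seed=42)
        alpha = inversion_efficiency(asl.alpha_control, asl.alpha_label, asl.vessel_mask)
        assert alpha == pytest.approx(default_phantom.alpha, rel=0.02)


class TestCbf:
    def _fit_maps(self, phantom, noise_sd=0.0, seed=0):
        ir = simulate_mri(phantom, "ir_t1", noise_sd=noise_sd, seed=seed)
        return fit_t1(ir.signals, ir.tis, mask=phantom.brain_mask)

    def test_zero_label_effect_gives_zero_cbf(self, small_phantom):
        ph = small_phantom
        m0 = np.where(ph.brain_mask, 100.0, np.nan)
        t1 = np.where(ph.brain_mask, 1.5, np.nan)
        qmap = quantify_cbf(
            m0, m0.copy(), AslModelParams(alpha=0.85, t1_map=t1, m0_map=m0), mask=ph.brain_mask
        )
        assert np.all(qmap.values[ph.brain_mask] == 0)

    def test_noiseless_round_trip_recovers_truth(self, default_phantom):
        ph = default_phantom
        fit = self._fit_maps(ph)
        asl = simulate_mri(ph, "pcasl", noise_sd=0.0)
        alpha = inversion_efficiency(asl.alpha_control, asl.alpha_label, asl.vessel_mask)
        qmap = quantify_cbf(
            asl.control,
            asl.label,
            AslModelParams(alpha=alpha, t1_map=fit.t1, m0_map=fit.m0),
            mask=ph.brain_mask & fit.converged,
        )
        assert np.nanmax(np.abs(qmap.values[ph.contra_mask] / 93.57 - 1)) < 1e-3
        assert np.nanmax(np.abs(qmap.values[ph.ipsi_mask] / 42.24 - 1)) < 1e-3

    def test_striatum_truths_give_38_percent_reduction(self):
        ph = Phantom.cortex_slab(shape=(32, 32, 4), margin=3, cbf=(81.21, 50.68))
        fit = self._fit_maps(ph)
        asl = simulate_mri(ph, "pcasl", noise_sd=0.3, seed=3)
        qmap = quantify_cbf(
            asl.control,
            asl.label,
            AslModelParams(alpha=ph.alpha, t1_map=fit.t1, m0_map=fit.m0),
            mask=ph.brain_mask & fit.converged,
        )
        from sonoperm.stats import extract_roi, relative_change

        mi, _ = extract_roi(qmap, ph.ipsi_mask)
        mc, _ = extract_roi(qmap, ph.contra_mask)
        raw, as_int = relative_change(mi, mc)
        assert as_int == 38

    def test_cbf_linear_in_dm_and_inverse_in_alpha(self, small_phantom):
        ph = small_phantom
        m0 = np.where(ph.brain_mask, 100.0, np.nan)
        t1 = np.where(ph.brain_mask, 1.5, np.nan)
        control = m0.copy()
        label = m0 - np.where(ph.brain_mask, 2.0, 0.0)
        base = quantify_cbf(
            control, label, AslModelParams(alpha=0.8, t1_map=t1, m0_map=m0), mask=ph.brain_mask
        )
        doubled_dm = quantify_cbf(
            control, 2 * label - control, AslModelParams(alpha=0.8, t1_map=t1, m0_map=m0), mask=ph.brain_mask
        )
        halved_alpha = quantify_cbf(
            control, label, AslModelParams(alpha=0.4, t1_map=t1, m0_map=m0), mask=ph.brain_mask
        )
        sel = ph.brain_mask
        assert np.allclose(doubled_dm.values[sel], 2 * base.values[sel])
        assert np.allclose(halved_alpha.values[sel], 2 * base.values[sel])


class TestBvf:
    def test_identical_series_give_zero(self, small_phantom):
        mge = simulate_mri(small_phantom, "mge_pre_post")
        qmap = quantify_bvf(mge.pre, mge.pre, mge.tes)
        assert np.nanmax(np.abs(qmap.values)) == 0

    def test_known_r2star_pair_exact(self):
        tes = 3.5e-3 + 5e-3 * np.arange(8)
        r2_pre, r2_post = 28.0, 63.0
        pre = (50 * np.exp(-tes * r2_pre)).reshape(-1, 1, 1, 1)
        post = (50 * np.exp(-tes * r2_post)).reshape(-1, 1, 1, 1)
        consts = SusceptibilityConstants()
        qmap = quantify_bvf(pre, post, tes, consts)
        expected = 100 * (3 / (4 * np.pi)) * (r2_post - r2_pre) / (
            consts.gamma * consts.delta_chi * consts.b0
        )
        assert qmap.values[0, 0, 0] == pytest.approx(expected, abs=1e-10)

    def test_round_trip_recovers_truth_and_13_percent_reduction(self, default_phantom):
        ph = default_phantom
        mge = simulate_mri(ph, "mge_pre_post")
        qmap = quantify_bvf(mge.pre, mge.post, mge.tes, mask=ph.brain_mask)
        assert np.nanmax(np.abs(qmap.values[ph.contra_mask] / 3.9 - 1)) < 1e-3
        from sonoperm.stats import extract_roi, relative_change

        mi, _ = extract_roi(qmap, ph.ipsi_mask)
        mc, _ = extract_roi(qmap, ph.contra_mask)
        assert relative_change(mi, mc)[1] == 13

    def test_doubling_delta_chi_halves_bvf(self, small_phantom):
        mge = simulate_mri(small_phantom, "mge_pre_post")
        c1 = SusceptibilityConstants()
        c2 = SusceptibilityConstants(delta_chi=2 * c1.delta_chi)
        q1 = quantify_bvf(mge.pre, mge.post, mge.tes, c1)
        q2 = quantify_bvf(mge.pre, mge.post, mge.tes, c2)
        assert np.allclose(q2.values, q1.values / 2, equal_nan=True)

    def test_negative_dr2star_clipped_and_flagged(self):
        tes = 3.5e-3 + 5e-3 * np.arange(8)
        pre = (50 * np.exp(-tes * 40.0)).reshape(-1, 1, 1, 1)
        post = (50 * np.exp(-tes * 30.0)).reshape(-1, 1, 1, 1)
        qmap = quantify_bvf(pre, post, tes)
        assert qmap.values[0, 0, 0] == 0
        assert qmap.flags[0, 0, 0]

    def test_nonmonotone_echoes_rejected(self):
        with pytest.raises(ValueError):
            quantify_bvf(np.ones((3, 1, 1, 1)), np.ones((3, 1, 1, 1)), [1e-3, 3e-3, 2e-3])


class TestAdc:
    def test_isotropic_closed_form_both_modes(self):
        dirs = fibonacci_directions(30)
        s0 = np.full((2, 2, 2), 100.0)
        dwi = np.stack([s0 * np.exp(-1000 * 1.0e-3) for _ in range(30)])
        for mode in ("tensor", "mean"):
            qmap = quantify_adc(s0, dwi, 1000.0, dirs, mode=mode)
            assert np.allclose(qmap.values, 1.0e-3)

    def test_modes_agree_exactly_on_isotropic_data(self, small_phantom):
        dwi = simulate_mri(small_phantom, "dwi")
        qt = quantify_adc(dwi.b0, dwi.dwi, dwi.bval, dwi.directions, mode="tensor")
        qm = quantify_adc(dwi.b0, dwi.dwi, dwi.bval, dwi.directions, mode="mean")
        assert np.allclose(qt.values, qm.values, atol=1e-12)

    def test_anisotropic_tensor_trace(self):
        dirs = fibonacci_directions(30)
        d_tensor = np.diag([2.0e-3, 1.0e-3, 0.0])
        s0 = np.full((1, 1, 1), 100.0)
        atten = np.exp(-1000.0 * np.einsum("ij,jk,ik->i", dirs, d_tensor, dirs))
        dwi = (100.0 * atten).reshape(-1, 1, 1, 1)
        qmap = quantify_adc(s0, dwi, 1000.0, dirs, mode="tensor")
        assert qmap.values[0, 0, 0] == pytest.approx(1.0e-3, rel=1e-6)

    def test_dwi_ratio_closed_form(self, small_phantom):
        dwi = simulate_mri(small_phantom, "dwi", params=DwiParams())
        sel = small_phantom.brain_mask
        ratio = dwi.dwi[0][sel] / dwi.b0[sel]
        assert np.allclose(ratio, np.exp(-1.0))

    def test_nonpositive_signal_rejected(self):
        dirs = fibonacci_directions(6)
        with pytest.raises(ValueError):
            quantify_adc(np.zeros((1, 1, 1)), np.ones((6, 1, 1, 1)), 1000.0, dirs)


class TestGdEnhancement:
    def test_no_leak_gives_zero(self, small_phantom):
        ph = small_phantom
        pre = np.where(ph.brain_mask, 100.0, 1.0)
        res = gd_enhancement(pre, pre.copy(), ph.ipsi_mask, ph.contra_mask, voxel_size=ph.voxel_size)
        assert res.mean_roi_enhancement == 0
        assert res.opened_volume_mm3 == 0

    def test_worked_core_enhancement_value(self, default_phantom):
        ph = default_phantom
        t1w = simulate_mri(ph, "t1w_pre_post_gd")
        res = gd_enhancement(t1w.pre, t1w.post, ph.core_mask, ph.contra_mask, voxel_size=ph.voxel_size)
        assert res.mean_roi_enhancement == pytest.approx(18.66, abs=0.01)

    def test_core_fraction_of_roi_recovered(self, default_phantom):
        ph = default_phantom
        t1w = simulate_mri(ph, "t1w_pre_post_gd")
        res = gd_enhancement(t1w.pre, t1w.post, ph.ipsi_mask, ph.contra_mask, voxel_size=ph.voxel_size)
        frac = res.opened_mask.sum() / ph.ipsi_mask.sum()
        assert frac == pytest.approx(0.05, abs=0.005)

    def test_delineation_invariant_to_global_scaling(self, default_phantom):
        ph = default_phantom
        t1w = simulate_mri(ph, "t1w_pre_post_gd", noise_sd=0.5, seed=9)
        r1 = gd_enhancement(t1w.pre, t1w.post, ph.ipsi_mask, ph.contra_mask)
        r2 = gd_enhancement(3.7 * t1w.pre, 3.7 * t1w.post, ph.ipsi_mask, ph.contra_mask)
        assert np.array_equal(r1.opened_mask, r2.opened_mask)
        assert r1.mean_roi_enhancement == pytest.approx(r2.mean_roi_enhancement)

    def test_zero_pre_signal_in_roi_rejected(self):
        pre = np.zeros((4, 4, 2))
        post = np.ones_like(pre)
        roi = np.ones_like(pre, bool)
        with pytest.raises(ValueError):
            gd_enhancement(pre, post, roi, roi)


class TestSimulatorContracts:
    def test_unknown_acquisition_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            simulate_mri(small_phantom, "bold")

    def test_negative_noise_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            simulate_mri(small_phantom, "dwi", noise_sd=-1.0)

    def test_seeded_simulation_reproducible(self, small_phantom):
        a = simulate_mri(small_phantom, "dwi", noise_sd=0.5, seed=5)
        b = simulate_mri(small_phantom, "dwi", noise_sd=0.5, seed=5)
        assert np.array_equal(a.dwi, b.dwi)

    def test_core_must_lie_inside_ipsi(self):
        label = np.zeros((8, 8, 2), dtype=int)
        label[0, 0, 0] = 3  # core in background
        z = np.zeros_like(label, dtype=float)
        with pytest.raises(ValueError):
            Phantom(label, z, z, z, z, z)
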