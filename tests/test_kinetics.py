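"""Tracer-kinetic fitting: Fermi, 2CXM, Patlak, Tikhonov, arrival search."""

import numpy as np
import pytest

from qperf.aif import ConcentrationCurve
from qperf.kinetics import (
    FermiModel,
    KineticParams,
    KineticsError,
    PatlakModel,
    TikhonovModel,
    TwoCompartmentExchangeModel,
    arrival_search,
    causal_convolve,
    crop_first_pass,
    deconvolve_tikhonov,
    fermi_irf,
    fermi_mbf,
    fit_patlak,
    residue_2cxm,
    residue_one_compartment,
)
from qperf.phantom import GammaVariateAif, forward_tissue, generate_aif


def plasma_curve(times, **shape_kw):
    shape = GammaVariateAif(**shape_kw)
    c = generate_aif(shape, times)
    return ConcentrationCurve(times=times, values=c.values / 0.58, role="aif_plasma")


class TestFermiIrf:
    def test_midpoint_value(self):
        assert fermi_irf(np.array([5.0]), 2.0, 5.0, 0.3, 0.1)[0] == pytest.approx(
            2.0 / 2 + 0.1
        )

    def test_arithmetic_example(self):
        val = fermi_irf(np.array([7.0]), 1.0, 5.0, 0.5, 0.0)[0]
        assert val == pytest.approx(1.0 / (np.e + 1.0), abs=1e-5)
        assert val == pytest.approx(0.26894, abs=1e-4)

    def test_large_k_approaches_step(self):
        t = np.array([0.0, 4.9, 5.1, 10.0])
        vals = fermi_irf(t, 1.0, 5.0, 1e3, 0.0)
        assert vals[0] == pytest.approx(1.0) and vals[1] == pytest.approx(1.0)
        assert vals[2] == pytest.approx(0.0, abs=1e-10)

    def test_monotone_non_increasing(self):
        t = np.linspace(0, 30, 200)
        vals = fermi_irf(t, 1.5, 4.0, 0.3, 0.2)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_negative_k_rejected(self):
        with pytest.raises(KineticsError):
            fermi_irf(np.array([1.0]), 1.0, 1.0, -0.1)


class TestResidues:
    def test_r0_is_one_and_monotone(self):
        t = np.linspace(0, 120, 500)
        for params in [(1.0, 0.08, 0.2, 0.5), (4.0, 0.05, 0.4, 1.5),
                       (0.5, 0.15, 0.1, 0.0)]:
            r = residue_2cxm(t, *params)
            assert r[0] == pytest.approx(1.0)
            assert np.all(np.diff(r) <= 1e-12)
        r1 = residue_one_compartment(t, 1.0, 0.1)
        assert r1[0] == 1.0 and np.all(np.diff(r1) < 0)

    def test_2cxm_reduces_to_one_compartment_at_zero_ps(self):
        t = np.linspace(0, 60, 300)
        r = residue_2cxm(t, 1.0, 0.08, 0.2, 0.0)
        assert r == pytest.approx(residue_one_compartment(t, 1.0, 0.08), abs=1e-12)


class TestConvolution:
    def test_matches_oversampled_riemann_oracle(self, aif_plasma):
        """Coarse-grid convolution vs a 100x-oversampled Riemann sum."""
        irf = lambda lag: 0.02 * np.exp(-lag / 6.0)
        got = causal_convolve(aif_plasma.times, irf, aif_plasma.values)
        t = aif_plasma.times
        dt_f = (t[1] - t[0]) / 100.0
        tf = np.arange(t[0], t[-1] + dt_f / 2, dt_f)
        af = np.interp(tf, t, aif_plasma.values)
        oracle = np.convolve(irf(tf - tf[0]), af)[: tf.size] * dt_f
        oracle_s = np.interp(t, tf, oracle)
        scale = oracle_s.max()
        assert np.abs(got - oracle_s).max() <= 0.01 * scale

    def test_nonuniform_grid_agrees_with_uniform(self, rest_kinetics):
        """RR-irregular sampling must not shift the forward curves by >3%."""
        rng = np.random.default_rng(8)
        tu = np.arange(0.0, 50.0, 1.0)
        tn = np.cumsum(rng.uniform(0.7, 1.4, size=50))
        tn = tn - tn[0]
        cu = plasma_curve(tu, recirc_fraction=0.0)
        cn = plasma_curve(tn, recirc_fraction=0.0)
        yu = forward_tissue(cu, rest_kinetics, "2cxm").values
        yn = forward_tissue(cn, rest_kinetics, "2cxm").values
        yn_on_u = np.interp(tu, tn, yn)
        mask = tu > 10.0  # compare where both grids are well supported
        assert np.abs((yn_on_u - yu)[mask]).max() <= 0.03 * yu.max()


class TestCropFirstPass:
    def test_no_recirculation_ends_at_30_percent_decay(self):
        t = np.arange(0.0, 50.0, 1.0)
        aif = plasma_curve(t, recirc_fraction=0.0)
        ac, tc, start = crop_first_pass(aif, aif)
        peak = aif.values.max()
        assert ac.values[-1] <= 0.30 * peak
        assert ac.values[-2] > 0.30 * peak

    def test_recirculation_crops_at_interpass_minimum(self):
        # strong, early recirculation: the inter-pass minimum arrives
        # before the 30%-of-peak decay level is reached
        t = np.arange(0.0, 50.0, 1.0)
        aif = plasma_curve(t, recirc_fraction=0.8, recirc_delay=8.0)
        ac, _, start = crop_first_pass(aif, aif)
        end_global = start + len(ac) - 1
        v = aif.values
        peak = int(np.argmax(v))
        mins = [i for i in range(peak + 1, len(v) - 1)
                if v[i] <= v[i - 1] and v[i] <= v[i + 1]]
        assert v[end_global] > 0.30 * v[peak]  # 30% rule did not fire first
        assert end_global == mins[0]

    def test_mismatched_grids_rejected(self):
        t = np.arange(0.0, 50.0, 1.0)
        aif = plasma_curve(t, recirc_fraction=0.0)
        longer = ConcentrationCurve(
            times=np.arange(0.0, 60.0, 1.0),
            values=np.zeros(60), role="tissue",
        )
        with pytest.raises(KineticsError):
            crop_first_pass(aif, longer)


class TestFermiFit:
    def make_fermi_tissue(self, aif, A=1.2, mu=4.0, k=0.3):
        kp = KineticParams(fermi_A=A, fermi_mu=mu, fermi_k=k)
        return forward_tissue(aif, kp, "fermi")

    def test_self_consistent_recovery_within_one_percent(self, aif_plasma):
        tis = self.make_fermi_tissue(aif_plasma)
        ac, tc, _ = crop_first_pass(aif_plasma, tis)
        res = FermiModel(tc, ac).fit()
        truth = fermi_mbf(1.2, 4.0, 0.3)
        assert res.converged
        assert res.params.F_p == pytest.approx(truth, rel=0.01)

    def test_tissue_scaling_scales_mbf_linearly(self, aif_plasma):
        tis = self.make_fermi_tissue(aif_plasma)
        ac, tc, _ = crop_first_pass(aif_plasma, tis)
        res1 = FermiModel(tc, ac).fit()
        tc2 = ConcentrationCurve(times=tc.times, values=2 * tc.values, role="tissue")
        res2 = FermiModel(tc2, ac).fit()
        assert res2.params.F_p == pytest.approx(2 * res1.params.F_p, rel=1e-3)

    def test_cross_model_mbf_within_ten_percent(self, aif_plasma, rest_kinetics,
                                                tissue_2cxm):
        ac, tc, _ = crop_first_pass(aif_plasma, tissue_2cxm)
        res = FermiModel(tc, ac).fit()
        assert res.params.F_p == pytest.approx(rest_kinetics.F_p, rel=0.10)

    def test_doubling_aif_halves_mbf(self, aif_plasma, tissue_2cxm):
        ac, tc, _ = crop_first_pass(aif_plasma, tissue_2cxm)
        res1 = FermiModel(tc, ac).fit()
        ac2 = ConcentrationCurve(times=ac.times, values=2 * ac.values,
                                 role="aif_plasma")
        res2 = FermiModel(tc, ac2).fit()
        assert res2.params.F_p == pytest.approx(res1.params.F_p / 2, rel=1e-2)


class TestTwoCompartmentExchange:
    def test_noise_free_recovery_within_two_percent(self, aif_plasma, rest_kinetics,
                                                    tissue_2cxm):
        res = TwoCompartmentExchangeModel(tissue_2cxm, aif_plasma).fit()
        p = res.params
        assert p.F_p == pytest.approx(rest_kinetics.F_p, rel=0.02)
        assert p.v_p == pytest.approx(rest_kinetics.v_p, rel=0.02)
        assert p.v_e == pytest.approx(rest_kinetics.v_e, rel=0.02)
        assert p.PS == pytest.approx(rest_kinetics.PS, rel=0.02)
        assert p.v == pytest.approx(p.v_p + p.v_e)

    def test_zero_ps_phantom_recovered_degenerate(self, aif_plasma):
        kp = KineticParams(F_p=1.0, v_p=0.08, v_e=0.2, PS=0.0)
        tis = forward_tissue(aif_plasma, kp, "2cxm")
        res = TwoCompartmentExchangeModel(tis, aif_plasma).fit()
        assert res.params.PS < 0.01
        assert res.params.F_p == pytest.approx(1.0, rel=0.02)


class TestTikhonov:
    def test_delta_aif_returns_tissue_curve(self):
        # discrete delta under the trapezoid quadrature (half weight on
        # the first sample): amplitude 2/dt integrates to one
        t = np.arange(0.0, 10.0, 1.0)
        dt = 1.0
        aif = np.zeros(10)
        aif[0] = 2.0 / dt
        tissue = np.exp(-t / 4.0) * 0.5
        irf, res = deconvolve_tikhonov(
            ConcentrationCurve(times=t, values=aif, role="aif_plasma"),
            ConcentrationCurve(times=t, values=tissue, role="tissue"),
            lam=0.0,
        )
        assert irf / 60.0 == pytest.approx(tissue, abs=1e-10)

    def test_lambda_zero_matches_direct_inverse(self):
        """5-sample system: the lam=0 solution equals A^{-1} b to 1e-8."""
        t = np.arange(5.0)
        aif = np.array([1.0, 0.8, 0.5, 0.2, 0.1])
        rng = np.random.default_rng(1)
        tissue = rng.random(5)
        A = np.zeros((5, 5))
        for j in range(5):
            A[j:, j] = aif[: 5 - j]
        A[np.arange(5), np.arange(5)] *= 0.5
        A[:, 0] *= 0.5
        A[0, 0] *= 2.0
        oracle = np.linalg.solve(A * 1.0, tissue)  # dt = 1
        irf, _ = deconvolve_tikhonov(
            ConcentrationCurve(times=t, values=aif, role="aif_plasma"),
            ConcentrationCurve(times=t, values=tissue, role="tissue"),
            lam=0.0,
        )
        assert irf / 60.0 == pytest.approx(oracle, abs=1e-8)

    def test_singular_system_at_lambda_zero_advises(self):
        t = np.arange(6.0)
        aif = np.zeros(6)
        aif[2] = 1.0  # AIF starts at zero -> singular triangular system
        with pytest.raises(KineticsError, match="lambda"):
            deconvolve_tikhonov(
                ConcentrationCurve(times=t, values=aif, role="aif_plasma"),
                ConcentrationCurve(times=t, values=np.ones(6), role="tissue"),
                lam=0.0,
            )

    def test_phantom_mbf_within_ten_percent_at_swept_lambda(
        self, aif_plasma, rest_kinetics, tissue_2cxm
    ):
        ac, tc, _ = crop_first_pass(aif_plasma, tissue_2cxm)
        best = None
        for lam in [1e-4, 1e-3, 1e-2, 0.05, 0.1]:
            _, res = deconvolve_tikhonov(ac, tc, lam=lam)
            err = abs(res.params.F_p - rest_kinetics.F_p)
            if best is None or err < best:
                best = err
        assert best <= 0.10 * rest_kinetics.F_p


class TestPatlak:
    def test_pure_plasma_tissue_gives_zero_slope(self, aif_plasma):
        tissue = ConcentrationCurve(
            times=aif_plasma.times, values=0.07 * aif_plasma.values, role="tissue"
        )
        res = PatlakModel(tissue, aif_plasma).fit()
        assert res.params.K_trans == pytest.approx(0.0, abs=1e-6)
        assert res.params.v_p == pytest.approx(0.07, abs=1e-4)

    def test_kety_tofts_early_window_slope(self, aif_plasma):
        # slow efflux (k_ep = K_trans/v_e small) keeps the Patlak
        # linearization valid over the early window
        kp = KineticParams(K_trans=0.2, v_e=0.5, v_p=0.05)
        tis = forward_tissue(aif_plasma, kp, "kety_tofts")
        peak = int(np.argmax(aif_plasma.values))
        res = PatlakModel(tis, aif_plasma, window=peak + 3).fit()
        assert res.params.K_trans == pytest.approx(0.2, rel=0.05)

    def test_negative_slope_clamped_and_flagged(self, aif_plasma):
        tissue = ConcentrationCurve(
            times=aif_plasma.times,
            values=-0.01 * np.cumsum(aif_plasma.values),
            role="tissue",
        )
        res = PatlakModel(tissue, aif_plasma).fit()
        assert res.params.K_trans == 0.0
        assert not res.converged

    def test_too_few_points_rejected(self):
        t = np.arange(5.0)
        aif = ConcentrationCurve(times=t, values=np.zeros(5), role="aif_plasma")
        tis = ConcentrationCurve(times=t, values=np.zeros(5), role="tissue")
        with pytest.raises(KineticsError):
            fit_patlak(aif, tis)


class TestArrivalSearch:
    def test_delayed_tissue_arrival_recovered(self, aif_plasma, rest_kinetics):
        delay = 3  # samples
        t = aif_plasma.times
        shifted_aif = ConcentrationCurve(
            times=t,
            values=np.interp(t - delay, t, aif_plasma.values, left=0.0),
            role="aif_plasma",
        )
        tissue = forward_tissue(shifted_aif, rest_kinetics, "2cxm")
        from qperf.aif import detect_arrival

        aif_arr = detect_arrival(aif_plasma).index
        res = arrival_search(
            TwoCompartmentExchangeModel,
            aif_plasma,
            tissue,
            range(aif_arr, aif_arr + 6),
        )
        assert res.arrival_index == aif_arr + delay
        assert res.params.F_p == pytest.approx(rest_kinetics.F_p, rel=0.02)

    def test_tie_broken_to_earliest(self, aif_plasma, tissue_2cxm):
        from qperf.aif import detect_arrival

        arr = detect_arrival(aif_plasma).index
        res = arrival_search(
            TwoCompartmentExchangeModel,
            aif_plasma,
            tissue_2cxm,
            [arr, arr, arr],  # duplicate candidates: rss ties exactly
        )
        assert res.arrival_index == arr

    def test_empty_candidate_range_rejected(self, aif_plasma, tissue_2cxm):
        with pytest.raises(KineticsError):
            arrival_search(
                TwoCompartmentExchangeModel, aif_plasma, tissue_2cxm, []
            )


def test_summary_contains_key_fields(aif_plasma, tissue_2cxm):
    res = TwoCompartmentExchangeModel(tissue_2cxm, aif_plasma).fit()
    text = res.summary()
    for token in ("MBF", "F_p", "v_p", "PS", "RSS", "2cxm"):
        assert token in text
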