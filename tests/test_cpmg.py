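"""Dispersion forward models, fitting, model selection and Rex."""

import warnings

import numpy as np
import pytest
import scipy.linalg

from nmrkin import FieldContext, cpmg
from nmrkin.cpmg import (DispersionCurve, KineticNetwork, TwoStateParams,
                         bm_r2eff, bm_r2eff_rate, cr_r2eff, cr_rex,
                         fit_dispersion, fit_flat, rex, select_model)

NU = np.array([25., 50., 75., 100., 150., 200., 300., 400., 500., 600., 800., 1000.])


def bm_oracle(network, field, nus, trelax=0.04, nucleus="N15"):
    """Independent Bloch-McConnell propagation: scipy expm + explicit
    per-echo loop (different exponential algorithm and echo bookkeeping)."""
    omega = network.offsets_ppm * 1e-6 * abs(field.larmor(nucleus))
    r2 = network.r2_vector(field.proton_mhz)
    A = network.K.T.astype(complex) + 1j * np.diag(omega) - np.diag(r2)
    out = []
    for nu in nus:
        n = max(1, int(round(2 * trelax * nu)))
        tau = 1.0 / (4.0 * (n / (2.0 * trelax)))
        u = scipy.linalg.expm(A * tau)
        m = network.populations.astype(complex)
        for _ in range(n):
            m = u @ np.conj(u @ m)
        out.append(-np.log(abs(m.sum()) / network.populations.sum()) / trelax)
    return np.array(out)


class TestCarverRichards:
    def test_no_shift_difference_is_flat(self, field600):
        p = TwoStateParams(0.9, 1000.0, 0.0, {600.0: 12.0})
        assert np.allclose(cr_r2eff(p, field600, NU), 12.0)

    def test_vanishing_minor_state(self, field600):
        p = TwoStateParams(1.0 - 1e-9, 800.0, 2.0, {600.0: 12.0})
        r = np.asarray(cr_r2eff(p, field600, NU))
        assert np.abs(r - 12.0).max() < 1e-3

    @pytest.mark.parametrize("mhz", [600.0, 950.0])
    def test_matches_bloch_mcconnell_rate(self, mhz):
        # the closed form is the dominant-mode decay rate of the echo train
        field = FieldContext(mhz)
        p = TwoStateParams(0.95, 500.0, 2.0, {mhz: 12.0})
        net = KineticNetwork.two_state(0.95, 500.0, 2.0, {mhz: 12.0})
        cr = np.asarray(cr_r2eff(p, field, NU))
        bm = bm_r2eff_rate(net, field, NU)
        assert np.max(np.abs(cr - bm) / bm) < 0.01

    def test_sweep_agreement_and_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            pA = rng.uniform(0.6, 0.99)
            kex = 10 ** rng.uniform(2.0, np.log10(5000.0))
            dw = rng.uniform(0.5, 4.0)
            for mhz in (600.0, 950.0):
                field = FieldContext(mhz)
                p = TwoStateParams(pA, kex, dw, {mhz: 12.0})
                net = KineticNetwork.two_state(pA, kex, dw, {mhz: 12.0})
                cr = np.asarray(cr_r2eff(p, field, NU))
                bm = bm_r2eff_rate(net, field, NU)
                assert np.max(np.abs(cr - bm) / bm) < 0.01
                # dispersion decays overall; strict monotonicity only holds
                # once pulsing outruns the shift difference (slow-pulsing
                # refocusing oscillations are genuine)
                assert cr[0] == pytest.approx(cr.max(), rel=0.03)
                assert cr[-1] == pytest.approx(cr.min(), rel=1e-9)
                dw_hz = dw * 1e-6 * abs(field.larmor("N15")) / (2 * np.pi)
                fast = NU >= dw_hz
                assert (np.diff(cr[fast]) <= 1e-9).all()

    def test_no_overflow_at_slow_pulsing(self, field950):
        p = TwoStateParams(0.6, 5000.0, 4.0, {950.0: 12.0})
        r = cr_r2eff(p, field950, 1.0)  # eta huge; log-stable branch
        assert np.isfinite(r)


class TestBlochMcConnell:
    def test_single_state_is_exact_intrinsic(self, field600):
        net = KineticNetwork(np.zeros((1, 1)), np.array([1.0]), np.zeros(1),
                             {600.0: 17.5})
        assert np.allclose(bm_r2eff(net, field600, NU), 17.5, atol=1e-10)

    def test_equal_offsets_give_population_weighted_r2(self, field600):
        # fast exchange between states differing only in intrinsic R2
        net = KineticNetwork.two_state(0.7, 50000.0, 0.0, {})
        net = KineticNetwork(net.K, net.populations, np.zeros(2),
                             {600.0: np.array([10.0, 20.0])})
        r = bm_r2eff(net, field600, np.array([100.0, 1000.0]))
        assert np.allclose(r, 0.7 * 10.0 + 0.3 * 20.0, rtol=0.01)

    def test_three_state_matches_independent_expm_oracle(self, planted_network,
                                                         field600, field950):
        net = KineticNetwork(planted_network.K, planted_network.populations,
                             np.array([3.0, 0.2, 0.0]),
                             dict(planted_network.r2_by_field))
        for field in (field600, field950):
            mine = np.asarray(bm_r2eff(net, field, NU))
            oracle = bm_oracle(net, field, NU)
            assert np.max(np.abs(mine - oracle) / oracle) < 1e-3

    def test_off_grid_nu_snaps_with_warning(self, field600):
        net = KineticNetwork.two_state(0.9, 800.0, 1.0, {600.0: 12.0})
        with pytest.warns(UserWarning, match="nearest valid grid"):
            bm_r2eff(net, field600, 30.0)  # 2*0.04*30 = 2.4 echoes


class TestFitting:
    def make_curves(self, truth, sigma=0.0, seed=0, residue=5):
        rng = np.random.default_rng(seed)
        out = []
        for mhz in sorted(truth.r2_0):
            field = FieldContext(mhz)
            y = np.asarray(cr_r2eff(truth, field, NU))
            if sigma > 0:
                y = y + rng.normal(0, sigma, NU.size)
            out.append(DispersionCurve(residue, field, NU, y,
                                       np.full_like(NU, sigma)))
        return out

    def test_noiseless_round_trip(self):
        truth = TwoStateParams(0.92, 800.0, 1.5, {600.0: 12.0, 950.0: 15.0})
        fit = fit_dispersion(self.make_curves(truth), n_bootstrap=0)
        assert fit.success
        p = fit.params
        assert p.pA == pytest.approx(0.92, rel=1e-3)
        assert p.kex == pytest.approx(800.0, rel=1e-3)
        assert p.dw_ppm == pytest.approx(1.5, rel=1e-3)
        assert p.r2_0[600.0] == pytest.approx(12.0, rel=1e-3)
        assert p.r2_0[950.0] == pytest.approx(15.0, rel=1e-3)

    def test_noisy_recovery_within_bootstrap_intervals(self):
        truth = TwoStateParams(0.92, 800.0, 1.5, {600.0: 12.0, 950.0: 15.0})
        curves = self.make_curves(truth, sigma=0.3, seed=42)
        fit = fit_dispersion(curves, n_bootstrap=200, seed=7)
        for name, val in [("pA", 0.92), ("kex", 800.0), ("dw_ppm", 1.5)]:
            lo, hi = fit.param_ci[name]
            assert lo <= val <= hi, f"{name}: {val} outside [{lo}, {hi}]"

    def test_flat_data_selects_no_exchange(self):
        truth = TwoStateParams(0.9, 800.0, 0.0, {600.0: 12.0, 950.0: 15.0})
        curves = self.make_curves(truth, sigma=0.3, seed=3)
        fit_ex = fit_dispersion(curves, n_starts=10, n_bootstrap=0)
        fit_no = fit_flat(curves)
        assert select_model(fit_ex, fit_no) == "no-exchange"
        if fit_ex.params is not None:
            r = rex(fit_ex.params, FieldContext(950.0))
            assert abs(r.value) < 1.0

    def test_dispersed_data_selects_exchange(self):
        truth = TwoStateParams(0.95, 800.0, 2.0, {600.0: 12.0, 950.0: 15.0})
        curves = self.make_curves(truth, sigma=0.3, seed=4)
        fit_ex = fit_dispersion(curves, n_starts=10, n_bootstrap=0)
        fit_no = fit_flat(curves)
        assert select_model(fit_ex, fit_no) == "exchange"

    def test_tie_breaks_to_parsimony(self):
        a = cpmg.FitResult("exchange", None, None, 1.0, 5.0, 24, 5)
        b = cpmg.FitResult("no-exchange", None, {600.0: 12.0}, 1.0, 5.0, 24, 2)
        assert select_model(a, b) == "no-exchange"

    def test_fit_invariant_under_point_reordering(self):
        truth = TwoStateParams(0.92, 800.0, 1.5, {600.0: 12.0, 950.0: 15.0})
        curves = self.make_curves(truth, sigma=0.2, seed=9)
        fit1 = fit_dispersion(curves, n_starts=8, n_bootstrap=0)
        # reorder the underlying points; the curve container re-sorts them
        shuffled = []
        rng = np.random.default_rng(1)
        for c in curves:
            idx = rng.permutation(c.n_points)
            order = np.argsort(c.nu_cpmg[idx])
            shuffled.append(DispersionCurve(c.residue, c.field,
                                            c.nu_cpmg[idx][order],
                                            c.r2eff[idx][order],
                                            c.sigma[idx][order]))
        fit2 = fit_dispersion(shuffled, n_starts=8, n_bootstrap=0)
        assert fit1.params.kex == pytest.approx(fit2.params.kex, rel=1e-6)
        assert fit1.params.pA == pytest.approx(fit2.params.pA, rel=1e-6)

    def test_requires_shared_residue(self, field600):
        c1 = DispersionCurve(1, field600, NU, np.full_like(NU, 12.0), np.zeros_like(NU))
        c2 = DispersionCurve(2, field600, NU, np.full_like(NU, 12.0), np.zeros_like(NU))
        with pytest.raises(ValueError, match="share residue"):
            fit_dispersion([c1, c2], n_bootstrap=0)


class TestRex:
    def test_zero_without_shift_difference(self, field600):
        p = TwoStateParams(0.9, 1000.0, 0.0, {600.0: 12.0})
        r = rex(p, field600)
        assert r.value == 0.0 and not r.flagged

    def test_vanishes_as_minor_state_empties(self, field600):
        p = TwoStateParams(1.0 - 1e-9, 800.0, 2.0, {600.0: 12.0})
        assert rex(p, field600).value < 1e-3

    def test_matches_bm_frequency_sweep_difference(self, field600):
        p = TwoStateParams(0.95, 500.0, 2.0, {600.0: 12.0})
        net = KineticNetwork.two_state(0.95, 500.0, 2.0, {600.0: 12.0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bm_diff = (bm_r2eff(net, field600, 10.0)
                       - bm_r2eff(net, field600, 1.0e4))
        assert rex(p, field600).value == pytest.approx(bm_diff, rel=0.05)

    def test_field_squared_scaling_in_fast_exchange(self, field600, field950):
        # kex >> dw at both fields: Rex ~ pA pB dw^2 / kex scales with B0^2
        r2 = {600.0: 12.0, 950.0: 12.0}
        p = TwoStateParams(0.9, 20000.0, 0.5, r2)
        ratio = cr_rex(p, field950) / cr_rex(p, field600)
        assert ratio == pytest.approx((950.0 / 600.0) ** 2, rel=0.1)

    def test_threshold_is_strict(self, field600):
        r = cpmg.RexResult(5.0, False)
        assert not r.flagged  # constructed; flag logic checked via rex()
        p = TwoStateParams(0.95, 500.0, 2.0, {600.0: 12.0})
        assert rex(p, field600, threshold=1e6).flagged is False
        assert rex(p, field600, threshold=1.0).flagged is True


def test_curve_validation(field600):
    with pytest.raises(ValueError, match="strictly increasing"):
        DispersionCurve(1, field600, [100.0, 50.0, 200.0, 300.0],
                        [12, 12, 12, 12.0], [0, 0, 0, 0.0])
    with pytest.raises(ValueError, match="positive"):
        DispersionCurve(1, field600, [-1.0, 50.0, 100.0, 200.0],
                        [12, 12, 12, 12.0], [0, 0, 0, 0.0])


def test_dispersion_tsv_round_trip(tmp_path, field600, field950):
    truth = TwoStateParams(0.92, 800.0, 1.5, {600.0: 12.0, 950.0: 15.0})
    curves = [DispersionCurve(7, f, NU, np.asarray(cr_r2eff(truth, f, NU)),
                              np.full_like(NU, 0.3))
              for f in (field600, field950)]
    path = tmp_path / "disp.tsv"
    cpmg.write_dispersion_tsv(curves, path)
    back = cpmg.read_dispersion_tsv(path)
    assert len(back) == 2
    orig = {c.field.proton_mhz: c for c in curves}
    for c in back:
        np.testing.assert_allclose(c.r2eff, orig[c.field.proton_mhz].r2eff)
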