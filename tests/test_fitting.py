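"""Calibration fitting: exact recovery, the packaged-fixture fit, local
optimality, and the synthetic survival generator."""

import numpy as np
import pytest

from ionrbe import (
    AlphaSaturationModel,
    BetaSaturationModel,
    LQParams,
    LQSurvivalModel,
    ZSaturationModel,
    let_u_from_z,
    ZSaturationParams,
    generate_synthetic_survival,
)


class TestZSaturationFit:
    def test_noiseless_exact_recovery(self):
        truth = ZSaturationParams.from_amplitude(amplitude=200.0, k=0.4)
        z = np.array([1.0, 2.0, 4.0, 7.0, 12.0])
        y = let_u_from_z(z, truth)
        res = ZSaturationModel(z, y).fit()
        assert res.converged
        assert res.params["amplitude"] == pytest.approx(200.0, rel=1e-6)
        assert res.params["rate"] == pytest.approx(0.4, rel=1e-6)
        assert res.rss < 1e-12

    def test_packaged_fixture_fit(self, calibration):
        """The four pooled turnover points give k ~ 0.42 and amplitude
        S/k ~ 205 keV/um."""
        res = ZSaturationModel(calibration["z"], calibration["let_u"]).fit()
        assert res.converged
        assert res.params["rate"] == pytest.approx(0.423, abs=0.01)
        assert res.params["amplitude"] == pytest.approx(205.2, abs=1.0)
        # residuals recompute exactly from params and data
        pred = res.predict(calibration["z"])
        assert np.allclose(calibration["let_u"] - pred, res.resid, atol=1e-10)
        assert res.rss == pytest.approx(float(res.resid @ res.resid), rel=1e-10)

    def test_fixture_predicts_family_turnovers(self, fitted_z_params):
        """Predicted per-ion turnover LETs match the nine published family
        values to <= 2% relative (nearest integer for Z >= 6)."""
        family = {1: 30.5, 2: 103, 3: 150, 5: 200, 6: 213, 7: 221, 8: 227,
                  10: 232, 18: 237}
        for z, expected in family.items():
            pred = let_u_from_z(z, fitted_z_params)
            assert abs(pred - expected) / expected <= 0.02
        assert round(let_u_from_z(10, fitted_z_params)) == pytest.approx(232, abs=1)

    def test_anchor_held_fixed(self, calibration):
        res = ZSaturationModel(calibration["z"], calibration["let_u"]).fit()
        params = ZSaturationModel.results_to_params(res)
        assert let_u_from_z(1, params) == 30.5

    def test_free_anchor_variant(self, calibration):
        res = ZSaturationModel(calibration["z"], calibration["let_u"],
                               fix_anchor=False).fit()
        assert res.converged
        assert "anchor_let" in res.params
        # an extra free parameter cannot fit worse
        fixed = ZSaturationModel(calibration["z"], calibration["let_u"]).fit()
        assert res.rss <= fixed.rss + 1e-8

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            ZSaturationModel([1.0, 2.0], [30.5, 103.4])
        with pytest.raises(ValueError):
            ZSaturationModel([1.0, 2.0, 2.0], [30.5, 100.0, 105.0])

    def test_local_optimality_audit(self, calibration):
        """RSS at the fit is <= RSS everywhere on a 50x50 grid around it."""
        res = ZSaturationModel(calibration["z"], calibration["let_u"]).fit()
        z = calibration["z"].to_numpy()
        y = calibration["let_u"].to_numpy()
        amps = np.linspace(0.5, 1.5, 50) * res.params["amplitude"]
        rates = np.linspace(0.5, 1.5, 50) * res.params["rate"]
        grid_rss = np.array([
            [np.sum((y - 30.5 - a * (1 - np.exp(-k * (z - 1)))) ** 2)
             for k in rates] for a in amps
        ])
        assert res.rss <= grid_rss.min() + 1e-8


class TestRadiosensitivityFits:
    def test_linear_zero_residual(self):
        x = np.array([0.05, 0.1, 0.2, 0.3])
        res = AlphaSaturationModel(x, 6.47 * x, mode="linear").fit()
        assert res.params["slope"] == pytest.approx(6.47, rel=1e-12)
        assert res.rss == pytest.approx(0.0, abs=1e-20)

    def test_alpha_nonlinear_exact_recovery(self):
        x = np.linspace(0.02, 0.8, 9)
        y = (5.37 / 3.68) * (1 - np.exp(-3.68 * x))
        res = AlphaSaturationModel(x, y, mode="nonlinear").fit()
        assert res.params["slope"] == pytest.approx(5.37, rel=1e-6)  # A
        assert res.params["rate"] == pytest.approx(3.68, rel=1e-6)   # j
        assert AlphaSaturationModel.results_to_params(res).A == pytest.approx(
            5.37, rel=1e-6
        )

    def test_beta_nonlinear_exact_recovery(self):
        # steep rate (u = 25) sits at the top of the profile grid; the polish
        # must still recover it exactly
        x = np.linspace(0.005, 0.2, 8)
        y = (2.5 / 25.0) * (1 - np.exp(-25.0 * x))
        res = BetaSaturationModel(x, y, mode="nonlinear").fit()
        assert res.params["slope"] == pytest.approx(2.5, rel=1e-6)   # R
        assert res.params["rate"] == pytest.approx(25.0, rel=1e-6)   # u
        assert res.rss < 1e-12

    def test_noisy_slope_within_three_se(self):
        """Simulated noisy linear alpha data: the fitted slope lies within
        3 standard errors of the generating truth."""
        rng = np.random.default_rng(1234)
        x = np.linspace(0.05, 0.35, 12)
        y = 6.47 * x * np.exp(rng.normal(0.0, 0.05, x.size))
        res = AlphaSaturationModel(x, y, mode="linear").fit()
        assert abs(res.params["slope"] - 6.47) < 3 * res.bse["slope"]

    def test_consistency_as_n_grows(self):
        """On a fixed seed ladder the standard error shrinks with sample
        size and every estimate stays within 3 SE of the generating truth."""
        bses = []
        for n in (10, 40, 160, 640):
            rng = np.random.default_rng(99)
            x = np.linspace(0.02, 0.34, n)
            y = 6.47 * x * np.exp(rng.normal(0.0, 0.08, n))
            res = AlphaSaturationModel(x, y, mode="linear").fit()
            assert abs(res.params["slope"] - 6.47) < 3 * res.bse["slope"]
            bses.append(res.bse["slope"])
        assert np.all(np.diff(bses) < 0)


class TestLQSurvivalFit:
    DOSES = np.arange(1.0, 9.0)

    def test_exact_recovery(self):
        lq = LQParams(0.16, 0.046)
        sf = np.exp(-(0.16 * self.DOSES + 0.046 * self.DOSES**2))
        res = LQSurvivalModel(self.DOSES, sf).fit()
        assert res.params["alpha"] == pytest.approx(0.16, abs=1e-8)
        assert res.params["beta"] == pytest.approx(0.046, abs=1e-8)
        assert res.lq.alpha == pytest.approx(lq.alpha, abs=1e-8)
        assert res.lq.beta == pytest.approx(lq.beta, abs=1e-8)

    def test_pure_linear_beta_at_boundary(self):
        sf = np.exp(-0.3 * self.DOSES)
        res = LQSurvivalModel(self.DOSES, sf).fit()
        assert res.params["beta"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["alpha"] == pytest.approx(0.3, abs=1e-8)

    def test_mean_bias_small_over_replicates(self):
        """200 noisy replicates (CV 10%): mean alpha estimate within 5% of
        the generating truth."""
        truth = LQParams(0.16, 0.046)
        table = generate_synthetic_survival(truth, self.DOSES, noise_cv=0.1,
                                            n_reps=200, seed=2015)
        alphas = [
            LQSurvivalModel(g["dose"], np.clip(g["sf"], None, 1.0)).fit().params["alpha"]
            for _, g in table.groupby("rep")
        ]
        assert abs(np.mean(alphas) - truth.alpha) / truth.alpha < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            LQSurvivalModel([1.0, 2.0], [0.9, 0.8])  # too few points
        with pytest.raises(ValueError):
            LQSurvivalModel([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])  # no effect
        with pytest.raises(ValueError):
            LQSurvivalModel([1.0, 1.0, 2.0], [0.9, 0.9, 0.7])  # repeated dose


class TestSyntheticSurvival:
    def test_noise_free_is_exact_lq(self):
        lq = LQParams(0.2, 0.03)
        tab = generate_synthetic_survival(lq, [1.0, 2.0, 4.0])
        assert np.allclose(tab["sf"], np.exp(-(0.2 * tab["dose"] + 0.03 * tab["dose"]**2)))

    def test_seeded_determinism(self):
        lq = LQParams(0.2, 0.03)
        a = generate_synthetic_survival(lq, [1.0, 2.0, 4.0], 0.1, 5, seed=11)
        b = generate_synthetic_survival(lq, [1.0, 2.0, 4.0], 0.1, 5, seed=11)
        assert a.equals(b)
        c = generate_synthetic_survival(lq, [1.0, 2.0, 4.0], 0.1, 5, seed=12)
        assert not a["sf"].equals(c["sf"])

    def test_empirical_cv_matches_target(self):
        """Monte-Carlo: per-dose empirical CV of the noisy SF within 20% of
        the requested 0.1."""
        lq = LQParams(0.16, 0.046)
        tab = generate_synthetic_survival(lq, [2.0, 4.0, 6.0], noise_cv=0.1,
                                          n_reps=200, seed=3)
        for _, g in tab.groupby("dose"):
            cv = g["sf"].std(ddof=1) / g["sf"].mean()
            assert abs(cv - 0.1) / 0.1 < 0.2

    def test_seed_required_for_noise(self):
        with pytest.raises(ValueError):
            generate_synthetic_survival(LQParams(0.2, 0.03), [1.0], noise_cv=0.1)
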