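"""Prior risk, Gaussian marker likelihood ratios, posterior odds arithmetic."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from pescreen.cohort import MaternalRecord
from pescreen.params import default_prior_model
from pescreen.risk import (
    GaussianRiskModel,
    fit_gaussian_model,
    format_risk,
    marker_lr,
    posterior_risk,
    prior_risk,
    screen_positive,
)


def _record(weight=53.0, height=160.0, parity="parous", prior_pe=False, chtn=False):
    return MaternalRecord(
        id="X",
        age=30.0,
        weight=weight,
        height=height,
        ethnicity="chinese",
        smoking=False,
        parity=parity,
        prior_pe_history=prior_pe,
        chronic_hypertension=chtn,
        conception="spontaneous",
        ga_screening=89,
        crl=63.0,
    )


class TestPriorRisk:
    def test_reference_subject_gets_baseline(self):
        model = default_prior_model()
        rec = _record()  # BMI 20.7: reference band; all other factors reference
        assert prior_risk(rec, model, "early") == pytest.approx(model.baseline["early"])
        assert prior_risk(rec, model, "late") == pytest.approx(model.baseline["late"])

    def test_single_factor_odds_arithmetic(self):
        from pescreen.risk import PriorModel

        model = PriorModel(
            baseline={"early": 0.01},
            lr_tables={
                "early": {
                    "bmi": {"<25": 1.0, "25-30": 1.0, ">=30": 1.0},
                    "ethnicity": {"chinese": 1.0},
                    "parity": {"parous": 1.0, "nulliparous": 10.0},
                    "prior_pe": {"true": 1.0, "false": 1.0},
                    "chronic_htn": {"true": 1.0, "false": 1.0},
                }
            },
        )
        # baseline 1/100 -> odds 1/99, x10 -> 10/99 -> p = 10/109
        p = prior_risk(_record(parity="nulliparous"), model, "early")
        assert p == pytest.approx(10.0 / 109.0)

    def test_factor_order_irrelevant(self):
        model = default_prior_model()
        rec = _record(weight=75.0, parity="nulliparous", chtn=True)  # several factors on
        # compute expected by direct product of LRs in arbitrary orders
        p = prior_risk(rec, model, "early")
        table = model.lr_tables["early"]
        lrs = [
            table["bmi"][model.bmi_band(rec.bmi)],
            table["parity"]["nulliparous"],
            table["chronic_htn"]["true"],
        ]
        odds = model.baseline["early"] / (1 - model.baseline["early"])
        for lr in reversed(lrs):
            odds *= lr
        assert p == pytest.approx(odds / (1 + odds))

    def test_unmapped_level_errors(self):
        model = default_prior_model()
        rec = _record()
        object.__setattr__(rec, "ethnicity", "martian")
        with pytest.raises(ValueError):
            prior_risk(rec, model, "early")


class TestMarkerLR:
    def test_identical_hypotheses_give_unit_lr(self, rng):
        mean = np.array([0.0, 0.05, -0.03])
        cov = np.diag([0.02, 0.04, 0.05]) + 0.005
        for _ in range(5):
            x = rng.normal(0, 0.2, 3)
            assert marker_lr(x, (mean, cov), (mean, cov)) == pytest.approx(1.0)

    def test_one_dimensional_closed_form(self):
        # mu_affected=-0.14, mu_unaffected=0.05, shared sigma=0.2, x at mu_affected
        lr = marker_lr(
            np.array([-0.14]),
            (np.array([-0.14]), np.array([[0.04]])),
            (np.array([0.05]), np.array([[0.04]])),
        )
        assert lr == pytest.approx(np.exp(0.19**2 / (2 * 0.04)), rel=1e-12)
        assert lr == pytest.approx(1.5703, abs=1e-4)

    def test_matches_density_ratio_oracle(self, rng):
        """Log-space LR equals direct scipy density evaluation to 1e-10."""
        for _ in range(50):
            a_mean = rng.normal(0, 0.3, 3)
            u_mean = rng.normal(0, 0.3, 3)
            a_cov = _random_spd(rng)
            u_cov = _random_spd(rng)
            x = rng.normal(0, 0.5, 3)
            expected = multivariate_normal.pdf(x, a_mean, a_cov) / multivariate_normal.pdf(
                x, u_mean, u_cov
            )
            assert marker_lr(x, (a_mean, a_cov), (u_mean, u_cov)) == pytest.approx(
                expected, rel=1e-10
            )

    def test_monotone_decreasing_when_affected_below(self):
        a = (np.array([-0.14]), np.array([[0.04]]))
        u = (np.array([0.05]), np.array([[0.04]]))
        xs = np.linspace(-0.5, 0.5, 30)[:, None]
        lrs = marker_lr(xs, a, u)
        assert np.all(np.diff(lrs) < 0)

    def test_non_pd_covariance_errors(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="positive definite"):
            marker_lr(np.zeros(2), (np.zeros(2), bad), (np.zeros(2), np.eye(2)))


def _random_spd(rng, k=3):
    a = rng.normal(0, 0.2, (k, k))
    return a @ a.T + 0.05 * np.eye(k)


class TestPosterior:
    def test_unit_lr_preserves_prior(self):
        assert posterior_risk(0.013, 1.0) == pytest.approx(0.013)

    def test_odds_arithmetic(self):
        assert posterior_risk(0.5, 3.0) == pytest.approx(0.75)

    def test_composition_associativity(self, rng):
        for _ in range(50):
            p = rng.uniform(0.001, 0.999)
            a, b = rng.lognormal(0, 1.0, 2)
            two_step = posterior_risk(posterior_risk(p, a), b)
            one_step = posterior_risk(p, a * b)
            assert two_step == pytest.approx(one_step, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            posterior_risk(0.0, 2.0)
        with pytest.raises(ValueError):
            posterior_risk(0.5, -1.0)


class TestRiskFormatting:
    def test_one_in_n(self):
        assert format_risk(1 / 45) == "1 in 45"
        assert format_risk(0.05) == "1 in 20"
        assert format_risk(0.9) == "1 in 1"

    def test_cutoff_boundary_inclusive(self):
        assert screen_positive(0.05, 20) is True
        assert screen_positive(0.049, 20) is False
        assert screen_positive(0.2, 20) is True


class TestGaussianFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(77)
        mu_u = np.array([-0.013, 0.045, -0.032])
        mu_a = np.array([0.053, -0.143, -0.310])
        cov_u = np.diag([0.0466, 0.20, 0.21]) ** 2
        cov_a = np.diag([0.023, 0.196, 0.45]) ** 2
        n = 5000
        X = np.vstack(
            [
                rng.multivariate_normal(mu_u, cov_u, n),
                rng.multivariate_normal(mu_a, cov_a, n),
            ]
        )
        y = np.array(["none"] * n + ["early"] * n)
        model = fit_gaussian_model(X, y)
        np.testing.assert_allclose(model.means["none"], mu_u, atol=0.01)
        np.testing.assert_allclose(model.means["early"], mu_a, atol=0.02)
        np.testing.assert_allclose(model.covariances["none"], cov_u, atol=0.003)

    def test_identical_groups_equal_means(self, rng):
        X = np.tile(rng.normal(0, 0.2, (40, 3)), (2, 1))
        y = np.array(["none"] * 40 + ["early"] * 40)
        model = fit_gaussian_model(X, y)
        np.testing.assert_allclose(model.means["none"], model.means["early"])

    def test_diagonal_mode_zeroes_off_diagonals(self, rng):
        X = rng.multivariate_normal(np.zeros(3), _random_spd(rng), 200)
        y = np.array(["none"] * 100 + ["early"] * 100)
        model = fit_gaussian_model(X, y, covariance="diagonal")
        for cov in model.covariances.values():
            off = cov - np.diag(np.diag(cov))
            assert np.all(off == 0.0)

    def test_tiny_group_rejected(self, rng):
        X = rng.normal(0, 1, (5, 3))
        y = np.array(["none", "none", "none", "none", "early"])
        with pytest.raises(ValueError, match="early"):
            fit_gaussian_model(X, y)

    def test_singular_covariance_falls_back_to_diagonal(self, rng):
        X = np.zeros((40, 3))  # zero variance: singular
        X[:, 0] = rng.normal(0, 1, 40)
        X[:, 1] = X[:, 0]  # perfectly collinear
        y = np.array(["none"] * 20 + ["early"] * 20)
        with pytest.warns(UserWarning, match="diagonal"):
            model = fit_gaussian_model(X, y)
        for cov in model.covariances.values():
            assert GaussianRiskModel._is_pd(cov)

    def test_posterior_risk_sign_consistency(self, small_scored):
        """Posterior rises with MAP MoM, falls with PLGF/PAPP-A MoM, matching
        the direction of the published group shifts."""
        moms, status = small_scored
        X = moms[["log10_mom_map", "log10_mom_plgf", "log10_mom_pappa"]]
        est = GaussianRiskModel().fit(X, status)
        base = np.array([0.0, 0.0, 0.0])
        lr0 = est.likelihood_ratio(base[None, :], affected="early")[0]
        up_map = est.likelihood_ratio(np.array([[0.05, 0.0, 0.0]]), affected="early")[0]
        up_plgf = est.likelihood_ratio(np.array([[0.0, 0.1, 0.0]]), affected="early")[0]
        up_pappa = est.likelihood_ratio(np.array([[0.0, 0.0, 0.1]]), affected="early")[0]
        assert up_map > lr0
        assert up_plgf < lr0
        assert up_pappa < lr0

    def test_calibration_on_model_generated_cohort(self):
        """Mean posterior ~ prevalence when scores come from the true model."""
        rng = np.random.default_rng(5)
        prevalence = 0.02
        n = 20000
        affected = rng.random(n) < prevalence
        mu_u, mu_a = np.array([0.0]), np.array([0.15])
        cov = np.array([[0.04]])
        x = np.where(affected, rng.normal(0.15, 0.2, n), rng.normal(0.0, 0.2, n))[:, None]
        lr = marker_lr(x, (mu_a, cov), (mu_u, cov))
        post = posterior_risk(np.full(n, prevalence), lr)
        assert post.mean() == pytest.approx(affected.mean(), abs=0.005)
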