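"""MNL estimation against closed forms, finite differences, and grid search."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

import accesslogit as al
from accesslogit.choicedata import ChoiceDataset, ModelSpec
from accesslogit.mnl import (
    ConvergenceError,
    DestinationChoiceModel,
    NonIdentifiedError,
    choice_probabilities,
    horowitz_test,
    mcfadden_rho,
)


def long_df(obs):
    """Build a long frame from [(covariate vectors, chosen_index), ...]."""
    rows = []
    for i, (covs, chosen) in enumerate(obs):
        for j, x in enumerate(covs):
            rows.append({
                "obs_id": i, "zone_id": "z", "resource_id": f"r{j}",
                "chosen": j == chosen,
                **{f"x{k}": v for k, v in enumerate(np.atleast_1d(x))},
            })
    return pd.DataFrame(rows)


def model_from(obs, k=1):
    covs = [f"x{i}" for i in range(k)]
    return DestinationChoiceModel.from_dataframe(long_df(obs), covs)


class TestChoiceProbabilities:
    def test_equal_utilities_split_evenly(self):
        P = choice_probabilities([0.5], np.array([[1.0], [1.0]]))
        np.testing.assert_allclose(P, [0.5, 0.5])

    def test_zero_coef_gives_uniform_over_eleven(self):
        P = choice_probabilities([0.0], np.ones((11, 1)))
        np.testing.assert_allclose(P, np.full(11, 1 / 11))

    def test_dominant_alternative(self):
        P = choice_probabilities([1.0], np.array([[20.0], [0.0], [0.0]]))
        assert P[0] > 0.9999

    def test_probabilities_normalize_tightly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 7, 3))
        P = choice_probabilities(rng.normal(size=3), X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestLoglikAndScore:
    def test_null_loglik_closed_form(self):
        m = model_from([([0.0, 1.0, 2.0], 0)] * 5)
        assert m.loglike(np.zeros(1)) == pytest.approx(5 * math.log(1 / 3))
        assert m.llnull == pytest.approx(5 * math.log(1 / 3))

    def test_binary_logit_closed_form(self):
        # one obs, two alternatives, utility gap delta for the chosen one
        delta = 0.7
        m = model_from([([delta, 0.0], 0)])
        assert m.loglike(np.ones(1)) == pytest.approx(-math.log(1 + math.exp(-delta)))

    def test_score_matches_central_finite_differences(self):
        rng = np.random.default_rng(7)
        obs = [(rng.normal(size=(5, 3)), int(rng.integers(5))) for _ in range(12)]
        m = model_from(obs, k=3)
        beta = rng.normal(size=3) * 0.5
        g = m.score(beta)
        h = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fd = (m.loglike(beta + e) - m.loglike(beta - e)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_hessian_matches_score_finite_differences(self):
        rng = np.random.default_rng(8)
        obs = [(rng.normal(size=(4, 2)), int(rng.integers(4))) for _ in range(9)]
        m = model_from(obs, k=2)
        beta = np.array([0.3, -0.2])
        H = m.hessian(beta)
        h = 1e-6
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            fd = (m.score(beta + e) - m.score(beta - e)) / (2 * h)
            np.testing.assert_allclose(H[:, k], fd, rtol=1e-5, atol=1e-6)


class TestFit:
    def test_constant_covariate_not_identified(self):
        m_df = long_df([([1.0, 1.0, 1.0], 0)] * 4)
        with pytest.raises(NonIdentifiedError):
            DestinationChoiceModel.from_dataframe(m_df, ["x0"])

    def test_perfect_separation_detected(self):
        # chosen always has the strictly largest covariate -> divergence
        obs = [([1.0, 0.0], 0)] * 20
        with pytest.raises(ConvergenceError):
            model_from(obs).fit()

    def test_matches_grid_search_oracle_tiny_instance(self):
        obs = [([0.0, 1.0, 2.0], 2), ([0.0, 2.0, 1.0], 1), ([1.0, 0.0, 3.0], 0)]
        m = model_from(obs)

        # independent brute-force log-likelihood in plain python
        def brute_ll(b):
            total = 0.0
            for covs, chosen in obs:
                expv = [math.exp(b * x) for x in covs]
                total += math.log(expv[chosen] / sum(expv))
            return total

        oracle = minimize_scalar(lambda b: -brute_ll(b), bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-10})
        res = m.fit()
        assert res.params.iloc[0] == pytest.approx(oracle.x, abs=1e-4)

    def test_score_vanishes_and_ll_beats_null(self, park_dataset):
        res = DestinationChoiceModel(park_dataset).fit()
        assert res.converged
        assert np.max(np.abs(res.model.score(res.params.to_numpy()))) < 1e-6
        assert res.llf >= res.llnull
        assert res.rho_squared == pytest.approx(1 - res.llf / res.llnull)

    def test_vcov_positive_semidefinite(self, park_dataset):
        res = DestinationChoiceModel(park_dataset).fit()
        eig = np.linalg.eigvalsh(res.cov_params.to_numpy())
        assert eig.min() > -1e-10
        np.testing.assert_allclose(
            res.tvalues, res.params / np.sqrt(np.diag(res.cov_params)), rtol=1e-12
        )

    def test_summary_reports_fit_statistics(self, park_dataset):
        res = DestinationChoiceModel(park_dataset).fit()
        text = res.summary()
        assert "Num.Obs." in text and "Log Likelihood" in text and "McFadden Rho-Sq" in text

    def test_coefficient_file_roundtrip(self, park_dataset, tmp_path):
        import json

        res = DestinationChoiceModel(park_dataset).fit()
        p = tmp_path / "model.json"
        res.to_json(p)
        payload = json.loads(p.read_text())
        assert payload["coef"]["t_auto"] == pytest.approx(res.params["t_auto"])
        assert payload["n_alt"] == park_dataset.n_alt_per_obs


class TestMcFaddenRho:
    @pytest.mark.parametrize(
        "ll, n, expected",
        [
            (-8945.6, 9119, 0.591),   # park, car-time only
            (-14256.7, 10_000, 0.405),  # grocery, car-time only
            (-11198.0, 10_000, 0.533),  # library, car-time only
        ],
    )
    def test_published_convention_examples(self, ll, n, expected):
        assert round(mcfadden_rho(ll, n, 11), 3) == expected

    def test_null_model_gives_zero(self):
        assert mcfadden_rho(100 * math.log(1 / 11), 100, 11) == pytest.approx(0.0)


class TestHorowitz:
    LLNULL = 9119 * math.log(1 / 11)

    def test_identical_models_give_half(self):
        assert horowitz_test((-100.0, 3), (-100.0, 3), llnull=self.LLNULL) == pytest.approx(0.5)

    def test_park_all_models_closed_form(self):
        # two full park specifications, equal K=6, LLs -4603.5 vs -4603.2:
        # z = 0.3/|llnull|, stat = sqrt(0.6), p = Phi(-sqrt(0.6)) ~ 0.2193
        p = horowitz_test((-4603.5, 6), (-4603.2, 6), llnull=self.LLNULL)
        assert p == pytest.approx(norm.cdf(-math.sqrt(0.6)), abs=1e-12)
        assert p == pytest.approx(0.2193, abs=1e-4)

    def test_monotone_in_dataset_size_at_fixed_z(self):
        # same adjusted-rho-sq gap on a dataset twice the size -> smaller p
        p1 = horowitz_test((-4603.5, 6), (-4603.2, 6), llnull=self.LLNULL)
        p2 = horowitz_test((-4603.5, 6), (-4602.9, 6), llnull=2 * self.LLNULL)
        assert p2 < p1

    def test_wrong_order_rejected(self):
        with pytest.raises(ValueError):
            horowitz_test((-100.0, 3), (-200.0, 3), llnull=self.LLNULL)
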