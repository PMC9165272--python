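"""Conditional-logit choice model: utilities, probabilities, estimation."""

import numpy as np
import pandas as pd
import pytest

import hospvol as hv
from hospvol.choice import CHARACTERISTICS, Coefficients, fit_coefficients, modal_choices
from hospvol.curves import InputError


def _patients(n, rng=None, **over):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "id": [f"p{i:04d}" for i in range(n)],
            "province": over.get("province", "A"),
            "age": rng.standard_normal(n),
            "sex": rng.binomial(1, 0.5, n),
            "rurality": rng.binomial(1, 0.3, n),
            "admission_type": rng.binomial(1, 0.35, n),
            "comorbidity": rng.binomial(1, 0.4, n),
        }
    ).set_index("id", drop=False)
    return df


def _dist(patients, dists_by_hosp):
    return pd.DataFrame(dists_by_hosp, index=patients.index)


class TestUtility:
    def test_distance_and_quality_terms_cancel(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        assert hv.utility(c, np.zeros(5), d=10.0, lagged_volume=100.0) == pytest.approx(0.0)

    def test_zero_inputs_zero_utility(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        assert hv.utility(c, np.ones(5), d=0.0, lagged_volume=0.0) == 0.0

    def test_characteristic_interaction_shifts_distance_slope(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.0, alpha_d=(-0.05, 0, 0, 0, 0))
        g = np.array([1.0, 0, 0, 0, 0])  # age = 1
        assert hv.utility(c, g, d=10.0, lagged_volume=0.0) == pytest.approx(-1.5)

    def test_dimension_mismatch_rejected(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        with pytest.raises(InputError):
            hv.utility(c, np.zeros(3), 1.0, 1.0)


class TestChoiceProbabilities:
    def test_symmetric_pair_splits_evenly(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        pats = _patients(4)
        dist = _dist(pats, {"h1": 7.0, "h2": 7.0})
        vols = pd.Series({"h1": 30.0, "h2": 30.0})
        P = hv.choice_probabilities(c, pats, dist, vols)
        assert np.allclose(P.to_numpy(), 0.5)

    def test_singleton_choice_set_is_certain(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        pats = _patients(3)
        dist = _dist(pats, {"h1": 3.0, "h2": 9.0})
        vols = pd.Series({"h1": 30.0, "h2": 10.0})
        P = hv.choice_probabilities(c, pats, dist, vols, open_ids=["h2"])
        assert np.allclose(P.to_numpy(), 1.0)

    def test_log_spaced_utilities_give_known_shares(self):
        # utilities (0, ln2, ln4) via quality volumes with beta_q = 1 -> shares 1/7, 2/7, 4/7
        c = Coefficients(beta_d=-0.1, beta_q=1.0)
        pats = _patients(2)
        dist = _dist(pats, {"h1": 0.0, "h2": 0.0, "h3": 0.0})
        vols = pd.Series({"h1": 0.0, "h2": np.log(2), "h3": np.log(4)})
        P = hv.choice_probabilities(c, pats, dist, vols)
        assert np.allclose(P.to_numpy(), [[1 / 7, 2 / 7, 4 / 7]] * 2, atol=1e-12)

    def test_literal_ratio_mode_matches_plain_ratio(self):
        c = Coefficients(beta_d=0.0, beta_q=1.0)  # positive utilities only
        pats = _patients(2)
        dist = _dist(pats, {"h1": 0.0, "h2": 0.0})
        vols = pd.Series({"h1": 1.0, "h2": 3.0})
        P = hv.choice_probabilities(c, pats, dist, vols, mode="literal-ratio")
        assert np.allclose(P.to_numpy(), [[0.25, 0.75]] * 2)

    def test_literal_ratio_refuses_nonpositive_utilities(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        pats = _patients(2)
        dist = _dist(pats, {"h1": 100.0, "h2": 80.0})
        vols = pd.Series({"h1": 5.0, "h2": 5.0})
        with pytest.raises(InputError, match="literal-ratio"):
            hv.choice_probabilities(c, pats, dist, vols, mode="literal-ratio")

    def test_empty_choice_set_rejected(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        pats = _patients(1)
        with pytest.raises(InputError):
            hv.choice_probabilities(c, pats, _dist(pats, {"h1": 1.0}), pd.Series(dtype=float), open_ids=[])

    def test_normalization_and_conservation_on_random_patients(self):
        """Rows sum to 1 (1e-12) and predicted volumes conserve patients (1e-9)."""
        rng = np.random.default_rng(99)
        c = Coefficients(beta_d=-0.08, beta_q=0.012, alpha_d=(-0.01, 0.002, 0.0, 0.003, 0.0))
        pats = _patients(1000, rng)
        hosp = [f"h{j}" for j in range(8)]
        dist = pd.DataFrame(rng.uniform(1, 120, (1000, 8)), index=pats.index, columns=hosp)
        vols = pd.Series(rng.integers(5, 300, 8).astype(float), index=hosp)
        P = hv.choice_probabilities(c, pats, dist, vols)
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) <= 1e-12
        pred = hv.predict_volumes(c, pats, dist, vols)
        assert abs(pred.sum() - 1000) <= 1e-9

    def test_quality_shift_common_to_all_hospitals_changes_nothing(self):
        """Translation invariance: a constant added to every utility (here via a
        uniform lagged-volume shift) leaves softmax probabilities unchanged."""
        rng = np.random.default_rng(5)
        c = Coefficients(beta_d=-0.08, beta_q=0.012)
        pats = _patients(50, rng)
        hosp = ["h1", "h2", "h3"]
        dist = pd.DataFrame(rng.uniform(1, 60, (50, 3)), index=pats.index, columns=hosp)
        vols = pd.Series([20.0, 90.0, 150.0], index=hosp)
        P1 = hv.choice_probabilities(c, pats, dist, vols)
        P2 = hv.choice_probabilities(c, pats, dist, vols + 500.0)
        assert np.allclose(P1.to_numpy(), P2.to_numpy(), atol=1e-12)

    def test_monotone_in_own_distance_and_volume(self):
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        pats = _patients(1)
        vols = pd.Series({"h1": 50.0, "h2": 50.0})
        base = hv.choice_probabilities(c, pats, _dist(pats, {"h1": 10.0, "h2": 10.0}), vols)
        farther = hv.choice_probabilities(c, pats, _dist(pats, {"h1": 20.0, "h2": 10.0}), vols)
        assert farther.iloc[0]["h1"] < base.iloc[0]["h1"]
        bigger = hv.choice_probabilities(
            c, pats, _dist(pats, {"h1": 10.0, "h2": 10.0}), pd.Series({"h1": 80.0, "h2": 50.0})
        )
        assert bigger.iloc[0]["h1"] > base.iloc[0]["h1"]


class TestSimulateChoices:
    def test_degenerate_probabilities_always_chosen(self):
        c = Coefficients(beta_d=-1.0, beta_q=0.0)
        pats = _patients(20)
        dist = _dist(pats, {"h1": 0.0, "h2": 100.0})  # h2 utility is hopeless
        vols = pd.Series({"h1": 0.0, "h2": 0.0})
        chosen = hv.simulate_choices(c, pats, dist, vols, seed=1)
        assert (chosen == "h1").all()

    def test_fixed_seed_reproducible(self):
        c = Coefficients(beta_d=-0.05, beta_q=0.01)
        pats = _patients(100)
        dist = _dist(pats, {"h1": 5.0, "h2": 9.0})
        vols = pd.Series({"h1": 40.0, "h2": 60.0})
        a = hv.simulate_choices(c, pats, dist, vols, seed=123)
        b = hv.simulate_choices(c, pats, dist, vols, seed=123)
        assert a.equals(b)

    def test_symmetric_pair_shares_near_half(self):
        n = 10_000
        c = Coefficients(beta_d=-0.1, beta_q=0.01)
        pats = _patients(n)
        dist = _dist(pats, {"h1": 7.0, "h2": 7.0})
        vols = pd.Series({"h1": 30.0, "h2": 30.0})
        chosen = hv.simulate_choices(c, pats, dist, vols, seed=42)
        share = (chosen == "h1").mean()
        assert abs(share - 0.5) <= 3 * np.sqrt(0.25 / n)


class TestFitCoefficients:
    # survival::clogit estimates on the identical deterministic dataset
    # (region seed 9, history seed 77), frozen as an independent oracle
    R_COEF = [-0.08148932, 0.01183690, 0.00779049, -0.06040776, 0.00851758,
              -0.00458306, -0.01534216, 0.00533758, 0.00907558, -0.01406734,
              -0.01258441, 0.00954437]
    R_SE = [0.02306275, 0.00899178, 0.01445547, 0.03645834, 0.02585408,
            0.02717315, 0.02783079, 0.00609682, 0.01224740, 0.01089900,
            0.01075613, 0.01063027]
    R_LOGLIK = -79.81376081

    @staticmethod
    def _oracle_records():
        cfg = hv.RegionConfig(
            seed=9,
            hospitals_per_province=(2, 2),
            total_patients=150,
            T=20,
            true_coeffs=Coefficients(beta_d=-0.10, beta_q=0.01),
        )
        inst, pats, dist = hv.generate_region(cfg)
        return hv.generate_choice_history(inst, pats, dist, cfg.true_coeffs, n_years=1, seed=77)

    def test_matches_independent_partial_likelihood_fit(self):
        """Our MLE equals an independent conditional-likelihood implementation."""
        fit = fit_coefficients(self._oracle_records())
        assert fit.converged
        assert np.allclose(fit.coefficients.as_vector(), self.R_COEF, atol=1e-5)
        assert np.allclose(fit.std_errors.as_vector(), self.R_SE, atol=1e-5)
        assert fit.loglik == pytest.approx(self.R_LOGLIK, abs=1e-5)

    def test_null_model_estimates_near_zero(self):
        cfg = hv.RegionConfig(seed=3, hospitals_per_province=(2, 2), total_patients=300, T=20)
        inst, pats, dist = hv.generate_region(cfg)
        null = Coefficients(0.0, 0.0)
        rec = hv.generate_choice_history(inst, pats, dist, null, n_years=3, seed=11)
        fit = fit_coefficients(rec)
        assert fit.converged
        z = np.abs(fit.coefficients.as_vector() / fit.std_errors.as_vector())
        assert np.all(z <= 3.0)

    def test_likelihood_at_optimum_dominates_truth(self):
        records = self._oracle_records()
        fit = fit_coefficients(records)
        truth = Coefficients(beta_d=-0.10, beta_q=0.01)

        # independent log-likelihood evaluation at the true parameters
        def loglik(coeffs):
            ll = 0.0
            for _, grp in records.groupby("decision_id", sort=False):
                u = np.array(
                    [
                        hv.utility(coeffs, r[list(CHARACTERISTICS)].to_numpy(float),
                                   r.distance, r.lagged_volume)
                        for _, r in grp.iterrows()
                    ]
                )
                ll += u[grp["chosen"].to_numpy(bool)][0] - np.log(np.sum(np.exp(u)))
            return ll

        assert fit.loglik >= loglik(truth) - 1e-9

    def test_single_alternative_sets_flagged_non_identified(self):
        rec = pd.DataFrame(
            {
                "decision_id": ["d1", "d2"],
                "hospital_id": ["h1", "h1"],
                "chosen": [1, 1],
                "distance": [5.0, 7.0],
                "lagged_volume": [10.0, 10.0],
                **{c: [0.0, 1.0] for c in CHARACTERISTICS},
            }
        )
        fit = fit_coefficients(rec)
        assert not fit.converged
        assert "single alternative" in fit.message

    def test_two_chosen_rows_in_one_decision_rejected(self):
        rec = pd.DataFrame(
            {
                "decision_id": ["d1", "d1"],
                "hospital_id": ["h1", "h2"],
                "chosen": [1, 1],
                "distance": [5.0, 7.0],
                "lagged_volume": [10.0, 20.0],
                **{c: [0.0, 0.0] for c in CHARACTERISTICS},
            }
        )
        with pytest.raises(InputError):
            fit_coefficients(rec)


class TestAdherence:
    def test_all_in_province_zero_divergence(self):
        chosen = pd.Series({"p1": "h1", "p2": "h1"})
        prov = pd.Series({"p1": "A", "p2": "A"})
        assert hv.adherence_rate(chosen, prov, {"A": ["h1"]}) == 0.0

    def test_all_out_of_province_full_divergence(self):
        chosen = pd.Series({"p1": "h9", "p2": "h9"})
        prov = pd.Series({"p1": "A", "p2": "A"})
        assert hv.adherence_rate(chosen, prov, {"A": ["h1"]}) == 1.0

    def test_expected_divergence_matches_hand_count(self):
        P = pd.DataFrame({"h1": [0.8, 0.3], "h2": [0.2, 0.7]}, index=["p1", "p2"])
        prov = pd.Series({"p1": "A", "p2": "B"})
        # p1's planned set is {h1} -> 0.2 leaks; p2's is {h2} -> 0.3 leaks
        div = hv.expected_divergence(P, prov, {"A": ["h1"], "B": ["h2"]})
        assert div == pytest.approx(0.25)

    def test_modal_choice_picks_highest_probability(self):
        P = pd.DataFrame({"h1": [0.8, 0.3], "h2": [0.2, 0.7]}, index=["p1", "p2"])
        assert modal_choices(P).tolist() == ["h1", "h2"]
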