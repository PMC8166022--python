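import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_network, make_response

from mlcdn.io import CONTINUOUS, FeatureMatrix, ResponseMatrix
from mlcdn.model import (
    MLCDN,
    DecayParams,
    decay_weight,
    grid_search,
    objective,
    predict_loo,
    predict_new,
    similarity_to_training,
)
from mlcdn.similarity import SimilarityNetwork
from oracles import oracle_objective, oracle_predict_loo, oracle_predict_new


def all_ones_network(ids, layer="path"):
    return SimilarityNetwork(ids, np.ones((len(ids), len(ids))), layer, "pearson")


class TestDecayWeight:
    def test_hand_value(self):
        assert decay_weight(0.9, 0.1) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_perfect_similarity_gives_unit_weight(self):
        for decay in (0.01, 0.3, 1.0):
            assert decay_weight(1.0, decay) == 1.0

    def test_zero_decay_indicator_limit(self):
        assert decay_weight(1.0, 0.0) == 1.0
        assert decay_weight(0.99, 0.0) == 0.0
        assert decay_weight(-0.5, 0.0) == 0.0

    def test_similarity_above_one_rejected_but_rounding_tolerated(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            decay_weight(1.1, 0.5)
        assert decay_weight(1.0 + 1e-12, 0.5) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(-1.0, 1.0 - 1e-6),
        st.floats(-1.0, 1.0),
        st.floats(1e-3, 1.0),
        st.floats(1e-3, 1.0),
    )
    def test_monotone_in_rho_and_in_decay(self, rho, rho2, d1, d2):
        lo_rho, hi_rho = sorted((rho, rho2))
        lo_d, hi_d = sorted((d1, d2))
        assert decay_weight(lo_rho, lo_d) <= decay_weight(hi_rho, lo_d) + 1e-15
        assert decay_weight(lo_rho, lo_d) <= decay_weight(lo_rho, hi_d) + 1e-15


class TestPredictLoo:
    def test_constant_responses_predict_the_constant(self, rng):
        resp = make_response(rng, 6, 5, missing_frac=0.3)
        const = resp.values.where(resp.values.isna(), 2.5)
        resp_c = ResponseMatrix(const)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        pred = predict_loo(resp_c, csn, dsn, DecayParams(0.3, 0.4))
        defined = pred.defined_mask.to_numpy()
        np.testing.assert_allclose(pred.values.to_numpy()[defined], 2.5, atol=1e-12)

    def test_two_by_two_unit_similarity_averages_other_three(self):
        vals = pd.DataFrame([[1.0, 2.0], [3.0, 5.0]], index=["C0", "C1"], columns=["D0", "D1"])
        resp = ResponseMatrix(vals)
        csn = all_ones_network(["C0", "C1"])
        dsn = all_ones_network(["D0", "D1"], layer="sens")
        pred = predict_loo(resp, csn, dsn, DecayParams(0.5, 0.5))
        assert pred.values.loc["C0", "D0"] == pytest.approx((2.0 + 3.0 + 5.0) / 3)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(10):
            resp = make_response(rng, 10, 8, missing_frac=0.2)
            csn = make_network(rng, resp.cell_ids)
            dsn = make_network(rng, resp.drug_ids, layer="sens")
            sigma, tau = rng.uniform(0.01, 1.0, size=2)
            params = DecayParams(float(sigma), float(tau))
            pred = predict_loo(resp, csn, dsn, params)
            exp_pred, exp_def = oracle_predict_loo(
                resp.values.to_numpy(),
                csn.aligned_rho(resp.cell_ids),
                dsn.aligned_rho(resp.drug_ids),
                params.sigma,
                params.tau,
            )
            np.testing.assert_allclose(pred.values.to_numpy(), exp_pred, atol=1e-10)
            np.testing.assert_array_equal(pred.defined_mask.to_numpy(), exp_def)

    def test_predictions_bounded_by_observed_range(self, rng):
        resp = make_response(rng, 8, 6, missing_frac=0.25)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        pred = predict_loo(resp, csn, dsn, DecayParams(0.2, 0.2))
        obs = resp.observed_values()
        vals = pred.values.to_numpy()[pred.defined_mask.to_numpy()]
        assert vals.min() >= obs.min() - 1e-12
        assert vals.max() <= obs.max() + 1e-12

    def test_affine_equivariance_of_predictions(self, rng):
        resp = make_response(rng, 7, 6, missing_frac=0.2)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        params = DecayParams(0.3, 0.3)
        base = predict_loo(resp, csn, dsn, params)
        scaled = predict_loo(ResponseMatrix(resp.values * 3.0 - 1.5), csn, dsn, params)
        np.testing.assert_allclose(
            scaled.values.to_numpy(), base.values.to_numpy() * 3.0 - 1.5, atol=1e-9
        )

    def test_invariant_under_simultaneous_permutation(self, rng):
        resp = make_response(rng, 6, 5, missing_frac=0.2)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        params = DecayParams(0.4, 0.25)
        base = predict_loo(resp, csn, dsn, params)
        cp = rng.permutation(6)
        dp = rng.permutation(5)
        perm_resp = ResponseMatrix(resp.values.iloc[cp, dp])
        perm = predict_loo(perm_resp, csn, dsn, params)
        np.testing.assert_allclose(
            perm.values.to_numpy(), base.values.to_numpy()[np.ix_(cp, dp)], atol=1e-10
        )

    def test_targets_restrict_output(self, rng):
        resp = make_response(rng, 5, 4, missing_frac=0.0)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        pred = predict_loo(resp, csn, dsn, DecayParams(0.3, 0.3), targets=[("C0", "D1")])
        assert pred.values.notna().sum().sum() == 1
        assert bool(pred.defined_mask.loc["C0", "D1"])

    def test_id_mismatch_rejected(self, rng):
        resp = make_response(rng, 5, 4)
        csn = make_network(rng, ["X0", "X1", "X2", "X3", "X4"])
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        with pytest.raises(ValueError, match="missing"):
            predict_loo(resp, csn, dsn, DecayParams(0.3, 0.3))


class TestObjective:
    def test_zero_for_constant_responses(self, rng):
        resp = ResponseMatrix(pd.DataFrame(np.full((5, 4), 1.7)))
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        for sigma, tau in [(0.0, 0.0), (0.05, 0.5), (1.0, 1.0)]:
            assert objective(resp, csn, dsn, DecayParams(sigma, tau)) == pytest.approx(0.0, abs=1e-18)

    def test_single_observed_pair_scores_zero_via_fallback(self, rng):
        vals = pd.DataFrame(np.full((3, 3), np.nan))
        vals.iloc[1, 2] = 4.0
        resp = ResponseMatrix(vals)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        # only pair excluded from its own sum -> fallback = global mean = the value itself
        assert objective(resp, csn, dsn, DecayParams(0.3, 0.3)) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        resp = make_response(rng, 8, 6, missing_frac=0.2)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        params = DecayParams(0.35, 0.2)
        expected = oracle_objective(
            resp.values.to_numpy(),
            csn.aligned_rho(resp.cell_ids),
            dsn.aligned_rho(resp.drug_ids),
            params.sigma,
            params.tau,
        )
        assert objective(resp, csn, dsn, params) == pytest.approx(expected, abs=1e-8)


class TestGridSearch:
    def test_constant_response_tie_breaks_to_origin(self, rng):
        resp = ResponseMatrix(pd.DataFrame(np.full((4, 4), 3.0)))
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        gs = grid_search(resp, csn, dsn, grid_step=0.25)
        assert (gs.best.sigma, gs.best.tau) == (0.0, 0.0)
        assert gs.j_best == 0.0
        np.testing.assert_allclose(gs.surface.to_numpy(), 0.0, atol=1e-18)

    def test_surface_matches_pointwise_objective(self, rng):
        resp = make_response(rng, 6, 5, missing_frac=0.2)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        gs = grid_search(resp, csn, dsn, grid_step=0.1)
        for sigma in gs.surface.index:
            for tau in gs.surface.columns:
                J = objective(resp, csn, dsn, DecayParams(float(sigma), float(tau)))
                assert gs.surface.loc[sigma, tau] == J
        flat = gs.surface.to_numpy()
        assert gs.j_best == flat.min()

    def test_argmin_is_first_minimum_in_sigma_then_tau_order(self, rng):
        resp = make_response(rng, 5, 5, missing_frac=0.0)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        gs = grid_search(resp, csn, dsn, grid_step=0.2)
        J = gs.surface.to_numpy()
        a, b = np.unravel_index(np.argmin(J), J.shape)
        assert gs.best.sigma == float(gs.surface.index[a])
        assert gs.best.tau == float(gs.surface.columns[b])


class TestNewSample:
    def test_similarity_to_training_endpoints(self, rng):
        basis_vals = rng.normal(size=(5, 12))
        basis = FeatureMatrix(
            pd.DataFrame(basis_vals, index=[f"C{i}" for i in range(5)]), CONTINUOUS
        )
        rho = similarity_to_training(basis_vals[3], basis)
        assert rho["C3"] == pytest.approx(1.0)
        neg = similarity_to_training(-(basis_vals[2] - basis_vals[2].mean()), basis)
        assert neg["C2"] == pytest.approx(-1.0)

    def test_similarity_to_training_matches_per_pair_oracle(self, rng):
        from oracles import oracle_pearson

        basis_vals = rng.normal(size=(5, 15))
        basis = FeatureMatrix(
            pd.DataFrame(basis_vals, index=[f"C{i}" for i in range(5)]), CONTINUOUS
        )
        x = rng.normal(size=15)
        rho = similarity_to_training(x, basis)
        for i in range(5):
            assert rho[f"C{i}"] == pytest.approx(oracle_pearson(x, basis_vals[i]), abs=1e-12)

    def test_feature_mismatch_reports_symmetric_difference(self, rng):
        basis = FeatureMatrix(
            pd.DataFrame(rng.normal(size=(4, 3)), columns=["a", "b", "c"]), CONTINUOUS
        )
        profile = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "z"])
        with pytest.raises(ValueError, match="missing \\['c'\\], unexpected \\['z'\\]"):
            similarity_to_training(profile, basis)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(10):
            resp = make_response(rng, 10, 8, missing_frac=0.2)
            dsn = make_network(rng, resp.drug_ids, layer="sens")
            rho_sample = rng.uniform(-1.0, 1.0, size=10)
            sigma, tau = rng.uniform(0.01, 1.0, size=2)
            params = DecayParams(float(sigma), float(tau))
            pred = predict_new(rho_sample, resp, dsn, params)
            exp_pred, exp_def = oracle_predict_new(
                resp.values.to_numpy(),
                rho_sample,
                dsn.aligned_rho(resp.drug_ids),
                params.sigma,
                params.tau,
            )
            np.testing.assert_allclose(pred.values.to_numpy()[0], exp_pred, atol=1e-10)
            np.testing.assert_array_equal(pred.defined_mask.to_numpy()[0], exp_def)

    def test_constant_responses_predict_the_constant(self, rng):
        resp = ResponseMatrix(pd.DataFrame(np.full((5, 4), -0.7)))
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        pred = predict_new(rng.uniform(-1, 1, size=5), resp, dsn, DecayParams(0.5, 0.5))
        np.testing.assert_allclose(pred.values.to_numpy(), -0.7, atol=1e-12)

    def test_differs_from_loo_only_by_target_term(self, rng):
        """A new sample identical to training cell line C: the Eq-1 and Eq-5
        sums differ only by the (C, D) term itself."""
        resp = make_response(rng, 6, 5, missing_frac=0.0)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        params = DecayParams(0.4, 0.3)
        c = 2
        rho_sample = csn.aligned_rho(resp.cell_ids)[c]
        new = predict_new(rho_sample, resp, dsn, params).values.to_numpy()[0]
        loo = predict_loo(resp, csn, dsn, params).values.to_numpy()[c]
        rho_d = dsn.aligned_rho(resp.drug_ids)
        R = resp.values.to_numpy()
        Wc = np.exp(-((1 - csn.aligned_rho(resp.cell_ids)) ** 2) / (2 * params.sigma**2))
        Wd = np.exp(-((1 - rho_d) ** 2) / (2 * params.tau**2))
        for d in range(5):
            num = loo_num = 0.0
            den = loo_den = 0.0
            for k in range(6):
                for l in range(5):
                    w = Wc[c, k] * Wd[d, l]
                    num += w * R[k, l]
                    den += w
                    if not (k == c and l == d):
                        loo_num += w * R[k, l]
                        loo_den += w
            assert new[d] == pytest.approx(num / den, abs=1e-10)
            assert loo[d] == pytest.approx(loo_num / loo_den, abs=1e-10)

    def test_length_mismatch_rejected(self, rng):
        resp = make_response(rng, 5, 4)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        with pytest.raises(ValueError, match="length"):
            predict_new(np.ones(3), resp, dsn, DecayParams(0.3, 0.3))


class TestModelFrontEnd:
    def test_fit_reproduces_grid_search_and_summarizes(self, rng):
        resp = make_response(rng, 8, 6, missing_frac=0.15)
        csn = make_network(rng, resp.cell_ids)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        res = MLCDN(resp, csn, dsn).fit(grid_step=0.1)
        gs = grid_search(resp, csn, dsn, grid_step=0.1)
        assert res.params == gs.best
        assert res.j_best == gs.j_best
        text = res.summary()
        assert "sigma" in text and "tau" in text
        assert f"{res.params.sigma:.4g}" in text

    def test_results_predict_new_accepts_profile_and_basis(self, rng):
        resp = make_response(rng, 6, 5, missing_frac=0.1)
        basis_vals = rng.normal(size=(6, 20))
        basis = FeatureMatrix(pd.DataFrame(basis_vals, index=resp.cell_ids), CONTINUOUS)
        from mlcdn.similarity import pearson_similarity

        csn = pearson_similarity(basis)
        dsn = make_network(rng, resp.drug_ids, layer="sens")
        res = MLCDN(resp, csn, dsn).fit(grid_step=0.25)
        via_profile = res.predict_new(sample_profile=basis_vals[1], basis=basis)
        via_rho = res.predict_new(rho_sample=csn.aligned_rho(resp.cell_ids)[1])
        np.testing.assert_allclose(
            via_profile.values.to_numpy(), via_rho.values.to_numpy(), atol=1e-10
        )
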