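"""Unit tests for the model equations and containers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from notreached.model_core import (
    Dataset,
    DropoutParams,
    ItemResponseParams,
    PersonHyperParams,
    QMatrix,
    attribute_prob,
    cell_loglik,
    conjunction,
    dropout_hazard,
    inverse_reparameterize,
    reparameterize_gs,
    response_prob,
    row_loglik,
)


class TestResponseProb:
    @pytest.mark.parametrize("alpha,q,beta,delta,expected", [
        ([1, 1], [1, 1], 0.0, 0.0, 0.5),            # neutral logit
        ([0, 1], [1, 0], -2.197, 4.394, 0.0999),    # guessing effect ~0.1
        ([1, 1], [1, 1], -2.197, 4.394, 0.9001),    # 1 - slipping ~0.9
        ([1, 0], [0, 1], -2.197, 4.394, 0.0999),    # required attribute absent
    ])
    def test_values(self, alpha, q, beta, delta, expected):
        assert response_prob(np.array(alpha), np.array(q), beta, delta) == \
            pytest.approx(expected, abs=1e-3)

    def test_two_values_per_item_over_all_profiles(self):
        """Over all 2^K profiles an item takes exactly the values g and 1-s."""
        rng = np.random.default_rng(0)
        for K in (2, 3, 5):
            q = (rng.random(K) < 0.6).astype(int)
            q[rng.integers(K)] = 1
            beta, delta = -1.3, 2.9
            profiles = np.array(np.meshgrid(*[[0, 1]] * K)).T.reshape(-1, K)
            probs = {round(float(response_prob(a, q, beta, delta)), 12)
                     for a in profiles}
            assert probs == {round(float(expit(beta)), 12),
                             round(float(expit(beta + delta)), 12)}

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            response_prob(np.array([1, 0, 1]), np.array([1, 0]), 0.0, 1.0)


class TestReparameterization:
    def test_paper_anchor(self):
        beta, delta = reparameterize_gs(0.1, 0.1)
        assert beta == pytest.approx(-2.197, abs=1e-3)
        assert delta == pytest.approx(4.394, abs=1e-3)

    def test_neutral(self):
        assert reparameterize_gs(0.5, 0.5) == pytest.approx((0.0, 0.0))

    @given(st.floats(-5, 5), st.floats(0.05, 8))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, beta, delta):
        """(beta, delta) -> (g, s) -> (beta, delta) is the identity."""
        g, s = inverse_reparameterize(beta, delta)
        b2, d2 = reparameterize_gs(g, s)
        assert b2 == pytest.approx(beta, abs=1e-10)
        assert d2 == pytest.approx(delta, abs=1e-10)

    @pytest.mark.parametrize("g,s", [(0.0, 0.1), (1.0, 0.1), (0.1, -0.2)])
    def test_domain_errors(self, g, s):
        with pytest.raises(ValueError):
            reparameterize_gs(g, s)


class TestDropoutHazard:
    def test_threshold_at_last_item(self):
        # theta_d = eta0 at j = J puts the logit argument exactly at zero
        assert dropout_hazard(1.0, 30, 30, 1.0, -0.7) == pytest.approx(0.5)

    def test_last_and_first_item_levels(self):
        assert dropout_hazard(0.0, 30, 30, 1.0, -0.7) == pytest.approx(expit(-1.0))
        assert dropout_hazard(0.0, 1, 30, 1.0, -0.7) == pytest.approx(expit(-21.3), rel=1e-6)
        assert dropout_hazard(0.0, 1, 30, 1.0, -0.7) < 1e-9

    def test_monotone_in_position_and_propensity(self):
        j = np.arange(1, 31)
        h = dropout_hazard(0.3, j, 30, 1.0, -0.32)
        assert (np.diff(h) > 0).all()
        assert dropout_hazard(1.0, 15, 30, 1.0, -0.32) > \
            dropout_hazard(0.0, 15, 30, 1.0, -0.32)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            dropout_hazard(0.0, 31, 30, 1.0, -0.7)

    def test_linear_restriction_anchors_last_item(self):
        dp = DropoutParams(eta0=1.0, eta1=-0.32)
        assert dp.beta_d(30)[-1] == pytest.approx(1.0)


class TestAttributeProb:
    def test_indifference_point(self):
        assert attribute_prob(-1.0 / 1.5, 1.5, -1.0) == pytest.approx(0.5)

    def test_study_truth_value(self):
        assert attribute_prob(0.0, 1.5, -1.0) == pytest.approx(expit(1.0), abs=1e-12)

    def test_monotone_in_ability(self):
        assert attribute_prob(1.0, 2.0, 0.3) > attribute_prob(0.0, 2.0, 0.3)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            attribute_prob(0.0, -1.5, 0.0)


class TestCellAndRowLoglik:
    def test_observed_cell(self, toy_dataset):
        """Observed cell = log(1-h) + log P(y | alpha)."""
        from notreached.model_core import (AttributeStructureParams,
                                           ItemHyperParams, ModelParams,
                                           PersonParams)
        params = ModelParams(
            items=ItemResponseParams(beta=np.array([-2.0, 0.0, 1.0]),
                                     delta=np.array([4.0, 2.0, 1.0])),
            item_hypers=ItemHyperParams(-2.197, 4.394, np.eye(2)),
            structure=AttributeStructureParams(np.ones(2), np.zeros(2)),
            dropout=DropoutParams(eta0=1.0, eta1=-0.7),
            persons=PersonParams(theta_h=np.zeros(3), theta_d=np.zeros(3),
                                 alpha=np.array([[1, 1], [0, 1], [1, 0]])),
            person_hypers=PersonHyperParams(sigma_hd=-0.1, sigma_d2=0.25),
        )
        got = cell_loglik(toy_dataset, params, 0, 0)
        h = dropout_hazard(0.0, 1, 3, 1.0, -0.7)
        p = expit(-2.0 + 4.0)  # person 0 masters both attributes
        assert got == pytest.approx(np.log1p(-h) + np.log(p))
        # first dropped cell contributes log h; later dropped cells nothing
        h2 = dropout_hazard(0.0, 2, 3, 1.0, -0.7)
        assert cell_loglik(toy_dataset, params, 1, 1) == pytest.approx(np.log(h2))
        assert cell_loglik(toy_dataset, params, 1, 2) == 0.0
        h3 = dropout_hazard(0.0, 3, 3, 1.0, -0.7)
        assert cell_loglik(toy_dataset, params, 1, 2, convention="full-product") == \
            pytest.approx(np.log(h3))
        # row sums agree with the row-level reference under both conventions
        for conv in ("sequential", "full-product"):
            row = row_loglik(toy_dataset.Y[1], toy_dataset.D[1], 0.0,
                             params.persons.alpha[1], params.items,
                             params.dropout, toy_dataset.Q, convention=conv)
            cells = sum(cell_loglik(toy_dataset, params, 1, j, convention=conv)
                        for j in range(3))
            assert cells == pytest.approx(row)

    def test_sequential_row_equals_hand_computation(self):
        """3-item person dropping at item 2: log[(1-h1) p(y1) h2]."""
        Q = QMatrix(np.array([[1], [1], [1]]))
        items = ItemResponseParams(beta=np.array([0.0, 0.0, 0.0]),
                                   delta=np.array([1.0, 1.0, 1.0]))
        dp = DropoutParams(eta0=0.5, eta1=-0.2)
        y = np.array([1.0, np.nan, np.nan])
        d = np.array([0, 1, 1])
        theta_d = 0.3
        h1 = dropout_hazard(theta_d, 1, 3, 0.5, -0.2)
        h2 = dropout_hazard(theta_d, 2, 3, 0.5, -0.2)
        p1 = expit(0.0 + 1.0)  # master answering item 1
        expected = np.log(1 - h1) + np.log(p1) + np.log(h2)
        got = row_loglik(y, d, theta_d, np.array([1]), items, dp, Q)
        assert got == pytest.approx(expected, abs=1e-12)


class TestContainers:
    def test_conjunction_matrix_form(self):
        alpha = np.array([[1, 1, 0], [1, 1, 1]])
        Q = np.array([[1, 1, 0], [0, 0, 1]])
        expected = np.array([[1, 0], [1, 1]])
        assert (conjunction(alpha, Q) == expected).all()

    def test_q_matrix_validation(self):
        with pytest.raises(ValueError):
            QMatrix(np.array([[1, 0], [0, 0]]))  # empty row
        with pytest.raises(ValueError):
            QMatrix(np.array([[1, 2], [0, 1]]))  # non-binary

    def test_item_params_derived_quantities(self):
        items = ItemResponseParams(beta=np.array([-2.197]), delta=np.array([4.394]))
        assert items.guess[0] == pytest.approx(0.1, abs=1e-3)
        assert items.slip[0] == pytest.approx(0.1, abs=1e-3)
        assert items.idi[0] == pytest.approx(0.8, abs=2e-3)

    def test_person_hypers_pd_constraint(self):
        with pytest.raises(ValueError):
            PersonHyperParams(sigma_hd=0.6, sigma_d2=0.25)

    def test_dataset_consistency_checks(self, tiny_q):
        Y = np.array([[1.0, np.nan, 0.0]])
        with pytest.raises(ValueError):
            Dataset(Y=Y, D=np.array([[0, 0, 0]]), Q=tiny_q)
        with pytest.raises(ValueError):
            Dataset(Y=np.array([[2.0, 0.0, 1.0]]), D=np.zeros((1, 3), int), Q=tiny_q)
        ds = Dataset(Y=Y, D=np.array([[0, 1, 0]]), Q=tiny_q)
        assert not ds.monotone

    def test_monotone_flag(self, toy_dataset):
        assert toy_dataset.monotone
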