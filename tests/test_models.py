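import numpy as np
import pytest

from sferlab.gru import GRUModel, _pad
from sferlab.models import (HMMBinary, ModelSpec, SFERModel, cross_validate,
                            evaluate_nll, fit_model, hmm_emission_ladder,
                            nll_at_step, predict_reexpression,
                            transfer_validate, update_monotonicity_audit)
from sferlab.sequences import FieldStateSequence


def seqs(*rows):
    return [FieldStateSequence(np.array(r)) for r in rows]


class TestEmissionLadder:
    def test_five_state_ladder(self):
        B = hmm_emission_ladder(5)
        np.testing.assert_allclose(B[:, 1], [0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(B.sum(axis=1), 1.0)

    def test_middle_state_is_half(self):
        assert hmm_emission_ladder(5)[2, 1] == 0.5

    def test_invalid_state_count(self):
        with pytest.raises(ValueError):
            hmm_emission_ladder(0)


class TestSimpleRates:
    def test_equal_rate_closed_form(self):
        # 70% ones among states at steps >= 2
        model = fit_model(ModelSpec("equal_rate"),
                          seqs([1, 1, 1, 1, 1, 1, 1, 1], [1, 0, 0, 0]))
        assert model.p == pytest.approx(0.7)

    def test_state_equal_rate_brute_force(self):
        """Conditional rates match an independent brute-force transition
        count on random sequences."""
        rng = np.random.default_rng(0)
        data = [np.concatenate([[1], rng.integers(0, 2, rng.integers(1, 9))])
                for _ in range(60)]
        model = fit_model(ModelSpec("state_equal_rate"),
                          [FieldStateSequence(d) for d in data])
        after = {0: [], 1: []}
        for d in data:
            for t in range(1, len(d)):
                after[d[t - 1]].append(d[t])
        assert model.pa == pytest.approx(np.mean(after[1]))
        assert model.pi == pytest.approx(np.mean(after[0]))


class TestNLL:
    def test_half_probability_is_log_two(self):
        preds = [np.full(3, 0.5)] * 4
        data = seqs([1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0])
        assert nll_at_step(preds, data, 3) == pytest.approx(np.log(2))

    def test_confident_predictions_near_zero(self):
        preds = [np.array([1.0, 1.0])]
        assert nll_at_step(preds, seqs([1, 1]), 2) < 1e-5

    def test_hand_arithmetic(self):
        # P = 0.8 on outcomes {1, 1, 0} at step 2
        preds = [np.array([0.8]), np.array([0.8]), np.array([0.8])]
        data = seqs([1, 1], [1, 1], [1, 0])
        expected = -(2 * np.log(0.8) + np.log(0.2)) / 3
        assert nll_at_step(preds, data, 2) == pytest.approx(expected, rel=1e-6)

    def test_no_sequence_reaches_step(self):
        with pytest.raises(ValueError):
            nll_at_step([np.array([0.5])], seqs([1, 1]), 5)


class TestSFERModel:
    def test_constant_links(self):
        m = SFERModel(link="linear").set_params([0.0, 0.9], [0.0, 0.1], p2=0.5)
        # g maps via a2*(1-P)+b2 -> with a2=0: constant 0.1
        assert predict_reexpression(m, [1, 1])[-1] == pytest.approx(0.9)
        assert predict_reexpression(m, [1, 0])[-1] == pytest.approx(0.1)

    def test_prediction_depends_only_on_last_step(self):
        """The recursive update uses only (P_{t-1}, s_{t-1}): two histories
        agreeing on their final (P, s) yield the same next update."""
        m = SFERModel(link="quadratic").set_params([0.3, 0.2, 0.4],
                                                   [-0.2, 0.1, 0.15], p2=0.5)
        for P in np.linspace(0.05, 0.95, 7):
            up1 = m.f(P)
            up2 = m.f(P)
            assert up1 == up2
            assert m.g(P) <= 1.0 and m.f(P) <= 1.0

    def test_outputs_clipped(self):
        m = SFERModel(link="linear").set_params([5.0, 5.0], [-5.0, -5.0], p2=0.5)
        p = predict_reexpression(m, [1, 1, 0, 1])
        assert np.all((p >= 0) & (p <= 1))

    def test_fit_recovers_generating_links(self):
        """Fitting on sequences generated from known linear links recovers
        the link maps (compared on the visited probability range)."""
        rng = np.random.default_rng(3)
        true = SFERModel(link="linear").set_params([0.5, 0.45], [-0.3, 0.33],
                                                   p2=0.6)
        data = []
        for _ in range(3000):
            s = [1]
            P = true.p2
            for _ in range(14):
                s.append(int(rng.random() < P))
                P = float(true.f(P)) if s[-1] == 1 else float(true.g(P))
            data.append(FieldStateSequence(np.array(s)))
        fit = SFERModel(link="linear", seed=0, n_starts=4).fit(data, p2=0.6)
        grid = np.linspace(0.1, 0.9, 9)
        assert np.max(np.abs(fit.f(grid) - true.f(grid))) < 0.05
        assert np.max(np.abs(fit.g(grid) - true.g(grid))) < 0.05

    def test_empty_history_rejected(self):
        m = SFERModel(link="linear").set_params([0.1, 0.5], [0.1, 0.1])
        with pytest.raises(ValueError):
            predict_reexpression(m, [])


class TestHMM:
    def test_two_state_forward_by_hand(self):
        """Filtered predictions on a 2-state chain match a hand-run forward
        recursion (ladder emissions {0.25, 0.75})."""
        m = HMMBinary(n_states=2)
        m.B = hmm_emission_ladder(2)
        m.A = np.array([[0.8, 0.2], [0.3, 0.7]])
        m.pi = np.array([0.0, 1.0])
        m.p2 = 0.7
        pred = m.predict(np.array([1, 0]))
        # P_2 = pi . B[:,1] = 0.75
        assert pred[0] == pytest.approx(0.75)
        # observe s_2 = 0: posterior prop pi * B[:,0] = [0, 0.25] -> [0, 1]
        # predictive: ([0,1] @ A) . B[:,1] = [0.3, 0.7] . [0.25, 0.75]
        assert pred[1] == pytest.approx(0.3 * 0.25 + 0.7 * 0.75)

    def test_forward_matches_reference_implementation(self):
        """Model log-likelihood agrees with hmmlearn's forward pass to
        1e-10 on random small instances."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(0)
        for trial in range(8):
            n = int(rng.integers(2, 6))
            m = HMMBinary(n_states=n)
            m.B = hmm_emission_ladder(n)
            A = rng.dirichlet(np.ones(n), size=n)
            pi = rng.dirichlet(np.ones(n))
            m.A, m.pi = A, pi
            obs = rng.integers(0, 2, int(rng.integers(2, 9)))
            ref = hmmlearn.CategoricalHMM(n_components=n)
            ref.startprob_ = pi
            ref.transmat_ = A
            ref.emissionprob_ = m.B
            expected = ref.score(obs.reshape(-1, 1))
            S = np.concatenate([[1], obs])[None, :].astype(float)
            mask = np.ones_like(S, dtype=bool)
            emit = m.B[:, 0][None, None, :] * (obs[None, :, None] == 0) + \
                m.B[:, 1][None, None, :] * (obs[None, :, None] == 1)
            ll, _, _ = m._e_step(obs[None, :], mask[:, 1:], A, emit)
            assert ll == pytest.approx(expected, abs=1e-10)

    def test_baum_welch_rows_stochastic(self, hazard_sequences):
        m = HMMBinary(n_states=5, max_iter=30).fit(hazard_sequences[:800])
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m.A >= 0)

    def test_initial_state_nearest_ladder_entry(self, hazard_sequences):
        m = HMMBinary(n_states=5, max_iter=2).fit(hazard_sequences[:200])
        # P2 ~ 0.52 -> nearest 5-state ladder entry is 0.5 (state 3)
        assert m.pi[2] == 1.0


class TestGRU:
    def test_zero_weights_predict_half(self):
        m = GRUModel(hidden=8, p2=0.5, seed=0)
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        p = m.predict(np.array([1, 0, 1, 1]))
        np.testing.assert_allclose(p[1:], 0.5)

    def test_gradients_match_finite_differences(self):
        """Exact check on length-3 sequences, where the only supervised
        output has no probability-feedback path."""
        m = GRUModel(hidden=4, p2=0.5, seed=0)
        data = [np.array([1, 0, 1]), np.array([1, 1, 0]), np.array([1, 1, 1])]
        S, mask = _pad(data)
        P, cache = m._forward(S, mask, keep_cache=True)
        grads = m._backward(S, mask, P, cache)
        eps = 1e-6
        for k in m.params:
            flat = m.params[k].ravel()
            idx = 0 if flat.size == 1 else flat.size // 2
            orig = flat[idx]
            flat[idx] = orig + eps
            P1, _ = m._forward(S, mask)
            l1 = m._nll(P1, S, mask)
            flat[idx] = orig - eps
            P2, _ = m._forward(S, mask)
            l2 = m._nll(P2, S, mask)
            flat[idx] = orig
            num = (l1 - l2) / (2 * eps)
            assert grads[k].ravel()[idx] == pytest.approx(num, abs=1e-6)

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(1)
        data = [FieldStateSequence(np.concatenate(
            [[1], (rng.random(10) < 0.8).astype(int)])) for _ in range(400)]
        m = GRUModel(hidden=8, p2=0.8, seed=0, max_epochs=40, patience=40,
                     batch_size=256)
        m.fit(data)
        assert m.history_[-1] < m.history_[0] or min(m.history_) < m.history_[0]

    def test_history_must_start_active(self):
        m = GRUModel(hidden=4, seed=0)
        with pytest.raises(ValueError):
            m.predict(np.array([0, 1]))


class TestCrossValidation:
    def test_seeded_reproducibility(self, sfer_sequences):
        a = cross_validate(ModelSpec("state_equal_rate"), sfer_sequences[:800],
                           t=6, k=3, seed=5)
        b = cross_validate(ModelSpec("state_equal_rate"), sfer_sequences[:800],
                           t=6, k=3, seed=5)
        np.testing.assert_allclose(a.fold_losses, b.fold_losses)

    def test_mean_equals_fold_average(self, sfer_sequences):
        r = cross_validate(ModelSpec("equal_rate"), sfer_sequences[:600],
                           t=6, k=3, seed=1)
        assert r.mean_loss == pytest.approx(r.fold_losses.mean())

    def test_too_few_folds(self, sfer_sequences):
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("equal_rate"), sfer_sequences[:100],
                           t=6, k=1)

    def test_history_models_beat_state_beats_constant(self, sfer_sequences):
        """Model-family ordering on an evolution-rule cohort: history-aware
        <= state-conditioned <= unconditional (mean test NLL at t=12)."""
        nll_sfer = cross_validate(ModelSpec("sfer", {"link": "linear",
                                                     "n_starts": 3}),
                                  sfer_sequences, t=12, k=3, seed=2).mean_loss
        nll_prelim = cross_validate(ModelSpec("preliminary_sfer"),
                                    sfer_sequences, t=12, k=3, seed=2).mean_loss
        nll_state = cross_validate(ModelSpec("state_equal_rate"),
                                   sfer_sequences, t=12, k=3, seed=2).mean_loss
        nll_const = cross_validate(ModelSpec("equal_rate"),
                                   sfer_sequences, t=12, k=3, seed=2).mean_loss
        assert nll_sfer <= nll_state + 1e-3
        assert nll_prelim <= nll_state + 1e-3
        assert nll_state <= nll_const + 1e-3


class TestTransferValidation:
    def test_identical_cohorts_rejected(self, sfer_sequences):
        data = sfer_sequences[:300]
        with pytest.raises(ValueError):
            transfer_validate(ModelSpec("equal_rate"), [data], [data], t=6)

    def test_matrix_shape_and_mean(self, sfer_sequences):
        a, b, c = (sfer_sequences[:300], sfer_sequences[300:600],
                   sfer_sequences[600:900])
        out = transfer_validate(ModelSpec("state_equal_rate"), [a, b], [b, c],
                                t=6)
        assert out["matrix"].shape == (2, 2)
        assert np.isnan(out["matrix"][1, 0])  # b -> b excluded
        assert out["mean_loss"] == pytest.approx(np.nanmean(out["matrix"]))

    def test_exchangeable_cohorts_transfer(self, sfer_sequences):
        a, b = sfer_sequences[:800], sfer_sequences[800:1600]
        out = transfer_validate(ModelSpec("state_equal_rate"), [a], [b], t=8)
        within = cross_validate(ModelSpec("state_equal_rate"), a, t=8, k=3,
                                seed=0).mean_loss
        assert out["mean_loss"] == pytest.approx(within, abs=0.08)


class TestMonotonicityAudit:
    def test_opposing_links_fully_monotone(self):
        m = SFERModel(link="linear").set_params([0.5, 0.5], [-0.3, 0.3],
                                                p2=0.5)
        # f(P) = 0.5P + 0.5 > P on (0, 1); g(P) = 0.3P < P on (0, 1]
        data = seqs([1, 1, 0, 1, 0, 0, 1], [1, 0, 0, 0, 1, 1])
        assert update_monotonicity_audit(m, data) == 1.0

    def test_constant_predictor_all_ties(self):
        m = SFERModel(link="linear").set_params([0.0, 0.5], [0.0, 0.5], p2=0.5)
        data = seqs([1, 1, 0, 1], [1, 0, 0])
        assert update_monotonicity_audit(m, data) == 0.0

    def test_non_recursive_model_rejected(self):
        model = fit_model(ModelSpec("equal_rate"), seqs([1, 1, 0]))
        with pytest.raises(TypeError):
            update_monotonicity_audit(model, seqs([1, 1, 0]))


class TestGLMFamilies:
    @pytest.fixture(scope="class")
    @staticmethod
    def glm_data():
        from sferlab.cohort import generate_element_features, \
            generate_state_sequences
        from sferlab.config import GeneratorConfig
        from sferlab.sequences import prepare_sequences
        cfg = GeneratorConfig(seed=77, n_sessions=15)
        coh = generate_state_sequences(cfg, 1500, mode="sfer")
        feats = generate_element_features(coh, coupling={"peak_rate": 2.0},
                                          rng=np.random.default_rng(7))
        return prepare_sequences(coh.activity), feats

    def test_coupled_element_gets_positive_coefficient(self, glm_data):
        seqs_, feats = glm_data
        model = fit_model(ModelSpec("glm_single", {"element": "peak_rate"}),
                          seqs_, features=feats)
        assert model.coef_[1] > 0.05

    def test_state_augmented_glm_improves(self, glm_data):
        seqs_, feats = glm_data
        m_all = fit_model(ModelSpec("glm_all"), seqs_, features=feats)
        m_state = fit_model(ModelSpec("glm_state"), seqs_, features=feats)
        nll_all = evaluate_nll(m_all, seqs_, t=6, features=feats)
        nll_state = evaluate_nll(m_state, seqs_, t=6, features=feats)
        assert nll_state <= nll_all + 1e-3

    def test_missing_features_rejected(self, glm_data):
        seqs_, _ = glm_data
        with pytest.raises(ValueError):
            fit_model(ModelSpec("glm_all"), seqs_)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("glm_single", {})


class TestSpecValidation:
    @pytest.mark.parametrize("family, options", [
        ("nonsense", {}),
        ("sfer", {"link": "quartic"}),
        ("hmm", {"n_states": 0}),
    ])
    def test_invalid_specs(self, family, options):
        with pytest.raises(ValueError):
            ModelSpec(family, options)
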