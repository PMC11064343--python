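"""Score functions, NSSA loss, negative sampler, and training behavior."""

import math

import numpy as np
import pytest
from scipy.special import expit, log_expit, softmax

from kgablate import (
    KnowledgeGraph,
    ModelConfig,
    Triple,
    nssa_loss,
    sample_negatives,
    score,
    train,
    vec_scores,
)
from kgablate.embeddings import _CORES, EmbeddingSet


class TestScoreFunctions:
    def test_transe_perfect_translation_scores_zero(self):
        h, r = np.array([0.3, -0.2]), np.array([0.1, 0.5])
        assert score("TransE", h, r, h + r) == pytest.approx(0.0, abs=1e-12)

    def test_transe_printed_example(self):
        s = score("TransE", np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.zeros(2))
        assert s == pytest.approx(-math.sqrt(2))

    def test_distmult_symmetric_and_all_ones(self):
        rng = np.random.default_rng(0)
        h, r, t = rng.normal(size=(3, 5))
        assert score("DistMult", h, r, t) == pytest.approx(score("DistMult", t, r, h))
        ones = np.ones(3)
        assert score("DistMult", ones, ones, ones) == pytest.approx(3.0)

    def test_transe_is_not_symmetric(self):
        h, r, t = np.array([1.0]), np.array([1.0]), np.array([2.0])
        assert score("TransE", h, r, t) != score("TransE", t, r, h)

    def test_complex_with_real_embeddings_equals_distmult(self):
        rng = np.random.default_rng(1)
        h, r, t = rng.normal(size=(3, 8))
        assert score(
            "ComplEx", h.astype(complex), r.astype(complex), t.astype(complex)
        ) == pytest.approx(score("DistMult", h, r, t))

    def test_rotate_zero_phase_degenerates_to_distance(self):
        rng = np.random.default_rng(2)
        h = rng.normal(size=4) + 1j * rng.normal(size=4)
        t = rng.normal(size=4) + 1j * rng.normal(size=4)
        r = np.ones(4, dtype=complex)  # zero rotation
        assert score("RotatE", h, r, t) == pytest.approx(
            -np.linalg.norm(h - t)
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            score("TransE", np.zeros(3), np.zeros(4), np.zeros(3))

    def test_wrong_number_field_rejected(self):
        with pytest.raises(ValueError, match="complex"):
            score("ComplEx", np.zeros(3), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError, match="real"):
            score("TransE", np.zeros(3, dtype=complex), np.zeros(3, dtype=complex),
                  np.zeros(3, dtype=complex))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            vec_scores("ConvE", np.zeros(3), np.zeros(3), np.zeros(3))


class TestNegativeSampling:
    @pytest.fixture
    def kg(self):
        return KnowledgeGraph(
            [Triple("a", "r", "b"), Triple("b", "r", "c"), Triple("c", "r", "d")]
        )

    def test_each_negative_differs_in_exactly_one_endpoint(self, kg):
        pos = Triple("a", "r", "b")
        for neg in sample_negatives(kg, pos, 50, seed=0):
            assert neg.relation == pos.relation
            changed = (neg.head != pos.head) + (neg.tail != pos.tail)
            assert changed == 1

    def test_deterministic_given_seed(self, kg):
        pos = Triple("a", "r", "b")
        assert sample_negatives(kg, pos, 20, seed=5) == sample_negatives(
            kg, pos, 20, seed=5
        )

    def test_two_entity_graph_enumerates_both_corruptions(self):
        kg = KnowledgeGraph([Triple("a", "r", "b")])
        allowed = {Triple("b", "r", "b"), Triple("a", "r", "a")}
        negs = set(sample_negatives(kg, Triple("a", "r", "b"), 200, seed=1))
        assert negs <= allowed
        assert negs == allowed  # both appear over 200 draws

    def test_single_entity_rejected(self):
        kg = KnowledgeGraph([Triple("a", "r", "a")])
        with pytest.raises(ValueError):
            sample_negatives(kg, Triple("a", "r", "a"), 1, seed=0)


class TestNSSALoss:
    def test_hand_computed_value(self):
        # sigma(1) and sigma(-1) terms
        expected = -math.log(expit(1)) - math.log(expit(-1))
        assert nssa_loss(0.0, [0.0], margin_gamma=1.0) == pytest.approx(expected)
        assert nssa_loss(0.0, [0.0], margin_gamma=1.0) == pytest.approx(1.6265, abs=1e-4)

    def test_single_negative_weight_is_one_for_any_temperature(self):
        for temp in (0.0, 0.5, 10.0):
            assert nssa_loss(1.0, [-3.0], 2.0, temp) == pytest.approx(
                float(-log_expit(3.0) - log_expit(1.0))
            )

    def test_zero_temperature_weights_are_uniform(self):
        negs = [-1.0, 0.0, 2.0]
        manual = -log_expit(2.0 + 0.5) - np.mean(
            [log_expit(-f - 2.0) for f in negs]
        )
        assert nssa_loss(0.5, negs, 2.0, 0.0) == pytest.approx(float(manual))

    def test_adversarial_weighting_matches_softmax(self):
        negs = np.array([-1.0, 0.5, 1.5])
        w = softmax(1.0 * negs)
        manual = -log_expit(2.0) - float(np.sum(w * log_expit(-negs - 2.0)))
        assert nssa_loss(0.0, negs, 2.0, 1.0) == pytest.approx(manual)

    def test_nonnegative_and_monotone_in_positive_score(self):
        negs = [-1.0, 0.0]
        losses = [nssa_loss(fp, negs) for fp in (-2.0, 0.0, 2.0)]
        assert all(l >= 0 for l in losses)
        assert losses[0] > losses[1] > losses[2]

    def test_empty_negatives_rejected(self):
        with pytest.raises(ValueError):
            nssa_loss(0.0, [])


class TestGradients:
    @pytest.mark.parametrize("model", ["TransE", "DistMult", "ComplEx", "RotatE"])
    def test_analytic_gradients_match_finite_differences(self, model):
        """The training loop's gradients are exact derivatives of the loss."""
        core = _CORES[model]
        rng = np.random.default_rng(42)
        n_e, n_r, k, B, n = 7, 3, 4, 5, 6
        params = core.init_params(n_e, n_r, k, np.random.default_rng(1))
        hh = rng.integers(0, n_e, (B, n + 1))
        tt = rng.integers(0, n_e, (B, n + 1))
        rr = np.broadcast_to(rng.integers(0, n_r, (B, 1)), (B, n + 1)).copy()
        gamma = 2.0

        f, cache = core.forward(params, hh, rr, tt)
        w = softmax(f[:, 1:], axis=1)  # frozen adversarial weights

        def total_loss():
            f2, _ = core.forward(params, hh, rr, tt)
            return float(
                np.mean(
                    -log_expit(gamma + f2[:, 0])
                    - np.sum(w * log_expit(-f2[:, 1:] - gamma), axis=1)
                )
            )

        coeff = np.empty_like(f)
        coeff[:, 0] = (expit(gamma + f[:, 0]) - 1.0) / B
        coeff[:, 1:] = w * expit(f[:, 1:] + gamma) / B
        contribs = core.backward(params, cache, hh, rr, tt, coeff)
        eps = 1e-6
        for pname, parts in contribs.items():
            analytic = np.zeros_like(params[pname])
            for ix, v in parts:
                np.add.at(analytic, ix, v)
            numeric = np.zeros_like(analytic)
            it = np.nditer(params[pname], flags=["multi_index"])
            for _ in it:
                mi = it.multi_index
                orig = params[pname][mi]
                params[pname][mi] = orig + eps
                up = total_loss()
                params[pname][mi] = orig - eps
                down = total_loss()
                params[pname][mi] = orig
                numeric[mi] = (up - down) / (2 * eps)
            scale = max(1e-8, float(np.abs(numeric).max()))
            assert np.abs(numeric - analytic).max() / scale < 1e-5


class TestTraining:
    def test_zero_epochs_returns_seeded_initialization(self, small_planted_kg):
        kg, _ = small_planted_kg
        cfg = ModelConfig(model="TransE", epochs=0, seed=3)
        e1 = train(kg, cfg)
        e2 = train(kg, cfg)
        assert np.array_equal(e1.entity_vecs, e2.entity_vecs)
        assert e1.loss_history == []

    def test_training_is_deterministic(self, small_planted_kg):
        kg, _ = small_planted_kg
        cfg = ModelConfig(model="DistMult", epochs=3, seed=9)
        e1, e2 = train(kg, cfg), train(kg, cfg)
        assert np.array_equal(e1.entity_vecs, e2.entity_vecs)
        assert np.array_equal(e1.relation_vecs, e2.relation_vecs)

    def test_vocabulary_coverage(self, small_planted_kg):
        kg, _ = small_planted_kg
        emb = train(kg, ModelConfig(model="TransE", epochs=1, seed=0))
        assert emb.entities == sorted(kg.entities)
        assert emb.relations == sorted(kg.relations)
        assert np.isfinite(emb.entity_vecs).all()

    def test_rotate_relations_have_unit_modulus(self, small_planted_kg):
        kg, _ = small_planted_kg
        emb = train(kg, ModelConfig(model="RotatE", k=8, epochs=2, seed=0))
        assert np.allclose(np.abs(emb.relation_vecs), 1.0)

    @pytest.mark.parametrize("model", ["TransE", "DistMult", "ComplEx", "RotatE"])
    def test_mean_epoch_loss_decreases_early(self, small_planted_kg, model):
        """Optimization makes progress over the first epochs for every model."""
        kg, _ = small_planted_kg
        k = 16 if model in ("ComplEx", "RotatE") else None
        for seed in range(3):
            emb = train(kg, ModelConfig(model=model, k=k, epochs=10, seed=seed))
            losses = emb.loss_history
            assert losses[-1] < losses[0]
            # allow tiny stochastic upticks from minibatch reshuffling
            assert all(b <= a * 1.05 for a, b in zip(losses, losses[1:]))

    def test_invalid_inputs_rejected(self, small_planted_kg):
        kg, _ = small_planted_kg
        with pytest.raises(ValueError):
            train(kg, ModelConfig(model="TransE", learning_rate=0.0, epochs=1))
        with pytest.raises(ValueError):
            ModelConfig(model="HolE")
        with pytest.raises(ValueError):
            train(KnowledgeGraph(), ModelConfig())


class TestEmbeddingSerialization:
    @pytest.mark.parametrize("model", ["DistMult", "RotatE"])
    def test_save_load_round_trip(self, tmp_path, small_planted_kg, model):
        kg, _ = small_planted_kg
        emb = train(kg, ModelConfig(model=model, k=4, epochs=1, seed=0))
        emb.save(tmp_path / "emb")
        loaded = EmbeddingSet.load(tmp_path / "emb")
        assert loaded.model == model
        assert loaded.entities == emb.entities
        assert np.allclose(loaded.entity_vecs, emb.entity_vecs)
        assert np.allclose(loaded.relation_vecs, emb.relation_vecs)
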