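"""Network components: embeddings, MMOE, match towers, mimic, losses, grads."""

import numpy as np
import pytest

from tcmrank.corpus import FIELDS, build_vocabulary, build_samples
from tcmrank.model import (
    Batch,
    MMOEMatchModel,
    ModelConfig,
    batch_from_samples,
    fuse_match_feature,
    l2_normalize,
    make_model,
    mimic_augment,
    total_loss,
)
from tcmrank.synthetic import GeneratorConfig, generate_corpus


def tiny_config(fusion="none", **kw):
    defaults = dict(
        embedding_dim=3,
        n_experts=2,
        expert_layer_sizes=(5, 4),
        tower_layer_sizes=(3,),
        match_tower_sizes=(5, 4),
        fusion=fusion,
        lambda1=0.7,
        lambda_u=0.3,
        lambda_v=0.4,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="module")
def grad_fixture():
    """A 4-sample batch (with positives) over a small vocabulary."""
    cfg = GeneratorConfig(
        n_cases=20,
        seed=5,
        field_vocab_sizes={"engraving_symptoms": 30, "tongue": 8, "moss": 8, "pulse": 8},
    )
    cases, _ = generate_corpus(cfg)
    vocab = build_vocabulary(cases)
    samples = build_samples(cases, vocab)
    samples = sorted(samples, key=lambda s: -s.label)[:2] + samples[5:7]
    return vocab, batch_from_samples(samples)


def randomize_params(model, seed):
    """Replace the init with uniform values away from ReLU kinks."""
    r = np.random.default_rng(seed)
    for k in model.params:
        model.params[k] = r.uniform(-0.2, 0.2, model.params[k].shape)
        if k.startswith("emb_"):
            model.params[k][0] = 0.0


class TestEmbedFields:
    def make_batch(self, ids_per_field, element_ids):
        n = len(element_ids)
        return Batch(
            field_ids={f: np.array(ids_per_field[f]) for f in FIELDS},
            element_ids=np.array(element_ids),
            labels=np.zeros(n),
        )

    def test_single_token_field_is_its_embedding(self, grad_fixture):
        vocab, _ = grad_fixture
        m = make_model(tiny_config(), vocab, rng=0)
        b = self.make_batch({f: [[1]] for f in FIELDS}, [1])
        E, _ = m.embed_fields(b)
        np.testing.assert_allclose(E[0, :3], m.params["emb_engraving_symptoms"][1])
        np.testing.assert_allclose(E[0, -3:], m.params["emb_element"][1])

    def test_mean_pooling_idempotent_on_duplicates(self, grad_fixture):
        vocab, _ = grad_fixture
        m = make_model(tiny_config(), vocab, rng=0)
        single = self.make_batch({f: [[2]] for f in FIELDS}, [1])
        double = self.make_batch(
            {f: ([[2, 2]] if f == "tongue" else [[2]]) for f in FIELDS}, [1]
        )
        E1, _ = m.embed_fields(single)
        E2, _ = m.embed_fields(double)
        np.testing.assert_allclose(E1, E2)

    def test_padding_only_field_gives_zero_vector(self, grad_fixture):
        vocab, _ = grad_fixture
        m = make_model(tiny_config(), vocab, rng=0)
        b = self.make_batch(
            {f: ([[0, 0]] if f == "moss" else [[1]]) for f in FIELDS}, [1]
        )
        E, _ = m.embed_fields(b)
        np.testing.assert_array_equal(E[0, 6:9], 0.0)  # moss slot

    def test_zero_tables_give_zero_concatenation(self, grad_fixture):
        vocab, _ = grad_fixture
        m = make_model(tiny_config(), vocab, rng=0)
        for f in FIELDS:
            m.params[f"emb_{f}"][:] = 0.0
        m.params["emb_element"][:] = 0.0
        b = self.make_batch({f: [[1, 2]] for f in FIELDS}, [2])
        E, _ = m.embed_fields(b)
        np.testing.assert_array_equal(E, 0.0)


class TestMMOEForward:
    def test_gate_weights_normalized(self, grad_fixture):
        vocab, batch = grad_fixture
        m = make_model(tiny_config(n_experts=4), vocab, rng=1)
        randomize_params(m, 3)
        cache = m._forward_all(batch)
        g = cache["mmoe"]["gates"][0]
        assert (g >= 0).all()
        np.testing.assert_allclose(g.sum(axis=1), 1.0)

    def test_tied_experts_make_gates_irrelevant(self, grad_fixture):
        vocab, batch = grad_fixture
        m = make_model(tiny_config(n_experts=3), vocab, rng=1)
        randomize_params(m, 3)
        for i in (1, 2):  # tie every expert to expert 0
            for l in range(2):
                m.params[f"expert{i}_W{l}"] = m.params["expert0_W0" if l == 0 else "expert0_W1"].copy()
                m.params[f"expert{i}_b{l}"] = m.params[f"expert0_b{l}"].copy()
        y1 = m.predict(batch)
        m.params["gate0_W"] = np.random.default_rng(9).uniform(-1, 1, m.params["gate0_W"].shape)
        y2 = m.predict(batch)
        np.testing.assert_allclose(y1, y2, atol=1e-12)

    def test_single_expert_reduces_to_plain_mlp(self, grad_fixture):
        """An independently coded feed-forward pass must match exactly."""
        vocab, batch = grad_fixture
        m = make_model(tiny_config(n_experts=1), vocab, rng=1)
        randomize_params(m, 4)
        E, _ = m.embed_fields(batch)
        # independent forward: two relu layers, one relu tower layer, linear out
        h = np.maximum(E @ m.params["expert0_W0"] + m.params["expert0_b0"], 0)
        h = np.maximum(h @ m.params["expert0_W1"] + m.params["expert0_b1"], 0)
        t = np.maximum(h @ m.params["tower0_W0"] + m.params["tower0_b0"], 0)
        z = t @ m.params["tower0_out_W"] + m.params["tower0_out_b"]
        expected = 1 / (1 + np.exp(-z))
        np.testing.assert_allclose(m.predict(batch), expected, rtol=1e-12)

    def test_hand_computed_instance(self):
        """Forward pass on a dimension-2 instance against manual arithmetic."""
        cfg = ModelConfig(
            embedding_dim=1, n_experts=2, expert_layer_sizes=(1,),
            tower_layer_sizes=(1,), match_tower_sizes=(2,), fusion="none",
        )
        m = MMOEMatchModel(cfg, {f: 1 for f in FIELDS}, 1, rng=0)
        # craft every parameter by hand
        for i, f in enumerate(FIELDS):
            m.params[f"emb_{f}"] = np.array([[0.0], [0.1 * (i + 1)]])
        m.params["emb_element"] = np.array([[0.0], [0.5]])
        # x = [0.1, 0.2, 0.3, 0.4, 0.5]
        m.params["expert0_W0"] = np.ones((5, 1))
        m.params["expert0_b0"] = np.array([0.0])       # expert0: relu(1.5) = 1.5
        m.params["expert1_W0"] = -np.ones((5, 1))
        m.params["expert1_b0"] = np.array([2.0])       # expert1: relu(0.5) = 0.5
        m.params["gate0_W"] = np.zeros((5, 2))         # uniform gate: (1.5+0.5)/2 = 1.0
        m.params["tower0_W0"] = np.array([[2.0]])
        m.params["tower0_b0"] = np.array([0.0])        # tower: relu(2.0) = 2.0
        m.params["tower0_out_W"] = np.array([1.0])
        m.params["tower0_out_b"] = np.asarray(-1.0)    # logit 1.0
        b = Batch(
            field_ids={f: np.array([[1]]) for f in FIELDS},
            element_ids=np.array([1]),
            labels=np.array([1.0]),
        )
        assert m.predict(b)[0] == pytest.approx(1 / (1 + np.exp(-1.0)))


class TestMatchForward:
    def test_concat_zero_weights_give_half(self, grad_fixture):
        vocab, batch = grad_fixture
        m = make_model(tiny_config("auxiliary_loss"), vocab, rng=1)
        for k in list(m.params):
            if k.startswith("match_"):
                m.params[k] = np.zeros_like(m.params[k])
        E, cache = m.embed_fields(batch)
        z, _ = m.match_forward(cache["E_sym"], cache["elem_e"])
        np.testing.assert_allclose(1 / (1 + np.exp(-z)), 0.5)

    def test_cosine_unit_norms(self, grad_fixture):
        vocab, batch = grad_fixture
        m = make_model(tiny_config("mimic"), vocab, rng=1)
        randomize_params(m, 5)
        _, cache = m.embed_fields(batch)
        z, mc = m.match_forward(cache["E_sym"], cache["elem_e"])
        np.testing.assert_allclose(np.linalg.norm(mc["p_u"], axis=1), 1.0)
        np.testing.assert_allclose(np.linalg.norm(mc["p_v"], axis=1), 1.0)

    def test_cosine_score_invariant_to_tower_output_scale(self, grad_fixture):
        """L2 normalization makes the score scale-free per side."""
        vocab, batch = grad_fixture
        m = make_model(tiny_config("mimic"), vocab, rng=1)
        randomize_params(m, 5)
        _, cache = m.embed_fields(batch)
        z1, _ = m.match_forward(cache["E_sym"], cache["elem_e"])
        last = len(m.config.match_tower_sizes) - 1
        m.params[f"match_v_W{last}"] *= 3.7  # positive rescale through ReLU
        m.params[f"match_v_b{last}"] *= 3.7
        z2, _ = m.match_forward(cache["E_sym"], cache["elem_e"])
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_l2_normalize_zero_row_warns_and_passes_through(self):
        h = np.array([[0.0, 0.0], [3.0, 4.0]])
        with pytest.warns(UserWarning, match="zero vector"):
            p, _ = l2_normalize(h)
        np.testing.assert_array_equal(p[0], [0.0, 0.0])
        np.testing.assert_allclose(p[1], [0.6, 0.8])


class TestFusionPlumbing:
    def test_fuse_width(self):
        E = np.zeros((4, 320))
        out = fuse_match_feature(E, np.full(4, 0.5))
        assert out.shape == (4, 321)
        assert fuse_match_feature(E, None).shape == (4, 320)

    def test_mimic_augment_widths_and_zero_reduction(self):
        E_sym = np.ones((3, 8))
        elem = np.ones((3, 2))
        c_u, c_v = mimic_augment(E_sym, elem, np.zeros(4), np.zeros(4))
        assert c_u.shape == (3, 12) and c_v.shape == (3, 6)
        np.testing.assert_array_equal(c_u[:, :8], E_sym)
        np.testing.assert_array_equal(c_u[:, 8:], 0.0)

    def test_augmentation_is_global_across_samples(self, grad_fixture):
        vocab, batch = grad_fixture
        m = make_model(tiny_config("mimic"), vocab, rng=1)
        _, cache = m.embed_fields(batch)
        c_u, _ = mimic_augment(
            cache["E_sym"], cache["elem_e"], m.params["a_u"], m.params["a_v"]
        )
        # same trailing augmentation block for every sample
        assert (c_u[:, -m.augment_dim :] == c_u[0, -m.augment_dim :]).all()


class TestTotalLoss:
    def test_zero_lambdas_collapse_to_main(self):
        cfg = tiny_config("full", lambda1=0.0, lambda_u=0.0, lambda_v=0.0)
        y = np.array([1.0, 0.0, 1.0])
        p_main = np.array([0.8, 0.3, 0.6])
        out = total_loss(y, p_main, np.array([0.9, 0.1, 0.5]),
                         np.ones(2), np.ones(2), np.zeros((3, 2)), np.zeros((3, 2)), cfg)
        from tcmrank.model import bce

        assert out["total"] == bce(p_main, y)

    def test_single_positive_at_half_gives_two_ln2(self):
        cfg = tiny_config("auxiliary_loss", lambda1=1.0, lambda_u=0.0, lambda_v=0.0)
        y = np.array([1.0])
        out = total_loss(y, np.array([0.5]), np.array([0.5]), None, None, None, None, cfg)
        assert out["total"] == pytest.approx(2 * np.log(2))

    def test_mimic_zero_when_vectors_match(self):
        cfg = tiny_config("mimic")
        y = np.array([1.0, 1.0])
        p_v = np.array([[0.6, 0.8], [0.6, 0.8]])
        out = total_loss(y, np.array([0.9, 0.9]), np.array([0.9, 0.9]),
                         np.array([0.6, 0.8]), np.array([0.1, 0.2]),
                         np.tile([0.1, 0.2], (2, 1)), p_v, cfg)
        assert out["mimic_u"] == 0.0
        assert out["mimic_v"] == 0.0

    def test_mimic_counts_positives_only(self):
        cfg = tiny_config("mimic", lambda_u=1.0)
        y = np.array([0.0, 1.0])
        p_v = np.array([[1.0, 0.0], [0.0, 1.0]])
        a_u = np.array([0.0, 0.0])
        out = total_loss(y, np.array([0.5, 0.5]), np.array([0.5, 0.5]),
                         a_u, None, None, p_v, cfg)
        # only the positive sample contributes: ||0 - (0,1)||^2 / N = 1/2
        assert out["mimic_u"] == pytest.approx(0.5)

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError, match="empty"):
            total_loss(np.array([]), np.array([]), None, None, None, None, None, tiny_config())

    def test_perfect_predictions_vanishing_loss(self):
        cfg = tiny_config("auxiliary_loss")
        y = np.array([1.0, 0.0])
        near = np.array([1 - 1e-9, 1e-9])
        out = total_loss(y, near, near, None, None, None, None, cfg)
        assert out["main"] < 1e-7 and out["match"] < 1e-7


class TestGradients:
    """Analytic gradients against central finite differences.

    Stop-gradient paths (the detached fused match output and the mimic
    losses' frozen opposing towers) are by construction invisible to a
    finite difference of the total loss, so those paths are verified by
    dedicated closed-form checks below; the FD sweep covers every
    configuration whose objective is an ordinary function of the
    parameters.
    """

    @pytest.mark.parametrize(
        "fusion,detach,lu,lv",
        [
            ("none", True, 0.3, 0.4),
            ("auxiliary_loss", True, 0.3, 0.4),
            ("match_as_feature", False, 0.3, 0.4),
            ("mimic", True, 0.0, 0.0),
            ("full", False, 0.0, 0.0),
        ],
    )
    def test_finite_difference_agreement(self, grad_fixture, fusion, detach, lu, lv):
        vocab, batch = grad_fixture
        cfg = tiny_config(fusion, detach_match_feature=detach, lambda_u=lu, lambda_v=lv)
        m = make_model(cfg, vocab, rng=2)
        randomize_params(m, 9)
        _, grads = m.loss_and_grads(batch)
        eps = 1e-6
        checker = np.random.default_rng(0)
        for k, P in m.params.items():
            flat_idx = np.arange(P.size)
            if P.size > 25:
                flat_idx = checker.choice(P.size, 25, replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                old = P[idx]
                P[idx] = old + eps
                lp = m.loss_and_grads(batch)[0]["total"]
                P[idx] = old - eps
                lm = m.loss_and_grads(batch)[0]["total"]
                P[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k][idx]
                assert abs(num - ana) <= 1e-6 + 1e-4 * max(abs(num), abs(ana)), (
                    f"{k}{idx}: fd={num:.3e} analytic={ana:.3e}"
                )

    def test_mimic_gradients_closed_form(self, grad_fixture):
        """a_u/a_v grads equal the positives-only squared-error derivative."""
        vocab, batch = grad_fixture
        cfg = tiny_config("mimic", lambda1=0.0, lambda_u=0.3, lambda_v=0.4)
        m = make_model(cfg, vocab, rng=2)
        randomize_params(m, 9)
        _, grads = m.loss_and_grads(batch)
        cache = m._forward_all(batch)
        p_u, p_v = cache["match"]["p_u"], cache["match"]["p_v"]
        y, n = batch.labels, len(batch)
        exp_au = 0.3 * 2 / n * (y[:, None] * (m.params["a_u"][None] - p_v)).sum(0)
        exp_av = 0.4 * 2 / n * (y[:, None] * (m.params["a_v"][None] - p_u)).sum(0)
        np.testing.assert_allclose(grads["a_u"], exp_au, rtol=1e-10)
        np.testing.assert_allclose(grads["a_v"], exp_av, rtol=1e-10)

    def test_mimic_leaves_tower_gradients_untouched(self, grad_fixture):
        """Stop-gradient: mimic terms add nothing to the tower weights."""
        vocab, batch = grad_fixture
        base = tiny_config("mimic", lambda_u=0.0, lambda_v=0.0)
        withm = tiny_config("mimic", lambda_u=0.9, lambda_v=0.9)
        m1 = make_model(base, vocab, rng=2)
        m2 = make_model(withm, vocab, rng=2)
        randomize_params(m1, 9)
        randomize_params(m2, 9)
        _, g1 = m1.loss_and_grads(batch)
        _, g2 = m2.loss_and_grads(batch)
        for k in g1:
            if k not in ("a_u", "a_v"):
                np.testing.assert_allclose(g1[k], g2[k], atol=1e-12, err_msg=k)

    def test_detached_match_feature_blocks_main_gradient(self, grad_fixture):
        """With λ1 = 0 and the fused output detached, match weights get no grad."""
        vocab, batch = grad_fixture
        cfg = tiny_config("match_as_feature", lambda1=0.0, detach_match_feature=True)
        m = make_model(cfg, vocab, rng=2)
        randomize_params(m, 9)
        _, grads = m.loss_and_grads(batch)
        for k, g in grads.items():
            if k.startswith("match_"):
                np.testing.assert_array_equal(g, 0.0, err_msg=k)


class TestCheckpoint:
    def test_round_trip(self, grad_fixture, tmp_path):
        vocab, batch = grad_fixture
        m = make_model(tiny_config("full"), vocab, rng=3)
        m.save(tmp_path / "ckpt")
        m2 = MMOEMatchModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(m.predict(batch), m2.predict(batch))

    def test_shape_mismatch_rejected(self, grad_fixture, tmp_path):
        vocab, _ = grad_fixture
        m = make_model(tiny_config(), vocab, rng=3)
        m.save(tmp_path / "ckpt")
        meta = (tmp_path / "ckpt.yaml").read_text()
        (tmp_path / "ckpt.yaml").write_text(meta.replace("embedding_dim: 3", "embedding_dim: 4"))
        with pytest.raises(ValueError, match="shape"):
            MMOEMatchModel.load(tmp_path / "ckpt")
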