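"""Dual-adapter algebra, the mixed 3:1 objective, and the two-stage schedule."""

import numpy as np
import pytest
from scipy.special import erf

from aekit.adapters import (
    MixedObjectiveConfig,
    TokenBatch,
    mixed_nll_loss,
    pretrain_base,
    sample_mixed,
    token_accuracy,
    two_stage_finetune,
)
from aekit.autograd import Tensor
from aekit.synthgen import TokenTaskSpec, gen_token_task
from aekit.transformer import (
    IA3Adapter,
    LoRAAdapter,
    MicroTransformer,
    TransformerConfig,
    composite_forward,
    ia3_forward,
    lora_forward,
)


class TestAdapterAlgebra:
    def test_zero_init_is_identity(self):
        ad = LoRAAdapter.init(3, 3, rank=2)
        W = np.eye(3)
        x = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(lora_forward(x, W, ad), W @ x)

    def test_hand_matrix_product(self):
        # A = [[1,0]], B = [[0],[1]] -> delta_W = [[0,0],[1,0]]
        ad = LoRAAdapter.init(2, 2, rank=1)
        ad.A.data = np.array([[1.0, 0.0]])
        ad.B.data = np.array([[0.0], [1.0]])
        out = lora_forward(np.array([1.0, 0.0]), np.eye(2), ad)
        assert np.allclose(out, [1.0, 1.0])

    def test_rank_bound(self, rng):
        ad = LoRAAdapter.init(8, 8, rank=1)
        ad.A.data = rng.normal(size=(1, 8))
        ad.B.data = rng.normal(size=(8, 1))
        assert np.linalg.matrix_rank(ad.delta().data) == 1

    def test_ia3_identity_and_scaling(self):
        ad = IA3Adapter.init(2)
        h = np.array([3.0, 4.0])
        assert np.array_equal(ia3_forward(h, ad), h)
        ad.l.data = np.array([2.0, 0.5])
        assert np.allclose(ia3_forward(h, ad), [6.0, 2.0])
        ad.l.data = np.zeros(2)
        assert np.allclose(ia3_forward(h, ad), [0.0, 0.0])

    def test_shape_mismatch_errors(self):
        ad = LoRAAdapter.init(3, 3, rank=1)
        with pytest.raises(ValueError):
            lora_forward(np.ones(2), np.eye(2), ad)
        with pytest.raises(ValueError):
            ia3_forward(np.ones(3), IA3Adapter.init(2))

    def test_unsupported_lora_site_rejected(self):
        with pytest.raises(ValueError):
            LoRAAdapter.init(3, 3, site="key_projection")


def straight_line_forward(model: MicroTransformer, ids: np.ndarray) -> np.ndarray:
    """Independent, autograd-free re-implementation of the composite forward."""
    c = model.config
    T = len(ids)
    d_h = c.d_model // c.n_heads

    def ln(x, g, b, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / np.sqrt(var + eps) * g + b

    def gelu(x):
        return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))

    h = model.tok_emb.data[ids] + model.pos_emb.data[:T]
    for li, layer in enumerate(model.layers):
        a = ln(h, layer["ln1_g"].data, layer["ln1_b"].data)
        Wq = layer["Wq"].data + model.adapters.lora_q[li].B.data @ model.adapters.lora_q[li].A.data
        Wv = layer["Wv"].data + model.adapters.lora_v[li].B.data @ model.adapters.lora_v[li].A.data
        q, k, v = a @ Wq.T, a @ layer["Wk"].data.T, a @ Wv.T
        outs = []
        for hd in range(c.n_heads):
            sl = slice(hd * d_h, (hd + 1) * d_h)
            s = q[:, sl] @ k[:, sl].T / np.sqrt(d_h)
            s = s + np.triu(np.full((T, T), -1e30), k=1)
            s = s - s.max(axis=1, keepdims=True)
            p = np.exp(s)
            p /= p.sum(axis=1, keepdims=True)
            outs.append(p @ v[:, sl])
        h = h + np.concatenate(outs, axis=1) @ layer["Wo"].data.T
        f = ln(h, layer["ln2_g"].data, layer["ln2_b"].data)
        u = gelu(f @ layer["W1"].data.T + layer["b1"].data) * model.adapters.ia3[li].l.data
        h = h + u @ layer["W2"].data.T + layer["b2"].data
    h = ln(h, model.lnf_g.data, model.lnf_b.data)
    return h @ model.Wout.data.T


class TestCompositeForward:
    def test_identity_at_initialization_bitwise(self):
        model = MicroTransformer(seed=4)
        ids = np.arange(12) % 32
        base = model.forward(ids, use_lora=False, use_ia3=False).data
        assert np.array_equal(base, composite_forward(model, ids))

    def test_lora_only_equals_lora_model_when_l_is_one(self, rng):
        model = MicroTransformer(seed=4)
        for ad in (*model.adapters.lora_q, *model.adapters.lora_v):
            ad.B.data = rng.normal(0, 0.1, size=ad.B.shape)
        ids = np.arange(8)
        assert np.array_equal(
            composite_forward(model, ids),
            composite_forward(model, ids, use_ia3=False),
        )

    def test_matches_straight_line_oracle_with_trained_adapters(self, rng):
        model = MicroTransformer(seed=5)
        for ad in (*model.adapters.lora_q, *model.adapters.lora_v):
            ad.A.data = rng.normal(0, 0.1, size=ad.A.shape)
            ad.B.data = rng.normal(0, 0.1, size=ad.B.shape)
        for ad in model.adapters.ia3:
            ad.l.data = rng.uniform(0.5, 1.5, size=ad.l.shape)
        ids = rng.integers(0, 32, size=16)
        ours = composite_forward(model, ids)
        oracle = straight_line_forward(model, ids)
        assert np.allclose(ours, oracle, atol=1e-10)


class TestMixedObjective:
    def test_ratio_enforced(self):
        with pytest.raises(ValueError):
            MixedObjectiveConfig(lambda_d=0.5, lambda_g=0.5)

    def test_perfect_model_zero_loss(self):
        batch = TokenBatch(input_ids=[0, 1], targets=[1, 0], source="domain")

        def provider(b):
            logits = np.full((2, 2), -1e9)
            logits[np.arange(2), b.targets] = 0.0
            return Tensor(logits)

        assert mixed_nll_loss([batch], provider).item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_model_hand_arithmetic(self):
        # uniform over vocab 2, T=2, single domain sample: 0.75 * 2 ln 2
        batch = TokenBatch(input_ids=[0, 1], targets=[1, 0], source="domain")
        loss = mixed_nll_loss([batch], lambda b: Tensor(np.zeros((2, 2))))
        assert loss.item() == pytest.approx(0.75 * 2 * np.log(2), abs=1e-9)
        assert loss.item() == pytest.approx(1.0397, abs=1e-4)

    def test_weight_normalization_identity(self):
        # equal per-sample loss in both corpora -> total = (l_d + l_g) L0 = L0
        d = TokenBatch(input_ids=[0], targets=[1], source="domain")
        g = TokenBatch(input_ids=[0], targets=[1], source="general")
        loss = mixed_nll_loss([d, g], lambda b: Tensor(np.zeros((1, 4))))
        assert loss.item() == pytest.approx(np.log(4), abs=1e-9)

    def test_matches_brute_force_summation(self, rng):
        # oracle: explicit per-token -log p accumulation
        batches = []
        logit_map = {}
        for i in range(6):
            T = int(rng.integers(1, 5))
            b = TokenBatch(
                input_ids=rng.integers(0, 8, size=T),
                targets=rng.integers(0, 8, size=T),
                source="domain" if i % 3 else "general",
            )
            batches.append(b)
            logit_map[id(b)] = rng.normal(size=(T, 8))
        loss = mixed_nll_loss(batches, lambda b: Tensor(logit_map[id(b)]))

        sums = {"domain": [], "general": []}
        for b in batches:
            z = logit_map[id(b)]
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            nll = -np.log(p[np.arange(len(b.targets)), b.targets]).sum()
            sums[b.source].append(nll)
        expected = 0.75 * np.mean(sums["domain"]) + 0.25 * np.mean(sums["general"])
        assert loss.item() == pytest.approx(expected, abs=1e-6)


class TestSampleMixed:
    def _streams(self):
        d = [TokenBatch(input_ids=[0], targets=[1], source="domain")]
        g = [TokenBatch(input_ids=[0], targets=[1], source="general")]
        return d, g

    def test_deterministic_interleave_pattern(self):
        d, g = self._streams()
        tags = [b.source for b in sample_mixed(d, g, 8)]
        assert tags == ["domain"] * 3 + ["general"] + ["domain"] * 3 + ["general"]

    def test_one_to_one_ratio_alternates(self):
        d, g = self._streams()
        tags = [b.source for b in sample_mixed(d, g, 6, ratio=(1, 1))]
        assert tags == ["domain", "general"] * 3

    def test_stochastic_concentration(self):
        d, g = self._streams()
        tags = [b.source for b in sample_mixed(d, g, 100_000, seed=0, mode="stochastic")]
        frac = tags.count("domain") / len(tags)
        assert abs(frac - 0.75) < 0.01

    def test_empty_stream_error(self):
        d, _ = self._streams()
        with pytest.raises(ValueError):
            sample_mixed(d, [], 4)


@pytest.fixture(scope="module")
def token_task():
    domain, general = gen_token_task(TokenTaskSpec(seed=11))
    held, _ = gen_token_task(TokenTaskSpec(seed=12, n_domain=48, n_general=16))
    return domain, general, held


def _pretrained(seed=11):
    model = MicroTransformer(seed=seed)
    _, general = gen_token_task(TokenTaskSpec(seed=11))
    pretrain_base(model, general, steps=150, lr=2e-2, seed=20)
    return model


class TestTwoStageFinetune:
    def test_parameter_audit_matches_shape_enumeration(self):
        model = MicroTransformer()  # d=16, FFN 32, r=4, 2 layers
        c = model.config
        expected_lora = 2 * (c.lora_rank * c.d_model + c.d_model * c.lora_rank) * c.n_layers
        expected_ia3 = c.d_ff * c.n_layers
        audit = model.adapters.audit()
        assert audit["lora"] == expected_lora == 512
        assert audit["ia3"] == expected_ia3 == 64

    def test_zero_steps_leaves_model_identical(self, token_task):
        domain, general, _ = token_task
        model = MicroTransformer(seed=7)
        before = composite_forward(model, np.arange(10))
        two_stage_finetune(model, domain, general, stage1_steps=0, stage2_steps=0)
        assert np.array_equal(before, composite_forward(model, np.arange(10)))

    def test_stage_semantics_and_continuity(self, token_task):
        domain, general, _ = token_task
        model = _pretrained()
        result = two_stage_finetune(
            model, domain, general, stage1_steps=12, stage2_steps=6, lr=1e-2, seed=13
        )
        assert result.audits["stage1_trainable"] == 512
        assert result.audits["stage2_trainable"] == 64
        # loss continuity at the stage boundary
        assert result.stage2_initial_loss == result.stage1_final_loss
        stages = [s for _, s, _ in result.trace]
        assert stages == ["stage1"] * 12 + ["stage2"] * 6

    def test_base_frozen_after_training(self, token_task):
        domain, general, _ = token_task
        model = _pretrained()
        two_stage_finetune(model, domain, general, stage1_steps=8, stage2_steps=4, seed=13)
        assert model.base_unchanged()

    def test_seeded_run_reduces_loss(self, token_task):
        domain, general, _ = token_task
        model = _pretrained()
        result = two_stage_finetune(
            model, domain, general, stage1_steps=60, stage2_steps=30, lr=2e-2, seed=13
        )
        assert result.trace[-1][2] < result.trace[0][2]

    def test_dual_adapter_not_worse_than_singles(self, token_task):
        # mirrors the ablation ordering qualitatively: the dual run's held-out
        # accuracy is within 0.02 of (or above) each single-adapter run
        domain, general, held = token_task

        def run(s1, s2):
            model = _pretrained()
            two_stage_finetune(
                model, domain, general, stage1_steps=s1, stage2_steps=s2, lr=2e-2, seed=13
            )
            return token_accuracy(model, held)

        dual = run(120, 60)
        lora_only = run(180, 0)
        ia3_only = run(0, 180)
        assert dual >= lora_only - 0.02
        assert dual >= ia3_only - 0.02

    def test_joint_mode_trains_both_families(self, token_task):
        domain, general, _ = token_task
        model = _pretrained()
        result = two_stage_finetune(
            model, domain, general, stage1_steps=4, stage2_steps=2, seed=13, mode="joint"
        )
        assert result.audits["joint_trainable"] == 512 + 64
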