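"""Label smoothing, target builders, loss arithmetic, batching, toy training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nadesign import autodiff as ad
from nadesign.model import ModelConfig
from nadesign.ppm_align import AlignedColumn, AlignedTargetMap
from nadesign.structures import (
    Complex,
    NA_CANONICAL,
    N_TOKENS,
    PolymerClass,
    TOKEN_NA_UNK,
    interface_mask,
)
from nadesign.synthetic import (
    HelixSpec,
    make_duplex,
    make_planted_dataset,
    make_protein_dna_complex,
    make_protein_helix,
    make_single_strand,
)
from nadesign.targets_loss import (
    ClusterInfo,
    TargetDistribution,
    TargetError,
    assemble_batches,
    batch_loss,
    build_design_targets,
    build_specificity_targets,
    sampling_weight,
    smooth_within_class,
    train_toy,
)


def _onehot(i):
    v = np.zeros(N_TOKENS)
    v[i] = 1.0
    return v


class TestSmoothing:
    def test_epsilon_zero_is_identity(self):
        for tok in (0, 7, 21, 24):
            assert np.allclose(smooth_within_class(_onehot(tok), 0.0), _onehot(tok))

    def test_na_smoothing_values(self):
        y = smooth_within_class(_onehot(NA_CANONICAL[0]), 0.1)
        assert y[NA_CANONICAL[0]] == pytest.approx(0.925)
        for t in NA_CANONICAL[1:]:
            assert y[t] == pytest.approx(0.025)

    @given(tok=st.sampled_from(list(range(20)) + list(NA_CANONICAL)),
           eps=st.floats(0.0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_normalized_with_zero_cross_class_mass(self, tok, eps):
        y = smooth_within_class(_onehot(tok), eps)
        assert y.sum() == pytest.approx(1.0)
        if tok < 21:
            assert y[21:].sum() == 0.0
        else:
            assert y[:21].sum() == 0.0

    def test_unknown_token_gets_class_uniform(self):
        y = smooth_within_class(_onehot(TOKEN_NA_UNK))
        assert np.allclose(y[list(NA_CANONICAL)], 0.25)
        assert y.sum() == pytest.approx(1.0)


class TestDesignTargets:
    def test_protein_only_all_masks_false(self):
        t = build_design_targets(make_protein_helix(10))
        assert not t.mask.any()

    def test_rna_strand_pattern(self):
        c = make_single_strand(HelixSpec(form="A-RNA", sequence="ACGUACGUAC"))
        t = build_design_targets(c)
        assert t.mask.sum() == 10
        for i in range(10):
            row = t.y[i]
            assert row.max() == pytest.approx(0.925)
            assert np.sort(row[row > 0]) [:-1] == pytest.approx(0.025)

    def test_unknown_base_uniform(self, duplex10):
        import copy

        c = copy.deepcopy(duplex10)
        c.residues[0].token = TOKEN_NA_UNK
        t = build_design_targets(c)
        assert t.mask[0]
        assert np.allclose(t.y[0][list(NA_CANONICAL)], 0.25)


class TestSpecificityTargets:
    def test_na_only_uniform(self, duplex10):
        t, _, dropped = build_specificity_targets(
            duplex10, AlignedTargetMap(), None, np.random.default_rng(0))
        assert not dropped
        assert np.allclose(t.y[t.mask][:, list(NA_CANONICAL)], 0.25)

    def test_protein_drop_frequency(self):
        c = make_protein_dna_complex(contact_distance=4.0)
        iface = interface_mask(c)
        rng = np.random.default_rng(123)
        drops = sum(
            build_specificity_targets(c, AlignedTargetMap(), iface, rng)[2]
            for _ in range(4000)
        )
        assert drops / 4000 == pytest.approx(0.5, abs=0.025)

    class _NeverDrop:
        def random(self):
            return 0.99

    def test_aligned_column_copied_exactly(self):
        c = make_protein_dna_complex(contact_distance=4.0)
        iface = interface_mask(c)
        am = AlignedTargetMap()
        col = np.array([0.7, 0.1, 0.1, 0.1])
        target_res = c.residues[5]
        am.columns[(target_res.chain_id, target_res.index)] = AlignedColumn(col, 1.0, 5.0)
        t, _, dropped = build_specificity_targets(c, am, iface, self._NeverDrop())
        assert not dropped
        assert np.allclose(t.y[5][list(NA_CANONICAL)], col)

    def test_interface_vs_far_positions(self):
        c = make_protein_dna_complex(contact_distance=4.0)
        iface = interface_mask(c)
        assert iface.any()
        t, _, dropped = build_specificity_targets(
            c, AlignedTargetMap(), iface, self._NeverDrop())
        assert not dropped
        for i, r in enumerate(c.residues):
            if not t.mask[i]:
                continue
            if iface[i]:
                assert t.y[i].max() == pytest.approx(0.925)
            else:
                assert np.allclose(t.y[i][list(NA_CANONICAL)], 0.25)

    def test_bad_column_raises(self):
        c = make_protein_dna_complex(contact_distance=4.0)
        am = AlignedTargetMap()
        r5 = c.residues[5]
        am.columns[(r5.chain_id, r5.index)] = AlignedColumn(np.array([0.5, 0.1, 0.1, 0.1]), 1.0, 5.0)
        with pytest.raises(TargetError):
            build_specificity_targets(c, am, interface_mask(c), self._NeverDrop())

    def test_never_drop_stub_deterministic(self):
        c = make_protein_dna_complex(contact_distance=4.0)
        iface = interface_mask(c)
        a = build_specificity_targets(c, AlignedTargetMap(), iface, self._NeverDrop())[0]
        b = build_specificity_targets(c, AlignedTargetMap(), iface, self._NeverDrop())[0]
        assert np.array_equal(a.y, b.y)


class TestLoss:
    def test_all_masks_false_is_zero(self):
        logp = np.log(np.full((4, N_TOKENS), 1 / N_TOKENS))
        t = TargetDistribution(np.zeros((4, N_TOKENS)), np.zeros(4, bool))
        assert batch_loss([logp], [t]).item() == 0.0

    def test_uniform_prediction_closed_form(self):
        logp = np.log(np.full((1, N_TOKENS), 1 / N_TOKENS))
        t = TargetDistribution(_onehot(NA_CANONICAL[0])[None], np.array([True]))
        assert batch_loss([logp], [t]).item() == pytest.approx(np.log(26) / 6000)

    def test_linearity_in_masked_residues(self):
        logp = np.log(np.full((2, N_TOKENS), 1 / N_TOKENS))
        y = np.stack([_onehot(21), _onehot(21)])
        one = TargetDistribution(y, np.array([True, False]))
        two = TargetDistribution(y, np.array([True, True]))
        assert batch_loss([logp], [two]).item() == pytest.approx(
            2 * batch_loss([logp], [one]).item())

    def test_matches_scalar_loop_oracle(self, rng):
        logits = rng.normal(size=(3, 5, N_TOKENS))
        logp = logits - np.log(np.exp(logits).sum(-1, keepdims=True))
        raw = rng.random((3, 5, N_TOKENS))
        total = 0.0
        targets, logps = [], []
        for b in range(3):
            y = raw[b] / raw[b].sum(-1, keepdims=True)
            mask = rng.random(5) > 0.4
            targets.append(TargetDistribution(y, mask))
            logps.append(logp[b])
            for i in range(5):
                if mask[i]:
                    for cidx in range(N_TOKENS):
                        total -= y[i, cidx] * logp[b, i, cidx]
        got = batch_loss(logps, targets).item()
        assert got == pytest.approx(total / 6000, rel=1e-10)

    def test_nan_raises(self):
        logp = np.full((1, N_TOKENS), np.nan)
        t = TargetDistribution(_onehot(21)[None], np.array([True]))
        with pytest.raises(TargetError):
            batch_loss([logp], [t])


class TestSamplingWeight:
    def test_values(self, duplex10):
        one_chain = Complex(chains=[duplex10.chains[0]], resolution=2.0)
        assert sampling_weight(one_chain, ClusterInfo({"A": 0})) == 1.0
        assert sampling_weight(duplex10, ClusterInfo({"A": 1, "B": 3})) == pytest.approx(0.375)

    def test_monotone_decreasing(self, duplex10):
        w = [sampling_weight(duplex10, ClusterInfo({"A": d, "B": d})) for d in (0, 5, 500)]
        assert w[0] > w[1] > w[2]
        assert w[2] < 0.01

    def test_missing_degree_raises(self, duplex10):
        with pytest.raises(TargetError):
            sampling_weight(duplex10, ClusterInfo({"A": 0}))


class TestBatching:
    def test_single_token_examples_fill_budget(self, rng):
        gen = assemble_batches(list(range(50)), [1.0] * 50, [1] * 50, rng, budget=6000)
        batch = next(gen)
        assert len(batch.examples) == 6000
        assert batch.total_tokens == 6000

    def test_budget_never_exceeded(self, rng):
        sizes = [500, 1200, 3000, 2500, 900]
        gen = assemble_batches(list(range(5)), [1.0] * 5, sizes, rng, budget=6000)
        for _ in range(20):
            assert next(gen).total_tokens <= 6000

    def test_oversized_example_skipped(self, rng, caplog):
        gen = assemble_batches([0, 1], [1.0, 1.0], [7000, 10], rng, budget=6000)
        batch = next(gen)
        assert all(e == 1 for e in batch.examples)

    def test_empty_stream_yields_nothing(self, rng):
        assert list(assemble_batches([], [], [], rng)) == []

    def test_weighted_draw_ratio(self, rng):
        gen = assemble_batches(["a", "b"], [1.0, 0.5], [1, 1], rng, budget=1000)
        drawn = []
        while len(drawn) < 30000:
            drawn.extend(next(gen).examples)
        frac_a = drawn.count("a") / len(drawn)
        p = 2 / 3
        sigma = np.sqrt(p * (1 - p) / len(drawn))
        assert abs(frac_a - p) < 3 * sigma + 1e-9


@pytest.fixture(scope="module")
def tiny_run():
    ds = make_planted_dataset(4, seed=5, length=6)
    cfg = ModelConfig(hidden_dim=32, n_encoder_layers=1, n_decoder_layers=1,
                      dropout=0.0, seed=5)
    return ds, cfg, train_toy(ds.complexes, cfg, n_steps=30, seed=5, lr=2e-3)


class TestToyTraining:
    def test_loss_decreases(self, tiny_run):
        _, _, res = tiny_run
        assert res.losses[-1] < res.losses[0]

    def test_deterministic_under_seed(self, tiny_run):
        ds, cfg, res = tiny_run
        res2 = train_toy(ds.complexes, cfg, n_steps=30, seed=5, lr=2e-3)
        assert np.allclose(res.losses, res2.losses, rtol=1e-4)

    def test_gradient_clipping_bounds_norm(self, tiny_run):
        """After clipping, the global gradient norm never exceeds 1."""
        ds, cfg, res = tiny_run
        model = res.model
        from nadesign.featurize import build_graph
        from nadesign.model import complex_tokens
        from nadesign.targets_loss import build_design_targets

        c = ds.complexes[0]
        g = build_graph(c)
        t = build_design_targets(c)
        n = g.n_nodes
        order = np.arange(n)
        logits = model.forward_logits(g, complex_tokens(c), order, ~t.mask)
        loss = batch_loss([ad.log_softmax(logits)], [t])
        # amplify so the raw norm is well above 1, then clip
        big = ad.mul(loss, 1e7)
        ad.zero_grads(model.params)
        big.backward()
        pre = ad.clip_grad_norm(model.params, 1.0)
        assert pre > 1.0
        assert ad.global_grad_norm(model.params) <= 1.0 + 1e-6
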