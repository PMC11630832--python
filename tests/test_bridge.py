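"""Bridge architecture contracts and the three pretraining objectives."""

import numpy as np
import pytest
from scipy.stats import chisquare

from gobridge.bridge import (
    Bridge,
    BridgeConfig,
    TinyProteinEncoder,
    binary_match_loss,
    lm_loss,
    pad_protein_batch,
    ptc_loss,
    sample_hard_negatives,
    similarity_matrix,
)
from gobridge.nn.autograd import Tensor
from gobridge.nn.layers import AdamW


CFG = BridgeConfig(d_q=32, n_layers=2, n_heads=2, d_ff=64, n_queries=4,
                   d_protein=16, vocab_size=20, max_text_len=16, seed=0)


@pytest.fixture
def model():
    return Bridge(CFG)


@pytest.fixture
def encoder():
    return TinyProteinEncoder(d_protein=16, seed=1)


def _protein_batch(encoder, seqs):
    return pad_protein_batch([encoder(s) for s in seqs])


def _tokens(rows, width):
    toks = np.zeros((len(rows), width), dtype=int)
    pad = np.ones((len(rows), width), dtype=bool)
    for i, r in enumerate(rows):
        toks[i, : len(r)] = r
        pad[i, : len(r)] = False
    return toks, pad


class TestEncoder:
    def test_deterministic(self, encoder):
        a = encoder("MKTAYIAK")
        b = encoder("MKTAYIAK")
        assert np.array_equal(a.matrix, b.matrix)

    def test_row_per_residue(self, encoder):
        assert encoder("ACDEFGH").matrix.shape == (7, 16)

    def test_residue_perturbation_changes_its_row(self, encoder):
        a = encoder("ACDEFGHIKL").matrix
        b = encoder("ACDEFWHIKL").matrix  # position 5 changed
        assert not np.allclose(a[5], b[5])
        assert np.array_equal(a[0], b[0])  # far positions untouched

    def test_illegal_residue_rejected(self, encoder):
        with pytest.raises(ValueError, match="illegal"):
            encoder("ACDB1")

    def test_over_length_names_limit(self):
        enc = TinyProteinEncoder(max_len=10, seed=0)
        with pytest.raises(ValueError, match="10"):
            enc("A" * 11)


class TestMaskingContracts:
    def test_contrastive_queries_blind_to_text(self, model, encoder):
        """Changing the text leaves contrastive-mode query outputs
        bit-identical: the unimodal masking contract."""
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR", "ACDEFGHIKL"])
        t1, p1 = _tokens([[1, 5, 6, 2], [1, 7, 2]], 5)
        t2, p2 = _tokens([[1, 9, 2], [1, 8, 8, 8, 2]], 5)
        q1, _ = model.forward(prot, pmask, t1, p1, "contrastive")
        q2, _ = model.forward(prot, pmask, t2, p2, "contrastive")
        assert np.array_equal(q1.data, q2.data)

    def test_generative_logits_causal(self, model, encoder):
        """Token t's logits are bit-invariant to tokens after t."""
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR"])
        a, pa = _tokens([[1, 5, 6, 7, 2]], 5)
        b, pb = _tokens([[1, 5, 6, 9, 9]], 5)  # differs only at positions >= 3
        la = model.forward(prot, pmask, a, pa, "generative").data
        lb = model.forward(prot, pmask, b, pb, "generative").data
        assert np.array_equal(la[0, :3], lb[0, :3])

    def test_cross_attention_is_live(self, model, encoder):
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR"])
        q_real = model.encode_queries(prot, pmask)
        q_zero = model.encode_queries(np.zeros_like(prot), pmask)
        assert not np.allclose(q_real.data, q_zero.data)

    def test_matching_mode_sees_text(self, model, encoder):
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR"])
        t1, p1 = _tokens([[1, 5, 2]], 4)
        t2, p2 = _tokens([[1, 9, 2]], 4)
        l1 = model.forward(prot, pmask, t1, p1, "matching").data
        l2 = model.forward(prot, pmask, t2, p2, "matching").data
        assert not np.allclose(l1, l2)


class TestPTC:
    def test_uniform_similarities_give_ln_n(self):
        rng = np.random.default_rng(0)
        n, k, d = 5, 3, 8
        q = Tensor(np.tile(rng.normal(size=(1, 1, d)), (n, k, 1)))
        t = Tensor(np.tile(rng.normal(size=(1, d)), (n, 1)))
        # all pairs identical -> every similarity equal -> loss = ln N
        loss = ptc_loss(q, t, tau=1.0)
        assert float(loss.data) == pytest.approx(np.log(n), abs=1e-9)

    def test_dominant_diagonal_drives_loss_to_zero(self):
        n, d = 4, 6
        eye = np.eye(n, d)
        q = Tensor(eye[:, None, :])
        t = Tensor(eye)
        loss = ptc_loss(q, t, tau=1 / 50.0)  # diag cos=1 scaled to 50, off-diag 0
        assert float(loss.data) < 1e-15

    def test_two_by_two_matches_hand_calculation(self):
        # construct unit vectors with known cosine matrix [[1, 0], [0, 1]]
        q = Tensor(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        t = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        tau = 0.5
        loss = float(ptc_loss(q, t, tau=tau).data)
        z = np.array([[1 / tau, 0.0], [0.0, 1 / tau]])
        expected = -np.mean([
            z[0, 0] - np.log(np.exp(z[0]).sum()),
            z[1, 1] - np.log(np.exp(z[1]).sum()),
        ])
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_batch_of_one_rejected(self):
        q = Tensor(np.ones((1, 2, 4)))
        t = Tensor(np.ones((1, 4)))
        with pytest.raises(ValueError):
            ptc_loss(q, t, tau=1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        q = Tensor(rng.normal(size=(6, 4, 8)))
        t = Tensor(rng.normal(size=(6, 8)))
        base = float(ptc_loss(q, t, tau=0.1).data)
        perm = rng.permutation(6)
        shuffled = float(ptc_loss(Tensor(q.data[perm]), Tensor(t.data[perm]), tau=0.1).data)
        assert shuffled == pytest.approx(base, rel=1e-6)

    def test_max_aggregation_uses_best_query(self):
        # one query matches, others are orthogonal: max picks the match
        q = np.zeros((2, 2, 4))
        q[0, 1] = [1, 0, 0, 0]
        q[0, 0] = [0, 0, 0, 1]
        q[1, 0] = [0, 1, 0, 0]
        q[1, 1] = [0, 0, 0, 1]
        t = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        sim = similarity_matrix(Tensor(q), Tensor(t), "max").data
        assert sim[0, 0] == pytest.approx(1.0) and sim[1, 1] == pytest.approx(1.0)


class TestHardNegatives:
    def test_n2_returns_the_only_off_diagonal(self):
        rng = np.random.default_rng(0)
        sim = np.array([[5.0, 1.0], [0.0, 9.0]])
        neg_t, neg_p = sample_hard_negatives(sim, rng)
        assert neg_t.tolist() == [1, 0]
        assert neg_p.tolist() == [1, 0]

    def test_sampling_law_matches_masked_softmax(self):
        """Row logits (0, ln 3) => probabilities (0.25, 0.75)."""
        rng = np.random.default_rng(1)
        sim = np.array([
            [99.0, 0.0, np.log(3.0)],
            [0.0, 99.0, 0.0],
            [0.0, 0.0, 99.0],
        ])
        draws = 10**5
        counts = np.zeros(3)
        for _ in range(draws):
            neg_t, _ = sample_hard_negatives(sim, rng)
            counts[neg_t[0]] += 1
        assert counts[0] == 0
        stat = chisquare(counts[1:], f_exp=np.array([0.25, 0.75]) * draws)
        assert stat.pvalue > 0.01

    def test_diagonal_never_sampled(self):
        rng = np.random.default_rng(2)
        sim = rng.normal(size=(4, 4)) + 10 * np.eye(4)  # diagonal dominant
        for _ in range(2000):
            neg_t, neg_p = sample_hard_negatives(sim, rng)
            assert all(neg_t != np.arange(4))
            assert all(neg_p != np.arange(4))


class TestPTMAndLM:
    def test_uniform_match_logits_give_ln_2(self):
        logits = Tensor(np.zeros((6, 2)))
        labels = np.array([1, 1, 0, 0, 1, 0])
        assert float(binary_match_loss(logits, labels).data) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_separated_logits_give_negligible_loss(self):
        labels = np.array([1, 0, 0])
        logits = np.array([[-50.0, 50.0], [50.0, -50.0], [50.0, -50.0]])
        assert float(binary_match_loss(Tensor(logits), labels).data) < 1e-15

    def test_hand_built_bce(self):
        logits = np.array([[0.0, 1.0], [2.0, 0.0], [0.5, 0.5]])
        labels = np.array([1, 0, 0])
        expected = -np.mean([
            1.0 - np.log(np.exp(0) + np.exp(1)),
            2.0 - np.log(np.exp(2) + np.exp(0)),
            0.5 - np.log(2 * np.exp(0.5)),
        ])
        assert float(binary_match_loss(Tensor(logits), labels).data) == pytest.approx(
            expected, rel=1e-6
        )

    def test_untrained_lm_near_ln_vocab(self, model, encoder):
        """A fresh decoder's per-token loss is within 5% of ln V."""
        rng = np.random.default_rng(4)
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQRMKTAYIAKQR"] * 8)
        rows = [[1] + list(rng.integers(5, CFG.vocab_size, size=6)) + [2] for _ in range(8)]
        toks, pad = _tokens(rows, 8)
        tmask = ~pad
        tmask[:, 0] = False
        logits = model.generative_logits(prot, pmask, toks, pad)
        loss = float(lm_loss(logits, toks, tmask).data)
        assert loss == pytest.approx(np.log(CFG.vocab_size), rel=0.05)

    def test_overfit_single_pair_memorizes(self, model, encoder):
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR"])
        toks, pad = _tokens([[1, 5, 6, 7, 2]], 5)
        tmask = ~pad
        tmask[:, 0] = False
        opt = AdamW(list(model.parameters()), lr=5e-3)
        for _ in range(150):
            loss = lm_loss(model.generative_logits(prot, pmask, toks, pad), toks, tmask)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.01

    def test_masking_a_target_removes_its_contribution(self, model, encoder):
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR"])
        toks, pad = _tokens([[1, 5, 6, 7, 2]], 5)
        full = ~pad
        full[:, 0] = False
        logits = model.generative_logits(prot, pmask, toks, pad)
        # recompute the masked mean directly from per-position terms
        partial = full.copy()
        partial[0, 2] = False
        l_full = float(lm_loss(logits, toks, full).data)
        l_part = float(lm_loss(logits, toks, partial).data)
        ls = logits.data[:, :-1, :]
        ls = ls - ls.max(axis=-1, keepdims=True)
        ls = ls - np.log(np.exp(ls).sum(axis=-1, keepdims=True))
        per_pos = -np.take_along_axis(ls, toks[:, 1:, None], axis=-1)[0, :, 0]
        m_full = full[0, 1:]
        m_part = partial[0, 1:]
        assert l_full == pytest.approx(per_pos[m_full].mean(), rel=1e-5)
        assert l_part == pytest.approx(per_pos[m_part].mean(), rel=1e-5)

    def test_all_padding_text_rejected(self, model, encoder):
        prot, pmask = _protein_batch(encoder, ["MKTAYIAKQR"])
        toks, pad = _tokens([[1, 5, 2]], 4)
        logits = model.generative_logits(prot, pmask, toks, pad)
        with pytest.raises(ValueError):
            lm_loss(logits, toks, np.zeros_like(pad))


class TestTrainingDynamics:
    def test_losses_finite_and_nonnegative_on_random_inputs(self, model, encoder):
        rng = np.random.default_rng(5)
        seqs = ["".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 30))
                for _ in range(4)]
        prot, pmask = _protein_batch(encoder, seqs)
        rows = [[1] + list(rng.integers(5, 20, size=4)) + [2] for _ in range(4)]
        toks, pad = _tokens(rows, 6)
        q = model.encode_queries(prot, pmask)
        t = model.encode_text(toks, pad)
        l_ptc = float(ptc_loss(q, t[:, 0, :], tau=0.07).data)
        tmask = ~pad
        tmask[:, 0] = False
        l_lm = float(lm_loss(model.generative_logits(prot, pmask, toks, pad), toks, tmask).data)
        logits = model.forward_matching(prot, pmask, toks, pad)
        l_ptm = float(binary_match_loss(logits, np.array([1, 0, 1, 0])).data)
        for v in (l_ptc, l_ptm, l_lm):
            assert np.isfinite(v) and v >= 0

    def test_encoder_frozen_and_bridge_receives_gradient(self, model, encoder):
        seq = "MKTAYIAKQRMKTAYIAKQR"
        before = encoder(seq).matrix.copy()
        prot, pmask = _protein_batch(encoder, [seq] * 2)
        toks, pad = _tokens([[1, 5, 2], [1, 6, 2]], 4)
        q = model.encode_queries(prot, pmask)
        t = model.encode_text(toks, pad)
        loss = ptc_loss(q, t[:, 0, :], tau=0.07)
        model.zero_grad()
        loss.backward()
        assert model.queries.grad is not None and np.any(model.queries.grad != 0)
        assert any(p.grad is not None and np.any(p.grad != 0)
                   for n, p in model.parameters() if "cross_attn" in n)
        # the encoder is pure numpy: a training step cannot move it
        opt = AdamW(list(model.parameters()), lr=1e-3)
        opt.step()
        assert np.array_equal(encoder(seq).matrix, before)

    def test_joint_overfitting_decreases_total_loss(self, encoder):
        """Total loss drops over 200 steps on a fixed 16-pair batch (median
        over 3 seeds)."""
        rng = np.random.default_rng(6)
        seqs = ["".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 40))
                for _ in range(16)]
        prot, pmask = pad_protein_batch([encoder(s) for s in seqs])
        rows = [[1] + list(rng.integers(5, 20, size=5)) + [2] for _ in range(16)]
        toks, pad = _tokens(rows, 7)
        tmask = ~pad
        tmask[:, 0] = False
        ratios = []
        for seed in range(3):
            model = Bridge(BridgeConfig(d_q=32, n_layers=2, n_heads=2, d_ff=64,
                                        n_queries=4, d_protein=16, vocab_size=20,
                                        max_text_len=16, seed=seed))
            opt = AdamW(list(model.parameters()), lr=1e-3)
            srng = np.random.default_rng(seed)
            first = last = None
            for step in range(200):
                q = model.encode_queries(prot, pmask)
                t = model.encode_text(toks, pad)
                tp = t[:, 0, :]
                sim = similarity_matrix(q, tp)
                from gobridge.bridge import ptm_loss

                total = (
                    ptc_loss(q, tp, model.log_tau.exp())
                    + ptm_loss(model, prot, pmask, toks, pad, sim.data, srng)
                    + lm_loss(model.generative_logits(prot, pmask, toks, pad), toks, tmask)
                )
                opt.zero_grad()
                total.backward()
                opt.step()
                if step == 0:
                    first = float(total.data)
                last = float(total.data)
            ratios.append(last / first)
        assert np.median(ratios) < 0.5
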