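"""Fusion, hyperedge attention pooling, and the scoring head."""

import numpy as np
import pytest

from hyplink.autodiff import Tensor
from hyplink.decoder import (DecoderParams, embed_hyperedge, fuse,
                             hyperedge_attention, init_decoder_params,
                             member_arrays, score, score_edges)


@pytest.fixture()
def params():
    return init_decoder_params(d_in=8, dv=6, d_ea=5, de=4,
                               rng=np.random.default_rng(0))


def selector_params(dv, d1, d2, which):
    """W_FF that selects one channel exactly."""
    W = np.zeros((dv, d1 + d2))
    if which == "structure":
        W[:, :d1] = np.eye(dv, d1)
    else:
        W[:, d1:] = np.eye(dv, d2)
    return DecoderParams(W_FF=Tensor(W), W_EA=Tensor(np.zeros((2, dv))),
                         w=Tensor(np.zeros(2)), W_SC=Tensor(np.zeros((2, dv))),
                         b_SC=Tensor(np.zeros(2)), u=Tensor(np.zeros(2)))


class TestFusion:
    def test_selector_matrices(self):
        rng = np.random.default_rng(1)
        Zs, Za = Tensor(rng.random((5, 4))), Tensor(rng.random((5, 4)))
        p1 = selector_params(4, 4, 4, "structure")
        np.testing.assert_allclose(fuse([Zs, Za], p1).data, Zs.data)
        p2 = selector_params(4, 4, 4, "attribute")
        np.testing.assert_allclose(fuse([Zs, Za], p2).data, Za.data)

    def test_matches_row_oracle(self, params):
        rng = np.random.default_rng(2)
        Zs, Za = Tensor(rng.random((5, 3))), Tensor(rng.random((5, 5)))
        out = fuse([Zs, Za], params).data
        for i in range(5):
            row = params.W_FF.data @ np.concatenate([Zs.data[i], Za.data[i]])
            np.testing.assert_allclose(out[i], row, rtol=1e-12)

    def test_row_mismatch_rejected(self, params):
        with pytest.raises(ValueError, match="row counts"):
            fuse([Tensor(np.zeros((3, 4))), Tensor(np.zeros((2, 4)))], params)


class TestHyperedgeAttention:
    def test_singleton_weight_one(self, params):
        Zv = Tensor(np.random.default_rng(3).random((4, 6)))
        mem, seg = member_arrays([{2}])
        a = hyperedge_attention(Zv, mem, seg, 1, params)
        assert a.data[0] == pytest.approx(1.0)

    def test_identical_members_split_evenly(self, params):
        Zv = Tensor(np.tile(np.random.default_rng(4).random(6), (3, 1)))
        mem, seg = member_arrays([{0, 1, 2}])
        a = hyperedge_attention(Zv, mem, seg, 1, params)
        np.testing.assert_allclose(a.data, 1 / 3, atol=1e-12)

    def test_weights_normalized_and_interior(self, params):
        Zv = Tensor(np.random.default_rng(5).random((8, 6)) * 3)
        mem, seg = member_arrays([{0, 1, 2, 3, 4}, {5, 6}])
        a = hyperedge_attention(Zv, mem, seg, 2, params)
        assert a.data[:5].sum() == pytest.approx(1.0, abs=1e-9)
        assert a.data[5:].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((a.data > 0) & (a.data < 1))

    def test_uniform_flag(self, params):
        Zv = Tensor(np.random.default_rng(6).random((5, 6)))
        mem, seg = member_arrays([{0, 1, 2}, {3, 4}])
        a = hyperedge_attention(Zv, mem, seg, 2, params, uniform=True)
        np.testing.assert_allclose(a.data, [1 / 3, 1 / 3, 1 / 3, 0.5, 0.5])


class TestEmbedding:
    def test_singleton_returns_member_row(self, params):
        Zv = Tensor(np.random.default_rng(7).random((4, 6)))
        mem, seg = member_arrays([{3}])
        Ze = embed_hyperedge(Zv, mem, seg, 1, Tensor(np.ones(1)))
        np.testing.assert_allclose(Ze.data[0], Zv.data[3])

    def test_uniform_weights_give_centroid(self, params):
        Zv = Tensor(np.random.default_rng(8).random((5, 6)))
        mem, seg = member_arrays([{0, 2, 4}])
        Ze = embed_hyperedge(Zv, mem, seg, 1, Tensor(np.full(3, 1 / 3)))
        np.testing.assert_allclose(Ze.data[0], Zv.data[[0, 2, 4]].mean(axis=0))

    def test_matches_loop_oracle(self, params):
        rng = np.random.default_rng(9)
        Zv = Tensor(rng.random((6, 6)))
        edges = [{0, 1, 2}, {3, 5}]
        mem, seg = member_arrays(edges)
        a = hyperedge_attention(Zv, mem, seg, 2, params)
        Ze = embed_hyperedge(Zv, mem, seg, 2, a).data
        k = 0
        for j, e in enumerate(edges):
            expected = np.zeros(6)
            for i in sorted(e):
                expected += a.data[k] * Zv.data[i]
                k += 1
            np.testing.assert_allclose(Ze[j], expected, rtol=1e-10)

    def test_member_order_invariance(self, params):
        Zv = Tensor(np.random.default_rng(10).random((6, 6)))
        s1 = score_edges(Zv, [[0, 3, 5]], params).data
        s2 = score_edges(Zv, [[5, 0, 3]], params).data
        assert s1[0] == s2[0]


class TestScore:
    def test_zero_logit_gives_half(self, params):
        p = params
        p.u = Tensor(np.zeros(4))
        s = score(Tensor(np.random.default_rng(11).random((3, 6))), p)
        np.testing.assert_allclose(s.data, 0.5)

    def test_strictly_inside_unit_interval(self, params):
        Ze = Tensor(np.random.default_rng(12).normal(size=(50, 6)) * 10)
        s = score(Ze, params).data
        assert np.all((s > 0) & (s < 1))

    def test_monotone_in_logit_and_saturating(self, params):
        base = np.random.default_rng(13).random((1, 6))
        # scale u upward: logit grows monotonically in magnitude
        logits, scores = [], []
        for scale in (0.1, 1.0, 10.0, 1000.0):
            p = DecoderParams(W_FF=params.W_FF, W_EA=params.W_EA, w=params.w,
                              W_SC=params.W_SC, b_SC=params.b_SC,
                              u=Tensor(np.abs(params.u.data) * scale))
            hidden = np.maximum(base @ params.W_SC.data.T + params.b_SC.data, 0)
            logits.append(float((hidden @ p.u.data).item()))
            scores.append(float(score(Tensor(base), p).data[0]))
        order = np.argsort(logits)
        assert np.all(np.diff(np.asarray(scores)[order]) >= 0)
        assert scores[-1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_composition(self, params):
        rng = np.random.default_rng(14)
        Ze = rng.random((2, 6))
        expected = 1 / (1 + np.exp(-(np.maximum(
            Ze @ params.W_SC.data.T + params.b_SC.data, 0) @ params.u.data)))
        np.testing.assert_allclose(score(Tensor(Ze), params).data, expected,
                                   rtol=1e-12)


def test_empty_hyperedge_rejected(params):
    with pytest.raises(ValueError, match="empty"):
        member_arrays([set()])


def test_out_of_range_member_rejected(params):
    Zv = Tensor(np.zeros((3, 6)))
    with pytest.raises(ValueError, match="node 9"):
        score_edges(Zv, [{0, 9}], params)
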