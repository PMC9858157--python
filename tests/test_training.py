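"""Negative sampling, splitting, ranking loss, and the training loop."""

import numpy as np
import pytest

from hyplink import (HyperlinkModel, SplitSpec, TrainingConfig, ranking_loss,
                     sample_negative, sample_negatives, split_edges, train)
from hyplink.autodiff import Tensor


def all_train_split(n, seed=0):
    empty = np.array([], dtype=np.intp)
    return SplitSpec(np.arange(n), empty, empty, seed)


class TestNegativeSampling:
    def test_size_and_overlap_matched(self):
        rng = np.random.default_rng(0)
        e = frozenset({1, 3, 5, 7})
        for _ in range(50):
            neg = sample_negative(e, m=10, rng=rng)
            assert len(neg) == 4
            assert len(neg & e) == 2

    def test_pair_splits_one_one(self):
        rng = np.random.default_rng(1)
        e = frozenset({0, 1})
        for _ in range(50):
            neg = sample_negative(e, m=6, rng=rng)
            assert len(neg) == 2 and len(neg & e) == 1

    def test_odd_size_majority_outside(self):
        rng = np.random.default_rng(2)
        neg = sample_negative(frozenset({0, 1, 2}), m=12, rng=rng)
        assert len(neg & {0, 1, 2}) == 1 and len(neg) == 3

    def test_never_returns_observed(self):
        rng = np.random.default_rng(3)
        observed = {frozenset({0, 1}), frozenset({0, 2}), frozenset({0, 3})}
        for _ in range(200):
            neg = sample_negative(frozenset({0, 1}), m=5, rng=rng,
                                  observed=observed)
            assert neg not in observed and neg != frozenset({0, 1})

    def test_universe_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            sample_negative(frozenset({0, 1, 2, 3}), m=5,
                            rng=np.random.default_rng(4))

    def test_inside_membership_frequency_matches_binomial(self):
        """Each inside node is kept with probability floor(s/2)/s."""
        rng = np.random.default_rng(5)
        e = frozenset({0, 1, 2, 3, 4})
        counts = {i: 0 for i in e}
        n_draws = 10_000
        for _ in range(n_draws):
            for i in sample_negative(e, m=30, rng=rng) & e:
                counts[i] += 1
        p = (len(e) // 2) / len(e)
        sigma = np.sqrt(p * (1 - p) / n_draws)
        for i in e:
            assert abs(counts[i] / n_draws - p) < 3 * sigma + 0.01


class TestSplit:
    def test_sizes_100(self):
        s = split_edges(100, seed=0)
        assert (len(s.train_edges), len(s.val_edges), len(s.test_edges)) == \
            (70, 10, 20)

    def test_partition_and_determinism(self):
        s1, s2 = split_edges(57, 3), split_edges(57, 3)
        ids = np.concatenate([s1.train_edges, s1.val_edges, s1.test_edges])
        assert sorted(ids.tolist()) == list(range(57))
        for a, b in zip((s1.train_edges, s1.val_edges, s1.test_edges),
                        (s2.train_edges, s2.val_edges, s2.test_edges)):
            np.testing.assert_array_equal(a, b)

    def test_too_few_edges(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_edges(9, 0)


class TestRankingLoss:
    def test_equal_scores_give_log2(self):
        s = Tensor(np.full(5, 0.37))
        assert float(ranking_loss(s, s).data) == pytest.approx(np.log(2),
                                                               rel=1e-12)

    def test_unit_gap_closed_form(self):
        pos = Tensor(np.ones(4))
        neg = Tensor(np.zeros(4))
        expected = np.log(1 + np.exp(-1))
        assert float(ranking_loss(pos, neg).data) == pytest.approx(expected)

    @pytest.mark.parametrize("mode", ["mean", "paired"])
    def test_matches_naive_formula(self, mode):
        rng = np.random.default_rng(6)
        sp, sn = rng.random(8), rng.random(8)
        got = float(ranking_loss(Tensor(sp), Tensor(sn), mode=mode).data)
        if mode == "mean":
            expected = np.mean([np.log(1 + np.exp(sn.mean() - x)) for x in sp])
        else:
            expected = np.mean(np.log(1 + np.exp(sn - sp)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_numerically_stable_for_large_gaps(self):
        out = ranking_loss(Tensor([-500.0]), Tensor([500.0]))
        assert float(out.data) == pytest.approx(1000.0, rel=1e-9)
        assert np.isfinite(float(ranking_loss(Tensor([500.0]),
                                              Tensor([-500.0])).data))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ranking_loss(Tensor([np.nan]), Tensor([0.5]))


class TestTrainLoop:
    def test_zero_epochs_leaves_parameters_unchanged(self, tiny_net):
        cfg = TrainingConfig(max_epochs=0, seed=0)
        rng = np.random.default_rng(0)
        model = HyperlinkModel(tiny_net, seed=int(rng.integers(2 ** 31)))
        before = model.state_dict()
        trained, state = train(tiny_net, all_train_split(tiny_net.n), cfg,
                               model=model)
        assert state.loss == []
        for k, v in trained.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_same_seed_gives_identical_loss_trace(self, tiny_net):
        split = all_train_split(tiny_net.n)
        cfg = TrainingConfig(max_epochs=15, seed=7)
        _, s1 = train(tiny_net, split, cfg)
        _, s2 = train(tiny_net, split, cfg)
        assert s1.loss == s2.loss  # bitwise determinism

    def test_loss_starts_near_log2_and_decreases(self, tiny_net):
        """Symmetric random initial scores give loss ~ log 2; training
        reduces it."""
        split = all_train_split(tiny_net.n)
        _, state = train(tiny_net, split, TrainingConfig(max_epochs=60, seed=1))
        assert abs(state.loss[0] - np.log(2)) < 0.05
        assert state.loss[-1] < state.loss[0] - 0.05
        # trend is downward despite per-epoch negative resampling noise
        assert np.mean(state.loss[-10:]) < np.mean(state.loss[:10]) - 0.05
        sm = np.convolve(state.loss, np.ones(9) / 9, mode="valid")
        assert np.mean(np.diff(sm) <= 1e-3) >= 0.6

    def test_validation_tracking_and_early_stop(self, small_net):
        split = split_edges(small_net.n, seed=0)
        cfg = TrainingConfig(max_epochs=40, seed=2, patience=5)
        _, state = train(small_net, split, cfg)
        assert len(state.loss) <= 40
        assert state.best_val_auc == pytest.approx(max(state.val_auc))
        assert state.val_auc[state.best_epoch] == state.best_val_auc



def test_gradients_match_finite_differences(tiny_net):
    """Autodiff gradients of the ranking loss agree with central
    differences on a random parameter subset."""
    model = HyperlinkModel(tiny_net, seed=3)
    rng = np.random.default_rng(0)
    negs = sample_negatives(tiny_net.hyperedges, tiny_net.m, rng,
                            tiny_net.edge_sets())
    batch = list(tiny_net.hyperedges) + negs
    n_pos = tiny_net.n

    def loss():
        s = model.forward_scores(batch)
        return ranking_loss(s.gather(np.arange(n_pos)),
                            s.gather(np.arange(n_pos, len(batch))))

    L = loss()
    model.zero_grad()
    L.backward()
    params = model.parameters()
    names = sorted(params)
    check_rng = np.random.default_rng(42)
    for _ in range(10):
        name = names[check_rng.integers(len(names))]
        p = params[name]
        idx = tuple(check_rng.integers(s) for s in p.data.shape)
        eps = 1e-6
        orig = p.data[idx]
        p.data[idx] = orig + eps
        fp = float(loss().data)
        p.data[idx] = orig - eps
        fm = float(loss().data)
        p.data[idx] = orig
        fd = (fp - fm) / (2 * eps)
        ad = p.grad[idx]
        assert abs(fd - ad) <= 1e-4 * max(abs(fd), abs(ad)) + 1e-9, name
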