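"""The delta-rule learner: encoding, updates, convergence, ensembles."""

import numpy as np
import pandas as pd
import pytest

from causalearn.learner import (
    LESS,
    MORE,
    OTHER,
    CorpusSampler,
    LearnerConfig,
    LearnerState,
    encode,
    forward,
    init_state,
    judge,
    judge_all,
    run_ensemble,
    split_half,
    train,
    update,
)


def tiny_config(**kw) -> LearnerConfig:
    base = dict(n_verbs=4, epochs=2, utterances_per_epoch=50, n_runs=2,
                seed=11)
    base.update(kw)
    return LearnerConfig(**base)


def uniform_counts(n_verbs=4):
    return pd.DataFrame({
        "verb": [f"v{i}" for i in range(n_verbs)],
        "n_less": [10] * n_verbs,
        "n_more": [10] * n_verbs,
        "n_other": [20] * n_verbs,
    })


def semantics(n_verbs=4, rng=None):
    rng = rng or np.random.default_rng(0)
    return rng.uniform(0, 1, size=(n_verbs, 4))


class TestInitialization:
    def test_same_seed_identical_weights(self):
        cfg = tiny_config()
        a = init_state(cfg, np.random.default_rng(5))
        b = init_state(cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a.W, b.W)

    def test_zero_range_gives_uniform_softmax(self):
        cfg = tiny_config(init_range=0.0)
        state = init_state(cfg)
        acts = judge(state, 0, [0.3, 0.7, 0.1, 0.9])
        np.testing.assert_allclose(acts, [1 / 3] * 3, atol=1e-12)

    def test_weights_fill_uniform_bounds(self):
        cfg = tiny_config(n_verbs=1000, init_range=0.5)
        W = init_state(cfg, np.random.default_rng(1)).W.ravel()
        assert W.size >= 3000
        assert W.min() >= -0.5 and W.max() <= 0.5
        # quantiles of U(-0.5, 0.5) recovered within Monte-Carlo error
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(W, q) == pytest.approx(q - 0.5, abs=0.02)


class TestEncoding:
    def test_structure(self):
        x = encode(0, 1, [0.0, 0.0, 0.0, 0.0], n_verbs=4)
        assert x.shape == (10,)
        assert x[0] == 1.0 and x[4] == 1.0 and x[-1] == 1.0
        assert np.count_nonzero(x) == 3  # lexical + causative + bias

    def test_noncausative_drops_causative_bit(self):
        x = encode(2, 0, [0.5] * 4, n_verbs=4)
        assert x[4] == 0.0
        assert np.count_nonzero(x) >= 2  # lexical + bias at minimum

    def test_two_verbs_differ_in_two_positions(self):
        sem = [0.1, 0.2, 0.3, 0.4]
        a = encode(1, 1, sem, n_verbs=4)
        b = encode(3, 1, sem, n_verbs=4)
        assert np.count_nonzero(a != b) == 2

    def test_out_of_range_verb(self):
        with pytest.raises(IndexError):
            encode(4, 1, [0.0] * 4, n_verbs=4)


class TestForward:
    def test_matches_brute_force(self, rng):
        cfg = tiny_config()
        state = init_state(cfg, rng)
        x = encode(2, 1, rng.uniform(0, 1, 4), n_verbs=4)
        net = state.W.T @ x
        expected = np.exp(net) / np.exp(net).sum()
        np.testing.assert_allclose(forward(state, x), expected, rtol=1e-12)

    def test_sums_to_one_and_positive(self, rng):
        state = init_state(tiny_config(), rng)
        y = forward(state, encode(0, 0, [0.9] * 4, n_verbs=4))
        assert y.sum() == pytest.approx(1.0, abs=1e-12)
        assert (y > 0).all()

    def test_shift_invariance(self, rng):
        state = init_state(tiny_config(), rng)
        x = encode(1, 1, [0.5] * 4, n_verbs=4)
        shifted = LearnerState(W=state.W + 7.0 * 0, config=state.config)
        shifted.W = state.W.copy()
        shifted.W[-1] += 7.0  # constant added to every output's net input
        np.testing.assert_allclose(forward(state, x), forward(shifted, x),
                                   rtol=1e-9)


class TestUpdate:
    def test_matches_brute_force_formula(self, rng):
        cfg = tiny_config(learning_rate=0.05, weight_decay=0.3)
        state = init_state(cfg, rng)
        x = encode(3, 1, rng.uniform(0, 1, 4), n_verbs=4)
        W0 = state.W.copy()
        y = np.exp(W0.T @ x - (W0.T @ x).max())
        y = y / y.sum()
        t = np.array([0.0, 1.0, 0.0])
        expected = W0 + 0.05 * (np.outer(x, t - y) - cfg.lambda_step * W0)
        update(state, x, MORE)
        np.testing.assert_allclose(state.W, expected, rtol=1e-12)

    def test_zero_input_is_noop_without_decay(self):
        cfg = tiny_config(weight_decay=0.0)
        state = init_state(cfg)
        W0 = state.W.copy()
        update(state, np.zeros(cfg.n_inputs), LESS)
        np.testing.assert_array_equal(state.W, W0)

    def test_invalid_target_rejected(self):
        state = init_state(tiny_config())
        with pytest.raises(ValueError):
            update(state, np.zeros(state.config.n_inputs), 5)


class TestTraining:
    def test_zero_learning_rate_leaves_weights(self):
        cfg = tiny_config(learning_rate=0.0)
        sampler = CorpusSampler.from_counts(uniform_counts())
        snaps = train(cfg, sampler, semantics(), np.random.default_rng(2))
        np.testing.assert_array_equal(snaps[0], snaps[-1])

    def test_same_seed_identical_trajectories(self):
        cfg = tiny_config()
        sampler = CorpusSampler.from_counts(uniform_counts())
        S = semantics()
        a = train(cfg, sampler, S, np.random.default_rng(9))
        b = train(cfg, sampler, S, np.random.default_rng(9))
        for Wa, Wb in zip(a, b):
            np.testing.assert_array_equal(Wa, Wb)

    def test_conditional_frequency_fixed_point_two_verbs(self):
        """With no decay, per-verb judged activations approach the
        empirical P(form | verb, causative) of the corpus."""
        counts = pd.DataFrame({
            "verb": ["a", "b"],
            "n_less": [60, 10],
            "n_more": [40, 90],
            "n_other": [0, 0],
        })
        cfg = LearnerConfig(n_verbs=2, epochs=30, utterances_per_epoch=5000,
                            n_runs=1, learning_rate=0.01, weight_decay=0.0,
                            seed=4)
        S = np.array([[0.5] * 4, [0.5] * 4])
        snaps = train(cfg, CorpusSampler.from_counts(counts), S,
                      np.random.default_rng(4))
        acts = np.mean([judge_all(W, S) for W in snaps[-8:]], axis=0)
        np.testing.assert_allclose(acts[0, :2], [0.6, 0.4], atol=0.02)
        np.testing.assert_allclose(acts[1, :2], [0.1, 0.9], atol=0.02)

    def test_decay_shrinks_confidence(self):
        counts = uniform_counts(2)[:2]
        counts.loc[0, ["n_less", "n_more", "n_other"]] = [95, 5, 0]
        counts.loc[1, ["n_less", "n_more", "n_other"]] = [5, 95, 0]
        S = semantics(2)
        maxima = []
        for decay in (0.0, 2.0):
            cfg = LearnerConfig(n_verbs=2, epochs=10,
                                utterances_per_epoch=2000, n_runs=1,
                                learning_rate=0.05, weight_decay=decay, seed=8)
            snaps = train(cfg, CorpusSampler.from_counts(counts), S,
                          np.random.default_rng(8))
            maxima.append(judge_all(snaps[-1], S).max(axis=1).mean())
        assert maxima[1] <= maxima[0]


class TestJudging:
    def test_judge_is_pure_and_composes(self, rng):
        state = init_state(tiny_config(), rng)
        sem = rng.uniform(0, 1, 4)
        first = judge(state, 1, sem)
        second = judge(state, 1, sem)
        np.testing.assert_array_equal(first, second)
        np.testing.assert_allclose(
            first, forward(state, encode(1, 1, sem, n_verbs=4)), rtol=1e-12)

    def test_judge_all_matches_per_verb_judge(self, rng):
        state = init_state(tiny_config(), rng)
        S = semantics(4, rng)
        all_acts = judge_all(state.W, S)
        for v in range(4):
            np.testing.assert_allclose(all_acts[v], judge(state, v, S[v]),
                                       rtol=1e-12)


class TestEnsemble:
    def test_record_count_and_normalization(self):
        cfg = tiny_config()
        preds = run_ensemble(cfg, CorpusSampler.from_counts(uniform_counts()),
                             semantics())
        assert len(preds) == cfg.n_runs * (cfg.epochs + 1) * cfg.n_verbs
        sums = preds[["act_less", "act_more", "act_other"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_bit_reproducible(self):
        cfg = tiny_config()
        sampler = CorpusSampler.from_counts(uniform_counts())
        S = semantics()
        a = run_ensemble(cfg, sampler, S)
        b = run_ensemble(cfg, sampler, S)
        pd.testing.assert_frame_equal(a, b)

    def test_epoch_zero_mean_near_uniform(self):
        cfg = tiny_config(n_runs=40, init_range=0.05)
        preds = run_ensemble(cfg, CorpusSampler.from_counts(uniform_counts()),
                             semantics())
        epoch0 = preds[preds["epoch"] == 0]
        means = epoch0[["act_less", "act_more", "act_other"]].mean()
        np.testing.assert_allclose(means, 1 / 3, atol=0.01)


class TestSplitHalf:
    def test_exact_partition(self):
        cfg = tiny_config(n_verbs=6, n_runs=1)
        counts = uniform_counts(6)
        res = split_half(cfg, CorpusSampler.from_counts(counts), semantics(6),
                         np.random.default_rng(3))
        assert len(res.train_verbs) == 3 and len(res.heldout_verbs) == 3
        assert set(res.train_verbs) | set(res.heldout_verbs) == set(counts["verb"])
        assert not set(res.train_verbs) & set(res.heldout_verbs)
        assert set(res.predictions["verb"]) == set(res.heldout_verbs)

    def test_identical_semantics_identical_predictions_at_zero_init(self):
        """With zero initialization, held-out verbs sharing semantics are
        indistinguishable: their lexical weights never receive evidence."""
        cfg = tiny_config(n_verbs=6, n_runs=1, init_range=0.0, epochs=3)
        S = semantics(6)
        S[4] = S[5] = [0.2, 0.4, 0.6, 0.8]
        counts = uniform_counts(6)
        # force v4, v5 into the held-out half by depriving them of tokens
        rng = np.random.default_rng(0)
        for attempt in range(50):
            res = split_half(cfg, CorpusSampler.from_counts(counts), S, rng)
            if {"v4", "v5"} <= set(res.heldout_verbs):
                break
        else:
            pytest.fail("no split held out both twin verbs")
        final = res.predictions[res.predictions["epoch"] == cfg.epochs]
        a = final[final["verb"] == "v4"].iloc[0]
        b = final[final["verb"] == "v5"].iloc[0]
        for col in ("act_less", "act_more", "act_other"):
            assert a[col] == pytest.approx(b[col], rel=1e-12)

    def test_too_small_lexicon(self):
        cfg = tiny_config(n_verbs=1)
        with pytest.raises(ValueError):
            split_half(cfg, CorpusSampler.from_counts(uniform_counts(1)),
                       semantics(1), np.random.default_rng(0))


class TestSampler:
    def test_all_zero_counts_rejected(self):
        counts = uniform_counts(2)
        counts[["n_less", "n_more", "n_other"]] = 0
        with pytest.raises(ValueError):
            CorpusSampler.from_counts(counts)

    def test_restrict_renormalizes(self):
        sampler = CorpusSampler.from_counts(uniform_counts(4))
        sub = sampler.restrict([0, 1])
        verbs, _ = sub.sample(500, np.random.default_rng(0))
        assert set(verbs) <= {0, 1}
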