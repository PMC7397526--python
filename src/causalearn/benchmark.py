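"""Built-in evaluation scenarios run on synthetic data.

These are the package's standard end-to-end checks, each a self-contained
computation from a seed:

* :func:`benchmark_seed` — the default synthetic benchmark: generate a
  full study-scale dataset (60 verbs, 20 raters, 48 simulated judges),
  train the discriminative ensemble, and correlate ensemble-mean
  activations with the synthetic judgment means by verb, for the raw
  forms and for difference scores, on the full lexicon and in the
  split-half generalization test.  The ensemble is run at 8 runs x 20
  epochs, a scaled-down regimen that reaches the same late-training
  plateau as the full 48 x 50 regimen at a fraction of the cost.
* :func:`fixed_point_activations` — a single-verb corpus probing the
  delta rule's convergence to empirical conditional form frequencies.
* :func:`overgeneralization_trajectories` — the designed
  overgeneralization-then-retreat corpus (see
  :func:`causalearn.synthetic.overgeneralization_corpus`).
* :func:`predictor_recovery` — Pearson correlation between the
  corpus-derived signed chi-square preemption predictor and the
  generative allocation bias of the synthetic corpus.
"""

from __future__ import annotations

import numpy as np

from causalearn.corpus_stats import predictor_table
from causalearn.evaluation import activation_means, byverb_pearson, judgment_means
from causalearn.learner import (
    CorpusSampler,
    LearnerConfig,
    judge_all,
    run_ensemble,
    split_half,
    train,
)
from causalearn.semantics import build_profiles, unit_matrix
from causalearn.synthetic import (
    SyntheticSpec,
    allocation_bias,
    generate_dataset,
    overgeneralization_corpus,
)

__all__ = [
    "benchmark_seed",
    "fixed_point_activations",
    "overgeneralization_trajectories",
    "predictor_recovery",
]

BENCHMARK_RUNS = 8
BENCHMARK_EPOCHS = 20


def benchmark_seed(seed: int, n_runs: int = BENCHMARK_RUNS,
                   epochs: int = BENCHMARK_EPOCHS) -> dict:
    """Full-pipeline fit statistics for one seed of the default benchmark.

    Returns final-epoch by-verb correlations between ensemble-mean
    activations and synthetic judgment means: ``full_less_r``,
    ``full_more_r``, ``full_diff_r`` on all verbs, and ``split_diff_r``
    on the held-out half of the split-half test.
    """
    spec = SyntheticSpec(seed=seed)
    data = generate_dataset(spec)
    profiles = build_profiles(data.ratings)
    S = unit_matrix(profiles, data.counts["verb"])
    sampler = CorpusSampler.from_counts(data.counts)
    cfg = LearnerConfig(n_verbs=spec.n_verbs, epochs=epochs, n_runs=n_runs,
                        seed=seed)
    human = judgment_means(data.judgments)

    preds = run_ensemble(cfg, sampler, S)
    acts = activation_means(preds, epoch=epochs)
    out = {
        "full_less_r": byverb_pearson(acts["less"], human.loc[acts.index, "less"]),
        "full_more_r": byverb_pearson(acts["more"], human.loc[acts.index, "more"]),
        "full_diff_r": byverb_pearson(acts["diff"], human.loc[acts.index, "diff"]),
    }

    sh = split_half(cfg, sampler, S, np.random.default_rng(seed))
    held = activation_means(sh.predictions, epoch=epochs)
    out["split_diff_r"] = byverb_pearson(
        held["diff"], human.loc[held.index, "diff"])
    out["n_verbs"] = spec.n_verbs
    return out


def fixed_point_activations(seed: int, n_less: int = 80, n_more: int = 20,
                            n_other: int = 100, n_runs: int = 5,
                            epochs: int = 40,
                            utterances_per_epoch: int = 10_000) -> np.ndarray:
    """Judged (LESS, MORE) activations, renormalized over the causative pair.

    A single-verb corpus with a fixed causative split is trained with no
    weight decay and a small learning rate; because constant-step SGD
    fluctuates around the conditional-frequency fixed point, the judged
    activations are averaged over runs and over the last quarter of the
    epoch snapshots, whose stationary mean is the empirical
    P(form | verb, causative).
    """
    import pandas as pd

    counts = pd.DataFrame({"verb": ["v"], "n_less": [n_less],
                           "n_more": [n_more], "n_other": [n_other]})
    S = np.full((1, 4), 0.5)
    sampler = CorpusSampler.from_counts(counts)
    pairs = []
    for r in range(n_runs):
        cfg = LearnerConfig(n_verbs=1, epochs=epochs,
                            utterances_per_epoch=utterances_per_epoch,
                            n_runs=1, learning_rate=0.01, weight_decay=0.0,
                            seed=seed + r)
        snaps = train(cfg, sampler, S, np.random.default_rng(seed + r))
        for W in snaps[-(epochs // 4):]:
            acts = judge_all(W, S)[0]
            pairs.append(acts[:2] / acts[:2].sum())
    return np.mean(pairs, axis=0)


def overgeneralization_trajectories(n_seeds: int = 20, base_seed: int = 0,
                                    epochs: int = 15, n_runs: int = 4) -> list:
    """Per-seed LESS-activation trajectories of the designed target verb.

    Returns a list of (epochs+1)-long arrays, one per seed: the ensemble
    mean act_less of the low-frequency verb whose semantics match the
    less-transparent cluster but whose causative tokens are all
    more-transparent.
    """
    trajectories = []
    for i in range(n_seeds):
        seed = base_seed + i
        counts, latents, target = overgeneralization_corpus(seed=seed)
        cfg = LearnerConfig(n_verbs=len(counts), epochs=epochs,
                            utterances_per_epoch=5_000, n_runs=n_runs,
                            seed=seed)
        preds = run_ensemble(cfg, CorpusSampler.from_counts(counts),
                             latents.to_numpy())
        traj = (preds[preds["verb"] == target]
                .groupby("epoch")["act_less"].mean().to_numpy())
        trajectories.append(traj)
    return trajectories


def retreat_fraction(trajectories) -> float:
    """Fraction of trajectories whose peak within the first third of
    training exceeds the final-epoch value (overgeneralization followed
    by retreat)."""
    hits = 0
    for traj in trajectories:
        third = max(1, (len(traj) - 1) // 3)
        hits += traj[1:third + 1].max() > traj[-1]
    return hits / len(trajectories)


def predictor_recovery(seed: int) -> dict:
    """Correlations between corpus-derived predictors and generator truth.

    ``preemption_vs_bias_r``: Pearson r across verbs between the signed
    chi-square preemption-for-LESS predictor and the generative
    allocation bias b(v) of the default synthetic corpus.
    ``judgment_sign_r``: Pearson r between generated judgment difference
    scores and the event-merge latent — negative by construction, since
    high event merge raises less-transparent acceptability and the
    difference score is the MORE-minus-LESS preference.
    """
    spec = SyntheticSpec(seed=seed)
    data = generate_dataset(spec)
    predictors = predictor_table(data.counts)
    b = allocation_bias(data.counts)
    r_bias = byverb_pearson(predictors["preemption_less"].to_numpy(),
                            b.to_numpy())
    human = judgment_means(data.judgments)
    m = data.latents["event_merge"]
    r_sign = byverb_pearson(human.loc[m.index, "diff"], m)
    return {"preemption_vs_bias_r": r_bias, "judgment_sign_r": r_sign}
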