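"""Single-layer discriminative model of causative form choice.

The model maps an utterance encoding — a one-hot lexical block over the
verb lexicon, a binary causative unit (1 when the utterance uses either
causative structure), four continuous semantic activations in [0, 1] and a
constant bias — to a softmax over three output forms: the less-transparent
causative, the more-transparent causative, and "other" (non-causative).
There is no hidden layer.

Learning is online and error-driven: each corpus-sampled utterance drives
one delta-rule (Widrow-Hoff) step

    W_ij  <-  W_ij + eta * ((t_j - y_j) * x_i  -  lambda_step * W_ij)

where ``t`` is the one-hot attested form, ``y`` the softmax prediction and
``lambda_step`` a small per-update weight decay.  With softmax outputs
this is stochastic gradient descent on the cross-entropy, so with no decay
the per-verb output activations converge to the empirical conditional
form frequencies P(form | verb context).

Acceptability judgments are read off by a forward pass with learning
switched off and the causative unit clamped to 1: the activations of the
less- and more-transparent output units are the model's graded judgments
of the two causative structures for that verb.

An ensemble of independently initialized and independently sampling runs
(one per simulated participant) is trained for a fixed number of epochs,
with judgments extracted for every verb after every epoch.  A split-half
variant trains on a random half of the lexicon and extracts judgments for
the held-out half, probing generalization carried purely by the causative,
semantic and bias weights (held-out lexical weights never move off their
random initialization, apart from decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "LESS",
    "MORE",
    "OTHER",
    "FORMS",
    "LearnerConfig",
    "LearnerState",
    "CorpusSampler",
    "TrainingDivergedError",
    "init_state",
    "encode",
    "forward",
    "update",
    "train",
    "judge",
    "judge_all",
    "run_ensemble",
    "split_half",
    "SplitHalfResult",
]

# output-form codes; OTHER covers every non-causative use
LESS, MORE, OTHER = 0, 1, 2
FORMS = ("less", "more", "other")


class TrainingDivergedError(RuntimeError):
    """Weights became non-finite during training."""


@dataclass(frozen=True)
class LearnerConfig:
    """Architecture and training regimen of the discriminative model.

    ``weight_decay`` is the per-epoch decay budget: each update applies
    ``lambda_step = weight_decay / utterances_per_epoch`` so that one
    epoch exerts an O(weight_decay) regularizing pull regardless of epoch
    length.  ``init_range`` is the half-width of the uniform weight
    initialization.
    """

    n_verbs: int = 60
    n_semantic: int = 4
    n_outputs: int = 3
    epochs: int = 50
    utterances_per_epoch: int = 10_000
    n_runs: int = 48
    learning_rate: float = 0.01
    weight_decay: float = 0.5
    init_range: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_verbs", "n_semantic", "n_outputs", "epochs",
                     "utterances_per_epoch", "n_runs"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.init_range < 0:
            raise ValueError("init_range must be >= 0")

    @property
    def n_inputs(self) -> int:
        # lexical block + causative unit + semantic units + bias
        return self.n_verbs + 1 + self.n_semantic + 1

    @property
    def lambda_step(self) -> float:
        return self.weight_decay / self.utterances_per_epoch


@dataclass
class LearnerState:
    """Weights plus the configuration and RNG that produced them."""

    W: np.ndarray  # (n_inputs, n_outputs)
    config: LearnerConfig
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def check_finite(self, context: str = "") -> None:
        if not np.all(np.isfinite(self.W)):
            raise TrainingDivergedError(f"non-finite weights {context}".strip())


def init_state(config: LearnerConfig, rng: np.random.Generator | None = None) -> LearnerState:
    """Fresh state with weights i.i.d. uniform on [-init_range, +init_range]."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W = rng.uniform(-config.init_range, config.init_range,
                    size=(config.n_inputs, config.n_outputs))
    return LearnerState(W=W, config=config, rng=rng)


def encode(verb_id: int, causative: int, sem: Sequence[float],
           n_verbs: int) -> np.ndarray:
    """Input vector: one-hot lexical block, causative bit, semantics, bias."""
    verb_id = int(verb_id)
    if not 0 <= verb_id < n_verbs:
        raise IndexError(f"verb_id {verb_id} out of range [0, {n_verbs})")
    sem = np.asarray(sem, dtype=float)
    x = np.zeros(n_verbs + 1 + sem.size + 1)
    x[verb_id] = 1.0
    x[n_verbs] = float(causative)
    x[n_verbs + 1:n_verbs + 1 + sem.size] = sem
    x[-1] = 1.0  # bias
    return x


def _softmax(net: np.ndarray) -> np.ndarray:
    z = np.exp(net - net.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def forward(state: LearnerState, x: np.ndarray) -> np.ndarray:
    """Softmax output activations for one encoded input."""
    state.check_finite("in forward pass")
    return _softmax(state.W.T @ x)


def update(state: LearnerState, x: np.ndarray, target_form: int) -> LearnerState:
    """One in-place delta-rule step toward the attested form.

    Decay and error terms are both evaluated on the pre-update weights:
    W' = W + eta * ((t - y) outer x - lambda_step * W), with y = forward(W, x).
    """
    if target_form not in (LESS, MORE, OTHER):
        raise ValueError(f"invalid target form {target_form!r}")
    cfg = state.config
    y = forward(state, x)
    t = np.zeros(cfg.n_outputs)
    t[target_form] = 1.0
    state.W += cfg.learning_rate * (np.outer(x, t - y) - cfg.lambda_step * state.W)
    state.check_finite("after update")
    return state


@njit(cache=True)
def _train_epoch(W, verbs, forms, S, eta, lam_step):  # pragma: no cover - jitted
    n_in, n_out = W.shape
    n_sem = S.shape[1]
    n_verbs = n_in - n_sem - 2
    net = np.empty(n_out)
    y = np.empty(n_out)
    for i in range(verbs.shape[0]):
        v = verbs[i]
        f = forms[i]
        caus = 0.0 if f == 2 else 1.0
        for j in range(n_out):
            z = W[v, j] + caus * W[n_verbs, j] + W[n_in - 1, j]
            for k in range(n_sem):
                z += S[v, k] * W[n_verbs + 1 + k, j]
            net[j] = z
        m = net[0]
        for j in range(1, n_out):
            if net[j] > m:
                m = net[j]
        tot = 0.0
        for j in range(n_out):
            y[j] = np.exp(net[j] - m)
            tot += y[j]
        for j in range(n_out):
            y[j] /= tot
        # simultaneous decay + error step: both use the pre-update weights
        if lam_step > 0.0:
            shrink = 1.0 - eta * lam_step
            for a in range(n_in):
                for j in range(n_out):
                    W[a, j] *= shrink
        for j in range(n_out):
            d = eta * ((1.0 if j == f else 0.0) - y[j])
            W[v, j] += d
            if caus == 1.0:
                W[n_verbs, j] += d
            W[n_in - 1, j] += d
            for k in range(n_sem):
                W[n_verbs + 1 + k, j] += S[v, k] * d


class CorpusSampler:
    """With-replacement utterance sampler over a construction-count table.

    Tokens are (verb index, form) pairs drawn with probability proportional
    to the cell counts, mirroring random sampling from a finite corpus with
    replacement.  ``restrict`` returns a sampler over a verb subset (for
    split-half training) with probabilities renormalized.
    """

    def __init__(self, cell_counts: np.ndarray, verbs: Sequence[str]):
        counts = np.asarray(cell_counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 3:
            raise ValueError("cell_counts must have shape (n_verbs, 3)")
        if (counts < 0).any():
            raise ValueError("negative counts")
        total = counts.sum()
        if total == 0:
            raise ValueError("all-zero counts: nothing to sample")
        self.counts = counts
        self.verbs = list(verbs)
        self._flat_p = (counts / total).ravel()

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CorpusSampler":
        cells = counts[["n_less", "n_more", "n_other"]].to_numpy(dtype=float)
        return cls(cells, counts["verb"].tolist())

    @property
    def n_verbs(self) -> int:
        return self.counts.shape[0]

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n tokens; returns (verb_idx, form) int arrays."""
        flat = rng.choice(self._flat_p.size, size=n, p=self._flat_p)
        return (flat // 3).astype(np.int64), (flat % 3).astype(np.int64)

    def restrict(self, verb_indices: Iterable[int]) -> "CorpusSampler":
        keep = np.zeros(self.n_verbs, dtype=bool)
        keep[list(verb_indices)] = True
        masked = self.counts * keep[:, None]
        return CorpusSampler(masked, self.verbs)


def train(config: LearnerConfig, sampler: CorpusSampler, S: np.ndarray,
          rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Train one model; returns weight snapshots for epochs 0..epochs.

    Snapshot 0 is the random initialization; snapshot e the weights after
    epoch e.  Fully reproducible: the supplied generator (or one seeded
    from ``config.seed``) drives initialization and corpus sampling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    S = np.ascontiguousarray(S, dtype=float)
    if S.shape != (config.n_verbs, config.n_semantic):
        raise ValueError(f"semantic matrix shape {S.shape} != "
                         f"({config.n_verbs}, {config.n_semantic})")
    state = init_state(config, rng)
    snapshots = [state.W.copy()]
    for _epoch in range(config.epochs):
        verbs, forms = sampler.sample(config.utterances_per_epoch, rng)
        _train_epoch(state.W, verbs, forms, S,
                     config.learning_rate, config.lambda_step)
        state.check_finite(f"after epoch {_epoch + 1}")
        snapshots.append(state.W.copy())
    return snapshots


def judge(state: LearnerState, verb_id: int, sem: Sequence[float]) -> np.ndarray:
    """Graded judgment: forward pass with causative clamped to 1, no learning."""
    x = encode(verb_id, 1, sem, state.config.n_verbs)
    return forward(state, x)


def judge_all(W: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Judgments for every verb at once; rows sum to 1.

    Vectorized equivalent of :func:`judge` over the whole lexicon: net
    input is lexical weight + causative weight + semantic mix + bias.
    """
    n_verbs = W.shape[0] - S.shape[1] - 2
    net = W[:n_verbs] + W[n_verbs][None, :] + S @ W[n_verbs + 1:-1] + W[-1][None, :]
    return _softmax(net)


def _predictions_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame(records, columns=["run", "epoch", "verb",
                                          "act_less", "act_more", "act_other"])


def run_ensemble(config: LearnerConfig, sampler: CorpusSampler, S: np.ndarray,
                 verb_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Train n_runs independent models and collect per-epoch judgments.

    Run r seeds its generator with ``config.seed + r``.  Judgments are
    recorded for every verb (or ``verb_subset``) after every epoch, plus
    at epoch 0 before any training.  Returns a long frame with columns
    run, epoch, verb, act_less, act_more, act_other.
    """
    S = np.ascontiguousarray(S, dtype=float)
    judged = (np.arange(config.n_verbs) if verb_subset is None
              else np.asarray(verb_subset, dtype=int))
    records = []
    for r in range(config.n_runs):
        rng = np.random.default_rng(config.seed + r)
        snapshots = train(config, sampler, S, rng)
        for epoch, W in enumerate(snapshots):
            acts = judge_all(W, S)
            for v in judged:
                records.append((r, epoch, sampler.verbs[v], *acts[v]))
    return _predictions_frame(records)


@dataclass(frozen=True)
class SplitHalfResult:
    train_verbs: tuple[str, ...]
    heldout_verbs: tuple[str, ...]
    predictions: pd.DataFrame  # judgments for held-out verbs only


def split_half(config: LearnerConfig, sampler: CorpusSampler, S: np.ndarray,
               rng: np.random.Generator | None = None) -> SplitHalfResult:
    """Train on a random half of the lexicon, judge the held-out half.

    One random 2-block partition is drawn (floor split for odd lexica) and
    shared by every run in the ensemble; the sampler is restricted to the
    training half, so held-out verbs are judged with lexical weights still
    at initialization — their predictions are carried by the causative,
    semantic and bias weights alone.
    """
    if config.n_verbs < 2:
        raise ValueError("lexicon too small to split in half")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    perm = rng.permutation(config.n_verbs)
    half = config.n_verbs // 2
    train_idx = np.sort(perm[:half])
    held_idx = np.sort(perm[half:])
    restricted = sampler.restrict(train_idx)
    preds = run_ensemble(config, restricted, S, verb_subset=held_idx)
    return SplitHalfResult(
        train_verbs=tuple(sampler.verbs[i] for i in train_idx),
        heldout_verbs=tuple(sampler.verbs[i] for i in held_idx),
        predictions=preds,
    )
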