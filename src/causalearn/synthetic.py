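"""Synthetic corpora, rating tables and judgment tables.

The generator emulates the statistical structure of the three inputs the
pipeline consumes, so every stage is testable end to end with no external
data and parameter recovery can be verified against known ground truth:

* a per-verb *latent semantics* ``m_v`` (the event-merge dimension) drawn
  uniform on (0, 1), with three subsidiary scales made collinear with it
  by adding clipped Gaussian noise — mirroring the high collinearity of
  rated autonomy/directive/requires dimensions with event merge;
* a *corpus* whose per-verb totals follow a Zipfian rank-frequency law, a
  fixed share of tokens being causative, and causative tokens allocated
  between the less- and more-transparent structures by a logistic link on
  ``m_v`` (high event-merge verbs prefer the less-transparent form);
* *rater tables*: n_raters noisy analogue-scale readings of each latent
  per verb per scale, on a 0-100 scale;
* *judgment tables*: per-participant 1-5 acceptability ratings driven by
  a latent acceptability combining a semantic term (event merge raises
  less-transparent and lowers more-transparent acceptability) and a
  frequency term (the verb's corpus log-odds of the rated structure
  relative to the lexicon-wide base rate), plus participant noise,
  discretized into five equal-width bins.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from causalearn.learner import LESS, MORE, OTHER, CorpusSampler
from causalearn.semantics import SCALES

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "UtteranceToken",
    "gen_latent_semantics",
    "gen_ratings",
    "gen_counts",
    "gen_stream",
    "gen_judgments",
    "allocation_bias",
    "generate_dataset",
    "overgeneralization_corpus",
]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic study.

    Defaults mirror the study scale: 60 verbs, 20 semantic raters, 48
    judgment participants per age group.  ``zipf_exponent`` shapes the
    verb rank-frequency curve; ``causative_share`` is the probability
    that a token of any verb is causative; ``allocation_intercept`` and
    ``allocation_slope`` parameterize the logistic allocation of
    causative tokens to the less-transparent structure as a function of
    the event-merge latent.  ``judgment_semantic_weight`` and
    ``judgment_frequency_weight`` set the strength of the semantic and
    distributional signals in the simulated judgments.
    """

    n_verbs: int = 60
    n_raters: int = 20
    n_participants: int = 48
    corpus_tokens: int = 1_000_000
    zipf_exponent: float = 1.0
    causative_share: float = 0.1
    allocation_intercept: float = 0.0
    allocation_slope: float = 6.0
    latent_noise_sd: float = 0.1
    rater_noise_sd: float = 0.1
    judgment_semantic_weight: float = 2.0
    judgment_frequency_weight: float = 1.0
    judgment_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.causative_share < 1:
            raise ValueError("causative_share must be in (0, 1)")
        if self.corpus_tokens <= 0:
            raise ValueError("corpus_tokens must be positive")
        for name in ("latent_noise_sd", "rater_noise_sd", "judgment_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def verbs(self) -> list[str]:
        return [f"verb{i:02d}" for i in range(self.n_verbs)]

    def to_dict(self) -> dict:
        return asdict(self)


class UtteranceToken(NamedTuple):
    """One corpus utterance: a verb in one of the three forms."""

    verb_id: int
    form: int  # LESS / MORE / OTHER

    @property
    def causative(self) -> int:
        return int(self.form != OTHER)


def gen_latent_semantics(spec: SyntheticSpec,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Latent per-verb semantics: event merge plus collinear subsidiaries.

    ``event_merge`` is i.i.d. uniform on (0, 1); the three subsidiary
    scales add Gaussian noise (sd ``latent_noise_sd``) and clip to [0, 1],
    which induces high pairwise correlation among all four.
    """
    m = rng.uniform(0.0, 1.0, size=spec.n_verbs)
    data = {"event_merge": m}
    for scale in SCALES[1:]:
        noisy = m + rng.normal(0.0, spec.latent_noise_sd, size=spec.n_verbs)
        data[scale] = np.clip(noisy, 0.0, 1.0)
    return pd.DataFrame(data, index=pd.Index(spec.verbs, name="verb"))


def gen_ratings(spec: SyntheticSpec, latents: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Rater table: noisy 0-100 analogue readings of each latent.

    Each of ``n_raters`` raters reads every (verb, scale) latent with
    additive Gaussian noise before clipping to the scale, i.e.
    rating = 100 * clip(latent + N(0, rater_noise_sd), 0, 1).
    """
    rows = []
    for scale in SCALES:
        base = latents[scale].to_numpy()
        for r in range(spec.n_raters):
            noise = rng.normal(0.0, spec.rater_noise_sd, size=len(base))
            values = 100.0 * np.clip(base + noise, 0.0, 1.0)
            for verb, v in zip(latents.index, values):
                rows.append({"rater": f"rater{r:02d}", "verb": verb,
                             "scale": scale, "value": v})
    return pd.DataFrame(rows)


def _zipf_totals(spec: SyntheticSpec) -> np.ndarray:
    ranks = np.arange(1, spec.n_verbs + 1, dtype=float)
    weights = ranks ** (-spec.zipf_exponent)
    totals = np.floor(spec.corpus_tokens * weights / weights.sum()).astype(int)
    return np.maximum(totals, 1)


def gen_counts(spec: SyntheticSpec, latents: pd.DataFrame,
               rng: np.random.Generator) -> pd.DataFrame:
    """Construction-count table with Zipfian totals and a semantic split.

    Verb i (rank i+1) receives a total ~ rank^-s share of the corpus; a
    Binomial(total, causative_share) draw decides how many tokens are
    causative; causative tokens land on the less-transparent structure
    with probability sigmoid(intercept + slope * event_merge), the rest on
    the more-transparent one; non-causative tokens make up ``n_other``.
    """
    totals = _zipf_totals(spec)
    m = latents["event_merge"].to_numpy()
    p_less = _sigmoid(spec.allocation_intercept + spec.allocation_slope * m)
    causative = rng.binomial(totals, spec.causative_share)
    n_less = rng.binomial(causative, p_less)
    return pd.DataFrame({
        "verb": spec.verbs,
        "n_less": n_less,
        "n_more": causative - n_less,
        "n_other": totals - causative,
    })


def gen_stream(counts: pd.DataFrame,
               rng: np.random.Generator) -> Iterator[UtteranceToken]:
    """Infinite with-replacement utterance stream over a counts table.

    Tokens are drawn with probability proportional to the cell counts;
    this is the corpus view the learner trains on.
    """
    sampler = CorpusSampler.from_counts(counts)
    while True:
        verbs, forms = sampler.sample(1024, rng)
        for v, f in zip(verbs, forms):
            yield UtteranceToken(int(v), int(f))


def allocation_bias(counts: pd.DataFrame) -> pd.Series:
    """Signed log-odds of LESS vs MORE relative to the lexicon base rate.

    b(v) = log odds(less : more | v) - log odds(less : more | other verbs),
    with 0.5 added to every cell so zero counts stay finite.  Positive
    values mean the verb leans toward the less-transparent structure more
    than the rest of the lexicon does.
    """
    nl = counts["n_less"].to_numpy(dtype=float)
    nm = counts["n_more"].to_numpy(dtype=float)
    rest_l = nl.sum() - nl
    rest_m = nm.sum() - nm
    b = (np.log((nl + 0.5) / (nm + 0.5))
         - np.log((rest_l + 0.5) / (rest_m + 0.5)))
    return pd.Series(b, index=pd.Index(counts["verb"], name="verb"), name="b")


def gen_judgments(spec: SyntheticSpec, latents: pd.DataFrame,
                  counts: pd.DataFrame, rng: np.random.Generator,
                  age_group: str = "adult") -> pd.DataFrame:
    """Participant x verb x sentence-type table of 1-5 ratings.

    The latent acceptability of the less-transparent form for verb v is

        a_less(v) = g_sem * (m_v - 1/2) + g_freq * b(v) + noise

    with m_v the event-merge latent and b(v) the corpus allocation bias;
    for the more-transparent form both systematic terms flip sign (the
    log-odds of MORE vs LESS is -b(v)).  Latents are discretized into the
    five rating categories by equal-width bins spanning the generative
    range of the latent; a fully flat generator (both weights and noise
    zero) therefore lands every rating on the midpoint category 3.
    """
    m = latents["event_merge"].to_numpy()
    b = allocation_bias(counts).to_numpy()
    sem = spec.judgment_semantic_weight * (m - 0.5)
    freq = spec.judgment_frequency_weight * b
    # generative half-range of the latent (systematic extremes + 2 sd noise)
    half_range = (spec.judgment_semantic_weight * 0.5
                  + spec.judgment_frequency_weight * np.abs(b).max()
                  + 2.0 * spec.judgment_noise_sd)
    rows = []
    for p in range(spec.n_participants):
        pid = f"{age_group}-p{p:02d}"
        for sign, stype in ((1.0, "less"), (-1.0, "more")):
            latent = sign * (sem + freq) + rng.normal(
                0.0, spec.judgment_noise_sd, size=spec.n_verbs)
            if half_range == 0:
                rating = np.full(spec.n_verbs, 3, dtype=int)
            else:
                bins = np.floor((latent + half_range) / (2 * half_range / 5))
                rating = np.clip(bins, 0, 4).astype(int) + 1
            for verb, r in zip(latents.index, rating):
                rows.append({"participant": pid, "age_group": age_group,
                             "verb": verb, "sentence_type": stype,
                             "rating": int(r)})
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    """All generated tables plus the ground truth that produced them."""

    spec: SyntheticSpec
    latents: pd.DataFrame
    counts: pd.DataFrame
    ratings: pd.DataFrame
    judgments: pd.DataFrame


def generate_dataset(spec: SyntheticSpec,
                     age_groups: tuple[str, ...] = ("adult",)) -> SyntheticDataset:
    """Generate latents, corpus counts, ratings and judgments in one call.

    A single generator seeded from ``spec.seed`` drives every stage, so
    the whole dataset is reproducible from the spec alone.
    """
    rng = np.random.default_rng(spec.seed)
    latents = gen_latent_semantics(spec, rng)
    counts = gen_counts(spec, latents, rng)
    ratings = gen_ratings(spec, latents, rng)
    judgments = pd.concat(
        [gen_judgments(spec, latents, counts, rng, age_group=g)
         for g in age_groups],
        ignore_index=True,
    )
    return SyntheticDataset(spec=spec, latents=latents, counts=counts,
                            ratings=ratings, judgments=judgments)


def overgeneralization_corpus(n_verbs: int = 20,
                              corpus_tokens: int = 100_000,
                              target_total: int = 2_000,
                              causative_share: float = 0.3,
                              seed: int = 0):
    """A corpus designed to elicit overgeneralization-then-retreat.

    The lexicon splits into a high-event-merge cluster (causatives mostly
    less-transparent) and a low-event-merge cluster (mostly
    more-transparent).  One low-frequency *target* verb carries the
    semantics of the less-transparent cluster, but its few causative
    tokens are all more-transparent — like English *laugh*, whose meaning
    resembles verbs that causativize transitively but which is only
    attested periphrastically.  Early in learning the semantic weights,
    driven by the frequent cluster verbs, pull the target's
    less-transparent activation up; its own lexical evidence later pushes
    it back down.

    Returns ``(counts, latents, target_verb)``; the latents frame is
    directly usable as unit-interval semantic activations.
    """
    if n_verbs < 4:
        raise ValueError("need at least 4 verbs")
    rng = np.random.default_rng(seed)
    verbs = [f"verb{i:02d}" for i in range(n_verbs)]
    target = verbs[-1]
    # cluster semantics: half high event merge, half low; target joins high
    m = np.where(np.arange(n_verbs) % 2 == 0, 0.9, 0.1)
    m[-1] = 0.9
    m = np.clip(m + rng.normal(0, 0.03, size=n_verbs), 0.0, 1.0)
    latents = pd.DataFrame(
        {s: np.clip(m + (0 if s == "event_merge" else rng.normal(0, 0.05, n_verbs)),
                    0, 1) for s in SCALES},
        index=pd.Index(verbs, name="verb"))
    ranks = np.arange(1, n_verbs, dtype=float)  # target excluded from Zipf mass
    weights = ranks**-1.0
    totals = np.maximum(
        np.floor((corpus_tokens - target_total) * weights / weights.sum()), 1
    ).astype(int)
    causative = np.maximum((totals * causative_share).astype(int), 1)
    p_less = _sigmoid(12.0 * (m[:-1] - 0.5))
    n_less = (causative * p_less).round().astype(int)
    counts = pd.DataFrame({
        "verb": verbs[:-1],
        "n_less": n_less,
        "n_more": causative - n_less,
        "n_other": totals - causative,
    })
    target_caus = max(int(target_total * causative_share), 1)
    target_row = pd.DataFrame({
        "verb": [target], "n_less": [0], "n_more": [target_caus],
        "n_other": [target_total - target_caus],
    })
    counts = pd.concat([counts, target_row], ignore_index=True)
    return counts, latents, target
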