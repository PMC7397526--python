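"""Scoring model output against graded grammaticality judgments.

Human judgments are 1-5 ratings of one verb in one sentence type (the
less- or more-transparent causative); the model's judgments are softmax
activations extracted per verb per epoch.  Both are aggregated to by-verb
means and compared with Pearson correlations across verbs — separately
for the raw less-transparent and more-transparent forms and for
*difference scores*, the by-verb preference for the more- over the
less-transparent structure (MORE mean minus LESS mean).  Difference
scores are the fairest test of a model that makes relative rather than
absolute predictions: any per-verb shift common to both forms cancels.

Significance thresholds use the exact relation between the Pearson r and
Student's t: r* = t* / sqrt(t*^2 + df) with df = n_verbs - 2.

Cross-language analysis correlates each language's event-merge rating
means with each language's adult difference scores in a full matrix,
probing whether event-merge semantics is a constraint shared across
languages rather than a language-particular convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from causalearn.corpus_stats import DegenerateInputError

__all__ = [
    "difference_scores",
    "judgment_means",
    "activation_means",
    "byverb_pearson",
    "critical_r",
    "crosslanguage_matrix",
    "model_fit_curve",
]

AGE_GROUPS = ("5-6", "9-10", "adult")
SENTENCE_TYPES = ("less", "more")


def difference_scores(less: pd.Series, more: pd.Series) -> pd.Series:
    """Per-verb preference for the more- over the less-transparent form.

    ``diff(v) = more(v) - less(v)``; the two inputs are per-verb means
    (of human ratings or model activations) indexed by verb, and every
    verb must be present in both.
    """
    less, more = pd.Series(less), pd.Series(more)
    missing = less.index.symmetric_difference(more.index)
    if len(missing):
        raise ValueError(f"verbs missing one form: {list(missing)[:5]}")
    return (more - less.reindex(more.index)).rename("diff")


def judgment_means(judgments: pd.DataFrame,
                   age_group: str | None = None) -> pd.DataFrame:
    """Mean rating per verb per sentence type, optionally for one age group.

    Expects the long judgment table (participant, age_group, verb,
    sentence_type, rating); returns a frame indexed by verb with columns
    ``less``, ``more`` and ``diff``.
    """
    df = judgments
    if age_group is not None:
        df = df[df["age_group"] == age_group]
        if df.empty:
            raise ValueError(f"no judgments for age group {age_group!r}")
    means = df.pivot_table(index="verb", columns="sentence_type",
                           values="rating", aggfunc="mean")
    for st in SENTENCE_TYPES:
        if st not in means.columns or means[st].isna().any():
            raise ValueError(f"missing {st!r} ratings for some verb")
    means = means[list(SENTENCE_TYPES)]
    means["diff"] = difference_scores(means["less"], means["more"])
    return means


def activation_means(predictions: pd.DataFrame,
                     epoch: int | None = None) -> pd.DataFrame:
    """Ensemble-mean activations per verb (and epoch).

    Averages over runs first, matching the treatment of human
    participants.  With ``epoch`` given, returns one row per verb with
    columns ``less``, ``more``, ``other``, ``diff``; otherwise the frame
    is indexed by (epoch, verb).
    """
    df = predictions
    if epoch is not None:
        df = df[df["epoch"] == epoch]
        if df.empty:
            raise ValueError(f"no predictions at epoch {epoch}")
        group = ["verb"]
    else:
        group = ["epoch", "verb"]
    means = df.groupby(group)[["act_less", "act_more", "act_other"]].mean()
    means.columns = ["less", "more", "other"]
    means["diff"] = means["more"] - means["less"]
    return means


def byverb_pearson(x, y) -> float:
    """Sample Pearson correlation across verbs.

    Requires at least 3 items and non-constant inputs; a constant vector
    raises :class:`DegenerateInputError` rather than returning a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 verbs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def critical_r(df: int, alpha: float, tails: str = "one") -> float:
    """Smallest |r| significant at level alpha with df = n - 2.

    Inverts the t test of a correlation coefficient:
    r* = t* / sqrt(t*^2 + df), t* the upper alpha (or alpha/2 for
    two-tailed) quantile of Student's t on df degrees of freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    a = alpha / 2 if tails == "two" else alpha
    t_star = stats.t.ppf(1 - a, df)
    return float(t_star / np.sqrt(t_star**2 + df))


def crosslanguage_matrix(em_means: pd.DataFrame, diff_scores: pd.DataFrame,
                         alpha: float = 0.05, tails: str = "one"):
    """Correlate each language's event-merge means with each language's
    adult difference scores.

    Both inputs are verb x language frames sharing a verb index.  Returns
    ``(r, significant)``: an (n rating languages x n judgment languages)
    frame of Pearson r values and a boolean frame flagging cells that
    exceed ``critical_r(n_verbs - 2, alpha, tails)``.
    """
    if not em_means.index.equals(diff_scores.index):
        common = em_means.index.intersection(diff_scores.index)
        if len(common) < 3 or len(common) < len(em_means.index):
            raise ValueError("verb lexica of the two inputs do not match")
    n = len(em_means.index)
    r = pd.DataFrame(index=em_means.columns, columns=diff_scores.columns,
                     dtype=float)
    for rating_lang in em_means.columns:
        for judge_lang in diff_scores.columns:
            r.loc[rating_lang, judge_lang] = byverb_pearson(
                em_means[rating_lang], diff_scores[judge_lang])
    threshold = critical_r(n - 2, alpha, tails)
    return r, r > threshold


def model_fit_curve(predictions: pd.DataFrame,
                    judgments: pd.DataFrame,
                    age_group: str | None = None) -> pd.DataFrame:
    """By-verb model-human correlation per epoch, per form.

    Predictions are averaged over runs first; judgments over participants.
    For each epoch the frame gains three rows: r between model LESS
    activations and LESS rating means, MORE vs MORE, and difference score
    vs difference score.  Epochs where the model output is constant across
    verbs (e.g. a zero-weight initialization) are flagged ``degenerate``
    with r = NaN rather than silently scored 0.

    Returns columns epoch, form, r, n_verbs, degenerate.
    """
    human = judgment_means(judgments, age_group=age_group)
    acts = activation_means(predictions)
    rows = []
    for epoch, acts_e in acts.groupby(level="epoch"):
        acts_e = acts_e.droplevel("epoch")
        common = acts_e.index.intersection(human.index)
        if len(common) < len(acts_e.index):
            raise ValueError("prediction and judgment lexica do not match")
        for form in ("less", "more", "diff"):
            x = acts_e.loc[common, form]
            y = human.loc[common, form]
            try:
                r = byverb_pearson(x, y)
                degenerate = False
            except DegenerateInputError:
                r, degenerate = np.nan, True
            rows.append({"epoch": epoch, "form": form, "r": r,
                         "n_verbs": len(common), "degenerate": degenerate})
    return pd.DataFrame(rows)
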