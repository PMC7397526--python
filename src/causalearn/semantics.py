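"""Per-verb semantic profiles from multi-rater analogue-scale judgments.

Raters judge each verb on four continuous scales tapping the semantics of
caused events: *event_merge* (do the causing and caused events fuse into a
single spatio-temporally unified event?), *autonomy* (how autonomous is
the causee?), *directive* (is the causation directive/verbal rather than
physical?) and *requires* (does the event require an external causer?).
High values on these scales predict a preference for the less-transparent
causative structure.

Ratings are stored on a 0-100 analogue scale.  Per-verb means feed two
downstream forms: Z scores (regression predictors) and min-max scaled
values on [0, 1] (input activations for the discriminative learner).  Both
forms are invariant to affine rescaling of the raw scale, so the choice of
0-100 storage is cosmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from causalearn.corpus_stats import DegenerateInputError, standardize

__all__ = [
    "SCALES",
    "aggregate_ratings",
    "to_predictor",
    "to_unit_interval",
    "build_profiles",
    "unit_matrix",
]

#: the four rated semantic scales, in canonical order
SCALES = ("event_merge", "autonomy", "directive", "requires")

RATING_COLUMNS = ("rater", "verb", "scale", "value")


class MissingRatingsError(ValueError):
    """A (verb, scale) cell has no ratings at all."""


def _validate_ratings(ratings: pd.DataFrame) -> None:
    missing = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    bad_scale = set(ratings["scale"]) - set(SCALES)
    if bad_scale:
        raise ValueError(f"unknown scales: {sorted(bad_scale)}; expected {SCALES}")
    if ratings.duplicated(subset=["rater", "verb", "scale"]).any():
        raise ValueError("duplicate (rater, verb, scale) ratings")


def aggregate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean rating per (verb, scale).

    Missing raters are tolerated — means are taken over whatever ratings a
    cell has — but a (verb, scale) cell with no ratings at all raises
    :class:`MissingRatingsError` naming the cell.

    Returns a frame indexed by verb with one column per scale.
    """
    _validate_ratings(ratings)
    means = ratings.pivot_table(
        index="verb", columns="scale", values="value", aggfunc="mean"
    )
    for scale in SCALES:
        if scale not in means.columns:
            raise MissingRatingsError(f"no ratings at all for scale {scale!r}")
        empty = means.index[means[scale].isna()]
        if len(empty):
            raise MissingRatingsError(
                f"no ratings for verb {empty[0]!r} on scale {scale!r}"
            )
    return means[list(SCALES)]


def to_predictor(means: pd.DataFrame) -> pd.DataFrame:
    """Z-score each scale's per-verb means across verbs (predictor form)."""
    return means.apply(lambda col: standardize(col.to_numpy()), axis=0)


def to_unit_interval(means: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each scale's per-verb means to [0, 1] (model-input form)."""

    def _scale(col: pd.Series) -> np.ndarray:
        x = col.to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateInputError(
                f"scale {col.name!r} is constant across verbs; cannot min-max scale"
            )
        return (x - lo) / (hi - lo)

    return means.apply(_scale, axis=0)


def build_profiles(ratings: pd.DataFrame) -> pd.DataFrame:
    """Full per-verb profile: mean, Z and unit-interval form per scale.

    Columns are ``<scale>_mean``, ``<scale>_z``, ``<scale>_unit`` for each
    of the four scales; the index is the verb.
    """
    means = aggregate_ratings(ratings)
    z = to_predictor(means)
    unit = to_unit_interval(means)
    out = pd.concat(
        [
            means.rename(columns={s: f"{s}_mean" for s in SCALES}),
            z.rename(columns={s: f"{s}_z" for s in SCALES}),
            unit.rename(columns={s: f"{s}_unit" for s in SCALES}),
        ],
        axis=1,
    )
    return out


def unit_matrix(profiles: pd.DataFrame, verbs) -> np.ndarray:
    """Unit-interval semantic activations as an (n_verbs, 4) array.

    Rows follow the order of ``verbs``; columns follow :data:`SCALES`.
    This is the layout the discriminative learner consumes.
    """
    cols = [f"{s}_unit" for s in SCALES]
    missing = [v for v in verbs if v not in profiles.index]
    if missing:
        raise KeyError(f"verbs missing from profiles: {missing[:5]}")
    return profiles.loc[list(verbs), cols].to_numpy(dtype=float)
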