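"""Signed chi-square bias statistics from per-verb construction counts.

Two distributional predictors of a verb's resistance to causative
overgeneralization are computed from a table of per-verb token counts in
three construction categories: the less-transparent causative, the
more-transparent causative, and all non-causative ("other") uses.

*Preemption* asks whether the verb's distribution across the two competing
causative structures differs from that of all other verbs in the set: a
verb attested overwhelmingly in the periphrastic causative while the rest
of the lexicon prefers the transitive causative carries evidence against
the transitive form for that verb.  *Entrenchment* asks the same question
with the competing causative replaced by the verb's non-causative uses, so
that sheer attested usage — regardless of meaning context — argues against
unattested structures.  Causative tokens of the competing structure never
enter the entrenchment table; they are already counted by preemption, and
excluding them keeps the two predictors from trivially sharing counts.

Both statistics are the Pearson chi-square of a verb-versus-rest 2x2
contingency table, signed positive when the focal verb is biased toward
the rated structure relative to the rest of the lexicon and negative when
biased away, then standardized to Z scores across the verb set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LESS",
    "MORE",
    "DegenerateInputError",
    "ContingencyTable2x2",
    "chi_square_2x2",
    "signed_bias",
    "preemption_statistic",
    "entrenchment_statistic",
    "standardize",
    "predictor_table",
]

#: labels for the two rated causative structures
LESS = "less"
MORE = "more"

COUNT_COLUMNS = ("n_less", "n_more", "n_other")


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate to carry information."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Verb-versus-rest 2x2 table.

    Row 1 is the focal verb, row 2 the pooled counts of every other verb in
    the set.  Column 1 holds the rated structure, column 2 the comparison
    category (the competing causative for preemption, non-causative uses
    for entrenchment).
    """

    a: float  # focal verb, column 1
    b: float  # focal verb, column 2
    c: float  # all other verbs, column 1
    d: float  # all other verbs, column 2
    col1_label: str = ""
    col2_label: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} is negative: {v}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def chi_square_2x2(table: ContingencyTable2x2) -> float:
    """Pearson chi-square statistic of a 2x2 table, no continuity correction.

    Uses the closed form N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  A table
    with a zero marginal carries no association information and returns 0;
    an all-zero table raises :class:`DegenerateInputError`.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    if n == 0:
        raise DegenerateInputError("all-zero 2x2 table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def signed_bias(table: ContingencyTable2x2) -> float:
    """Chi-square magnitude with polarity toward/away from column 1.

    Positive when the focal verb's odds toward the rated structure
    (column 1) exceed the pooled other-verbs odds, negative when lower,
    zero when the rows are proportional.  The comparison is done on the
    cross products a*d vs b*c so zero cells need no special casing.
    """
    magnitude = chi_square_2x2(table)
    if magnitude == 0.0:
        return 0.0
    cross = float(table.a) * float(table.d) - float(table.b) * float(table.c)
    return float(np.sign(cross)) * magnitude


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("verb", *COUNT_COLUMNS) if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    if counts["verb"].duplicated().any():
        dup = counts.loc[counts["verb"].duplicated(), "verb"].tolist()
        raise ValueError(f"duplicate verbs in counts table: {dup}")
    for col in COUNT_COLUMNS:
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    return counts


def _focal_and_rest(counts: pd.DataFrame, verb_id: str):
    if len(counts) < 2:
        raise ValueError("need at least 2 verbs to compute a verb-vs-rest table")
    mask = counts["verb"] == verb_id
    if not mask.any():
        raise KeyError(f"unknown verb: {verb_id!r}")
    focal = counts.loc[mask].iloc[0]
    rest = counts.loc[~mask, list(COUNT_COLUMNS)].sum()
    return focal, rest


def preemption_statistic(
    counts: pd.DataFrame, verb_id: str, rated_structure: str
) -> float:
    """Signed preemption chi-square for one verb and one rated structure.

    Column 1 is the rated causative structure, column 2 the competing
    causative structure; rows are the focal verb versus the pooled counts
    of every other verb in the supplied set, which stands in for the
    language-wide base rate.
    """
    _validate_counts(counts)
    focal, rest = _focal_and_rest(counts, verb_id)
    rated_col = "n_less" if rated_structure == LESS else "n_more"
    other_col = "n_more" if rated_structure == LESS else "n_less"
    table = ContingencyTable2x2(
        a=focal[rated_col],
        b=focal[other_col],
        c=rest[rated_col],
        d=rest[other_col],
        col1_label=f"{rated_structure}-transparent causative",
        col2_label="competing causative",
    )
    return signed_bias(table)


def entrenchment_statistic(
    counts: pd.DataFrame, verb_id: str, rated_structure: str
) -> float:
    """Signed entrenchment chi-square for one verb and one rated structure.

    As :func:`preemption_statistic`, but the comparison column holds the
    verb's non-causative uses only: causative tokens of the competing
    structure are excluded so that they are not double-counted across the
    two predictors.
    """
    _validate_counts(counts)
    focal, rest = _focal_and_rest(counts, verb_id)
    rated_col = "n_less" if rated_structure == LESS else "n_more"
    table = ContingencyTable2x2(
        a=focal[rated_col],
        b=focal["n_other"],
        c=rest[rated_col],
        d=rest["n_other"],
        col1_label=f"{rated_structure}-transparent causative",
        col2_label="non-causative uses",
    )
    return signed_bias(table)


def standardize(values) -> np.ndarray:
    """Z-score a vector: (x - mean) / sample SD (n-1 denominator).

    Raises :class:`DegenerateInputError` for constant or too-short input
    rather than silently returning zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant vector cannot be standardized")
    return (x - x.mean()) / sd


def predictor_table(counts: pd.DataFrame) -> pd.DataFrame:
    """All four signed bias predictors for every verb, raw and Z-scored.

    Returns a frame with one row per verb and columns
    ``preemption_less, preemption_more, entrenchment_less,
    entrenchment_more`` (standardized across verbs) plus ``*_raw``
    variants.  For each verb the two preemption values are the same table
    read with columns swapped, so they are equal in magnitude and opposite
    in sign before standardization.
    """
    _validate_counts(counts)
    rows = []
    for verb in counts["verb"]:
        rows.append(
            {
                "verb": verb,
                "preemption_less_raw": preemption_statistic(counts, verb, LESS),
                "preemption_more_raw": preemption_statistic(counts, verb, MORE),
                "entrenchment_less_raw": entrenchment_statistic(counts, verb, LESS),
                "entrenchment_more_raw": entrenchment_statistic(counts, verb, MORE),
            }
        )
    out = pd.DataFrame(rows)
    for name in (
        "preemption_less",
        "preemption_more",
        "entrenchment_less",
        "entrenchment_more",
    ):
        out[name] = standardize(out[f"{name}_raw"].to_numpy())
    cols = ["verb"] + [c for c in out.columns if c != "verb" and not c.endswith("_raw")]
    cols += [c for c in out.columns if c.endswith("_raw")]
    return out[cols]
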