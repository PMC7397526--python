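"""Schema-validated TSV readers and writers for every pipeline table.

All tables are UTF-8 tab-separated files with a header row.  TSV rather
than CSV because verb labels across languages may contain commas or
quotes.  Validation failures are reported with the 1-based file line
number of the offending row (header = line 1).

Tables and their columns:

* counts:       verb, n_less, n_more, n_other
* ratings:      rater, verb, scale, value
* judgments:    participant, age_group, verb, sentence_type, rating
* predictions:  run, epoch, verb, act_less, act_more, act_other
* predictors:   verb, preemption_less, ..., entrenchment_more (+ _raw)
* profiles:     verb, <scale>_mean, <scale>_z, <scale>_unit per scale
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from causalearn.evaluation import AGE_GROUPS, SENTENCE_TYPES
from causalearn.semantics import SCALES

__all__ = [
    "SchemaError",
    "read_counts",
    "read_ratings",
    "read_judgments",
    "read_predictions",
    "write_table",
    "file_sha256",
]


class SchemaError(ValueError):
    """A table violates its declared schema."""


def _read_tsv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8",
                     keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _line(i: int) -> int:
    return i + 2  # 0-based data row -> 1-based file line under the header


def _to_number(df: pd.DataFrame, col: str, path, kind=float) -> pd.Series:
    def conv(item):
        i, raw = item
        try:
            v = kind(raw)
        except ValueError:
            raise SchemaError(
                f"{path}, line {_line(i)}: {col}={raw!r} is not "
                f"{'an integer' if kind is int else 'a number'}") from None
        return v

    return pd.Series([conv(t) for t in enumerate(df[col])], index=df.index)


def _check_unique(df: pd.DataFrame, keys, path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        i = int(dup.idxmax())
        raise SchemaError(
            f"{path}, line {_line(i)}: duplicate key {tuple(df.loc[i, keys])}")


def read_counts(path) -> pd.DataFrame:
    """Read a per-verb construction-count table."""
    df = _read_tsv(path, ("verb", "n_less", "n_more", "n_other"))
    for col in ("n_less", "n_more", "n_other"):
        vals = _to_number(df, col, path, kind=int)
        bad = vals < 0
        if bad.any():
            i = int(bad.idxmax())
            raise SchemaError(f"{path}, line {_line(i)}: negative count in {col}")
        df[col] = vals
    _check_unique(df, ["verb"], path)
    return df[["verb", "n_less", "n_more", "n_other"]]


def read_ratings(path) -> pd.DataFrame:
    """Read a rater x verb x scale analogue-rating table."""
    df = _read_tsv(path, ("rater", "verb", "scale", "value"))
    bad_scale = ~df["scale"].isin(SCALES)
    if bad_scale.any():
        i = int(bad_scale.idxmax())
        raise SchemaError(f"{path}, line {_line(i)}: unknown scale "
                          f"{df.loc[i, 'scale']!r}")
    vals = _to_number(df, "value", path, kind=float)
    out_of_range = (vals < 0) | (vals > 100)
    if out_of_range.any():
        i = int(out_of_range.idxmax())
        raise SchemaError(
            f"{path}, line {_line(i)}: value {vals[i]} outside [0, 100]")
    df["value"] = vals
    _check_unique(df, ["rater", "verb", "scale"], path)
    return df[["rater", "verb", "scale", "value"]]


def read_judgments(path) -> pd.DataFrame:
    """Read a participant x verb x sentence-type judgment table."""
    df = _read_tsv(path, ("participant", "age_group", "verb",
                          "sentence_type", "rating"))
    bad_group = ~df["age_group"].isin(AGE_GROUPS)
    if bad_group.any():
        i = int(bad_group.idxmax())
        raise SchemaError(f"{path}, line {_line(i)}: unknown age group "
                          f"{df.loc[i, 'age_group']!r}")
    bad_type = ~df["sentence_type"].isin(SENTENCE_TYPES)
    if bad_type.any():
        i = int(bad_type.idxmax())
        raise SchemaError(f"{path}, line {_line(i)}: unknown sentence type "
                          f"{df.loc[i, 'sentence_type']!r}")
    vals = _to_number(df, "rating", path, kind=int)
    bad = ~vals.isin([1, 2, 3, 4, 5])
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(
            f"{path}, line {_line(i)}: rating {vals[i]} outside 1-5")
    df["rating"] = vals
    _check_unique(df, ["participant", "verb", "sentence_type"], path)
    return df[["participant", "age_group", "verb", "sentence_type", "rating"]]


def read_predictions(path) -> pd.DataFrame:
    """Read a model-prediction table emitted by the learner."""
    df = _read_tsv(path, ("run", "epoch", "verb",
                          "act_less", "act_more", "act_other"))
    df["run"] = _to_number(df, "run", path, kind=int)
    df["epoch"] = _to_number(df, "epoch", path, kind=int)
    for col in ("act_less", "act_more", "act_other"):
        df[col] = _to_number(df, col, path, kind=float)
    _check_unique(df, ["run", "epoch", "verb"], path)
    return df


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> Path:
    """Write any pipeline table as UTF-8 TSV; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8",
              float_format=float_format)
    return path


def file_sha256(path) -> str:
    """Checksum used in run manifests."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
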