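"""Respondent tables: demographics, item answers, emotion and media flags."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import Codebook

#: emotion flags collected by the survey, in reporting order
EMOTIONS = (
    "alertness",
    "worry",
    "isolation",
    "anxiety",
    "alarm",
    "boredom",
    "confusion",
    "fear",
    "depression",
)

#: information-source (media) flags, in reporting order
MEDIA = (
    "social_media",
    "ministry_announcements",
    "television",
    "websites",
    "official_websites",
    "newspapers",
)

#: demographic columns expected in a respondent table
DEMOGRAPHICS = ("age", "gender", "civil_status", "education", "position")

GENDERS = ("female", "male")

#: age bands used throughout descriptive tables (lowest band starts at 15)
AGE_BANDS = (
    (15, 24),
    (25, 34),
    (35, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 84),
    (85, np.inf),
)

AGE_BAND_LABELS = tuple(
    f"{lo}-{hi}" if np.isfinite(hi) else f"{lo}+" for lo, hi in AGE_BANDS
)

MIN_AGE = AGE_BANDS[0][0]


def age_band(age) -> str:
    """Map an age in years to its band label (vectorised over arrays)."""
    ages = np.asarray(age)
    edges = [lo for lo, _ in AGE_BANDS[1:]]
    idx = np.digitize(ages, edges)
    labels = np.asarray(AGE_BAND_LABELS, dtype=object)
    out = labels[idx]
    return out.item() if np.isscalar(age) else out


class ResponseValidationError(ValueError):
    """A respondent table does not conform to its codebook/schema."""


@dataclass
class ResponseTable:
    """Validated respondent table.

    ``data`` holds one row per respondent with the columns
    ``respondent_id``, the demographics, one column per codebook item
    (categories as strings, missing as NaN) and one 0/1 column per emotion
    and media flag.
    """

    data: pd.DataFrame
    codebook: Codebook
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def respondent_ids(self) -> pd.Series:
        return self.data["respondent_id"]

    @property
    def item_columns(self) -> list:
        return list(self.codebook.item_ids)

    def flags(self, which: str = "emotion") -> pd.DataFrame:
        names = EMOTIONS if which == "emotion" else MEDIA
        return self.data[list(names)].astype(bool)

    @property
    def age_bands(self) -> pd.Series:
        return pd.Series(
            age_band(self.data["age"].to_numpy()),
            index=self.data.index,
            name="age_band",
        )


def _validate(df: pd.DataFrame, codebook: Codebook) -> list:
    problems = []
    expected = ["respondent_id", *DEMOGRAPHICS, *codebook.item_ids, *EMOTIONS, *MEDIA]
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ResponseValidationError(f"missing column(s): {missing_cols}")

    if df["respondent_id"].duplicated().any():
        dupes = df.loc[df["respondent_id"].duplicated(), "respondent_id"].tolist()
        raise ResponseValidationError(f"duplicate respondent_id(s): {dupes[:5]}")

    try:
        ages = pd.to_numeric(df["age"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ResponseValidationError(f"unparseable age value: {exc}") from exc
    if (ages < MIN_AGE).any():
        rows = df.index[ages < MIN_AGE].tolist()
        raise ResponseValidationError(
            f"age below {MIN_AGE} (lowest band) in row(s) {rows[:5]}"
        )
    df = df.copy()
    df["age"] = ages

    bad_gender = ~df["gender"].isin(GENDERS)
    if bad_gender.any():
        raise ResponseValidationError(
            f"unknown gender label(s): {sorted(df.loc[bad_gender, 'gender'].unique())}"
        )

    for item in codebook.items:
        col = df[item.item_id]
        observed = col.dropna()
        unknown = ~observed.isin(item.categories)
        if unknown.any():
            rows = observed.index[unknown].tolist()
            labels = sorted(observed[unknown].unique())
            raise ResponseValidationError(
                f"item {item.item_id!r}: unknown category label(s) {labels}"
                f" in row(s) {rows[:10]}; codebook lists {list(item.categories)}"
            )

    for flag in (*EMOTIONS, *MEDIA):
        vals = pd.to_numeric(df[flag], errors="coerce")
        if vals.isna().any() or not vals.isin((0, 1)).all():
            raise ResponseValidationError(f"flag column {flag!r} must be 0/1")
        df[flag] = vals.astype(int)

    return df, problems


def load_responses(path, codebook: Codebook) -> ResponseTable:
    """Read a respondent CSV and validate it against the codebook.

    An empty file (header only) yields a table with n = 0.  Unknown category
    labels, duplicate respondent ids, unparseable ages and out-of-range
    ages raise :class:`ResponseValidationError` naming item and row.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str}, keep_default_na=True)
    for item_id in codebook.item_ids:
        if item_id in df.columns:
            df[item_id] = df[item_id].astype("string").astype(object)
    df, problems = _validate(df, codebook)
    return ResponseTable(data=df.reset_index(drop=True), codebook=codebook,
                         warnings=problems)


def from_dataframe(df: pd.DataFrame, codebook: Codebook) -> ResponseTable:
    """Validate an in-memory respondent DataFrame (same contract as CSV)."""
    df, problems = _validate(df, codebook)
    return ResponseTable(data=df.reset_index(drop=True), codebook=codebook,
                         warnings=problems)
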