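"""Reading, validating and encoding survey tables.

The canonical dialect is a UTF-8, comma-separated table with a header and
one row per respondent: demographic columns (``respondent_id``,
``country``, ``location``, ``sex``, ``age``, ``politics``) followed by one
column per question.  Ordinal answers are integers ``1..K`` (1 = most
negative category), "I don't know" is the literal ``DK`` (only legal for
questions that declare a DK option), and an empty cell is item
non-response ("missing") — excluded from analysis and never modelled.

Deposited data rarely uses these column names, so :func:`read_survey`
accepts a column-mapping (source name -> canonical name) instead of
hard-coding any particular export's header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "DK",
    "LOCATIONS",
    "SEXES",
    "POLITICS_LEVELS",
    "QuestionSpec",
    "CountryMeta",
    "SurveyDataset",
    "EncodedVector",
    "read_survey",
    "write_survey",
    "encode_responses",
    "read_country_meta",
    "load_question_schema",
    "dump_question_schema",
]

DK = "DK"  # in-file and in-memory sentinel for an "I don't know" answer

DEMOGRAPHIC_COLUMNS = ("respondent_id", "country", "location", "sex", "age", "politics")
LOCATIONS = ("rural", "urban")
SEXES = ("female", "male")
POLITICS_LEVELS = ("extreme_left", "left", "centre", "right", "extreme_right", "missing")


@dataclass(frozen=True)
class QuestionSpec:
    """Schema of one ordinal survey question.

    ``n_categories`` is K, the number of ordered answer options;
    ``category_labels`` run from the most negative to the most positive
    option.  ``has_dont_know`` declares whether a separate DK option was
    offered (DK is a mixture component, never an ordinal category).
    """

    question_id: str
    n_categories: int
    has_dont_know: bool = False
    category_labels: Optional[tuple[str, ...]] = None
    dk_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_categories < 3:
            raise SchemaError(
                f"question {self.question_id!r}: need K >= 3, got {self.n_categories}"
            )
        if self.category_labels is not None:
            labels = tuple(self.category_labels)
            object.__setattr__(self, "category_labels", labels)
            if len(labels) != self.n_categories:
                raise SchemaError(
                    f"question {self.question_id!r}: {len(labels)} labels "
                    f"for K={self.n_categories} categories"
                )
        if self.dk_label is not None and not self.has_dont_know:
            raise SchemaError(
                f"question {self.question_id!r}: dk_label given but has_dont_know is false"
            )

    def labels_or_default(self) -> tuple[str, ...]:
        if self.category_labels is not None:
            return self.category_labels
        return tuple(str(k) for k in range(1, self.n_categories + 1))


@dataclass(frozen=True)
class CountryMeta:
    """Per-country weighting metadata: rural population share in [0, 1]."""

    country: str
    rural_proportion: float
    median_age: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rural_proportion <= 1.0:
            raise ValidationError(
                f"country {self.country!r}: rural_proportion "
                f"{self.rural_proportion} outside [0, 1]"
            )


@dataclass
class SurveyDataset:
    """Validated respondent-level survey records.

    ``frame`` holds one row per respondent with the canonical demographic
    columns plus one object-dtype column per question (int codes, the
    ``DK`` sentinel, or NaN for missing).  ``schema`` is the ordered list
    of question specs the answer columns were validated against.
    """

    frame: pd.DataFrame
    schema: tuple[QuestionSpec, ...]

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        _validate_frame(self.frame, self.schema)

    @property
    def n_respondents(self) -> int:
        return len(self.frame)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["country"].unique()))

    def question(self, question_id: str) -> QuestionSpec:
        for q in self.schema:
            if q.question_id == question_id:
                return q
        raise SchemaError(f"unknown question {question_id!r}")

    def validate_against_meta(self, meta: pd.DataFrame) -> None:
        """Check that every country in the data has a weighting row."""
        missing = sorted(set(self.frame["country"]) - set(meta.index))
        if missing:
            raise ValidationError(
                f"countries missing from the metadata table: {missing}"
            )


@dataclass(frozen=True)
class EncodedVector:
    """Responses of one stratum, ready for the likelihood.

    ``ordinal_codes`` are the non-DK, non-missing integer answers;
    ``dk_count`` the number of DK answers; ``n_total`` their sum (missing
    answers are excluded entirely).
    """

    ordinal_codes: np.ndarray
    dk_count: int
    question_id: str
    group: str
    n_categories: int
    has_dk: bool
    country: Optional[str] = None

    def __post_init__(self) -> None:
        codes = np.asarray(self.ordinal_codes, dtype=int)
        object.__setattr__(self, "ordinal_codes", codes)
        if self.dk_count < 0:
            raise ValidationError("dk_count cannot be negative")
        if self.dk_count > 0 and not self.has_dk:
            raise ValidationError(
                f"question {self.question_id!r} has no DK option but "
                f"{self.dk_count} DK answers were supplied"
            )

    @property
    def n_total(self) -> int:
        return self.ordinal_codes.size + self.dk_count

    @property
    def is_empty(self) -> bool:
        return self.n_total == 0


# ---------------------------------------------------------------------------
# reading / writing


def _coerce_age(value, row_label, problems):
    try:
        age = int(value)
    except (TypeError, ValueError):
        problems.append(f"row {row_label}: age {value!r} is not an integer")
        return None
    if age <= 0:
        problems.append(f"row {row_label}: age must be > 0, got {age}")
        return None
    return age


def _validate_frame(frame: pd.DataFrame, schema: Sequence[QuestionSpec]) -> None:
    missing_cols = [c for c in DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing demographic columns: {missing_cols}")
    for q in schema:
        if q.question_id not in frame.columns:
            raise SchemaError(f"missing answer column {q.question_id!r}")

    problems: list[str] = []
    if frame["respondent_id"].duplicated().any():
        dupes = frame.loc[frame["respondent_id"].duplicated(), "respondent_id"]
        problems.append(f"duplicate respondent_id values: {sorted(set(dupes))}")
    for col, allowed in (("location", LOCATIONS), ("sex", SEXES), ("politics", POLITICS_LEVELS)):
        bad = ~frame[col].isin(allowed)
        for idx in frame.index[bad]:
            problems.append(
                f"row {idx}: {col}={frame.at[idx, col]!r} not in {allowed}"
            )
    for idx, age in frame["age"].items():
        _coerce_age(age, idx, problems)
    for q in schema:
        col = frame[q.question_id]
        for idx, val in col.items():
            if pd.isna(val):
                continue
            if isinstance(val, str) and val == DK:
                if not q.has_dont_know:
                    problems.append(
                        f"row {idx}, column {q.question_id!r}: DK answer on a "
                        "question without a DK option"
                    )
                continue
            try:
                code = int(val)
            except (TypeError, ValueError):
                problems.append(
                    f"row {idx}, column {q.question_id!r}: unparseable answer {val!r}"
                )
                continue
            if not 1 <= code <= q.n_categories:
                problems.append(
                    f"row {idx}, column {q.question_id!r}: answer code {code} "
                    f"outside 1..{q.n_categories}"
                )
    if problems:
        raise ValidationError(
            "survey validation failed:\n  " + "\n  ".join(problems)
        )


def read_survey(
    path: Union[str, Path],
    schema: Sequence[QuestionSpec],
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
) -> SurveyDataset:
    """Read and validate a respondent-level survey table.

    Rows failing a type or range check are reported collectively in the
    raised :class:`ValidationError`, naming each offending row and column;
    nothing is silently dropped.

    Parameters
    ----------
    path : path
        Delimiter-separated text file with a header.
    schema : sequence of QuestionSpec
        One spec per expected answer column.
    column_map : mapping, optional
        Source-column -> canonical-column renaming applied before
        validation (for third-party exports with different headers).
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    if column_map:
        raw = raw.rename(columns=dict(column_map))

    frame = raw.copy()
    # normalise types after the structural check inside SurveyDataset
    missing_cols = [c for c in DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing demographic columns: {missing_cols}")
    with pd.option_context("mode.chained_assignment", None):
        frame["age"] = pd.to_numeric(frame["age"], errors="coerce")
        for q in schema:
            if q.question_id not in frame.columns:
                raise SchemaError(f"missing answer column {q.question_id!r}")
            frame[q.question_id] = [
                v if (pd.isna(v) or v == DK) else _try_int(v)
                for v in frame[q.question_id]
            ]
    frame = frame.reset_index(drop=True)
    return SurveyDataset(frame=frame, schema=tuple(schema))


def _try_int(v):
    try:
        return int(v)
    except (TypeError, ValueError):
        return v  # left as-is so validation can report it


def write_survey(dataset: SurveyDataset, path: Union[str, Path]) -> None:
    """Write the canonical comma-separated form (byte-stable round trip)."""
    cols = list(DEMOGRAPHIC_COLUMNS) + [q.question_id for q in dataset.schema]
    out = dataset.frame[cols].copy()
    out["age"] = out["age"].astype(int)
    for q in dataset.schema:
        out[q.question_id] = [
            "" if pd.isna(v) else (v if v == DK else str(int(v)))
            for v in out[q.question_id]
        ]
    out.to_csv(path, index=False)


def encode_responses(
    dataset: SurveyDataset,
    question_id: str,
    country: Optional[str] = None,
    group: str = "all",
) -> EncodedVector:
    """Encode one stratum's answers for the likelihood.

    ``group`` is ``"rural"``, ``"urban"`` or ``"all"``.  Missing answers
    are excluded from ``n_total``; DK answers are counted, not coded.  An
    empty stratum is returned as an :class:`EncodedVector` with
    ``n_total == 0`` (``is_empty`` true) — fitting functions refuse it
    with :class:`~ordsurvey.errors.EmptyStratumError`.
    """
    if group not in ("rural", "urban", "all"):
        raise ValueError(f"group must be rural/urban/all, got {group!r}")
    q = dataset.question(question_id)
    frame = dataset.frame
    mask = pd.Series(True, index=frame.index)
    if country is not None:
        mask &= frame["country"] == country
    if group != "all":
        mask &= frame["location"] == group
    answers = frame.loc[mask, question_id]
    answers = answers[~answers.isna()]
    dk_count = int((answers == DK).sum())
    codes = answers[answers != DK].astype(int).to_numpy()
    return EncodedVector(
        ordinal_codes=codes,
        dk_count=dk_count,
        question_id=question_id,
        group=group,
        n_categories=q.n_categories,
        has_dk=q.has_dont_know,
        country=country,
    )


def read_country_meta(path: Union[str, Path], delimiter: str = ",") -> pd.DataFrame:
    """Read the country weighting table.

    Expects columns ``country`` and ``rural_proportion`` (optionally
    ``median_age``); returns a DataFrame indexed by country code with the
    rural share validated into [0, 1].
    """
    meta = pd.read_csv(path, sep=delimiter)
    for col in ("country", "rural_proportion"):
        if col not in meta.columns:
            raise SchemaError(f"country metadata missing column {col!r}")
    if meta["country"].duplicated().any():
        dupes = sorted(set(meta.loc[meta["country"].duplicated(), "country"]))
        raise ValidationError(f"duplicate country rows: {dupes}")
    bad = ~meta["rural_proportion"].between(0.0, 1.0)
    if bad.any():
        rows = meta.loc[bad, ["country", "rural_proportion"]]
        raise ValidationError(
            "rural_proportion outside [0, 1]:\n" + rows.to_string(index=False)
        )
    return meta.set_index("country")


# ---------------------------------------------------------------------------
# question schema config


def load_question_schema(path: Union[str, Path]) -> tuple[QuestionSpec, ...]:
    """Load question specs from a YAML file (a list of mappings)."""
    with open(path, "r", encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise SchemaError("question schema file must contain a list")
    specs = []
    for e in entries:
        specs.append(
            QuestionSpec(
                question_id=e["question_id"],
                n_categories=int(e["n_categories"]),
                has_dont_know=bool(e.get("has_dont_know", False)),
                category_labels=tuple(e["category_labels"]) if e.get("category_labels") else None,
                dk_label=e.get("dk_label"),
            )
        )
    return tuple(specs)


def dump_question_schema(schema: Sequence[QuestionSpec], path: Union[str, Path]) -> None:
    entries = []
    for q in schema:
        e = {
            "question_id": q.question_id,
            "n_categories": q.n_categories,
            "has_dont_know": q.has_dont_know,
        }
        if q.category_labels:
            e["category_labels"] = list(q.category_labels)
        if q.dk_label:
            e["dk_label"] = q.dk_label
        entries.append(e)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
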