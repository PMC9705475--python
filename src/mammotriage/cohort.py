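"""Domain model for screening cohorts.

A *cohort* is an ordered table of screening examinations, one row per
examination.  Each examination carries the AI suspicion score (a continuous
raw score on (0, 10] and its decile 1-10), the two radiologists'
interpretation scores (1-5), the real-world consensus and recall flags, and
the cancer outcome: ``NEGATIVE``, ``SDC`` (screen-detected cancer, i.e.
cancer diagnosed after a recall) or ``IC`` (the screening examination prior
to an interval cancer).

The invariants encode the double-reading workflow: an interpretation score
of 2 or higher by either reader sends the examination to consensus; only
consensus-discussed examinations can be recalled; and a screen-detected
cancer is by definition a recalled examination.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._util import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "Outcome",
    "Examination",
    "Cohort",
    "Violation",
    "COLUMNS",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]


class Outcome(str, enum.Enum):
    """Screening outcome of an examination."""

    NEGATIVE = "NEGATIVE"
    SDC = "SDC"  # screen-detected cancer: diagnosed after a recall
    IC = "IC"  # exam is the prior screen of an interval cancer

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Column order of the on-disk cohort CSV.
COLUMNS = [
    "exam_id",
    "woman_id",
    "ai_raw",
    "ai_score",
    "r1_score",
    "r2_score",
    "consensus",
    "recall",
    "outcome",
]


@dataclass(frozen=True)
class Examination:
    """One screening examination — the unit of all scenario accounting."""

    exam_id: str
    woman_id: str
    ai_raw: float
    ai_score: int
    r1_score: int
    r2_score: int
    consensus: bool
    recall: bool
    outcome: Outcome


class Cohort:
    """An ordered collection of examinations backed by a :class:`pandas.DataFrame`.

    The frame always has the columns in :data:`COLUMNS` with ``consensus`` and
    ``recall`` as booleans and ``outcome`` as one of ``NEGATIVE|SDC|IC``.
    Construction normalises dtypes but does *not* validate invariants; use
    :func:`validate_cohort` (or ``read_cohort(strict=True)``) for that.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort frame missing column(s): {missing}")
        df = df.loc[:, COLUMNS].reset_index(drop=True)
        df["exam_id"] = df["exam_id"].astype(str)
        df["woman_id"] = df["woman_id"].astype(str)
        try:
            df["ai_raw"] = df["ai_raw"].astype(float)
            for c in ("ai_score", "r1_score", "r2_score"):
                df[c] = df[c].astype(np.int64)
            df["consensus"] = df["consensus"].astype(np.int64).astype(bool)
            df["recall"] = df["recall"].astype(np.int64).astype(bool)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"unparsable value in cohort table: {exc}") from exc
        bad = ~df["outcome"].isin([o.value for o in Outcome])
        if bad.any():
            raise SchemaError(
                f"unknown outcome value(s): {sorted(df.loc[bad, 'outcome'].unique())}"
            )
        if df["exam_id"].duplicated().any():
            dupes = df.loc[df["exam_id"].duplicated(), "exam_id"].head(5).tolist()
            raise SchemaError(f"duplicate exam_id(s): {dupes}")
        self._df = df

    # -- construction ------------------------------------------------------
    @classmethod
    def from_examinations(cls, exams: Iterable[Examination]) -> "Cohort":
        rows = [
            (
                e.exam_id,
                e.woman_id,
                e.ai_raw,
                e.ai_score,
                e.r1_score,
                e.r2_score,
                e.consensus,
                e.recall,
                Outcome(e.outcome).value,
            )
            for e in exams
        ]
        df = pd.DataFrame(rows, columns=COLUMNS)
        if not rows:  # keep dtypes sane for the empty cohort
            df = df.astype(
                {
                    "ai_raw": float,
                    "ai_score": np.int64,
                    "r1_score": np.int64,
                    "r2_score": np.int64,
                    "consensus": bool,
                    "recall": bool,
                }
            )
        return cls(df)

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self._df.equals(other._df)

    def examinations(self) -> Iterator[Examination]:
        for row in self._df.itertuples(index=False):
            yield Examination(
                exam_id=row.exam_id,
                woman_id=row.woman_id,
                ai_raw=row.ai_raw,
                ai_score=int(row.ai_score),
                r1_score=int(row.r1_score),
                r2_score=int(row.r2_score),
                consensus=bool(row.consensus),
                recall=bool(row.recall),
                outcome=Outcome(row.outcome),
            )

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying frame (a defensive copy is *not* made; treat as read-only)."""
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def n_women(self) -> int:
        return self._df["woman_id"].nunique()

    @property
    def n_sdc(self) -> int:
        return int((self._df["outcome"] == Outcome.SDC.value).sum())

    @property
    def n_ic(self) -> int:
        return int((self._df["outcome"] == Outcome.IC.value).sum())

    @property
    def n_consensus(self) -> int:
        return int(self._df["consensus"].sum())

    @property
    def n_recall(self) -> int:
        return int(self._df["recall"].sum())

    # Baseline rates are pure functions of the table.
    @property
    def consensus_rate(self) -> float:
        return self.n_consensus / self.n

    @property
    def recall_rate(self) -> float:
        return self.n_recall / self.n

    @property
    def sdc_rate(self) -> float:
        return self.n_sdc / self.n

    @property
    def ic_rate(self) -> float:
        return self.n_ic / self.n

    def __repr__(self) -> str:
        return (
            f"<Cohort n={self.n} women={self.n_women} "
            f"sdc={self.n_sdc} ic={self.n_ic}>"
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation, attributable to a single examination."""

    exam_id: str
    rule: str
    message: str


def _violation_mask(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Boolean mask per rule name; True marks a violating row."""
    r1, r2 = df["r1_score"], df["r2_score"]
    either_positive = (r1 >= 2) | (r2 >= 2)
    ceil_score = np.ceil(df["ai_raw"]).astype(np.int64, copy=False)
    return {
        "ai_raw_out_of_range": ~((df["ai_raw"] > 0) & (df["ai_raw"] <= 10)),
        "score_not_ceiling": df["ai_score"] != ceil_score,
        "reader_score_out_of_range": ~(
            r1.between(1, 5) & r2.between(1, 5)
        ),
        "consensus_rule": df["consensus"] != either_positive,
        "recall_requires_consensus": df["recall"] & ~df["consensus"],
        "sdc_requires_recall": (df["outcome"] == Outcome.SDC.value) & ~df["recall"],
    }


def validate_cohort(
    cohort: Cohort, max_exams_per_woman: int | None = None
) -> list[Violation]:
    """Check every cohort invariant; return one record per violated rule and exam.

    Rules checked per examination: ``ai_raw`` in (0, 10] with
    ``ai_score == ceil(ai_raw)``; reader scores in 1..5; consensus iff either
    reader scored >= 2; recall only with consensus; SDC only with recall.
    With ``max_exams_per_woman`` set, every woman must have at most that many
    examinations (reported against her first exam).

    Returns an empty list iff the cohort is valid.
    """
    df = cohort.df
    out: list[Violation] = []
    for rule, mask in _violation_mask(df).items():
        for exam_id in df.loc[mask, "exam_id"]:
            out.append(Violation(exam_id, rule, f"invariant '{rule}' violated"))
    if max_exams_per_woman is not None:
        counts = df.groupby("woman_id")["exam_id"].agg(["count", "first"])
        for _, row in counts[counts["count"] > max_exams_per_woman].iterrows():
            out.append(
                Violation(
                    row["first"],
                    "too_many_exams_per_woman",
                    f"woman has {row['count']} exams (max {max_exams_per_woman})",
                )
            )
    return out


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read a cohort CSV (header required, booleans encoded 0/1).

    With ``strict=True`` (the default) any invariant violation aborts with
    :class:`CohortValidationError` naming the offending examinations.  With
    ``strict=False`` violating rows are dropped and the drop count is logged
    and exposed as ``cohort.dropped`` on the returned object.  Schema-level
    problems (missing column, duplicate exam_id, unparsable score) always
    raise :class:`SchemaError`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            dtype={"exam_id": str, "woman_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, header required") from exc
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")

    if strict:
        cohort = Cohort(raw)
        violations = validate_cohort(cohort)
        if violations:
            head = ", ".join(f"{v.exam_id}:{v.rule}" for v in violations[:5])
            raise CohortValidationError(
                f"{path}: {len(violations)} invariant violation(s), e.g. {head}"
            )
        cohort.dropped = 0
        return cohort

    # Lenient path: coerce, drop unparsable rows, then drop invariant violators.
    for c in ("ai_raw",):
        raw[c] = pd.to_numeric(raw[c], errors="coerce")
    for c in ("ai_score", "r1_score", "r2_score", "consensus", "recall"):
        raw[c] = pd.to_numeric(raw[c], errors="coerce")
    parsable = raw[COLUMNS[2:-1]].notna().all(axis=1) & raw["outcome"].isin(
        [o.value for o in Outcome]
    )
    n_unparsable = int((~parsable).sum())
    cohort = Cohort(raw[parsable])
    bad_ids = {v.exam_id for v in validate_cohort(cohort)}
    n_invalid = len(bad_ids)
    if bad_ids:
        cohort = Cohort(cohort.df[~cohort.df["exam_id"].isin(bad_ids)])
    dropped = n_unparsable + n_invalid
    if dropped:
        logger.warning(
            "%s: dropped %d row(s) (%d unparsable, %d invariant violations)",
            path,
            dropped,
            n_unparsable,
            n_invalid,
        )
    cohort.dropped = dropped
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV (UTF-8, comma-separated, booleans as 0/1).

    ``ai_raw`` is written with the shortest round-tripping decimal
    representation, so ``read_cohort(write_cohort(c))`` reproduces the cohort
    bit-exactly.
    """
    df = cohort.df.copy()
    df["consensus"] = df["consensus"].astype(int)
    df["recall"] = df["recall"].astype(int)
    df["ai_raw"] = df["ai_raw"].map(lambda x: repr(float(x)))
    df.to_csv(path, index=False, lineterminator="\n")
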