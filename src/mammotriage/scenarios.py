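"""Reading scenarios and their counterfactual evaluation.

A *scenario* is a rule for combining an AI suspicion score with radiologist
double reading.  Three shapes exist:

``TRIAGE``
    Raw-AI-score bands partition (0, 10]; each band is read by no one
    (``NEGATIVE``), by reader 1 only (``SINGLE_R1``) or by both readers
    (``DOUBLE``).  An exam reaches consensus when a reader who saw it
    scored it >= 2.
``AI_AS_READER``
    Reader 1 reads everything; AI replaces reader 2 and flags either a
    fixed fraction of exams (highest raw scores) or a decile cutoff.
    Consensus is the union of R1 positives and AI flags.
``AI_STANDALONE``
    AI alone selects a fixed fraction of exams directly for recall.

Evaluation is counterfactual on retrospective double-read data: scenario
recalls are exams the scenario sends to consensus *and* that were actually
recalled; detected cancers are verified screen-detected cancers among those
recalls; and interval cancers whose prior exam the scenario selects for
consensus are reported as the pool with potential for earlier detection.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from ._util import SpecError
from .cohort import Cohort, Outcome

__all__ = [
    "ReadingMode",
    "ScenarioMode",
    "Band",
    "ScenarioSpec",
    "ScenarioResult",
    "NOMINAL",
    "scenario_catalog",
    "select_top_fraction",
    "evaluate_scenario",
    "volume_reduction",
]


class ReadingMode(str, enum.Enum):
    NEGATIVE = "NEGATIVE"  # nobody reads the exam
    SINGLE_R1 = "SINGLE_R1"  # reader 1 only
    DOUBLE = "DOUBLE"  # independent double reading


class ScenarioMode(str, enum.Enum):
    TRIAGE = "TRIAGE"
    AI_AS_READER = "AI_AS_READER"
    AI_STANDALONE = "AI_STANDALONE"


@dataclass(frozen=True)
class Band:
    """Half-open raw-score interval (low, high] mapped to a reading mode."""

    low: float
    high: float
    read: ReadingMode

    @property
    def width(self) -> float:
        return self.high - self.low


#: Sentinel: compute volume reduction from exact decile widths (10% per
#: decile, the 7.5 split giving 25%) rather than from an empirical cohort.
NOMINAL = "nominal"


@dataclass(frozen=True)
class ScenarioSpec:
    """A declarative triage/replacement rule; validated on construction."""

    name: str
    mode: ScenarioMode
    bands: tuple[Band, ...] | None = None
    ai_selection_rate: float | None = None
    ai_score_cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.mode is ScenarioMode.TRIAGE:
            if not self.bands:
                raise SpecError(f"{self.name}: TRIAGE scenario requires bands")
            bands = sorted(self.bands, key=lambda b: b.low)
            if not math.isclose(bands[0].low, 0.0) or not math.isclose(
                bands[-1].high, 10.0
            ):
                raise SpecError(f"{self.name}: bands must cover (0, 10]")
            for a, b in zip(bands, bands[1:]):
                if not math.isclose(a.high, b.low):
                    raise SpecError(
                        f"{self.name}: bands must partition (0, 10] without "
                        f"gaps or overlap (got {a.high} then {b.low})"
                    )
            for b in bands:
                if b.width <= 0:
                    raise SpecError(f"{self.name}: empty band {b}")
            object.__setattr__(self, "bands", tuple(bands))
        else:
            if self.bands:
                raise SpecError(f"{self.name}: bands only valid for TRIAGE")
            has_rate = self.ai_selection_rate is not None
            has_cut = self.ai_score_cutoff is not None
            if has_rate == has_cut:
                raise SpecError(
                    f"{self.name}: exactly one of ai_selection_rate or "
                    "ai_score_cutoff required"
                )
            if has_rate and not 0.0 < self.ai_selection_rate <= 1.0:
                raise SpecError(f"{self.name}: ai_selection_rate outside (0, 1]")
            if has_cut and not 1 <= self.ai_score_cutoff <= 10:
                raise SpecError(f"{self.name}: ai_score_cutoff outside 1..10")
            if self.mode is ScenarioMode.AI_STANDALONE and has_cut:
                raise SpecError(f"{self.name}: AI_STANDALONE uses a selection rate")


@dataclass(frozen=True)
class ScenarioResult:
    """Counterfactual counts for one scenario on one cohort."""

    name: str
    n: int
    n_consensus: int | None  # None for AI_STANDALONE (no consensus stage)
    n_recall: int
    n_sdc: int
    n_ic_selected: int
    n_ic_total: int
    n_sdc_total: int
    reader_fraction_r1: float
    reader_fraction_r2: float

    # Derived rates -------------------------------------------------------
    @property
    def consensus_pct(self) -> float | None:
        return None if self.n_consensus is None else 100.0 * self.n_consensus / self.n

    @property
    def recall_pct(self) -> float:
        return 100.0 * self.n_recall / self.n

    @property
    def sdc_per_1000(self) -> float:
        return 1000.0 * self.n_sdc / self.n

    @property
    def ic_selected_per_1000(self) -> float:
        return 1000.0 * self.n_ic_selected / self.n

    @property
    def detection_fraction(self) -> float:
        """Share of the cohort's screen-detected cancers the scenario keeps."""
        return self.n_sdc / self.n_sdc_total


def _bands(*triples: tuple[float, float, str]) -> tuple[Band, ...]:
    return tuple(Band(lo, hi, ReadingMode(m)) for lo, hi, m in triples)


def scenario_catalog() -> list[ScenarioSpec]:
    """The 11 built-in scenarios, S1..S11.

    S1/S2 use AI as one of two readers (5.8% top-fraction mimicking the
    per-reader positive rate, or the top decile); S3-S10 are triage rules
    over raw-score bands (decile labels "1-5" = (0,5], "6-10" = (5,10],
    "6-7.5" = (5,7.5], "7.6-10" = (7.5,10]); S11 is standalone AI recalling
    3.2% (the double-reading recall rate).
    """
    T, A, S = ScenarioMode.TRIAGE, ScenarioMode.AI_AS_READER, ScenarioMode.AI_STANDALONE
    NEG, R1, DBL = "NEGATIVE", "SINGLE_R1", "DOUBLE"
    return [
        ScenarioSpec("S1", A, ai_selection_rate=0.058),
        ScenarioSpec("S2", A, ai_score_cutoff=10),
        ScenarioSpec("S3", T, _bands((0, 5, NEG), (5, 10, DBL))),
        ScenarioSpec("S4", T, _bands((0, 7, NEG), (7, 10, DBL))),
        ScenarioSpec("S5", T, _bands((0, 9, NEG), (9, 10, DBL))),
        ScenarioSpec("S6", T, _bands((0, 5, NEG), (5, 10, R1))),
        ScenarioSpec("S7", T, _bands((0, 5, R1), (5, 10, DBL))),
        ScenarioSpec("S8", T, _bands((0, 7, R1), (7, 10, DBL))),
        ScenarioSpec("S9", T, _bands((0, 5, NEG), (5, 7.5, R1), (7.5, 10, DBL))),
        ScenarioSpec("S10", T, _bands((0, 5, NEG), (5, 7.5, DBL), (7.5, 10, R1))),
        ScenarioSpec("S11", S, ai_selection_rate=0.032),
    ]


def select_top_fraction(cohort: Cohort, rate: float) -> frozenset[str]:
    """Exam ids of the ``round(rate * n)`` highest-raw-score examinations.

    Rounding is half-up; ties in ``ai_raw`` break deterministically by
    ascending ``exam_id``.
    """
    if not 0.0 < rate <= 1.0:
        raise SpecError(f"selection rate {rate} outside (0, 1]")
    n = cohort.n
    if n == 0:
        return frozenset()
    k = int(math.floor(rate * n + 0.5))
    df = cohort.df
    order = df.sort_values(
        ["ai_raw", "exam_id"], ascending=[False, True], kind="mergesort"
    )
    return frozenset(order["exam_id"].head(k))


def _ai_selection_mask(cohort: Cohort, spec: ScenarioSpec) -> np.ndarray:
    df = cohort.df
    if spec.ai_score_cutoff is not None:
        return (df["ai_score"] >= spec.ai_score_cutoff).to_numpy()
    chosen = select_top_fraction(cohort, spec.ai_selection_rate)
    return df["exam_id"].isin(chosen).to_numpy()


def _band_masks(cohort: Cohort, spec: ScenarioSpec) -> dict[ReadingMode, np.ndarray]:
    """Exam membership per reading mode; raises if a raw score falls outside."""
    raw = cohort.df["ai_raw"].to_numpy()
    masks = {m: np.zeros(len(raw), dtype=bool) for m in ReadingMode}
    covered = np.zeros(len(raw), dtype=bool)
    for band in spec.bands:
        m = (raw > band.low) & (raw <= band.high)
        masks[band.read] |= m
        covered |= m
    if not covered.all():
        bad = cohort.df.loc[~covered, "exam_id"].head(3).tolist()
        raise SpecError(f"{spec.name}: raw score not covered by any band for {bad}")
    return masks


def evaluate_scenario(cohort: Cohort, spec: ScenarioSpec) -> ScenarioResult:
    """Counterfactual accounting of one scenario over a cohort.

    Semantics (all per-exam, vectorised):

    * TRIAGE — consensus-selected iff the exam's band is DOUBLE and either
      reader scored >= 2, or SINGLE_R1 and reader 1 scored >= 2.  Scenario
      recall = consensus-selected and actually recalled.  ``n_sdc`` counts
      SDC outcomes among scenario recalls; ``n_ic_selected`` counts IC
      outcomes among consensus-selected exams.
    * AI_AS_READER — consensus-selected iff reader 1 scored >= 2 or AI
      flagged the exam; recall/SDC/IC accounting as for TRIAGE.
    * AI_STANDALONE — the AI selection *is* the recall set; ``n_sdc`` and
      ``n_ic_selected`` count SDC/IC among selected exams; consensus is
      reported as absent (``None``).
    """
    df = cohort.df
    n = cohort.n
    r1_pos = (df["r1_score"] >= 2).to_numpy()
    r2_pos = (df["r2_score"] >= 2).to_numpy()
    actual_recall = df["recall"].to_numpy()
    is_sdc = (df["outcome"] == Outcome.SDC.value).to_numpy()
    is_ic = (df["outcome"] == Outcome.IC.value).to_numpy()

    if spec.mode is ScenarioMode.TRIAGE:
        masks = _band_masks(cohort, spec)
        selected = (masks[ReadingMode.DOUBLE] & (r1_pos | r2_pos)) | (
            masks[ReadingMode.SINGLE_R1] & r1_pos
        )
        recall = selected & actual_recall
        n_consensus: int | None = int(selected.sum())
        f_r1 = float((masks[ReadingMode.SINGLE_R1] | masks[ReadingMode.DOUBLE]).mean()) if n else 0.0
        f_r2 = float(masks[ReadingMode.DOUBLE].mean()) if n else 0.0
        ic_pool = selected
    elif spec.mode is ScenarioMode.AI_AS_READER:
        selected = r1_pos | _ai_selection_mask(cohort, spec)
        recall = selected & actual_recall
        n_consensus = int(selected.sum())
        f_r1, f_r2 = 1.0, 0.0
        ic_pool = selected
    else:  # AI_STANDALONE
        selected = _ai_selection_mask(cohort, spec)
        recall = selected
        n_consensus = None
        f_r1 = f_r2 = 0.0
        ic_pool = selected

    return ScenarioResult(
        name=spec.name,
        n=n,
        n_consensus=n_consensus,
        n_recall=int(recall.sum()),
        n_sdc=int((recall & is_sdc).sum()),
        n_ic_selected=int((ic_pool & is_ic).sum()),
        n_ic_total=int(is_ic.sum()),
        n_sdc_total=int(is_sdc.sum()),
        reader_fraction_r1=f_r1,
        reader_fraction_r2=f_r2,
    )


def _nominal_fractions(spec: ScenarioSpec) -> tuple[float, float]:
    """(fraction read by R1, by R2) under exact decile band widths."""
    if spec.mode is ScenarioMode.AI_AS_READER:
        return 1.0, 0.0
    if spec.mode is ScenarioMode.AI_STANDALONE:
        return 0.0, 0.0
    f_r1 = sum(
        b.width / 10.0
        for b in spec.bands
        if b.read in (ReadingMode.SINGLE_R1, ReadingMode.DOUBLE)
    )
    f_r2 = sum(b.width / 10.0 for b in spec.bands if b.read is ReadingMode.DOUBLE)
    return f_r1, f_r2


def volume_reduction(spec: ScenarioSpec, cohort: Cohort | str = NOMINAL) -> float:
    """Percent reduction in human screen-readings vs. two readings per exam.

    ``100 * (1 - (f_R1 + f_R2) / 2)`` where ``f_Ri`` is the fraction of
    examinations reader *i* interprets under the scenario.  AI readings are
    never counted as human workload.  With ``cohort=NOMINAL`` the fractions
    come from exact band widths (each decile holding 10% of exams); with a
    cohort they are empirical.  Returned unrounded (62.5 stays 62.5).
    """
    if isinstance(cohort, str):
        if cohort != NOMINAL:
            raise SpecError(f"unknown cohort sentinel {cohort!r}")
        f_r1, f_r2 = _nominal_fractions(spec)
    else:
        result = evaluate_scenario(cohort, spec)
        f_r1, f_r2 = result.reader_fraction_r1, result.reader_fraction_r2
    return 100.0 * (1.0 - (f_r1 + f_r2) / 2.0)
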