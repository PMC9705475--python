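"""Screening performance metrics and report tables.

Sensitivity is estimated as TP / (TP + FN) with a logit-transformed
confidence interval: with ``L = ln(TP/FN)`` and ``SE = sqrt(1/TP + 1/FN)``
the bounds are ``expit(L -+ z * SE)``.  Two accounting variants exist per
scenario: variant A counts only the scenario's screen-detected cancers as
true positives; variant B additionally credits interval cancers whose
prior examination the scenario selected for consensus (the optimistic
assumption that these would have been detected at screening).

The *potential* SDC/IC rates move consensus-selected interval cancers from
the interval-cancer column to the screen-detected column; their sum is
therefore invariant in the number moved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._util import MammotriageError, round_half_up
from .cohort import Cohort
from .scenarios import (
    NOMINAL,
    ScenarioResult,
    ScenarioSpec,
    evaluate_scenario,
    scenario_catalog,
    volume_reduction,
)

__all__ = [
    "SensitivityEstimate",
    "PotentialRates",
    "RateReport",
    "sensitivity_logit_ci",
    "scenario_sensitivity",
    "potential_rates",
    "cluster_design_effect",
    "rates_report",
    "sensitivity_table",
]


@dataclass(frozen=True)
class SensitivityEstimate:
    """A proportion with its logit-transformed CI and the counts behind it."""

    tp: int
    fn: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    variant: str | None = None  # "A" | "B" | None for plain proportions
    degenerate: bool = False  # continuity fallback applied (tp or fn was 0)

    def __str__(self) -> str:
        flag = " (continuity-corrected)" if self.degenerate else ""
        return (
            f"{100 * self.point:.1f}% "
            f"({100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}%){flag}"
        )


def sensitivity_logit_ci(
    tp: int, fn: int, level: float = 0.95, design_effect: float = 1.0
) -> SensitivityEstimate:
    """Proportion ``tp/(tp+fn)`` with a logit-transformed confidence interval.

    When ``tp`` or ``fn`` is zero the logit is undefined; a continuity
    fallback adds 0.5 to both counts for the interval (the point estimate
    keeps the raw counts) and the result is flagged ``degenerate=True``.

    ``design_effect`` inflates the squared standard error (variance) for
    clustered observations; 1.0 (default) is the unadjusted interval.
    """
    if tp < 0 or fn < 0 or tp + fn == 0:
        raise MammotriageError(f"invalid counts tp={tp}, fn={fn}")
    if design_effect < 1.0:
        raise MammotriageError(f"design_effect {design_effect} must be >= 1")
    point = tp / (tp + fn)
    degenerate = tp == 0 or fn == 0
    a, b = (tp + 0.5, fn + 0.5) if degenerate else (float(tp), float(fn))
    logit = np.log(a / b)
    se = np.sqrt((1.0 / a + 1.0 / b) * design_effect)
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = expit(logit - z * se), expit(logit + z * se)
    if degenerate:  # pin the degenerate side to the boundary
        lo, hi = (lo, 1.0) if fn == 0 else (0.0, hi)
    return SensitivityEstimate(
        tp=int(tp),
        fn=int(fn),
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        degenerate=degenerate,
    )


def scenario_sensitivity(
    result: ScenarioResult,
    variant: str = "A",
    level: float = 0.95,
    design_effect: float = 1.0,
) -> SensitivityEstimate:
    """Scenario sensitivity under accounting variant A or B.

    Variant A: TP = scenario SDC; FN = missed SDC plus all interval cancers.
    Variant B: TP = scenario SDC plus consensus-selected interval cancers;
    FN = missed SDC plus unselected interval cancers.
    """
    missed_sdc = result.n_sdc_total - result.n_sdc
    if variant == "A":
        tp, fn = result.n_sdc, missed_sdc + result.n_ic_total
    elif variant == "B":
        tp = result.n_sdc + result.n_ic_selected
        fn = missed_sdc + (result.n_ic_total - result.n_ic_selected)
    else:
        raise MammotriageError(f"unknown sensitivity variant {variant!r}")
    est = sensitivity_logit_ci(tp, fn, level=level, design_effect=design_effect)
    return SensitivityEstimate(
        tp=est.tp,
        fn=est.fn,
        point=est.point,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        level=level,
        variant=variant,
        degenerate=est.degenerate,
    )


@dataclass(frozen=True)
class PotentialRates:
    """Per-1000 SDC/IC rates under the optimistic interval-cancer transfer."""

    sdc_per_1000: float
    sdc_ci: tuple[float, float]
    ic_per_1000: float
    ic_ci: tuple[float, float]


def potential_rates(
    result: ScenarioResult, level: float = 0.95, design_effect: float = 1.0
) -> PotentialRates:
    """Potential SDC and IC rates (per 1000 examinations) with CIs.

    Potential SDC counts the scenario's screen-detected cancers plus the
    interval cancers it selected for consensus; potential IC counts the
    remaining interval cancers.  CIs are logit-transformed binomial
    intervals on the corresponding proportions; ``design_effect`` > 1
    inflates them for within-woman clustering (default off).
    """
    if result.n == 0:
        raise MammotriageError("potential rates undefined for an empty cohort")
    n = result.n
    k_sdc = result.n_sdc + result.n_ic_selected
    k_ic = result.n_ic_total - result.n_ic_selected
    est_sdc = sensitivity_logit_ci(k_sdc, n - k_sdc, level, design_effect)
    est_ic = sensitivity_logit_ci(k_ic, n - k_ic, level, design_effect)
    return PotentialRates(
        sdc_per_1000=1000.0 * k_sdc / n,
        sdc_ci=(1000.0 * est_sdc.ci_low, 1000.0 * est_sdc.ci_high),
        ic_per_1000=1000.0 * k_ic / n,
        ic_ci=(1000.0 * est_ic.ci_low, 1000.0 * est_ic.ci_high),
    )


def cluster_design_effect(cohort: Cohort, column: str = "recall") -> float:
    """Design effect ``1 + (m_bar - 1) * ICC`` for a binary exam-level column.

    The intraclass correlation over women is estimated with the one-way
    ANOVA (moment) estimator on the 0/1 indicator, clusters being each
    woman's examinations; ``m_bar`` is the mean cluster size.  Values near
    1 mean within-woman correlation barely widens the intervals.  Clamped
    below at 1.0 so it can only widen an interval.
    """
    df = cohort.df
    y = df[column].astype(float)
    groups = df.groupby("woman_id")[column]
    sizes = groups.size().to_numpy(dtype=float)
    k = len(sizes)
    n = float(len(df))
    if k <= 1 or n == k:
        return 1.0
    means = groups.mean().to_numpy(dtype=float)
    grand = float(y.mean())
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    denom = ms_between + (n0 - 1) * ms_within
    icc = (ms_between - ms_within) / denom if denom > 0 else 0.0
    m_bar = n / k
    return max(1.0, 1.0 + (m_bar - 1.0) * icc)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateReport:
    """One row per scenario plus a baseline row of actual double-reading rates."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2)

    def __str__(self) -> str:
        return self.frame.to_string(index=False, na_rep="-")


def _fmt_ci(ci: tuple[float, float]) -> str:
    return f"{round_half_up(ci[0], 1):.1f}-{round_half_up(ci[1], 1):.1f}"


def _report_row(
    result: ScenarioResult,
    spec: ScenarioSpec | None,
    level: float,
    design_effect: float,
) -> dict:
    pot = potential_rates(result, level=level, design_effect=design_effect)
    sens_a = scenario_sensitivity(result, "A", level, design_effect)
    sens_b = scenario_sensitivity(result, "B", level, design_effect)
    vol = volume_reduction(spec, NOMINAL) if spec is not None else 0.0
    return {
        "scenario": result.name,
        "n": result.n,
        "consensus_n": result.n_consensus,
        "consensus_pct": None
        if result.consensus_pct is None
        else round_half_up(result.consensus_pct, 1),
        "recall_n": result.n_recall,
        "recall_pct": round_half_up(result.recall_pct, 1),
        "sdc_n": result.n_sdc,
        "sdc_per_1000": round_half_up(result.sdc_per_1000, 1),
        "ic_selected_n": result.n_ic_selected,
        "ic_selected_per_1000": round_half_up(result.ic_selected_per_1000, 1),
        "potential_sdc_per_1000": round_half_up(pot.sdc_per_1000, 1),
        "potential_sdc_ci": _fmt_ci(pot.sdc_ci),
        "potential_ic_per_1000": round_half_up(pot.ic_per_1000, 1),
        "potential_ic_ci": _fmt_ci(pot.ic_ci),
        "sensitivity_a_pct": round_half_up(100 * sens_a.point, 1),
        "sensitivity_a_ci": _fmt_ci((100 * sens_a.ci_low, 100 * sens_a.ci_high)),
        "sensitivity_b_pct": round_half_up(100 * sens_b.point, 1),
        "sensitivity_b_ci": _fmt_ci((100 * sens_b.ci_low, 100 * sens_b.ci_high)),
        "volume_reduction_pct": round_half_up(vol, 0),
    }


def _baseline_result(cohort: Cohort) -> ScenarioResult:
    """Actual double-reading outcomes cast as a ScenarioResult."""
    return ScenarioResult(
        name="baseline",
        n=cohort.n,
        n_consensus=cohort.n_consensus,
        n_recall=cohort.n_recall,
        n_sdc=cohort.n_sdc,
        n_ic_selected=0,
        n_ic_total=cohort.n_ic,
        n_sdc_total=cohort.n_sdc,
        reader_fraction_r1=1.0,
        reader_fraction_r2=1.0,
    )


def rates_report(
    cohort: Cohort,
    specs: Sequence[ScenarioSpec] | None = None,
    level: float = 0.95,
    cluster_adjust: bool = False,
) -> RateReport:
    """Scenario-by-scenario rate table over a cohort.

    The first row is the baseline: actual independent double-reading
    consensus/recall/SDC/IC rates (its potential columns coincide with the
    observed rates since no interval cancers are transferred).  Remaining
    rows evaluate each spec counterfactually.  With ``cluster_adjust`` the
    CIs are widened by the woman-level design effect on the recall
    indicator (documented in :func:`cluster_design_effect`).
    """
    if cohort.n == 0:
        raise MammotriageError("cannot report on an empty cohort")
    specs = scenario_catalog() if specs is None else list(specs)
    deff = cluster_design_effect(cohort) if cluster_adjust else 1.0
    rows = [_report_row(_baseline_result(cohort), None, level, deff)]
    for spec in specs:
        rows.append(_report_row(evaluate_scenario(cohort, spec), spec, level, deff))
    frame = pd.DataFrame(rows)
    frame["consensus_pct"] = frame["consensus_pct"].astype(float)  # None -> NaN
    return RateReport(frame)


def sensitivity_table(
    cohort: Cohort,
    specs: Sequence[ScenarioSpec] | None = None,
    level: float = 0.95,
    cluster_adjust: bool = False,
) -> pd.DataFrame:
    """Long-format sensitivity table: one row per scenario and variant."""
    specs = scenario_catalog() if specs is None else list(specs)
    deff = cluster_design_effect(cohort) if cluster_adjust else 1.0
    rows = []
    results = [_baseline_result(cohort)] + [
        evaluate_scenario(cohort, s) for s in specs
    ]
    for result in results:
        for variant in ("A", "B"):
            est = scenario_sensitivity(result, variant, level, deff)
            rows.append(
                {
                    "scenario": result.name,
                    "variant": variant,
                    "tp": est.tp,
                    "fn": est.fn,
                    "sensitivity_pct": round_half_up(100 * est.point, 1),
                    "ci_low_pct": round_half_up(100 * est.ci_low, 1),
                    "ci_high_pct": round_half_up(100 * est.ci_high, 1),
                }
            )
    return pd.DataFrame(rows)
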