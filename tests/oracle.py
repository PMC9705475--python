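"""Naive one-exam-at-a-time reference evaluator.

Deliberately independent of the vectorised production engine: plain-Python
loops over :class:`Examination` objects, with its own band lookup and its
own top-fraction selection.  Used as the ground truth in equivalence tests.
"""

from __future__ import annotations

import math

from mammotriage import Cohort, Outcome, ReadingMode, ScenarioMode, ScenarioSpec


def naive_top_fraction(cohort: Cohort, rate: float) -> set[str]:
    exams = list(cohort.examinations())
    k = math.floor(rate * len(exams) + 0.5)
    ranked = sorted(exams, key=lambda e: (-e.ai_raw, e.exam_id))
    return {e.exam_id for e in ranked[:k]}


def _band_mode(spec: ScenarioSpec, ai_raw: float) -> ReadingMode:
    for band in spec.bands:
        if band.low < ai_raw <= band.high:
            return band.read
    raise AssertionError(f"no band covers {ai_raw}")


def naive_evaluate(cohort: Cohort, spec: ScenarioSpec) -> dict:
    """Per-exam counterfactual accounting, one examination at a time."""
    exams = list(cohort.examinations())
    if spec.mode is ScenarioMode.TRIAGE:
        ai_flagged: set[str] = set()
    elif spec.ai_score_cutoff is not None:
        ai_flagged = {e.exam_id for e in exams if e.ai_score >= spec.ai_score_cutoff}
    else:
        ai_flagged = naive_top_fraction(cohort, spec.ai_selection_rate)

    n_consensus = n_recall = n_sdc = n_ic_selected = 0
    for e in exams:
        r1_pos = e.r1_score >= 2
        r2_pos = e.r2_score >= 2
        if spec.mode is ScenarioMode.TRIAGE:
            mode = _band_mode(spec, e.ai_raw)
            if mode is ReadingMode.DOUBLE:
                selected = r1_pos or r2_pos
            elif mode is ReadingMode.SINGLE_R1:
                selected = r1_pos
            else:
                selected = False
            recalled = selected and e.recall
        elif spec.mode is ScenarioMode.AI_AS_READER:
            selected = r1_pos or (e.exam_id in ai_flagged)
            recalled = selected and e.recall
        else:  # AI_STANDALONE
            selected = e.exam_id in ai_flagged
            recalled = selected
        if selected:
            n_consensus += 1
            if e.outcome is Outcome.IC:
                n_ic_selected += 1
        if recalled:
            n_recall += 1
            if e.outcome is Outcome.SDC:
                n_sdc += 1
    return {
        "n_consensus": None
        if spec.mode is ScenarioMode.AI_STANDALONE
        else n_consensus,
        "n_recall": n_recall,
        "n_sdc": n_sdc,
        "n_ic_selected": n_ic_selected,
    }
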