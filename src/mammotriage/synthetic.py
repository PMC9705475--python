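"""Synthetic screening cohorts with study-like marginal structure.

The generator emulates a biennial double-reading screening programme:
~123k examinations from ~48k women (2-3 exams each), per-reader positive
rate 5.8%, consensus 8.8%, recall 3.2%, screen-detected cancer (SDC)
6.1 per 1000 exams and interval cancer (IC) 1.7 per 1000, with cancers
concentrated at high AI scores.  The two readers' positivity on the same
examination is a correlated Bernoulli pair (2x2 joint table parameterised
by the phi correlation), which is what makes the consensus rate (union of
positives) smaller than the independence value ``1 - (1 - p)^2``.

:func:`calibrate_params` inverts the generative model analytically so that
named marginal targets are hit in expectation; :class:`CohortParams`'s
defaults are the calibrated solution for the study targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np

from ._util import CalibrationError
from .cohort import COLUMNS, Cohort, Outcome

import pandas as pd

__all__ = [
    "CohortParams",
    "CalibrationTargets",
    "STUDY_TARGETS",
    "generate_cohort",
    "calibrate_params",
    "expected_rates",
]

_UNIFORM_DECILES = (0.1,) * 10

#: Default AI-decile distribution for SDC exams: mass concentrated at the top,
#: shaped so that band-restricted triage retains SDC shares like the study's
#: (about 97.8% at scores 6-10, 95.6% at 8-10, 86.8% at score 10).
_SDC_DECILES = (
    0.0044, 0.0044, 0.0044, 0.0044, 0.0044,
    0.011, 0.011, 0.038, 0.050, 0.868,
)

#: Default AI-decile distribution for IC exams: intermediate concentration —
#: interval cancers are enriched at high scores but far less than SDC.
_IC_DECILES = (0.05, 0.05, 0.05, 0.05, 0.05, 0.07, 0.08, 0.10, 0.15, 0.35)

#: How positive reader scores spread over 2..5. Only the >=2 threshold matters
#: downstream; the spread exists so files look like real interpretation data.
_POSITIVE_SCORE_DIST = (0.55, 0.25, 0.13, 0.07)


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for a synthetic screening cohort.

    The reader-model defaults are the :func:`calibrate_params` solution for
    :data:`STUDY_TARGETS` (per-reader 5.8%, consensus 8.8%, recall 3.2%,
    SDC 6.1/1000, IC 1.7/1000, 23% of SDC positive by one reader only).

    Parameters
    ----------
    n_exams
        Total examinations to generate.
    exams_per_woman
        Distribution over exams per woman; default gives ~47,877 women for
        the default ``n_exams`` (mean 122969/47877 ~ 2.568 exams/woman).
    sdc_rate, ic_rate
        Per-exam prevalence of screen-detected and interval cancer.
    score_dist_negative, score_dist_sdc, score_dist_ic
        Probability vectors over AI deciles 1..10 per outcome class.
    reader_positive_rate
        P(reader score >= 2) on a non-cancer exam.
    reader_sensitivity
        P(reader score >= 2) on an SDC exam (before conditioning on the
        at-least-one-positive constraint that recall imposes).
    reader_positive_rate_ic
        P(reader score >= 2) on an IC-prior exam.
    reader_correlation
        Phi correlation between the two readers' positivity (shared across
        outcome classes).
    recall_given_consensus_negative
        P(recall | consensus) for non-cancer exams (the false-positive rate
        of consensus meetings).
    ic_recall_fraction
        P(recall | consensus) for IC-prior exams; default 0 (IC exams are
        screening negatives; a small positive value models the
        false-positive-then-interval-cancer pathway).
    """

    n_exams: int = 122_969
    exams_per_woman: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.4315, 3: 0.5685}
    )
    sdc_rate: float = 0.00611
    ic_rate: float = 0.00167
    score_dist_negative: tuple[float, ...] = _UNIFORM_DECILES
    score_dist_sdc: tuple[float, ...] = _SDC_DECILES
    score_dist_ic: tuple[float, ...] = _IC_DECILES
    reader_positive_rate: float = 0.05276939590
    reader_sensitivity: float = 0.77913384259
    reader_positive_rate_ic: float = 0.14
    reader_correlation: float = 0.41166403966
    recall_given_consensus_negative: float = 0.31752103724
    ic_recall_fraction: float = 0.0
    positive_score_dist: tuple[float, ...] = _POSITIVE_SCORE_DIST
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("score_dist_negative", "score_dist_sdc", "score_dist_ic"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (10,) or abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise CalibrationError(
                    f"{name} must be 10 nonnegative probabilities summing to 1"
                )
        v = np.asarray(self.positive_score_dist, dtype=float)
        if v.shape != (4,) or abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
            raise CalibrationError(
                "positive_score_dist must be 4 probabilities (scores 2..5) summing to 1"
            )
        w = dict(self.exams_per_woman)
        if not w or abs(sum(w.values()) - 1.0) > 1e-9 or any(
            k < 1 or p < 0 for k, p in w.items()
        ):
            raise CalibrationError("exams_per_woman must be a distribution over k >= 1")
        for name in (
            "sdc_rate",
            "ic_rate",
            "reader_positive_rate",
            "reader_sensitivity",
            "reader_positive_rate_ic",
            "recall_given_consensus_negative",
            "ic_recall_fraction",
        ):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise CalibrationError(f"{name}={r} outside [0, 1]")
        if self.sdc_rate + self.ic_rate >= 1.0:
            raise CalibrationError("sdc_rate + ic_rate must be < 1")
        # The joint reader table must be a probability table for every class.
        for p in (
            self.reader_positive_rate,
            self.reader_sensitivity,
            self.reader_positive_rate_ic,
        ):
            _joint_table(p, self.reader_correlation)


@dataclass(frozen=True)
class CalibrationTargets:
    """Marginal rates :func:`calibrate_params` should reproduce in expectation."""

    reader_positive_rate: float = 0.058
    consensus_rate: float = 0.088
    recall_rate: float = 0.032
    sdc_rate: float = 0.00611
    ic_rate: float = 0.00167
    single_reader_sdc_fraction: float = 0.23


#: The study-sample marginals used for the default cohort.
STUDY_TARGETS = CalibrationTargets()


# ---------------------------------------------------------------------------
# Correlated Bernoulli pair machinery
# ---------------------------------------------------------------------------

def _joint_table(p: float, rho: float) -> tuple[float, float, float, float]:
    """(P00, P01, P10, P11) for two Bernoulli(p) with phi correlation rho."""
    q = 1.0 - p
    p11 = p * p + rho * p * q
    p10 = p * q * (1.0 - rho)
    p00 = q * q + rho * p * q
    cells = (p00, p10, p10, p11)
    if min(cells) < -1e-12:
        raise CalibrationError(
            f"reader correlation {rho:.4f} infeasible for marginal {p:.4f} "
            "(negative joint probability)"
        )
    return tuple(max(c, 0.0) for c in cells)  # type: ignore[return-value]


def _p_any(p: float, rho: float) -> float:
    """P(at least one of the pair positive)."""
    p00, *_ = _joint_table(p, rho)
    return 1.0 - p00


def _draw_pairs(
    rng: np.random.Generator, n: int, p: float, rho: float, condition_any: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated positivity pairs; optionally condition on >=1 positive."""
    p00, p01, p10, p11 = _joint_table(p, rho)
    probs = np.array([p00, p01, p10, p11])
    if condition_any:
        probs[0] = 0.0
        total = probs.sum()
        if total <= 0:
            raise CalibrationError(
                "cannot condition on a positive reader with zero positivity mass"
            )
        probs = probs / total
    cells = rng.choice(4, size=n, p=probs)
    return (cells >= 2), (cells % 2 == 1)  # r1 positive, r2 positive


# ---------------------------------------------------------------------------
# Closed-form marginals (used by calibration and tests)
# ---------------------------------------------------------------------------

def expected_rates(params: CohortParams) -> dict[str, float]:
    """Exact model-implied marginal rates for the given parameters.

    Keys: ``reader_positive_rate`` (per-reader, all exams), ``consensus_rate``,
    ``recall_rate``, ``sdc_rate``, ``ic_rate``, ``single_reader_sdc_fraction``
    (share of SDC positive by exactly one reader).
    """
    rho = params.reader_correlation
    f_sdc, f_ic = params.sdc_rate, params.ic_rate
    f_neg = 1.0 - f_sdc - f_ic

    p_sdc = params.reader_sensitivity
    u = 1.0 - p_sdc
    any_sdc = _p_any(p_sdc, rho)
    # Marginal per-reader positivity for SDC exams after conditioning on >=1.
    m_sdc = p_sdc / any_sdc if any_sdc > 0 else 1.0
    one_only = 2 * p_sdc * u * (1 - rho) / any_sdc if any_sdc > 0 else 0.0

    c_neg = _p_any(params.reader_positive_rate, rho)
    c_ic = _p_any(params.reader_positive_rate_ic, rho)

    reader = (
        f_neg * params.reader_positive_rate
        + f_sdc * m_sdc
        + f_ic * params.reader_positive_rate_ic
    )
    consensus = f_neg * c_neg + f_sdc * 1.0 + f_ic * c_ic
    recall = (
        f_sdc
        + f_neg * c_neg * params.recall_given_consensus_negative
        + f_ic * c_ic * params.ic_recall_fraction
    )
    return {
        "reader_positive_rate": reader,
        "consensus_rate": consensus,
        "recall_rate": recall,
        "sdc_rate": f_sdc,
        "ic_rate": f_ic,
        "single_reader_sdc_fraction": one_only,
    }


def calibrate_params(
    targets: CalibrationTargets, base: CohortParams | None = None
) -> CohortParams:
    """Solve the reader model so the generated marginals hit the targets.

    The model is inverted in closed form with a short fixed-point loop
    (the equations couple only weakly through the rare cancer classes):

    1. the SDC reader rate ``p_s`` solves the detected-by-one-reader-only
       share ``2 p_s (1-p_s)(1-rho) / P(any) = t`` given the correlation;
    2. the non-cancer reader rate makes the overall per-reader positive
       rate match;
    3. the correlation ``rho`` solves the consensus (union) rate, linear
       in ``rho``;
    4. the recall probability at consensus matches the recall rate.

    Raises :class:`CalibrationError` when the targets are jointly
    infeasible, e.g. a consensus target above the two-reader union bound.
    """
    base = base or CohortParams()
    r = targets.reader_positive_rate
    c = targets.consensus_rate
    f_sdc, f_ic = targets.sdc_rate, targets.ic_rate
    f_neg = 1.0 - f_sdc - f_ic
    p_ic = base.reader_positive_rate_ic
    t = targets.single_reader_sdc_fraction

    if c > 2 * r - r * r + 1e-12:
        raise CalibrationError(
            f"consensus target {c:.4f} exceeds the union bound "
            f"2r - r^2 = {2 * r - r * r:.4f} for reader rate {r:.4f}"
        )
    if c < r - 1e-12:
        raise CalibrationError(
            f"consensus target {c:.4f} below the per-reader rate {r:.4f} "
            "(unreachable even with perfectly agreeing readers)"
        )

    rho = base.reader_correlation
    p_neg = r
    p_s = base.reader_sensitivity
    for _ in range(200):
        # (1) SDC reader rate from the one-reader-only share, given rho.
        # one_only = 2u(1-rho) / (1 + (1-rho)u) with u = 1 - p_s.
        u = t / ((1.0 - rho) * (2.0 - t)) if rho < 1.0 else 0.0
        if not 0.0 <= u < 1.0:
            raise CalibrationError(
                f"single-reader SDC fraction {t} infeasible at correlation {rho:.4f}"
            )
        p_s = 1.0 - u
        m_sdc = 1.0 / (1.0 + (1.0 - rho) * u)
        # (2) non-cancer reader rate from the overall per-reader marginal.
        p_neg_new = (r - f_sdc * m_sdc - f_ic * p_ic) / f_neg
        if not 0.0 < p_neg_new < 1.0:
            raise CalibrationError(
                "per-reader target infeasible after removing the cancer-class share"
            )
        # (3) correlation from the consensus rate: linear in rho.
        #   c = f_neg * (2p - p^2 - rho p(1-p)) + f_sdc + f_ic * (...)
        a0 = (
            f_neg * (2 * p_neg_new - p_neg_new**2)
            + f_sdc
            + f_ic * (2 * p_ic - p_ic**2)
        )
        a1 = f_neg * p_neg_new * (1 - p_neg_new) + f_ic * p_ic * (1 - p_ic)
        rho_new = (a0 - c) / a1
        if not -1.0 <= rho_new <= 1.0:
            raise CalibrationError(
                f"consensus target {c:.4f} requires reader correlation "
                f"{rho_new:.3f} outside [-1, 1]"
            )
        _joint_table(p_neg_new, rho_new)  # feasibility of the joint table
        if abs(rho_new - rho) < 1e-12 and abs(p_neg_new - p_neg) < 1e-12:
            rho, p_neg = rho_new, p_neg_new
            break
        rho, p_neg = rho_new, p_neg_new
    # (4) recall probability at consensus for non-cancer exams.
    c_neg = _p_any(p_neg, rho)
    c_ic = _p_any(p_ic, rho)
    numer = (
        targets.recall_rate - f_sdc - f_ic * c_ic * base.ic_recall_fraction
    )
    denom = f_neg * c_neg
    if denom <= 0 or not 0.0 <= numer / denom <= 1.0:
        raise CalibrationError(
            f"recall target {targets.recall_rate:.4f} infeasible: implied "
            "P(recall | consensus) outside [0, 1]"
        )
    return replace(
        base,
        sdc_rate=f_sdc,
        ic_rate=f_ic,
        reader_positive_rate=p_neg,
        reader_sensitivity=p_s,
        reader_correlation=rho,
        recall_given_consensus_negative=numer / denom,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _allocate_women(
    rng: np.random.Generator, params: CohortParams
) -> np.ndarray:
    """Return the woman index of each exam; women sized per exams_per_woman."""
    sizes = np.array(sorted(params.exams_per_woman), dtype=np.int64)
    probs = np.array([params.exams_per_woman[int(k)] for k in sizes])
    mean = float((sizes * probs).sum())
    n_women_guess = int(params.n_exams / mean * 1.05) + 16
    draws = rng.choice(sizes, size=n_women_guess, p=probs)
    while draws.sum() < params.n_exams:  # pragma: no cover - guess suffices
        draws = np.concatenate([draws, rng.choice(sizes, size=1024, p=probs)])
    cum = np.cumsum(draws)
    n_women = int(np.searchsorted(cum, params.n_exams)) + 1
    draws = draws[:n_women]
    draws[-1] -= int(cum[n_women - 1] - params.n_exams)  # trim the last woman
    return np.repeat(np.arange(n_women), draws)


def generate_cohort(params: CohortParams | None = None) -> Cohort:
    """Generate a valid synthetic cohort; identical seed gives identical output.

    Stages (each on its own random substream, so adding a stage never
    perturbs earlier draws): woman allocation; outcome per exam; AI decile
    from the outcome's score distribution then ``ai_raw`` uniform within the
    decile; correlated reader pair conditional on outcome (SDC conditioned
    on at least one positive reader); consensus from the >=2 rule; recall
    (forced for SDC, Bernoulli at consensus otherwise).
    """
    params = params or CohortParams()
    streams = np.random.SeedSequence(params.seed).spawn(6)
    rng_women, rng_outcome, rng_decile, rng_raw, rng_readers, rng_recall = (
        np.random.default_rng(s) for s in streams
    )

    woman_idx = _allocate_women(rng_women, params)
    n = params.n_exams

    f_neg = 1.0 - params.sdc_rate - params.ic_rate
    outcome_code = rng_outcome.choice(
        3, size=n, p=[f_neg, params.sdc_rate, params.ic_rate]
    )  # 0 NEGATIVE, 1 SDC, 2 IC

    decile = np.empty(n, dtype=np.int64)
    dists = (
        params.score_dist_negative,
        params.score_dist_sdc,
        params.score_dist_ic,
    )
    for code, dist in enumerate(dists):
        mask = outcome_code == code
        decile[mask] = rng_decile.choice(10, size=int(mask.sum()), p=dist) + 1
    # ai_raw in (decile - 1, decile]: decile minus U[0, 1).
    ai_raw = decile - rng_raw.random(n)

    r1_pos = np.empty(n, dtype=bool)
    r2_pos = np.empty(n, dtype=bool)
    class_p = (
        params.reader_positive_rate,
        params.reader_sensitivity,
        params.reader_positive_rate_ic,
    )
    for code, p in enumerate(class_p):
        mask = outcome_code == code
        r1_pos[mask], r2_pos[mask] = _draw_pairs(
            rng_readers,
            int(mask.sum()),
            p,
            params.reader_correlation,
            condition_any=(code == 1),  # SDC must reach consensus
        )

    # Positive readings get a score in 2..5, negative readings score 1.
    score_choices = np.arange(2, 6)
    r1_score = np.ones(n, dtype=np.int64)
    r2_score = np.ones(n, dtype=np.int64)
    r1_score[r1_pos] = rng_readers.choice(
        score_choices, size=int(r1_pos.sum()), p=params.positive_score_dist
    )
    r2_score[r2_pos] = rng_readers.choice(
        score_choices, size=int(r2_pos.sum()), p=params.positive_score_dist
    )

    consensus = r1_pos | r2_pos
    recall = np.zeros(n, dtype=bool)
    recall[outcome_code == 1] = True
    u = rng_recall.random(n)
    neg_mask = (outcome_code == 0) & consensus
    recall[neg_mask] = u[neg_mask] < params.recall_given_consensus_negative
    ic_mask = (outcome_code == 2) & consensus
    recall[ic_mask] = u[ic_mask] < params.ic_recall_fraction

    width = len(str(max(n, 1)))
    outcome = np.array(
        [Outcome.NEGATIVE.value, Outcome.SDC.value, Outcome.IC.value]
    )[outcome_code]
    df = pd.DataFrame(
        {
            "exam_id": [f"E{i:0{width}d}" for i in range(n)],
            "woman_id": [f"W{w:0{width}d}" for w in woman_idx],
            "ai_raw": ai_raw,
            "ai_score": decile,
            "r1_score": r1_score,
            "r2_score": r2_score,
            "consensus": consensus,
            "recall": recall,
            "outcome": outcome,
        },
        columns=COLUMNS,
    )
    return Cohort(df)


def params_to_dict(params: CohortParams) -> dict:
    """JSON/YAML-serialisable form of the parameters (provenance sidecars)."""
    d = asdict(params)
    d["exams_per_woman"] = {int(k): float(v) for k, v in d["exams_per_woman"].items()}
    for k in ("score_dist_negative", "score_dist_sdc", "score_dist_ic",
              "positive_score_dist"):
        d[k] = [float(x) for x in d[k]]
    return d


def params_from_dict(d: Mapping) -> CohortParams:
    """Inverse of :func:`params_to_dict`."""
    d = dict(d)
    if "exams_per_woman" in d:
        d["exams_per_woman"] = {int(k): float(v) for k, v in d["exams_per_woman"].items()}
    for k in ("score_dist_negative", "score_dist_sdc", "score_dist_ic",
              "positive_score_dist"):
        if k in d:
            d[k] = tuple(float(x) for x in d[k])
    return CohortParams(**d)
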