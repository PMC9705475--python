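import numpy as np
import pytest

from mammotriage import Cohort, Examination, Outcome

SIX_ROW_CSV = """\
exam_id,woman_id,ai_raw,ai_score,r1_score,r2_score,consensus,recall,outcome
E1,W1,0.5,1,1,1,0,0,NEGATIVE
E2,W1,3.2,4,1,1,0,0,NEGATIVE
E3,W2,9.4,10,3,4,1,1,SDC
E4,W2,6.2,7,3,1,1,0,IC
E5,W3,7.5,8,2,1,1,1,NEGATIVE
E6,W3,5.0,5,1,2,1,0,NEGATIVE
"""


@pytest.fixture
def six_row_file(tmp_path):
    path = tmp_path / "six.csv"
    path.write_text(SIX_ROW_CSV)
    return path


def _exam(eid, wid, raw, r1, r2, recall, outcome):
    import math

    return Examination(
        exam_id=eid,
        woman_id=wid,
        ai_raw=raw,
        ai_score=math.ceil(raw),
        r1_score=r1,
        r2_score=r2,
        consensus=(r1 >= 2 or r2 >= 2),
        recall=recall,
        outcome=Outcome(outcome),
    )


@pytest.fixture
def ten_exam_cohort():
    """Hand-built cohort straddling the score-5 triage cut.

    Contains one screen-detected cancer at a high raw score (recalled) and
    one interval cancer at raw score 6.2 with a positive first reader but
    no recall, plus false positives and consensus-only cases.
    """
    return Cohort.from_examinations(
        [
            _exam("A01", "W1", 1.2, 1, 1, False, "NEGATIVE"),
            _exam("A02", "W1", 4.8, 2, 1, False, "NEGATIVE"),
            _exam("A03", "W2", 5.5, 1, 1, False, "NEGATIVE"),
            _exam("A04", "W2", 6.2, 3, 1, False, "IC"),
            _exam("A05", "W3", 9.4, 4, 5, True, "SDC"),
            _exam("A06", "W3", 7.9, 2, 1, True, "NEGATIVE"),
            _exam("A07", "W4", 3.3, 1, 3, True, "NEGATIVE"),
            _exam("A08", "W4", 8.8, 1, 2, False, "NEGATIVE"),
            _exam("A09", "W5", 2.2, 1, 1, False, "NEGATIVE"),
            _exam("A10", "W5", 5.1, 1, 2, True, "NEGATIVE"),
        ]
    )


def random_cohort(rng: np.random.Generator, n: int) -> Cohort:
    """A random *valid* cohort for property tests (not study-calibrated)."""
    import math

    exams = []
    for i in range(n):
        raw = float(10.0 * (1.0 - rng.random()))
        r1 = int(rng.choice([1, 1, 1, 1, 2, 3, 4, 5]))
        r2 = int(rng.choice([1, 1, 1, 1, 2, 3, 4, 5]))
        consensus = r1 >= 2 or r2 >= 2
        recall = bool(consensus and rng.random() < 0.5)
        if recall and rng.random() < 0.3:
            outcome = "SDC"
        elif rng.random() < 0.08:
            outcome = "IC"
        else:
            outcome = "NEGATIVE"
        exams.append(
            Examination(
                exam_id=f"E{i:04d}",
                woman_id=f"W{i // 3:04d}",
                ai_raw=raw,
                ai_score=math.ceil(raw),
                r1_score=r1,
                r2_score=r2,
                consensus=consensus,
                recall=recall,
                outcome=Outcome(outcome),
            )
        )
    return Cohort.from_examinations(exams)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
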