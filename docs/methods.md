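# Methods

## Cohort model

An examination carries a continuous AI suspicion score `ai_raw` on the
half-open interval (0, 10] with decile `ai_score = ceil(ai_raw)`, two
reader interpretation scores in 1–5, consensus and recall flags, and an
outcome in {NEGATIVE, SDC, IC}. The raw-score scale is a repository
convention: vendors do not publish the raw scale, and fixing
`ai_score = ceil(ai_raw)` makes decile labels and sub-decile splits
well defined — "scores 1–5" is the band (0, 5], "6–7.5" is (5, 7.5],
"7.6–10" is (7.5, 10].

Hard invariants (checked by `validate_cohort`, enforced by strict reads):
consensus is true iff a reader scored ≥ 2; recall implies consensus; SDC
implies recall (screen-detected means diagnosed after recall). IC exams
may carry either recall value: a false-positive screen followed by an
interval cancer within 6–24 months is legitimate. In sensitivity
accounting an IC is always a miss at screening regardless of that flag.

Files are plain CSV (UTF-8, header, booleans 0/1). `ai_raw` is written
with the shortest round-tripping decimal and read back with
correctly-rounded parsing, so write-then-read is the identity bit for bit.
Strict reading is the default; lenient reading drops violating rows and
reports the count, which is useful for triaging third-party exports but
hides calibration errors if used routinely.

## Synthetic cohort generator

The generator draws, in order and on separate random substreams (so adding
a stage never perturbs earlier draws): women and exams-per-woman (2 or 3,
weighted to give ~47.9k women per 123k exams); an outcome per exam
(multinomial with SDC 6.11/1000, IC 1.67/1000); an AI decile from the
outcome's decile distribution, then `ai_raw` uniform within the decile;
the reader pair's positivity; positive scores spread over 2–5 (cosmetic —
only the ≥ 2 threshold matters downstream); consensus from the ≥ 2 rule;
and recall.

**Reader dependence.** The two readers' positivity on the same exam is a
correlated Bernoulli pair sampled from its 2×2 joint table, parameterised
by the phi (Pearson) correlation ρ. This is the minimal model constrained
by the data the accounting needs: per-reader marginals and the union
(consensus) rate. At the study marginals, independent readers at 5.8%
would produce a consensus rate of 1 − (1 − 0.058)² ≈ 11.3%; the observed
8.8% forces ρ > 0 (the calibrated value is ρ ≈ 0.412).

**SDC conditioning.** Screen-detected cancer is defined through recall, so
SDC exams are forced to recall and their reader pair is drawn conditional
on at least one positive (the (0,0) cell is zeroed and the table
renormalised). The per-reader rate on SDC exams is calibrated so that 23%
of SDC are positive by exactly one reader, a figure reported for the
source programme.

**Calibration.** `calibrate_params` inverts the model analytically with a
short fixed-point loop: the SDC reader rate from the one-reader-only share
given ρ; the non-cancer reader rate from the overall per-reader marginal;
ρ from the consensus rate (linear in ρ); and the consensus-to-recall
probability from the recall rate. Infeasible targets (consensus above the
union bound 2r − r², or below the per-reader rate) raise a
`CalibrationError` naming the violated bound. The frozen `CohortParams`
defaults are the solution for the study targets; `expected_rates` confirms
they reproduce all six targets to machine precision, and a 122,969-exam
generation recovers each within three binomial standard errors.

**Decile distributions.** The joint distribution of AI score and outcome
is not published for the source sample, so the per-outcome decile vectors
are parameters. Defaults: uniform for non-cancer exams (the AI's design
goal); SDC mass concentrated high (86.8% in decile 10, 95.6% in 8–10,
97.8% in 6–10 — chosen once from the band shares implied by the published
per-scenario detection counts); IC intermediate (35% in decile 10). These
defaults make detection fall as the double-read band narrows, matching the
qualitative ordering of the published scenario table.

**What the generator does not emulate.** (1) Raw scores are uniform
*within* a decile and independent of everything else given the decile.
Real AI scores rank cancers within the top decile too, so scenarios that
select a top *fraction* of raw scores (AI-as-reader at 5.8%, standalone at
3.2%) capture far fewer synthetic cancers than the study observed (the
study's standalone scenario kept 74% of SDC; the synthetic default keeps
roughly a third of that). Tests of those scenarios therefore check
accounting semantics, not effect sizes. (2) Reader positivity is
independent of the AI score given the outcome, whereas real readers and
AI respond to the same image features; synthetic consensus counts in
band-restricted scenarios are accordingly lower than the study's.
(3) No screening-round dependence within a woman beyond the shared
identifier, and no reader learning. Passing marginal-recovery tests shows
the calibration machinery is correct, not that the joint structure of real
screening data is reproduced.

## Scenario engine

Scenarios are declarative specs: TRIAGE (bands over (0, 10] mapped to
NEGATIVE / SINGLE_R1 / DOUBLE, validated to partition the interval),
AI_AS_READER (reader 1 plus an AI selection: a top fraction of raw scores
or a decile cutoff), AI_STANDALONE (AI selection is the recall set). The
built-in catalog has 11 entries: AI as second reader at the 5.8%
per-reader rate (S1) and at the decile-10 cutoff (S2); triage variants
(S3–S10); standalone AI at the 3.2% recall rate (S11).

Counterfactual semantics on retrospective double-read data: an exam is
consensus-selected when a reader who would still see it under the scenario
scored ≥ 2 (or AI flags it); scenario recalls are consensus-selected exams
that really were recalled; detected cancers are SDC among scenario
recalls; `n_ic_selected` counts ICs among consensus-selected exams
(selected-for-recall exams in the standalone case). Consequences worth
noting: scenario recalls are a subset of actual recalls for S1–S10, so
counts are monotone under band enlargement and reading-mode upgrades
(property-tested); in AI-as-reader scenarios, SDC selected by AI alone
count as detected, which may be optimistic — real consensus meetings could
dismiss an AI-only flag (surfaced as interpretation guidance, not a
computation); the standalone scenario has no consensus stage and its
consensus column is reported absent.

Top-fraction selection takes `k = round(rate × n)` exams (half-up) by
descending raw score, ties broken by ascending exam id — both choices are
conventions fixed for determinism. The decile-cutoff form of S2 is
primary; its ~10% selection share is an empirical consequence, not the
definition.

Volume reduction is `100 × (1 − (f_R1 + f_R2)/2)`; nominal fractions come
from exact band widths (each decile 10%, the 7.5 split 25%), empirical
fractions from a cohort. AI readings never count as human workload. The
value is returned unrounded; reports round half-up (62.5 → 63).

## Metrics

Sensitivity uses the logit-transformed interval: `L = ln(TP/FN)`,
`SE = √(1/TP + 1/FN)`, bounds `expit(L ∓ z·SE)` with z = 1.959964 at 95%.
This closed form reproduces the published baseline 78.6% (75.9–81.1) from
TP = 752, FN = 205 exactly after one-decimal half-up rounding, which is
why it is the package's verifiable default. When TP or FN is zero the
logit is undefined; the interval falls back to adding 0.5 to both counts,
pins the degenerate side to its boundary, keeps the raw point estimate,
and flags the result — reports stay total without hiding the boundary
case.

Variant A counts scenario SDC as TP (FN: missed SDC plus all IC); variant
B moves consensus-selected ICs from FN to TP. B ≥ A pointwise by
construction. Potential rates transfer selected ICs from the IC column to
the SDC column; potential-SDC + potential-IC ≡ (n_sdc + n_ic_total)/n per
cohort, an identity the tests assert exactly.

The published potential-rate CIs were adjusted for non-independent
observations by an unnamed method. Default here is the *unadjusted* logit
binomial interval (consistent with the verifiable sensitivity formula). A
documented cluster-aware option multiplies the squared SE by a design
effect `1 + (m̄ − 1)·ICC`, with the ICC estimated from the within-woman
one-way ANOVA on the 0/1 indicator and clamped so it can only widen an
interval; it is off by default and clearly labelled, and no claim is made
that it matches the original adjustment.

Reported tables round half-up: percentages and per-1000 rates to one
decimal, volume reductions to integers.

## Numerical and design choices

* Problem sizes in the default test run: marginal recovery at 100k exams
  (unit suite) and the full 122,969 (acceptance suite); engine-vs-oracle
  equivalence on 1000 random 50-exam cohorts; property sweeps on cohorts
  of 40–500 exams. The full suite runs in well under a minute.
* One master seed per generation, spawned into per-stage substreams
  (`numpy.random.SeedSequence`); identical parameters give byte-identical
  cohort files.
* The per-exam reference evaluator used to verify the vectorised engine
  lives in the test suite and shares no code with it.
* CLI exit codes: 0 success, 2 configuration, 3 cohort validation,
  4 calibration.

## Known limitations

Within-decile uniformity and reader–AI independence (above) are the two
substantive gaps between the generator and real screening data. The
framework itself is retrospective by construction: it cannot model how
radiologists would change behaviour when shown AI scores, and its
AI-as-reader detection counts assume consensus follows an AI-only flag as
often as a reader flag. Per-breast scores are collapsed to per-exam
maxima, matching the accounting unit but discarding laterality.
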