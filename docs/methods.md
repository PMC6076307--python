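# Methods

## The decision flow

A patient record moves through at most three gates. The questionnaire
pre-classifier produces two probabilities, one per disease; only if the
larger one *strictly* exceeds the triage threshold (default 50%) is
spirometry requested — at exactly the threshold the patient remains
healthy, reading the decision rule's "greater than" literally. A record
flagged suspect but lacking spirometry yields a decision requesting the
test (`tests_requested=["SPIR"]`), never an exception. The network then
classifies the five normalized inputs; any class other than INCONCLUSIVE
maps directly to a final category and severity (ASTHMAx → asthma/step x,
GOLDx → copd/stage x, NORMAL → healthy), and a bronchial test already on
record is ignored in that case — spirometry conclusiveness wins, matching
the flow's ordering. INCONCLUSIVE triggers a BDT/BPT request; with a test
on record the fuzzy classifier decides. If no fuzzy rule fires the system
reports "inconclusive — refer to a specialist" rather than forcing a
class.

`stage_reached` records the furthest stage a record entered; a record
terminated at triage is by construction healthy.

## Questionnaire scoring

The significance factors are weights, not probabilities; the
normalization constant `A_k = 1/Σ_j sf_jk` makes the score scale-free
(rescaling a disease column by any positive constant leaves the
probability unchanged — property-tested). No numeric factor table is
published, so the default table encodes the questionnaire's qualitative
directionality: questions pointing at COPD (age > 40, exertional
problems, sputum, morning wheeze) weight the COPD column 2 vs 1,
nocturnal cough and nocturnal/exertional wheeze weight asthma 2 vs 1, and
resting dyspnoea weights both 2. Question 1 is directional — affirmative
suggests COPD, negative suggests asthma — so the asthma column scores
`1−O_1` by default (`asthma_inverted_questions = {1}`, configurable).
All tests parameterize the table explicitly, so correctness never
depends on these defaults.

The pre-classification evaluation formulas are the signed error
`E_k = p_k^c − p_k` against the clinician probability and the ratio
accuracy `p_k/p_k^c × 100%`; the latter is undefined (an explicit error,
not 0 or ∞) when the clinician probability is zero.

## Severity staging

COPD requires airflow obstruction (Tiffeneau < 70%) and then stages by
percent-of-predicted FEV1 at the canonical 80/50/30 cutoffs; asthma
staging is gated on a positive reversibility/provocation result and uses
the classic four-step bands (≥ 80, 60–80, < 60). All bands are
left-closed and configurable. The published class list places both
ASTHMA1 and ASTHMA2 at FEV1 ≥ 80% predicted, distinguished clinically by
symptom frequency; since a spirometry measurement alone cannot carry that
information, `stage_asthma` takes an explicit `symptoms_rare` flag with
an objective default criterion (≤ 2 affirmative questionnaire answers).
With fixed flags the staging functions partition their domains — no
measurement maps to two stages.

`FEV1 ≤ FVC` is enforced with 1% relative tolerance to absorb device
rounding. Whether the network's fourth input is the Tiffeneau ratio or
percent-of-predicted is ambiguous in the source description; both are
carried on the measurement and the network consumes the **ratio** by
default.

## Network and training

Architecture: 5 inputs → N tanh hidden units → linear output. The
default output encoding is the literal one-neuron class index with
round-half-up and clamping to [0, 9]; an optional one-hot/argmax mode
exists in configuration because index regression imposes an artificial
ordering on the classes (NORMAL at code 8 sits numerically next to GOLD4
at 7, which costs accuracy near soft boundaries — see Limitations).

Min-max normalization bounds are fitted from the training cohort
(observed per-feature min/max), persisted inside the model document, and
applied with clipping at inference so out-of-range inputs cannot
extrapolate.

Levenberg–Marquardt: the flattened parameter vector is updated by
solving `(JᵀJ + λI)δ = −Jᵀe` with the analytic residual Jacobian
(verified against central finite differences to 1e−6 relative).
Schedule: λ₀ = 1e−3, ×10 on rejected steps, ÷10 on accepted ones, at
most 200 iterations, stopping on MSE ≤ 1e−8, gradient ≤ 1e−10, or when
no improving step exists up to λ = 1e12. Accepted-step MSE is
non-increasing by construction. Weights initialize uniform in
[−0.5, 0.5] from a seeded generator; identical seed, data and settings
reproduce bit-identical weights. Because the index-encoded 10-class
target is a hard regression surface, training uses multi-start (default
3 seeded restarts, keeping the lowest-MSE fit) — single-start LM lands in
poor local minima on some cross-validation folds.

Model selection: k-fold cross-validation (default k = 10; every sample
tested exactly once, fold sizes differing by at most one) over the
candidate hidden sizes {5, 10, 12, 14, 17, 20} — the union of the two
published candidate lists. Selection takes the smallest mean test MSE,
except that any smaller architecture within the configurable parsimony
margin of the best wins (ties to the smaller); with a margin of 0.084
this reproduces the published preference for 14 hidden neurons (mean MSE
12.569) over 17 (12.485).

## Fuzzy output classifier

No membership shapes or rule table are published; the defaults encode
guideline logic. Inputs are the *reversibility evidence* — the signed
FEV1 change after bronchodilator, or the negated fall after provocation,
so both tests point the same way — and the two questionnaire
probabilities. Probability terms are low / medium / high with
breakpoints 0–40–60–100; reversibility terms are low / high shouldered
at the 0–12% reversibility window. BDT positivity itself is the
guideline criterion FEV1 gain ≥ 12% **and** ≥ 200 mL; BPT positivity is a
fall of ≥ 20% (both configurable). The eight default rules send positive
reversibility to asthma, irreversible medium/high COPD scores to COPD,
and everything irreversible with a low COPD score to healthy. Inference
is Mamdani (min conjunction, consequent clipping, max aggregation) with
centroid defuzzification over a 0–100 output universe whose three
triangular terms center at 15/50/85; the centroid maps to the nearest
center *among terms that actually fired* (a bimodal aggregate must not
land on an unfired middle term), with ties broken healthy < asthma <
copd. The whole rule base is loadable from YAML and validated with
located errors.

## Synthetic cohorts

The generator emulates the validation population's class structure —
859:636:155 asthma:COPD:healthy out of 1650 (≈ 52/39/9%), severity
uniform within disease — with class-conditional Gaussians for
percent-predicted FEV1, Tiffeneau index, predicted FEV1 volume and a
VC/FVC ratio; Bernoulli symptom answers; and a Gaussian bronchodilator
response (mean +20% for asthma, +2% otherwise). Volumes derive as
`FEV1 = pct/100 × predicted`, `FVC = FEV1/(tiff/100)`, `VC = FVC × ratio`.
Each record is rejection-sampled (cap 1000 attempts) until it re-stages
to its own label under the staging rules, so ground truth is
self-consistent by construction and asserted in tests; an infeasible
spec raises a rejection-limit error rather than silently truncating.

Profiles: `separable` uses pairwise-disjoint percent-predicted windows
and nearly deterministic symptoms (a sanity ceiling — classifiers should
approach 100%); `hard` multiplies every spread by 1.6, flattens the
symptom contrast and widens the predicted-FEV1 spread. `realistic` is
defined by construction as overlapping class-conditional distributions
from which ≥ 90% of labels remain recoverable; its spreads and acceptance
windows (inset one to a few points from the raw guideline cutoffs) were
calibrated once to that construction and frozen. Measured held-out
recovery by the default index-encoded network is 94.5–97.4% across seeds.

What the generator does **not** model, hence what passing tests cannot
show about real data: demographic covariates (age, sex, medication),
partially reversible COPD (COPD and healthy records are rejection-sampled
to be bronchodilator-negative so labels stay unambiguous), correlated
symptom reporting, device/session variability beyond independent
Gaussian noise, and longitudinal visits. Mild intermittent asthma is
generated with genuinely sparse symptoms, so the 50% symptom-triage gate
misses much of it — end-to-end pipeline category accuracy (~80% on a
fresh realistic cohort) therefore sits well below the network's own
cross-validated recovery; the miss is a property of symptom-only
screening, not of the classifier.

## Evaluation

All statistics derive from the 2×2 disease-vs-healthy table: sensitivity
tp/(tp+fn), specificity tn/(tn+fp), accuracy, PPV, NPV, prevalence, and
the four complements (miss rate, FPR, FDR, false condition rate), which
satisfy exact complementarity identities; likelihood ratios use the
standard formulas LR+ = sensitivity/FPR and LR− = miss rate/specificity.
The published table's likelihood-ratio cells do not match these standard
formulas computed from its own printed counts (its LR+ ≈ the ratio of
the two printed percentages; its LR− does not correspond to any reading
we found); the standard definitions are implemented and the discrepancy
is noted, not imitated. Zero-denominator metrics surface as explicit
`None`/undefined, never 0. Percentages are kept at full precision;
`display` offers two-decimal rounding plus a truncation mode (96.666…%
prints as 96.66 under the source tables' apparent convention). The
triage table reports both the pooled correct/total percentage and the
unweighted row mean, which differ (96.31% vs 96.93% on the validation
tallies). Cost savings multiply correctly-triaged healthy patients by
the per-patient work-up cost (SPIR $60 + filter $1 + specialist visit
$100 + blood gas $10 by default).

## Problem sizes and numerical choices

The synthetic study uses cohorts of n = 1000 with k = 10 and 14 hidden
neurons (99 free parameters, ~900 training samples per fold), chosen to
mirror the scale at which the method is meaningful while each
cross-validation completes in seconds. Defuzzification integrates on a
1001-point grid. Fold seeds and restart seeds derive deterministically
from the user seed via `numpy` seed sequences, so every reported number
is bit-reproducible.

## Known limitations

* The index output encoding is faithful to the published architecture
  but strictly worse than one-hot/argmax near class boundaries; the
  alternative is available behind `ann.output_encoding: onehot`.
* The default significance factors, membership functions and rule base
  are guideline-shaped engineering defaults, not fitted quantities.
* The published headline accuracies were measured on a real two-year
  hospital cohort that is not deposited; synthetic-data results
  characterize the algorithms, not clinical performance.
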