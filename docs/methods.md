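# Methods

## Scope and model

`gaittwin` models one assessment point (independent walking at 24 months
corrected age, "T24") of a preterm/full-term toddler cohort. A child is
"high-risk" iff gestational age ≤ 28 weeks or birth weight ≤ 1000 g; all
other children (moderately preterm and full-term) are "low-risk". The
pipeline is four stages — cohort/signal simulation, gait-metric extraction,
twin-record storage, risk analysis — each usable on its own; the simulator
exists so that every downstream computation is testable against exact ground
truth without access to any clinical recording.

## Synthetic cohort

Covariates are configuration, not claims about any real sample. Defaults:

* Preterm GA ~ 23 + 13·Beta(1.4, 1) weeks — skewed toward late preterm,
  which dominates clinically; full-term GA ~ N(39.5, 1.0) clipped to
  [37.5, 42]. With 29 preterm + 17 full-term this yields an expected
  high-risk count of ≈ 8 of 46.
* Birth weight | GA is linear-Gaussian: mean 500 g + 180 g/week above
  22 weeks, SD 250 g, floored at 350 g. The risk label is assigned from the
  stored (rounded) GA and birth weight so the rule holds exactly on the
  serialized table.
* Anthropometry at 24 months, walking experience and cognitive score are
  Gaussian with small high-risk deficits; twins are over-represented in the
  preterm group (20% vs 3%).
* Per-child random streams are derived by SHA-256 hashing of
  (master seed, child id, stream name), so records are reproducible and
  independent of cohort size or generation order.

## Gait-signal model

Signals are phenomenological, not musculoskeletal. A trial is a sequence of
gait cycles with i.i.d. Gaussian stride durations (default mean 0.95 s,
SD 0.03 s, fs = 100 Hz, 60 s — roughly 60 strides, enough for stable
entropy/recurrence estimates while keeping a 200-child run in minutes).
Within each cycle of duration c:

* left heel strike at the cycle start; right heel strike at phase
  φ = 1/(1+a), where a is the left/right step-time ratio (a = 1 ⇒ φ = 0.5);
* toe-offs at the stance fraction s of each leg's own stride (default 0.64,
  i.e. double support 2(s − 0.5) = 28% of the stride for symmetric gait,
  toddler-like);
* shank angular velocity = a positive mid-swing Gaussian bump (300 deg/s)
  with negative dips placed exactly at toe-off and heel-strike times, plus
  white noise — so events are recoverable to one sample on clean signals;
* trunk acceleration per axis = Σ_k A_k sin(2π k θ) on the stride's own
  phase θ, plus white noise. Defaults are even-dominant for the vertical and
  antero-posterior axes and odd-dominant for the medio-lateral axis,
  mirroring the biphasic/monophasic structure of real trunk accelerations.
  The broadband component defaults to ~10% of the harmonic amplitude scale;
  real complexity in trunk signals is stride-shape variability rather than
  white noise, so sample-entropy levels here should be read relatively
  (between groups), not as absolute physiological values.

High-risk children differ by configurable effect sizes, defaulting to the
direction pattern the analyses are designed to detect: +0.10 s stride time,
×1.8 stride-time SD, +4 points double support %, ×1.5 harmonic amplitudes,
×0.4 broadband noise (more periodic, less complex, slower, less stable).
Because these effects are injected, "passing" the recovery tests shows the
pipeline recovers what was put in — it says nothing about effect sizes in
real cohorts.

A note on symmetry: for any interleaved event stream both legs span the same
walking interval with the same stride count, so per-leg *stride-time means*
are equal by construction and the stride-symmetry index is ≈ 0 for any
generator that keeps events interleaved. Timing asymmetry is therefore
injected into, and recovered from, *step* times; the symmetry formula
(100·|mean_L − mean_R| / leg average) itself is verified exactly on
constructed per-leg inputs.

## Event detection and temporal parameters

Sagittal shank angular velocity (auto-selected as the maximal-variance gyro
channel) is band-passed 0.5–10 Hz (4th-order zero-phase Butterworth).
Mid-swings are peaks above 50 deg/s separated by ≥ 0.4 s; heel strike is the
most prominent minimum 0.05–0.4 s after a mid-swing, toe-off the most
prominent minimum 0.05–0.4 s before it. All thresholds are configuration.

Stride time is the ipsilateral heel-strike interval; step time the
ipsilateral-to-contralateral interval; stance% the ipsilateral toe-off delay
as % of the stride; double support% the sum of the two bilateral-contact
intervals as % of the stride. Dimensionless times divide by √(L/g) with L
the body length at assessment (Hof normalization); if L is unknown the
normalized values are omitted with a warning.

Poincaré SD1 uses the RMSSD convention (uncentered mean square of successive
differences over 2) and std/SD2 the population (1/N) variance, making
SD1² + SD2² = 2·std² an exact identity; SD2 is floored at 0 in the
pathological strongly anticorrelated case, which is the only case where the
identity can fail. Centered difference variance was rejected because it
breaks the closed form for alternating series of odd difference count.
Poincaré indices are computed on temporally ordered sequences (left-leg
stride times, interleaved step times, left-stride double-support values).

## Complexity metrics

* **Harmonic ratio**: per stride, Fourier amplitudes at harmonics 1..20 of
  that stride's own fundamental (the stride spans exactly one period, so
  harmonic k is DFT bin k of the stride segment); even/odd amplitude-sum
  ratio for V and AP, odd/even for ML; mean over strides. Only the stride
  mean (DC) is removed before the transform: a least-squares linear detrend
  over a single period has systematically non-zero slope against odd
  harmonics and provably leaks power across bins. Near-zero denominators are
  capped (default 50) with a warning.
* **Sample entropy**: m = 2, r = 0.2 × SD, Chebyshev distance, self-matches
  excluded, both template lengths counted over the same index range.
  Counting goes through a KD-tree under the max norm and is exactly equal to
  the O(N²) double loop (asserted to 1e-12 against an independent dense
  implementation in the tests). A = 0 or B = 0 yields NaN with a warning.
* **Multiscale entropy**: coarse-graining by non-overlapping means at scales
  1..6, r fixed from the scale-1 SD (the original convention; per-scale
  rescaling is one config flag away). Scales too short for the embedding
  yield NaN for that scale only.
* **RQA**: embedding (5, 10 samples), Euclidean radius 0.2 × SD, Theiler
  window 1, minimal line length 2. Recurrent pairs are enumerated sparsely
  (KD-tree) and diagonal lines obtained by run-length encoding over pair
  offsets; statistics are computed on the upper triangle. RR is the fraction
  of admissible pairs recurring, DET the fraction of recurrent points on
  diagonals ≥ lmin, AvgL their mean length. A zero-variance series returns
  the degenerate convention RR = DET = 1 with AvgL the longest possible
  diagonal.

Gestational age and birth weight are never features — they define the label.

## Twin records

Documents mirror FHIR Patient/Observation shapes without claiming release
conformance: one bundle per child-timepoint, a local `GT-*` code system
(a production system would bind SNOMED-CT/LOINC), units in UCUM style, the
fixed T0–T24 timepoint vocabulary, and clinical domains without numeric
payload in this cohort (brain imaging, nutrition, pregnancy/delivery, NICU
stay) recorded as presence flags. Subjects are pseudonymised with a keyed
HMAC-SHA256 (16 hex chars); tests sweep every serialized byte stream for raw
identifiers. Turtle output is canonicalised by sorting triples, so reparse +
reserialize is byte-identical. The knowledge graph types instances against
six concept classes (Child, Examination, MotorTask, Metric, RiskFactor,
Timepoint) with has_assessment / measured_by / at_timepoint /
has_risk_factor edges.

## Risk analysis

Min-max scaling to [0, 1] (constant features map to 0 with a warning),
mean/median imputation with retained masks, inverse-frequency class weights
w_c = n/(k·n_c), and SMOTE by convex interpolation between k = 5 minority
neighbours. All statistics are fit on the training partition only; SMOTE
never touches test rows (asserted by corrupting test rows and observing
identical training-side results).

Clustering: k-means, k = 2, 30 runs with derived seeds, labels matched to
the first run by centroid proximity, consensus by per-sample majority.
"Feature importance" for a 2-cluster solution is the absolute scaled-centroid
difference per feature, mean ± SD over the 30 runs — deterministic, and
directly renderable as the usual heatmap; KDE (Gaussian, Silverman bandwidth)
is attached for the top-5 features. t-SNE (perplexity 10) is QC-only and
reported with a 5-NN neighbourhood-preservation score.

Classification: stratified 75/25 split; randomized search (default 15
draws) over small per-learner grids, scored by balanced accuracy under
stratified 5-fold CV (folds reduce with a warning when the minority class is
smaller); evaluation on the held-out test set with Acc, BA, precision,
recall, F1, MCC (documented zero conventions for empty denominators) and
rank-statistic AUC (ties half credit). Printed-table comparisons round
half-up at 2 decimals. `confusion_from_metrics` exhaustively searches
integer confusion matrices consistent with printed Acc/precision/recall and
refuses ambiguous or unsolvable inputs.

Attribution defaults to permutation importance (mean balanced-accuracy drop
over 30 shuffles) with a direction sign from the feature/score correlation;
XGBoost's exact additive contributions are available behind `exact=True`.

## Problem sizes and determinism

Default experiment sizes: 46 children for cohort-composition checks, 60
(30 vs 30) for effect-direction recovery, 200 for the end-to-end run —
chosen so the full pipeline completes in a few minutes on one CPU while
keeping group contrasts well out of sampling noise. Everything downstream of
the master seed is deterministic; twin documents embed a fixed creation
timestamp when byte-reproducibility is required.

## Known limitations

* The signal model has no spatial gait parameters, turning, or non-walking
  tasks; complexity enters only through white noise and timing jitter, so
  absolute entropy levels are not physiological.
* Stride-symmetry asymmetry cannot be injected (see above); the index is
  exposed but will be ≈ 0 on all simulated gait.
* The twin layer is FHIR-flavoured, not FHIR-conformant; no server, no
  ontology reasoning, no SWRL rules.
* Classification results on synthetic cohorts with injected effects are
  near-ceiling by construction; they validate plumbing and leakage-freedom,
  not clinical performance.
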