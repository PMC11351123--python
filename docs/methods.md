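# Methods

This note documents the model, the numerical choices, the defaults that
matter, and what the synthetic tests do and do not establish.

## Association substrate

All inference runs on categorical attribute values (AVs). Numeric
attributes are binned first:

- **Clinical schemes** use printed cut points (e.g. heart rate
  <60 / 60–100 / >100 bpm; GCS 3–8 / 9–12 / 13–15). Interval
  membership: the first range is open above, later ranges are closed
  above, so a value on a shared boundary (systolic 90) belongs to the
  range whose closed printed interval contains it (Normal). Values
  outside declared closed bounds are rejected; missing values become an
  explicit `missing` category (no imputation, no row drops).
- **Equal-frequency binning** (default 3 bins) sorts the non-missing
  values and cuts at the last member of each ideal bin; every value
  equal to a cut falls in the lower bin, so ties never split and the
  result is independent of record order. Heavy ties can empty a bin;
  the realized occupancies are reported through the fitted scheme, not
  corrected.

The association between two AVs is the Haberman adjusted standardized
residual (see README for the formula). The denominator carries a square
root so the statistic has unit variance under independence — this is
what makes the 1.96 gate a ~95% normal quantile. Cells with a vanishing
denominator (expected count 0, or a marginal equal to N) are set to 0
and flagged rather than propagated as infinities. Same-attribute pairs
and the diagonal are structural zeros: a record holds one category per
attribute, so their co-occurrence is impossible and computing them
would distort the decomposition.

Label AVs are included in the SR-matrix by default. This is what gives
disentangled units a direct, readable class association; pass
`include_label=False` for a fully label-blind run (class association
then relies on the enrichment fallback below).

## Disentanglement

The SR-matrix is symmetric, so its eigendecomposition gives the unique
additive rank-one split SR = Σ λ_k v_k v_kᵀ; RSR_k = λ_k v_k v_kᵀ is
the per-component reconstructed matrix. Components are kept when
max |RSR_k| (outside the structural zeros) reaches the significance
threshold (default 1.96, configurable). Eigenvector signs are
canonicalized (largest-|loading| entry positive) so group numbering is
deterministic; eigenvalues below 1e-10 of the spectral radius are
dropped as numeric noise.

On a retained component, an AV that has at least one partner with
|RSR| ≥ threshold joins the extremal group matching its loading sign;
AVs with no significant partner project near the origin and are set
aside. Groups are subdivided by average-linkage agglomerative
clustering on 1 − Jaccard overlap of the records each AV covers, cut at
distance 0.8. The cut matters: for a minority class at prevalence π
with per-attribute carriage probability p, the expected Jaccard between
two same-source AVs scales roughly like πp² / (2p − πp²); at π ≈ 0.24
and p ≈ 0.73 this is ~0.35, so a 0.5 cut would shatter the minority
group into singletons and the minority class would never grow patterns.
0.8 keeps same-source AVs together while AVs living on disjoint record
subsets (distance ≈ 1) still separate.

**Class association.** A label AV among a unit's members decides
directly. Otherwise the unit's covered entities vote — but by
*enrichment over global prevalence* (share − prevalence > margin,
default 0.1), not absolute majority: under imbalance the majority class
dominates every cover, and an absolute-majority rule fabricates
majority-class associations for minority-flavored units. A 50/50 cover
in a balanced dataset has zero enrichment and yields no association
("rare patterns not associated with any class"). After pattern growth,
each patterned unit's entity set is tightened from "holds ≥ 1 member
AV" to "possesses ≥ 1 comprehensive pattern" — a zero pattern count
means the record is not covered by the unit — and the association is
re-derived from that sharper cover.

## Pattern growth and scoring

Comprehensive patterns are AV sets of order 2..`max_order` (default 5)
within one unit, at most one AV per attribute, support ≥ `min_support`
(default max(5, 0.5% of N)), in which every AV has |SR| ≥ threshold
with at least one other member. Enumeration is exhaustive: candidates
grow level-wise on the anti-monotone support test only, and the
connectivity test is applied at emission (connectivity is not monotone,
so pruning on it would silently lose valid sets — the unit tests pin
equality with a brute-force subset enumeration). Label AVs never enter
pattern AV sets; counting patterns that contain the label would leak it
into the coverage scores.

A record's class score is the mean possessed-fraction over that class's
covered units (zero-count units excluded). Two guards:

- Units whose pattern count is below `min_class_patterns` (default 5%
  of the largest same-class unit, minimum 2, capped so a class's
  largest unit always scores; an integer sets an absolute floor) do not
  contribute a class score. A unit with one or two patterns casts a 0/1
  vote whose granularity swamps the mean — empirically it inflates the
  scores of genuine outliers far past the 0.01 outlier gate. The
  relative form keeps scores scale-free.
- When a class has no scoring units at all (e.g. a null dataset), every
  record scores 0 for it and is flagged uncovered rather than erroring.

Cluster assignment is the argmax class; exact ties and fully uncovered
records get sentinels that the triage resolves (ties → undecided,
uncovered → outlier, since both scores are 0 ≤ 0.01).

## Triage

Precedence is outlier → undecided → mislabelled → normal. The order is
deliberate: with both scores near zero the relative difference is
numerically meaningless, and an exact tie must never be read as a
mislabel. Comparators follow the printed rules: outlier uses ≤ 0.01 on
every class score, undecided uses < 0.001 on the top-two absolute
difference (ties included), mislabelled requires the argmax class to
differ from the label *and* relative difference > 0.1. Multi-class
inputs use the top two scores. The 0.1 constant is treated as a tunable
threshold, not a statistical test. Abnormal records are removed, not
relabelled, to avoid writing new incorrect information.

A documented arithmetic subtlety: the undecided-rule reference example
(counts 50/60/110/100 over units of 100/100/200/200 patterns) is
described alongside a sepsis score of 0.55, but the mean-of-fractions
rule — which reproduces every other reference score exactly — gives
mean(50/100, 110/200) = 0.525. The implementation follows the rule;
the equal-score case is exercised in tests with counts that genuinely
tie.

## Synthetic worlds

The generator emulates an imbalanced discretized clinical table:
defaults are 2000 records, two classes at 24.4% / 75.6%, 10 signal and
10 noise attributes with 3 categories each, signal strength 0.6
(preferred-category probability (1−s)/k + s ≈ 0.73), 10% mislabels, 1%
outliers, 2% ambiguous records. Mislabelled records keep their
class-typical profile and only flip the recorded label — that is what
makes them detectable by pattern disagreement and what distinguishes
them from outliers, which draw every attribute uniformly. Ambiguous
records draw each signal attribute from a 50/50 class mixture. Output
is bit-for-bit reproducible under the seed.

What the generator does **not** emulate: attribute entanglement.
Signal attributes are conditionally independent given the class and
noise is uniform, so the class axis is the dominant variance direction.
One consequence, verified numerically: 2-means on the one-hot table
approximates the Bayes rule in this world (both near 0.97–0.98 balanced
accuracy), so a green clustering test here establishes that coverage
clustering is near-optimal, not that it dominates every baseline — on
real entangled data the baselines degrade in ways this generator cannot
show. Temporal vital-sign structure and real missingness patterns are
also out of scope.

## Known limitations

- The enrichment fallback needs a meaningful prevalence estimate; with
  very few records per class the margin test is noisy.
- Pattern growth is exponential in the unit size in the worst case;
  `max_order` and `min_support` are the controls. At the default desk
  scale a full fit runs in ~1 s.
- The knowledge-base loader restores the three spaces exactly but not
  the in-memory entity sets (only their sizes are serialized); refit to
  recover full traceability.
- Records whose categories were never seen at fit time simply match no
  patterns; they surface as uncovered/outliers rather than errors.
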