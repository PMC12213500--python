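# Methods

## Model

A molecule is summarised by six descriptors: molecular weight (MW,
g/mol), Wildman–Crippen logP, hydrogen-bond acceptors (HBA, Lipinski
N/O rule), hydrogen-bond donors (HBD, N–H/O–H), rotatable bonds (nRotB,
non-ring single bonds between non-terminal heavy atoms, amide C–N
excluded) and aromatic rings (nArR). All six are computed with RDKit on
the largest covalent fragment of the input structure, so salts and
formulation mixtures are scored on their main component. The structure
is reparsed from its canonical SMILES before descriptor evaluation so
additive descriptors (logP in particular) are bit-identical however the
input SMILES was written. The exact rule-set identifiers are embedded
in every fitted profile, and scoring refuses a profile whose
conventions differ from the running engine's — a fitted curve is only
meaningful under the descriptor definitions it was fitted with.

The desirability of descriptor value x is the four-parameter asymmetric
peak

    df(x) = o + a·exp(−exp(−t) − t + 1),  t = (x − b)/c,

with baseline o, peak height o + a attained exactly at x = b, and
width/asymmetry scale c; both tails decay to o, and a negative c mirrors
the skew for left-skewed distributions. The QEA score aggregates the six
desirabilities as the unweighted geometric mean computed through
logarithms, with a hard zero whenever any desirability is ≤ 0. Evaluated
desirabilities are clamped to ≤ 1 before aggregation; the stored model
may overshoot to at most 1.05 from fit noise.

## Fitting

Frequency input. Continuous descriptors are histogrammed over
[min, max] with the bin count N ∈ [2, min(200, n)] minimising the
Shimazaki–Shinomoto cost C(Δ) = (2k̄ − v)/Δ², where k̄ and v are the mean
and biased variance of the per-bin counts and Δ the bin width; ties
break toward fewer bins. Bins are half-open [lo, hi) except the last,
which is closed so the maximum is counted. The x-coordinates passed to
fitting are bin centers — the unbiased representative value for a curve
that is a function of the descriptor itself. Discrete descriptors are
tallied exactly at every integer from 0 to the observed maximum,
including zero-count gaps.

Normalisation. Counts on a raw frequency scale (max > 1) are divided by
the tallest count so the target curve peaks near 1; inputs already on
the [0, 1] desirability scale are fitted as-is (this keeps a fit to
noise-free curve evaluations an identity rather than a rescaling).

Optimisation. Bounded trust-region least squares
(`scipy.optimize.least_squares`) from a fixed multi-start grid:
b ∈ {empirical mode, weighted mean}; c ∈ {±σ/2, ±σ} with σ the weighted
standard deviation; o₀ ∈ {0, min normalised count}; a₀ = 1 − o₀. Bounds:
o ∈ [0, 0.5], a ∈ (0, 1.2], b within the data range extended by 10%,
|c| ∈ [10⁻⁶·range, 10·range] with the sign fixed per start. The best
residual wins, ties resolved by grid order, so the fit is a
deterministic function of its input. A profile fit requires ≥ 30 valid,
deduplicated compounds (canonical-SMILES deduplication, first
occurrence kept) and ≥ 5 frequency points per descriptor.

Discrete descriptors are fitted with the same continuous curve over
integer x values; scoring evaluates it at the compound's integer value.

## Evaluation

ROC curves and the trapezoidal AUC come from scikit-learn with
`drop_intermediate=False`; with half-credit ties this equals the
Mann–Whitney statistic (probability a random positive outscores a
random negative), which the test suite verifies against exhaustive pair
counting. Tie handling matters here because the aggregation's zero rule
produces exact-zero score ties. Decoy subsets are drawn uniformly
without replacement from any user-supplied pool, seeded.

## Toxicity categories

Acute EC50/LC50 concentrations in mg/L map to the EPA five-level
scheme: > 100 practically non-toxic; (10, 100] slightly; (1, 10]
moderately; [0.1, 1] highly; < 0.1 very highly. The printed definitions
fix ">100" as strict and "<0.1" as strict; the interior shared
endpoints are assigned to the more toxic neighbour, a convention the
boundary tests pin down. Concentrations are inputs (e.g. from external
ADMET predictors or experiments); the package never predicts toxicity.
The −log10(mg/L) transform is provided for plotting on a
larger-is-more-toxic scale.

## Synthetic data generator

The simulator draws descriptor vectors directly, bypassing SMILES, so
fitting, scoring and ROC evaluation are testable end-to-end with known
ground truth. The default "positive" condition emulates a typical
algicide reference set: MW ~ LogNormal(median 330 g/mol, σ 0.30) —
mostly 200–500 g/mol; logP ~ LogNormal(median 3.0, σ 0.35) — peak
around 2–5; nRotB ~ Poisson(3); nArR ~ 1 + Poisson(0.8) — mostly one or
two rings; HBA ~ Poisson(3); HBD ~ Poisson(1.2). The "decoy" condition
is a diffuse, shifted background (MW median 480, σ 0.70; logP median
1.6, σ 0.90; Poisson means 6/3/7/2.5) standing in for a random
screening library. End-to-end runs use 500 positives vs 500 decoys,
which fits comfortably in seconds while leaving stable histogram fits.

What the simulator does not capture: correlations between descriptors
(real MW, HBA and nRotB are strongly correlated), multimodality from
distinct chemical classes, and any notion of chemical validity — so a
passing synthetic discrimination test shows the pipeline separates
distributions it was built to separate, not that the score transfers to
real screening libraries. A small hard-coded panel of 20 simple
molecules with hand-verifiable descriptor values regression-tests the
chemistry engine separately.

## Numerical notes and limitations

- The curve is a total function; for t ≪ 0 the doubly-exponential term
  is computed with overflow guarded and the value returns exactly o.
  Below t ≈ −3.5 the bump falls under o·machine-epsilon, so strict
  monotonicity tests operate on t ∈ [−3.5, 10].
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `random.Random`); profile JSON is
  written with sorted keys and no timestamps, so fit → score →
  evaluate reruns are byte-identical.
- Integer frequency tables grow linearly in max(value); pathological
  inputs (one huge outlier count) are the caller's responsibility.
- The zero rule makes QEA discontinuous at df = 0: a desirability of
  10⁻⁹ and one of −10⁻⁹ differ by a full score collapse. This is the
  model's published behaviour, kept deliberately rather than floored.
- Profiles are refitted from data, never shipped: likeness scores are
  only meaningful relative to the reference set they were fitted on.
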