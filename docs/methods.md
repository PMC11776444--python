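# Methods

`hoofbeats` analyzes the rhythm of quadruped footfall sound sequences. The
observable is a point process: the onset times (seconds) at which hooves
strike the ground, annotated per individual and per gait (walk, trot,
canter), with gait transitions excised so each recording is a single-gait
segment. This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Quantities

- **Inter-onset interval** `t_k = onset_{k+1} - onset_k`.
- **Rhythmic ratio** `r_k = t_k / (t_k + t_{k+1})`, computed over sliding
  adjacent pairs (stride 1). `r_k` lives in (0, 1); 1/2 is isochrony, 1/3
  and 2/3 are the 1:2 and 2:1 small-integer relations. Reversing a
  sequence maps each ratio to `1 - r`, a property the tests exploit.
- **Canter motion cycle**: three footfalls plus a suspension phase. The
  suspension is spanned by the long third interval, so a cycle reads
  (short, short, long). Phase ratios are `r_k1 = t1/(t1+t2)`,
  `r_k2 = t2/(t2+t3)`, and `r_k3 = t3/(t3+t1')` with `t1'` from the next
  cycle; the last cycle of a recording yields no `r_k3`.

## On-/off-integer bin scheme

Category tests bin ratios into on-integer acceptance ranges around 1/3,
1/2, 2/3 and flanking off-integer control ranges. All edges are
reciprocals of denominators offset by 0.25:

| bin          | lower   | upper   |
|--------------|---------|---------|
| off (0.286)  | 1/3.75  | 1/3.25  |
| 1:2 on       | 1/3.25  | 1/2.75  |
| off (0.400)  | 1/2.75  | 1/2.25  |
| 1:1 on       | 1/2.25  | 1-1/2.25|
| off (0.600)  | 1-1/2.25| 1-1/2.75|
| 2:1 on       | 1-1/2.75| 1-1/3.25|
| off (0.714)  | 1-1/3.25| 1-1/3.75|

Exact fractions are used internally; decimals such as 0.308 are display
roundings. Bins are half-open `[lower, upper)` with the final off bin
upper-closed, so every ratio in range gets exactly one label and the seven
bins tile `[1/3.75, 1 - 1/3.75]` without gaps. Ratios outside that range
carry no category and are excluded from the count models (they are kept
for densities and peak plots). Off-bin edges are our construction — the
flanking-reciprocal rule mirrors the on-bin construction and is the only
choice that tiles the axis; off *centers* (1/3.5, 1/2.5 and mirrors) are
fixed by the scheme's definition.

## Count models for category structure

For walk and trot, per-individual counts at six factor levels (each
category's on bin, and an off level pooling its two flanking off bins —
the shared middle off bins count toward both neighbors) enter a
negative-binomial (NB2) mixed model with a log link, `log(bin width)`
offset, and an individual random intercept. Significance is the
likelihood-ratio test (df = 5) of the full model against a null with only
the offset and the random intercept. The reported contrasts are
`off - on` per category on the link scale (negative = more mass
on-integer), with Tukey-style single-step multivariate-normal adjustment
over the three-contrast family.

For canter, each category gets its own Poisson mixed model on
per-individual x per-phase on/off counts with *additive* bin and phase
fixed factors. The design is additive rather than fully crossed because
each phase's ratios concentrate in a single category's on bin, which
makes interaction cells structurally empty. A Pearson dispersion ratio is
reported for Poisson fits as an overdispersion screen, and all fits
report a Shapiro–Wilk summary of randomized quantile residuals.

### The mixed-model engine

No installed Python package fits non-Gaussian GLMMs by maximum
likelihood, so the engine is implemented here: the single random
intercept makes the marginal likelihood a product of one-dimensional
integrals, each handled by a Laplace approximation whose mode is found by
a vectorized Newton iteration (the conditional log-density is concave in
the random effect for every supported family: Poisson, NB2, Gamma with
log link, Gaussian). The outer optimization over fixed effects, `log
sigma_u`, and the dispersion parameter uses L-BFGS-B with a
finite-difference step (1e-6) chosen above the inner solver's noise
floor, and a bounded Nelder–Mead polish on line-search failure. For the
Gaussian family the Laplace approximation is exact; the tests verify
agreement with `statsmodels` MixedLM (Gaussian) and GLM (the
`sigma_u -> 0` limit).

Degenerate inputs are handled explicitly rather than by crashing:
coefficients of all-zero cells drift to a box bound (complete
separation), and dispersion parameters can pin at a bound (theta -> inf
for Poisson-like counts). Such flat likelihood directions are detected by
near-zero Hessian curvature, excluded from the covariance inversion so
they cannot contaminate identified coefficients, and any Wald contrast
touching them is reported as `wald-degenerate` (z = 0, p = 1) — the
estimate remains available but no distributional claim is made. When the
random-intercept variance estimate hits its lower bound, the fit is the
fixed-effects model and is flagged as such.

## Walk/trot tempo comparison

Per-individual median `t_k` of walk and trot are compared with a paired
t-test (df = n_individuals - 1), with Shapiro–Wilk normality checks on
each median set. Unpaired individuals raise an error naming them.

## Isochrony accuracy and precision

Only ratios inside the open window `0.4 < r_k < 0.6` enter either metric
(endpoints excluded — a literal reading of the window definition).
Accuracy is the per-ratio deviance `|r_k - 0.5|`; precision is the
interquartile range of the in-window ratios per individual x gait,
computed with linear-interpolation (type-7) quantiles — the rule is fixed
so results are bit-stable; with fewer than 4 in-window ratios the IQR is
flagged undefined. Gait differences are tested with the same engine:
accuracy at the per-ratio level, precision at the per-individual level,
both with gait cell means and an individual random intercept. The
response family is selected by an AIC screen over Gamma, log-normal and
Gaussian candidates (positive-support families only when the data allow)
and recorded on the result; accuracy can be exactly zero after 1 ms
quantization, which in practice selects the Gaussian family for it.

## Embedding and classification

Triplets of adjacent intervals `(t_k, t_k+1, t_k+2)`, overlapping with
stride 1, are embedded in two dimensions by UMAP (defaults: 15
neighbors, min_dist 0.1, Euclidean metric, fully seeded). Durations are
deliberately *not* rescaled before embedding: tempo is itself diagnostic
of gait (walk and trot differ chiefly in tempo), and scaling would
discard it. The (V1, V2) coordinates feed a 1000-tree random forest with
a seeded, label-stratified 70/30 train/test split. The report carries the
out-of-bag error, the training confusion matrix, one-vs-rest ROC/AUC per
class from tree-vote fractions, Gini importances for V1/V2, a test-error
versus tree-count trace (a check that 1000 trees suffice), and two
accuracies: the pooled train+test figure (dominated by the in-sample fit
when trees are fully grown) and the test-only figure, which is the
defensible generalization metric and the one used in permutation-null
checks.

## Synthetic gait generator

No recordings ship with the package, so a seeded generator emulates their
statistical structure.

- **Patterns and tempi** (defaults): walk 0.287 s per interval; trot
  0.360 s; canter (0.148, 0.148, 0.267) s — the long interval spans the
  suspension phase at roughly 1.8x the short ones.
- **Timing jitter**: each interval is multiplied by `exp(N(0, sigma))`
  with sigma set so the interval CV equals `jitter_cv` (multiplicative
  log-normal noise preserves positivity; additive noise could produce
  negative intervals). Defaults: trot 0.03 < canter 0.05 < walk 0.06,
  encoding the trot-as-metronome ordering as a tunable default, not a
  measurement — within-gait interval CVs per individual are not published
  for this system, so these are calibration knobs.
- **Irregular steps**: with probability 0.02 an interval's noise SD is
  inflated 4x. Real riding-surface recordings contain occasional
  irregular steps; without this heavy-tail component a trot at CV 0.03
  would put *zero* ratios in off-integer bins (the bin boundary sits more
  than 5 sigma out), making off-bin coefficients unidentifiable — a
  degeneracy the real data evidently does not have. The mixture is inert
  at `jitter_cv = 0`, preserving the exact zero-noise invariants.
- **Individuals**: each individual draws one log-normal tempo multiplier
  (median 1, log-SD default 0.06 — a few percent of tempo, in line with
  morphology-driven differences) shared across its gaits.
- **Quantization**: intervals are rounded to 1 ms (manual annotation
  granularity); onsets, their cumulative sums, then live on the same
  grid. Rounding intervals rather than cumulative onsets keeps zero-noise
  sequences exactly periodic under any tempo multiplier.

What the generator does *not* emulate: speed (m/s) and its coupling to
variability, systematic within-recording tempo drift, hoof-identity
information, recording/annotation errors beyond the irregular-step
mixture, and any dependence between successive intervals beyond the
cycle pattern. Tests that pass on this generator demonstrate that the
pipeline recovers known structure of this kind; they do not certify
behavior on real recordings with richer dependence.

## Motion-cycle segmentation

Canter interval sequences are split into cycles by a two-cluster
partition of `log t_k` (minimal within-class sum of squares; the long
cluster is the suspension-spanning interval). Cycles are the
(short, short, long) runs ending at each long interval; leading/trailing
fragments and malformed runs are dropped and counted in diagnostics. If
the two clusters' geometric means are within a factor 1.3, no bimodal
structure is detectable and segmentation fails with diagnostics rather
than returning nonsense. Segmentation is pattern-based, not
hoof-identity-based: which hoof begins a cycle is unknowable from onset
times alone.

## Density peaks

Per-individual ratio densities use a Gaussian kernel with Silverman
bandwidth on a 512-point grid over (0, 1); peaks are strict local maxima
with prominence at least 5% of the maximum density. Below 10 ratios no
density is estimated (an empty peak set with a warning). All thresholds
are configurable; the defaults are fixed for reproducibility.

## Problem sizes and tolerances

The simulation-based tests run at the study scale of 19 individuals with
60 s per gait per individual (about 160–320 intervals per recording).
Replicate counts per check: 100 for category-structure recovery, 200 for
type-I-error control of the LRT (rejection at most 10% at a nominal 5% —
a deliberate allowance for the Laplace approximation and boundary
effects at finite n), 10 seeds for the metric-ordering and
classification-ordering checks. Zero-noise "exact" assertions use an
absolute tolerance of 1e-12, the float-accumulation noise floor of
cumulative onset sums. Unit tests use smaller populations (2–8
individuals, 25–30 s) where the property under test does not need study
scale.

## Known limitations

- The Laplace approximation can be crude for binary-like or tiny counts;
  with at most ~6 observations per group the random-intercept SD is
  weakly identified and often estimated at zero (flagged, and the fit
  then equals the fixed-effects model).
- Tukey adjustment uses the large-sample multivariate normal, not a
  multivariate t; with 19 groups the difference is small but the adjusted
  p-values are mildly anti-conservative.
- The accuracy model treats in-window ratios as exchangeable within
  individual; serial correlation between overlapping sliding ratios is
  not modeled (consecutive ratios share an interval by construction).
- Pooled-flank off levels double-count the two middle off bins across
  categories; contrasts are therefore not independent across categories,
  which the within-family Tukey adjustment does not attempt to correct.
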