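# Methods

## Model

Each gene's expression at time *t* is modelled as a linear function of every
gene's expression at the previous *L* time points (a lag-*L* vector
autoregression).  For effect gene *g* with candidate causes *g′*:

    X_t^g = Σ_{ℓ=1..L} α_ℓ^g X_{t−ℓ}^g
          + Σ_{g′≠g} Σ_{ℓ=1..L} β_ℓ^{g′,g} X_{t−ℓ}^{g′} + ε_t,   ε_t ~ N(0, 1)

A nonzero β_ℓ^{g′,g} means *g′* conditionally Granger-causes *g*: its past
improves prediction of *g* beyond *g*'s own past and that of all other
genes, which are all present in the same regression.  The default lag is
L = 2.  Replicates are treated as independently stacked rows; with *T* time
points and *R* replicates each per-gene regression has N = R·(T − L) rows
and L·p predictors, ordered lag-major (all genes at lag 1, then lag 2, …).

Because p·L typically exceeds N, each regression is penalised with an
elastic net, written with the mixing weight *a* on the ℓ₁ term and no ½ on
the ℓ₂ term:

    min_β ‖y − Xβ‖₂² + λ (a‖β‖₁ + (1 − a)‖β‖₂²)

scikit-learn's coordinate descent minimises (1/2n)‖y − Xβ‖² +
α(l1‖β‖₁ + (1−l1)/2·‖β‖₂²), so parameters are remapped as
α = λ(2 − a)/(2n), l1 = a/(2 − a); the remap is unit-tested against the
closed-form ridge solution and soft-thresholding on an orthonormal design.
Pure ridge (a = 0) is solved directly by the normal equations
(XᵀX + λI)⁻¹Xᵀy rather than coordinate descent, which converges poorly
without an ℓ₁ component.  No intercept is fit anywhere: every (gene,
replicate) temporal profile is centred to mean zero across time first.
Profiles are deliberately *not* scaled to unit variance — that would
over-weight the weak causal effects of genes with low variability.

## Hyperparameter selection

One global (λ*, a*) pair is chosen by leave-one-row-out cross-validation,
summing each gene's held-out squared error (divided by its row count) over
all genes and rows, over the grids λ ∈ {10⁻⁴, …, 1} and
a ∈ {0.1, 0.3, …, 0.9} (lasso: λ ∈ {10⁻⁵, …, 1}; ridge:
λ ∈ {10⁻⁵, …, 10⁶}).  Exact ties are broken toward the sparser model
(larger λ, then larger a).  The pair is tuned **once** on the original data
and reused for every permutation and bootstrap fit; this keeps the
hyperparameter search constant-time with respect to the bootstrap budget
and makes all downstream fits comparable.

## Permutation null and edge FDR

A single permuted data set is created by independently shuffling each
(gene, replicate) profile across time.  For each effect gene the regression
is refit with the *permuted* lagged values of all candidate causes while
the effect gene's own lagged columns and response stay unpermuted — the
null keeps each gene's autoregressive structure but severs its temporal
coupling to every candidate cause.  For each (effect gene, lag) the
coefficient threshold T_ℓ^g is the smallest observed |coefficient| value at
which

    #{|β̃| > T} / (#{|β̃| > T} + #{|β| > T}) ≤ 0.05

with strict inequalities and 0/0 := 0 (β̃ are the null coefficients).  An
edge g′ → g survives if it passes at any lag.  Self-lags (α) are never
edge candidates — self-regulatory loops are not scored.  At the largest
observed magnitude both counts are zero, so a finite threshold always
exists; when the null and real distributions coincide the chosen threshold
removes every edge, as it should.

## Stability selection and stability FDR

The edge-FDR inference is repeated over B bootstrap resamples (default
1000; B = 100 is a documented fast mode with near-identical edge sets) of
the N design rows, drawn with replacement.  The same row multiset I^j is
applied to both the real design (for coefficients) and the permutation-null
design (for that bootstrap's threshold).  Each edge's selection frequency
π_{g′,g,ℓ} is the fraction of bootstrap networks containing it at lag ℓ.

Null frequencies π̂ come from a second, independent permutation of the data
run through the identical procedure — playing the role of the real data,
with the first permutation still providing the coefficient null, and
re-using the same I^j.  The two permutation seeds must differ; identical
seeds are rejected.

With L = 2 each edge has two frequencies; the lag whose mean bootstrap
coefficient (averaged over all B fits, penalty zeros included) is larger in
magnitude is the edge's lag, separately on the real and null sides; exact
ties go to the smaller lag.  A single network-wide cutoff T_b — pooled over
all ordered gene pairs, since the published analysis reports one
network-wide frequency cutoff — is the smallest observed frequency at which

    #{π̂ > T_b} / (#{π̂ > T_b} + #{π > T_b}) ≤ 0.2

Edges with π > T_b enter the final network with sign and effect size taken
from the mean bootstrap coefficient at the chosen lag; an exactly-zero mean
coefficient cannot carry a sign and drops the edge (this requires every
one of B·p fits to return zero for that entry, so it essentially never
fires above T_b).  Both estimated-FDR inequalities are asserted on every
run.

## Evaluation

Ranked edge lists are scored against a gold standard over the full ordered
candidate universe (self-edges excluded).  AUPR uses the step
(average-precision) curve with tied blocks collapsed — candidates missing
from a ranking form one tied tail whose precision is the prevalence floor;
no linear interpolation between PR points, the conservative convention for
sparse networks.  AUROC is the midrank Mann–Whitney statistic, so it is
invariant to monotone score transforms and well-defined under ties.  The
stability ranking orders edges by selection frequency; the baseline
("Enet") ranking orders them by |full-data coefficient|.

Gene-class enrichment among, e.g., causal genes uses the 2×2 table
(a = selected∩class, b = selected∖class, c = class∖selected, d = rest),
reporting the sample odds ratio (a·d)/(b·c) with a two-sided Fisher exact
p-value and Benjamini–Hochberg adjustment across a batch of classes.  The
sample OR, not the conditional-MLE OR, is what reproduces the published
2.0 / 2.9 / 0.93 values from their counts.

## Overexpression validation

Perturbation (overexpression) series are short with coarse, uneven gaps,
so each candidate edge is scored by an unpenalised pairwise lag-1 VAR
(X_t^g = c·X_{t−1}^g + d·X_{t−1}^{g′} + ε) fit by OLS, replicates stacked,
first time point of each replicate dropped.  An identically-zero cause
series yields d = 0 with c the AR(1) coefficient; a cause collinear with
the effect's own history is an error.  Sign concordance regresses a sign
encoding of each network edge (one-hot positive, one-hot negative, or
signed +1/0/−1) against the d coefficients per overexpressed gene, with
two-sided t-test p-values, BH-adjusted across genes; groups with fewer
than three scored edges are flagged underpowered instead of tested.

## Synthetic data

The simulator draws a sparse coefficient tensor: lag-1 self-decay uniform
in (0.2, 0.5), cross edges planted per ordered pair with probability
`density`, magnitude uniform in (0.3, 0.8), negative with probability 0.3,
at a uniformly random lag ≤ L.  The companion-form spectral radius is
rescaled to ≤ 0.95 to guarantee stationarity, and each replicate series is
recorded after a 200-step burn-in from zero with Gaussian innovations
(default sd 0.2), so series start near the stationary distribution.  An
optional perturbation phase adds a constant shift to a random third (or
any fraction) of genes for the first half of the series.

The recovery studies use p = 15 genes, density 0.05, T = 21 time points,
R = 10 replicates and B = 100 — the benchmark-like series shape at a
problem size where a 20-replicate study completes in minutes on one core.
What the simulator does *not* emulate: non-stationary post-exposure
dynamics, measurement noise models beyond additive Gaussian innovations,
upstream normalisation (log/TPM, surrogate-variable correction), or
nonlinear regulation.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not performance on real RNA-seq data.

## Numerical choices and edge cases

- Coordinate-descent tolerance 1e-8, max 100 000 iterations, so solver
  oracle agreement holds to 1e-6.
- All FDR comparisons use strict ">" and candidate thresholds are the
  observed values; 0/0 ratios are defined as 0.
- Zero-variance genes are dropped with a logged warning before fitting
  (they carry no signal and destabilise leave-one-out CV).
- Missing values are linearly interpolated against real time coordinates,
  never extrapolated; a missing terminal time point is an error.
- A warning is logged when the max/min sampling-gap ratio exceeds 4, since
  the VAR assumes approximately even spacing.
- Bootstrap blocks reduce by summing counts, so worker count and execution
  order never change results; the full pipeline is bit-identical given the
  same (bootstrap, permutation-1, permutation-2) seed triple.

## Known limitations

- One global (λ*, a*) is shared by all genes; genes with atypical
  signal-to-noise may be over- or under-penalised.
- The stability-FDR pooling is network-wide; per-effect-gene calibration is
  not offered.
- Edge directionality from transcription alone is limited — reversed edges
  are expected for a fraction of true interactions.
- The LOOCV search is the runtime bottleneck at small p; at large p the
  bootstrap fits dominate and parallelise across workers.
- Runs are not checkpointed mid-bootstrap: outputs are bit-reproducible
  from the seed triple and supported problem sizes finish in minutes, so a
  resume layer was judged not worth its complexity.  Very large runs should
  be split by effect gene instead.
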