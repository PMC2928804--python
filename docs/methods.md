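# Methods

`survdr` implements survival dimensionality reduction (SDR): a
nonparametric screen for epistatic (non-additive gene-gene) interactions
that predict a right-censored time-to-event outcome, together with the
simulation machinery needed to study its statistical power.

## The classification procedure

For a candidate set of n SNPs (three-level genotypes coded 0/1/2), the
cohort is partitioned into the 3^n multilocus genotype cells. Writing
S&#770;(t) for the whole-cohort Kaplan-Meier estimate and S&#770;_c(t) for the
estimate inside cell c, both evaluated on the common grid of distinct
observed times t_1 < ... < t_m, the per-time difference is

    D_c(t_i) = S_c(t_i) - S(t_i),        -1 < D_c(t_i) <= 1.

Because the product-limit estimator is a geometric progression, the
differences are averaged geometrically after the +1 shift that makes them
positive:

    GM_c = ( prod_{i=1..m} (1 + D_c(t_i)) )^(1/m).

Cells with GM_c <= 1 — cells doing no better than the cohort — are
labelled *high-risk*, the rest *low-risk*; empty cells are labelled
`empty`. The boundary GM = 1 (e.g. a monomorphic SNP, whose single cell
reproduces the cohort curve exactly) maps to high-risk. D_c = +1 is
attainable in degenerate cohorts (population curve reaching 0 while an
all-censored cell stays at 1); the implementation only requires
1 + D_c > 0, which always holds.

Subjects are pooled by cell label into two groups, reducing the n-SNP
problem to one dimension. Each subject's predicted survival curve is the
Kaplan-Meier curve of their pooled group, and prediction quality is the
integrated censored Brier score:

    BS(t) = (1/N) * sum_i w_i(t) * (indicator_i(t) - pred_i(t))^2
    IBS   = (1/t_max) * integral_0^t_max BS(t) dt,

with Graf's inverse-probability-of-censoring weights: a subject with an
event at t_i <= t contributes pred_i(t)^2 / G(t_i^-); a subject still
under observation contributes (1 - pred_i(t))^2 / G(t); a subject censored
at or before t contributes 0. G is the Kaplan-Meier estimate of the
censoring distribution (indicators flipped); the left limit G(t_i^-) is
used for event subjects. Ties between events and censorings at the same
time follow the standard convention (events first). BS(t) is a
right-continuous step function changing only at observed times, so the
IBS integral is computed exactly by step decomposition; t_max defaults to
the largest observed event time, beyond which G and S are inestimable.
A required weight of zero raises an error rather than silently dropping
subjects (structurally this cannot occur when G is fitted on the same
cohort that is being scored).

## Feature selection, meta validation, permutation

The dataset is split into k mutually exclusive testing folds (default
k = 5, seeded; optional stratification by event status for heavily
censored data). For each interaction order n, every C(n_snps, n)
combination is fitted on each of the k training folds and scored by its
training IBS; the combination with the lowest mean training IBS wins,
ties breaking to the lexicographically first column tuple.

For validation the k testing folds are *merged*: each testing subject is
labelled with the cell assignment learned on its training folds and the
single merged set T_M (an individual-patient-data meta-analysis of the
folds) receives one meta-IBS, with censoring weights estimated on T_M
where they are reliable. By default each subject's predicted curve is the
pooled-group curve *fitted on its training folds* (carried), so the
meta-IBS is a genuine out-of-sample score; this is what lets the meta-IBS
detect overfitting — training IBS decreases monotonically with n while
the meta-IBS turns back up past the true interaction order. A refit
variant (`carry_training_curves=False`) scores only the grouping itself;
under refitting, concatenating identically-labelled folds exactly recovers
the whole-cohort IBS, a property used by the test suite. The final model
is the dimension with the lowest meta-IBS (ties to the lower dimension).

Testing subjects falling in a training-empty cell cannot be predicted by
the model proper. The default policy assigns them the training fold's
majority pooled group (ties to high-risk) and reports their count;
`high` and `exclude` policies are available.

Significance is assessed by permutation: (time, event) pairs are jointly
shuffled against the genotype rows, the entire pipeline (selection over
all dimensions plus meta validation) is rerun per permutation, and

    p = (1 + #{ permutations with best meta-IBS <= observed }) / (1 + n_perm),

the add-one correction avoiding p = 0. The permutation statistic inherits
the small dynamic range of the meta-IBS, so p-values for even strong
signals are rarely extreme — the observed value sits just below the null
distribution rather than far outside it.

## The epistatic lifetime simulator

**Survival shapes.** Populations follow the logistic-exponential family
S0(t) = 1/(1 + (e^{lambda t} - 1)^kappa), left-shifted and renormalised as
S(t) = S0(t + theta)/S0(theta) so S(0) = 1. Five named shapes are
provided, chosen by (kappa, theta) with lambda solved so that the
cumulative prevalence K(t_n) = 1 - S(t_n) hits 0.750 at t_n = 5 time
units:

| family | kappa | theta | hazard on (0, 5] |
|---|---|---|---|
| EXP | 1 | 0 | constant (lambda = ln4/5 ≈ 0.2773) |
| IFR | 2 | 0 | increasing |
| UBT | 2 | 8 | rises to a peak near t ≈ 2.6, then falls |
| DFR | 2 | 20 | decreasing |
| BT | 0.5 | 0 | falls steeply, minimum near t ≈ 4.2, then rises |

The shift selects the visible window of the kappa-determined hazard:
kappa > 1 hazards rise to a peak and relax to the asymptote
lambda*kappa, so theta = 0 shows the rising branch, a moderate shift
straddles the peak and a large shift lands past it. Survival is evaluated
in log space (ln(e^z - 1) = z + ln(1 - e^-z)) so the calibration solver
can probe large scales without overflow. The solved hazard's
finite-difference shape is verified against the family's monotonicity
pattern at a 1e-8 relative tolerance — the bathtub's rising tail is three
orders of magnitude shallower than its initial hazard, which dictates the
tolerance.

**Penetrance tables.** Two causative biallelic SNPs in Hardy-Weinberg
equilibrium at MAF 0.2 receive a 3x3 cumulative penetrance table f with
*no marginal effect at all*: both single-locus marginal penetrances equal
the prevalence K = 0.75 exactly. The zero-marginal tables form a
4-dimensional linear manifold around the constant table f = K; the
generator draws a seeded random direction in that manifold and scales it
to the target effect size, rejecting draws leaving [0, 1]^9.

Effect sizes are specified as cumulative broad-sense heritability on the
**liability scale**, the convention in which binary-trait heritabilities
are reported in genetic epidemiology, and converted to observed-scale
penetrance variance by the Dempster-Lerner factor phi(z)^2 / (K(1-K))
(0.539 at K = 0.75): a liability H2 of 0.10/0.15/0.20/0.25 corresponds to
an observed-scale H2 of 0.054/0.081/0.108/0.135. The realised
observed-scale heritability and the model-implied pooled high/low-risk
hazard ratio (an event-weighted average of per-interval log cumulative-
hazard increments, which matches large-sample Cox estimates to a few
parts in a thousand) are reported on the model object. These levels
induce pooled hazard ratios of roughly 1.5-2.1 — mild-to-moderate
effects. The choice of scale is the package's interpretation of how such
heritability levels are conventionally quoted; the observed-scale
formula itself is also exposed, and the two differ only by the fixed
conversion factor.

**Time decomposition.** The observation window is split into n equal
intervals (default 5 unit intervals). Cumulative penetrance tables at the
interior time points are proportional to the prevalence path,
F_i = (K(t_i)/K(t_n)) * f, which preserves the zero-marginal (purely
epistatic) property at every time point; per-interval hazards follow by
product-limit inversion, G_i = (F_i - F_{i-1})/(1 - F_{i-1}), which is
exactly consistent: 1 - prod_i(1 - G_i) = f. With one interval the
decomposition is the identity.

**Population simulation.** Per subject: a causative genotype pair from
the HWE cell probabilities; interval by interval, an event with
probability G_i[g] given survival so far, otherwise an independent
censoring clock at 5% per time unit; event/censoring times recorded at
interval boundaries; survivors censored at t_n. Event precedence within
an interval keeps the marginal event prevalence exact (the mean event
fraction by t_n with the censoring clock off is 0.750 exactly in
expectation). Thirteen unlinked noise SNPs at MAFs evenly spaced on
[0.1, 0.5] are appended and columns are shuffled so the causative pair
sits at random positions; the manifest records everything needed for
bit-exact reproduction.

**What the generator does not emulate:** linkage disequilibrium, genetic
heterogeneity, more than two causative loci, non-proportional (additive)
hazards, continuous event times within intervals, genotyping error or
missingness. Passing tests therefore speak to the algorithm's behaviour
under clean, proportional, interval-censored epistasis — not to robustness
against those real-data features.

## Power study

A condition is (hazard family, heritability level, censorship design).
One population of 65000 is built per (family, H2) and both designs — 200
events/200 censored (50% censorship) or 120/280 (70%) — draw their
replicate samples from it, so the censorship contrast is paired on the
same penetrance table. A replicate counts as a success when the winning
2-way combination (lowest mean training IBS over k = 5 folds) is exactly
the causative pair; requiring the full dimension-selection pipeline to
also prefer the 2-way model is available as `score_mode="final_model"`.
Power is the success fraction with a Wilson 95% interval. The summary
reports the grid, the median and IQR across conditions, a least-squares
logistic fit of power against H2 with its R^2, and a Kruskal-Wallis test
across families.

Desk-scale defaults are 25 replicates per condition (10 for the full
40-condition grid in the test suite); the binomial CI at 25 replicates is
roughly +-3 successes, which the tests' tolerances reflect.

## Numerical and degenerate-input choices

- Cell KM curves for all 3^n cells are computed simultaneously by
  bincount/cumprod on the common grid; a cell's curve carries its last
  value past its largest observed time (at-risk 0 contributes factor 1).
- GM comparison uses mean(log1p(D)) <= 0, the monotone equivalent of
  GM <= 1, avoiding the n-th root; the brute-force oracle in the tests
  uses the explicit product and root and agrees to 1e-12.
- A training fold with no events has no IBS horizon and raises; with the
  shipped sample sizes this requires extreme censorship imbalance, which
  fold stratification (`--stratify-folds`) prevents.
- Feature-selection ties break to the lexicographically first index
  tuple; dimension ties to the lower dimension; the full pipeline is
  bit-identical for fixed (data, k, max_dim, seed, n_perm).
- Monomorphic combinations collapse to a single pooled group; the final
  model is flagged `degenerate` when fewer than two labels are populated
  on the full data, and its predictions equal the cohort curve.
- Penetrance-table rejection sampling succeeds within a median of ~10
  draws at the largest shipped effect size; an unreachable target (e.g.
  H2 far above what [0,1]^9 admits) raises after a bounded number of
  draws.

## Known limitations

- The permutation p-value has low resolution for strong signals (the
  best-meta-IBS statistic separates weakly); the null calibration is
  accurate, which is what protects the type-I error rate.
- Exhaustive search scales as C(n_snps, n); the implementation is
  vectorised per combination-fold but no stochastic search is provided,
  matching the method's candidate-gene scope (tens of SNPs, n <= 3-4).
- Power at the lowest shipped effect level is sensitive to the particular
  random penetrance table drawn; tables at equal heritability and equal
  zero-marginal structure can differ in detectability by tens of
  percentage points at 400-subject sample sizes.
- Missing genotypes are rejected at load time; imputation is out of
  scope.
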