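# Methods

`ricegain` implements the quantitative-genetics workflow of a pedigree-driven
inbred breeding program — rice is the motivating crop — from plot-level trial
data to breeding values, genetic-gain trends, an elite core panel, and the
genomic characterization of that panel.  This note records the models, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## Pedigree quantities

The pedigree is a DAG of lines with at most two parents.  Derived statistics:

* **Equivalent complete generations (EqG)** measures pedigree completeness
  and serves as a proxy for realized breeding cycles:
  `EqG(x) = Σ_p 0.5 · (1 + EqG(p))` over known parents, equivalently the sum
  of `(1/2)^depth` over all ancestor *paths* (an ancestor reachable twice
  counts twice).  Founders score 0; a line with two founder parents scores 1.
  Unknown single parents simply contribute nothing.
* **Additive relationship matrix A** by the tabular method
  (`A_ii = 1 + 0.5·A_{sd}`, `A_ij = 0.5(A_{j,s} + A_{j,d})`), with the
  ancestral closure of any requested subset computed internally.  Inbreeding
  is `F_i = A_ii − 1` and the coefficient of parentage (kinship) is
  `f(i,j) = A_ij / 2`.
* **A-inverse** by Henderson's rules with inbreeding; Mendelian-sampling
  variances `D_i` come from a Meuwissen–Luo-style pass that accumulates
  `A_ii = Σ L² D` over each line's ancestors.  `log|A| = Σ log D_i` is
  returned alongside, since the stage-2 REML likelihood needs it.
* **Cross classification.**  Cross *status* is a pure threshold rule on the
  parents' EqG (elite ⇔ EqG ≥ 4, the program's convention anchoring "elite"
  at the most advanced cycle available when systematic records begin).
  Cross *type* uses structural rules: both parents F1 entries → double;
  exactly one F1 → backcross if the other parent is a parent of that F1,
  else three-way; neither F1 → backcross if one is the other's parent, else
  single; unresolvable parents → complex (flagged).  Backcross detection
  depth is one generation.

Rice lines are selfed to near-homozygosity, but A is deliberately the
standard sire–dam tabular matrix, matching the pedigree-BLUP tooling the
workflow mirrors.  An optional `fully_inbred_terminal` mode treats terminal
lines (non-parents) as completely inbred — diagonal 2, off-diagonals
unchanged, since selfing does not alter expected identity-by-descent with
relatives — and is off by default.

## Two-stage breeding-value estimation

**Stage 1 (per trial).**  Each environment (location × year × season) is
analyzed separately: trait = mean + blocking factors + genotype + error,
genotype iid random.  Candidate blocking factors depend on the declared
design (row-column: row, column; p-rep: row, column, replicate, block;
RCBD/augmented: replicate; alpha-lattice: replicate, block-in-replicate,
row, column), optionally plus a "missing hills" covariate `h_max − h`.
Factors with more than five levels enter as random effects, otherwise as
fixed.  The subset minimizing BIC is selected.  Trials with more than 15%
missing trait data are rejected.

Heterogeneous plot error: the residual diagonal is `h/h_max` by default,
where `h` is hills harvested (the program's stated convention).  Note this
gives *smaller* residual variance to short-stand plots, which is physically
inverted; `invert_hills_weight=True` provides `h_max/h`.  Both are tested;
the synthetic generator draws plot noise under whichever convention the
analysis will assume.

Per genotype the BLUP, its prediction-error variance (PEV), and the
reliability `r² = 1 − PEV/σ²_g` (clipped to [0, 1)) are extracted; the
process is repeated for days to flowering.  Single-trial repeatability is
line-mean based: `H² = σ²_g / (σ²_g + σ²_e / r̄)` with `r̄` the mean
replicate count.

**De-regression.**  `y_dr = trial mean + BLUP/r²`, weight `r²`.  Records
with `r²` below a floor (default 0.05) are dropped and counted; the floor
exists because de-regression divides by `r²`.  Carrying the trial mean means
stage-2 environment effects absorb it and breeding values come out on the
trait scale.

**Stage 2 (across trials).**  De-regressed yield records are fitted with
environment fixed (full dummy coding — estimable functions are invariant to
the coding), the per-genotype-per-environment stage-1 flowering BLUP as a
fixed covariate (centered; mean-imputed with a log count when missing), a
genetic effect `g ~ N(0, A σ²_g)` over the *whole* pedigree through the
sparse A-inverse, and residual diagonal `1/r²`.  Breeding value = mean of
environment effects + genetic effect; stage-2 reliabilities come from the
inverse coefficient matrix.  Unphenotyped relatives receive shrunken values
through the pedigree; unconnected lines are flagged low-information.

### REML engine

Variance ratios `λ_k = σ²_k/σ²_e` are optimized on the log scale (bounded
L-BFGS-B with a Nelder–Mead polish; convergence 1e−8 on the objective,
ratios bounded in [1e−7, 1e7], boundary estimates flagged).  The profiled
restricted likelihood is evaluated through the mixed-model equations with a
dense Cholesky factorization (incidence matrices are assembled sparse, the
coefficient matrix is dense — trial and pedigree problems here stay below a
few thousand equations).  Harville's `ln|X'X|` constant is included so
restricted likelihoods of models with different fixed parts sit on a common
footing.

**BIC** is computed from the *profile ML* likelihood evaluated at the REML
variance estimates, with `k` = number of fixed effects + number of variance
parameters.  A restricted-likelihood BIC would mechanically reward every
extra fixed-effect column by roughly `ln σ̂²` (the `(n−p)` prefactor), making
"lowest BIC" selection over blocking factors degenerate; the ML profile
restores comparability while the variance estimation itself stays REML.

## Genetic trend

Ordinary least squares of breeding value on year of cross (gain per year) or
on EqG (gain per cycle); lines missing the predictor are excluded and
counted.  The percentage rate is slope / fitted value at the first predictor
value × 100 — the baseline convention is a documented choice, as percentage
gains are often quoted without one.  A reliability-weighted variant and a
cluster-robust (by predictor value) standard error are available; both are
off by default.  The cluster-robust SE matters when comparing an estimated
trend with a known true value on simulated data: cohort members share
parents and trials, so the iid OLS SE understates the trend's sampling
spread.

**Known limitation — trend attenuation.**  When the true genetic trend is
exogenous to the analyzed data (as with the synthetic generator's injected
trend, or with real trends driven by unrecorded selection), pedigree BLUP
shrinks each generation's Mendelian deviation toward zero and the regression
of estimated breeding values on year recovers only a fraction of the true
slope — about 0.6–0.7 at the benchmark's reliabilities (stage-1 r² ≈ 0.45
per trial, two trials per line, matching the ~3 plots per line of the
historical data the benchmark mirrors).  This is a property of the estimator as
specified, not of the implementation: de-regression undoes stage-1 shrinkage
but stage-2 re-shrinks against the zero-mean pedigree prior.  The parameter
recovery benchmark therefore reports the attenuated estimate honestly rather
than tuning the generator's data richness to mask it; real-data trend
estimates from this pipeline should be read as conservative lower bounds.

## Elite core panel

A deterministic rule cascade: (1) reliability ≥ 0.4; (2) top 10% by breeding
value, ties broken by reliability then id; (3) greedy relatedness pruning —
scanning from the best line down, drop any line whose coefficient of
parentage with an already-kept line exceeds the ceiling (default 0.5;
setting it to 1 disables the stage, reproducing a purely
reliability/rank/availability cascade); (4) a seed-availability /
intellectual-property mask supplied as a boolean column.  All stage counts
are reported.  The relatedness rule is a design choice — the workflow the
package mirrors filtered on "relatedness" without stating an algorithm — and
greedy pruning was chosen for determinism and auditability.  Note greedy
pruning is not globally monotone in the CoP ceiling for arbitrary
relatedness structures (a looser ceiling can admit a line that then blocks a
later one); monotonicity does hold for the flat family structures typical of
breeding panels.

## SNP characterization

* **Filters**, in order: lines with > 15% heterozygous calls; markers with
  > 15% missing; markers with MAF < 0.05 computed on the surviving lines
  (heterozygotes count half an allele copy).  Counts are reported per step;
  relaxing any threshold retains supersets.
* **Dosage**: hom-ref 0, het 0.5, hom-alt 1 (alt-count orientation by
  default; minor-count available).  Missing propagates until imputation.
* **LD-kNN imputation**: for each missing cell, the `k=10` most correlated
  markers define a sub-space; the cell takes the marker's mean over the
  `k=5` nearest lines (Manhattan distance) among those with the marker
  observed.  Markers with no calls at all are set to 0.5 and flagged.  This
  follows the LD-kNNi idea; numerical parity with any particular
  implementation of it is not claimed.
* **PCA**: centered, unscaled, optionally joint with an external reference
  collection on shared markers (how a small elite panel is placed within a
  larger diversity panel).  Coordinates are sign-arbitrary.
* **Clustering**: Ward agglomeration on Manhattan dosage distances, with an
  optional cut into k clusters and Newick export of the dendrogram.
* **LD and Ne**: squared Pearson correlation of dosage columns for all
  same-chromosome pairs; genetic distance from physical distance under
  250 kb/cM (the standard rice-scale assumption), i.e.
  `c = bp / 25,000,000` Morgans.  A `literal_250kb_units` switch divides by
  250 kb only — the published wording of the conversion, which leaves c on a
  centiMorgan-like scale and changes Ne by two orders of magnitude; both
  readings are exposed because the published estimate does not state which
  was used.  Sved's relation `Ne = (1/(4c)) · (1/E(r²) − 1)` is applied per
  distance bin (default: 10 equal-count quantiles, ≥ 30 pairs each) and the
  overall estimate is the median over bins — robust to the hyperbolic shape
  of r² against distance.  Negative bins floor at 0.  The optional `1/n`
  finite-sample correction to mean r² is off by default (matching the plain
  formula) but is applied in the recovery benchmark: with 60 samples the
  sampling floor 1/60 dominates E(r²) at large distances and biases the
  uncorrected estimator low by about a factor of two.
* **Favorable-allele frequencies**: favorable / (favorable + unfavorable)
  × 100 per gene, with coverage (non-missing fraction) and a low-confidence
  flag at ≤ 95% coverage.

## Disease screens

Blast: mean of 0–5 infection scores over up to ten plants per line ×
isolate; lines missing more than 50% of their expected scores are dropped
(the threshold is configurable — the source protocol dropped for "high"
missingness without quantifying).  BLB: mean lesion length per line ×
isolate after requiring ≥ 4 of 6 leaf measurements; per-isolate virulence is
the mean over lines.  Lines are grouped into allele classes by their
favorable calls at the surveyed resistance genes, excluding genes fixed
favorable or absent everywhere; class × isolate means are unweighted, so the
size-weighted average of class means reproduces the grand mean exactly.
Isolate agreement is Spearman correlation on pairwise-complete line means
(≥ 3 shared lines).  Field evaluation of the panel reuses the stage-1
machinery (no hills weighting) and compares panel-entry BLUPs against local
checks with a Welch two-sample t-test at 5% — chosen over a mixed-model
contrast for transparency with very few checks; its type-I error calibrates
near nominal in simulation.

## Synthetic data generator

The generator produces every input the pipeline consumes, under the
statistical assumptions the pipeline makes:

* **Pedigree and true breeding values.**  Founders (initial pool plus a
  Poisson stream of introductions) carry bivariate normal (yield, flowering)
  true breeding values, genetic correlation 0.3; offspring take parental
  averages plus Mendelian noise `N(0, 0.5 σ²_a (1 − F̄))`, with F tracked by
  an incrementally grown kinship matrix.  Cross types follow the observed
  program mix (72% single, 25% three-way, 3% backcross, creating F1 records
  where needed).  Parents come from recent finished cohorts plus recent
  introductions; optional truncation selection on true breeding value.
  Twenty burn-in cycles precede the phenotyping era so cohorts are in steady
  state (EqG ≈ 4 by the first observed year, like the program's own 1985
  baseline).  The top line of each cohort is flagged a released variety.
* **Trend injection.**  Each cross gains `trend × elapsed years since the
  parents' cohorts` in yield — the aggregate of unmodelled within-cross
  selection — and the within-cross yield variance is reduced so the
  Mendelian second moment stays at its neutral value (as truncation
  selection would, cf. the Bulmer effect).  Telescoping over the pedigree,
  cohort means advance at exactly the injected rate in expectation, and the
  second-moment conservation keeps REML's genetic-variance estimate
  centered: injecting the trend through founder means alone (the obvious
  alternative) concentrates the trend variance in nominally unrelated
  founders and inflates σ̂²_g by 30–50%.  Introductions are drawn on-trend
  (competitive with their era).  The benchmark default disables truncation
  selection so "realized trend = injected trend" is exact in expectation;
  with selection on, the realized trend is emergent and is measured, not
  injected.
* **Trials.**  2,000 breeding lines over 40 years, each phenotyped in 2 of
  40 environments (about the plot density of the historical data set the
  design mirrors), plus released varieties as repeated checks connecting
  environments.  Designs are drawn from a mix of RCBD, alpha-lattice,
  row-column and p-rep layouts with the corresponding blocking-effect
  variances; plot error is 150,000 (kg/ha)² at full stand, scaled by the
  hills convention; hills lost per plot are binomial (15% loss rate), with
  5% of hills values unrecorded and 2% of yields missing.
* **Gene drop.**  Founder haplotypes are drawn per marker (alt frequency
  uniform on [0.1, 0.5]); meiosis recombines per interval with Haldane
  fractions under the same kb→Morgan map the LD analysis uses; terminal
  lines are selfed six generations (default) or doubled-haploid.  LD in
  descendants arises from co-inheritance of founder segments.
* **Wright–Fisher oracle.**  Discrete WF with recombination (default 4·Ne
  generations for drift–recombination equilibrium), sampling inbred lines
  (one gamete doubled).  Used to validate the Sved Ne estimator.

What the generator does *not* emulate: genotype-by-environment interaction
beyond environment main effects, spatial field trends within trials,
non-additive genetic effects, major-gene effects on yield, genotyping error,
and realistic allele-frequency spectra after ascertainment.  Passing tests
therefore demonstrate the estimators' correctness under their own
assumptions, not robustness to these violations.

All randomness derives from one root seed via deterministically spawned
per-component streams; a fixed seed reproduces every output byte for byte.

## Benchmark scales

The recovery benchmark runs the full pipeline at 2,000 lines × 40
environments (about 8,000 plots, two traits, then one pedigree fit over
~4,000 individuals) in a few minutes on one core; the Ne benchmark uses 20
Wright–Fisher replicates at Ne = 50 with 500 markers and 60 samples, and
rank-orders medians across Ne ∈ {20, 50, 200}; the check-test calibration
uses 200 null trials.  These sizes were chosen as the smallest at which the
quantities of interest are estimated with useful precision.
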