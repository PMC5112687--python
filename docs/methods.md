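# Methods

This note records the statistical model behind `rdskit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reproducing results.

## The recruitment forest

An RDS dataset is a forest: seeds at wave 0, every recruit one wave below
its recruiter.  Construction validates unique ids, degree ≥ 1, resolvable
recruiter links and acyclicity; waves are then forced by the links, so wave
assignment is idempotent and independent of row order.  Seed-productivity
cuts keep exactly the chains whose depth exceeds a threshold c (c = 0
drops unproductive seeds, c = 1 drops chains of ≤ 1 wave, …), always as
whole chains.  Cut-report percentages are computed at full precision and
rounded half-away-from-zero to one decimal for display — the convention
under which 50/719 prints as 7.0%.  Wave statistics in the cut report are
statistics of per-chain depths (so a 719-member, 119-chain sample with
total depth 208 reports a mean chain length of 1.75 waves).

Missing outcome cells are non-response: excluded from weighted estimators
and from recruiter–recruit transition pairs.  The crude estimator offers
both an all-records and a responders-only denominator because published
tables are often ambiguous about which was used.

## Estimators

**RDS-II** weights each respondent by 1/d_i, the with-replacement
random-walk inclusion probability up to a constant.  Degrees are used as
reported; no outlier truncation is applied by default (an optional cap
exists in the simulator's reporting-noise path only).

**RDS-I** estimates the recruitment Markov chain on outcome groups.  The
equilibrium is obtained by power iteration (tolerance 1e-12, cap 1e5
iterations) with a direct left-eigenvector solve as fallback; a reducible
or absorbing transition matrix is flagged and the equilibrium is computed
on the terminal class carrying the most observed pairs, with zeros
elsewhere.  Data-smoothing (on by default, as in the classic
implementation) replaces the flow matrix by its reciprocity average
S = (e_g T_gh + e_h T_hg)/2 before renormalizing; for symmetric count
matrices this is a no-op.  A category that never appears in any
recruiter–recruit pair makes the estimator undefined and raises with
guidance (pool categories or use RDS-II/RDS-SS) rather than silently
reporting 0%.

**RDS-SS** approximates without-replacement probability-proportional-
to-degree sampling at known population size N.  Inclusion probabilities
come from deterministic expected depletion: starting from estimated
population counts N̂_d per unique degree, each of the n draws removes one
unit of mass split in proportion to d·m_d; a class is never driven
negative — its excess is redistributed over surviving classes — so a
census (N = n) depletes everything and every π_d reaches 1 exactly.  π_d
is clipped monotone in d.  The weights 1/π_{d_i} and the degree
distribution estimate are iterated to a fixed point (tolerance 1e-6 on
max |Δπ|, cap 50 iterations; non-convergence returns the last iterate
flagged).  Deterministic depletion was chosen over Monte-Carlo draws for
exact reproducibility; the Monte-Carlo version survives as a test oracle.
Limits tested: N → ∞ recovers RDS-II to 1e-6; N = n recovers the
responders-only crude.

**Bootstrap CIs** use the grouped chain bootstrap: per group g, the pool
of participants whose recruiter belongs to g; each replicate starts at a
uniformly chosen observed seed and repeatedly draws, with replacement, a
successor from the current participant's group pool until the observed
(responding) sample size is reached, and the estimator is recomputed on
the replicate chain.  Defaults: B = 1000 and symmetric normal intervals
(point ± 1.96·SD of replicates, clipped to [0, 100] and forced to bracket
the point), because the published tables this mirrors report symmetric
CIs; percentile intervals are available.  The replicate stream is fully
determined by the seed.  Empirical coverage of the 95% interval, measured
over 200 simulated low-homophily samples (N = 10,000, n = 500, B = 200),
sits inside [0.90, 0.98] in the test suite.

## Diagnostics

Convergence series recompute the estimator on the first k enrollees
(enrollment order when recorded for everyone, else breadth-first by wave
with stable id order), k from k_min = 10 — earlier prefixes are noise —
to n; the final point equals the full-sample estimate by construction.
Bottleneck series apply the same construction per seed tree; chains
shorter than k_min are skipped.  RDS-II is the default series estimator
(fast and defined at almost every prefix); prefixes where an estimator is
undefined are skipped and flagged.  The homophily index compares
within-group recruitment with the equilibrium share, mapping proportionate
mixing to 0, pure self-recruitment to +1 and maximal avoidance to −1.
Waves-to-equilibrium iterates a start distribution through T and reports
the first wave whose maximum absolute component distance from the
equilibrium falls below ε (default 0.01); the worst-case mode maxes over
one-hot starts, and non-ergodic chains report infinite waves for
unreachable starts.  The ε here is a convergence tolerance on the measured
parameter — a quantity sometimes loosely called a "homophily level" in
applied reports.

## Sensitivity experiments

The cut ladder re-runs every estimator per cut with fresh bootstrap CIs
(sub-seeded deterministically from the master seed) and records whether
each crude value lies inside each weighted CI, per category.  The
subsampling comparison draws ⌈tree_fraction · #chains⌉ whole seed trees
without replacement per replicate (default tree_fraction = 0.5 — the
subsample size is a free design choice, logged prominently, since no
canonical value exists), recomputes all estimators, and summarizes
replicate-wise pairwise differences with a two-sided paired t-test at
α = 0.05 plus percentile intervals.  The p-value is descriptive:
replicates share chains and are not independent, and between
near-identical estimators the test will flag practically irrelevant
offsets, so magnitude and interval should be read first.  With
tree_fraction = 1 every replicate is the full sample and the tests are
degenerate (flagged, NaN p-values).

## Synthetic data

The generator emulates an urban hidden-population biobehavioral survey:
N = 33,960 individuals; binary outcomes at prevalences 27% (serostatus),
37% (recent high-risk sex) and 8% (injection drug use); negative-binomial
degrees shifted to a minimum of 1 (mean 20, dispersion 2 — a heavy right
tail typical of self-reported network sizes; the real distribution is
unreported, so this is an assumption, not a fact); and a row-stochastic
mixing matrix steering tie formation for one designated outcome.  Wiring
is degree-respecting stub pairing: stubs draw partner groups from their
mixing row over several matching rounds, leftovers pair within their own
group (so identity mixing yields exactly zero cross-group edges), and
self-loops/multi-edges are resolved by group-respecting rewiring with a
negligible dropped remainder.  Only the designated outcome carries
structural homophily; the others are assigned independently.  Proportionate
mixing (the default) produces |H| < 0.05 at N = 10,000, and realized
homophily increases strictly in the mixing diagonal.

Recruitment is a FIFO coupon queue: up to 6 coupons per enrollee, each
converting with probability 0.14 to a uniformly chosen not-yet-enrolled
neighbor, so chains are subcritical (6 × 0.14 ≈ 0.84 expected recruits)
and fresh uniform seeds are injected whenever the queue dies before the
target n = 719 — mirroring the pragmatic mid-study seed additions of the
emulated design and reproducing its shape (order-100 chains, short mean
chain length) from 30 initial seeds.  Waves equal BFS depth from the
recruiting seed.  Reported network size is the true realized degree,
floored at 1, with optional multiplicative log-normal reporting noise
(off by default).

What passing tests on these data do **not** show: real RDS samples have
reporting error in degrees, non-response correlated with outcomes,
differential coupon return, temporal dynamics and out-groups the chains
never reach — none of which the generator models.  Recovery results here
(mean RDS-II within 2 pp of a 30% true prevalence over 200 samples at
N = 10,000, n = 500) are therefore a correctness check of the estimators
under their own assumptions, not a field-validity claim.

## Reproducibility and problem sizes

One master seed drives everything through named sub-streams
(population, recruitment, bootstrap, subsampling), so equal configurations
give byte-identical output tables, and enlarging one stage's replicate
count never perturbs another stage.  The test suite and the acceptance
script run their simulation studies at deliberately moderate sizes —
20 replicates for the RDS-II/RDS-SS agreement study, 200 simulations for
recovery and coverage, B = 200 bootstrap replicates inside the coverage
loop — sizes at which the checked tolerances are already comfortably
resolved.

## Known limitations

* RDS-I is implemented in its multi-group equilibrium form; estimator
  variants with degree-weighted transition counts exist and will differ
  slightly on unbalanced data.
* The successive-sampling depletion is the expectation of the draw
  process, not its full distribution; π_d for degrees absent from the
  sample is not extrapolated.
* The grouped chain bootstrap conditions on the observed group pools; with
  very sparse groups it raises rather than improvising pools.
* No regression modelling, RDS-weighted GLMs, or analytic (non-bootstrap)
  variance estimators.
* The CLI's `simulate` defaults regenerate a study-shaped sample, not any
  particular real dataset.
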