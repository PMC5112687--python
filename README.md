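# rdskit

Estimation, diagnostics and simulation for **respondent-driven sampling
(RDS)** studies of hidden populations.

RDS recruits "hard-to-reach" populations (people who inject drugs, sex
workers, gay/bisexual and other men who have sex with men) through peer
chains: a handful of purposively chosen *seeds* receive a small number of
coupons, each redeemed coupon enrolls a network peer one *wave* deeper, and
every participant reports a personal network size (*degree*, d_i).  Because
well-connected people are over-sampled, population shares must be
re-weighted, and because seeds are a convenience sample, an analysis must
show that the estimates have escaped them.  `rdskit` implements the full
workflow for categorical outcomes: forest construction from flat CSV
tables, four estimators with chain-bootstrap confidence intervals,
graphical and analytic diagnostics, seed-productivity sensitivity analysis,
and a synthetic population + recruitment simulator with known ground truth.

## Estimators

For a sample S and outcome category A:

* **crude** — unweighted share, `P̂_A = n_A / n`;
* **RDS-I (Salganik–Heckathorn)** — models recruitment as a Markov chain on
  outcome groups.  With equilibrium distribution `e` of the (optionally
  data-smoothed) recruiter→recruit transition matrix `T` and per-group
  harmonic mean degrees `D̂_g = n_g / Σ_{i∈g} 1/d_i`:
  `P̂_g = (e_g/D̂_g) / Σ_h (e_h/D̂_h)`
  (the classic two-group form `P̂_A = C_BA·D̂_B / (C_AB·D̂_A + C_BA·D̂_B)`
  is the algebraic special case);
* **RDS-II (Volz–Heckathorn)** — inverse-degree importance weighting,
  `P̂_A = (Σ_{i∈A} 1/d_i) / (Σ_{i∈S} 1/d_i)`, valid when the sample
  fraction n/N is small;
* **RDS-SS (successive sampling)** — replaces `1/d_i` by `1/π_{d_i}`,
  where the inclusion probabilities `π_d` come from a deterministic
  expected-depletion approximation of without-replacement,
  probability-proportional-to-degree sampling from a population of known
  size N, iterated to self-consistency with the estimated population
  degree distribution.

Confidence intervals use the Salganik **grouped chain bootstrap**:
replicate chains are regrown from per-group recruit pools so the resampling
respects chain dependence.  Diagnostics include convergence plots
(running estimate vs. recruits), bottleneck plots (one series per seed
tree), a per-group homophily index
`H_g = (T_gg − e_g)/(1 − e_g)` (or `/e_g` below equilibrium), and the
analytic number of waves for a seed distribution to come within ε of
equilibrium.

## Worked example

```bash
python examples/01_simulate_and_estimate.py
```

```
sample: n=719, chains=114 (84 seeds injected), max wave=26
true prevalence: 27.4%

  crude:  27.0% (95% CI 22.0-32.0)
  rds_i:  25.6% (95% CI 20.1-31.0)
 rds_ii:  25.7% (95% CI 20.3-31.1)
 rds_ss:  25.7% (95% CI 20.3-31.1)
```

A population of N = 33,960 with 27% seropositivity and mild serostatus
homophily is wired, a coupon-referral sample of n = 719 is recruited from
30 initial seeds (84 more injected as chains die out), and each line shows
one estimator's population-share estimate with its bootstrap 95% CI.  At
this ~2% sample fraction RDS-II and RDS-SS agree to well under 0.1
percentage points, and the crude share sits inside every weighted CI — the
pattern expected when homophily is low and the estimate no longer depends
on seed selection.

The other examples walk through diagnostics
(`02_diagnostics.py`), the seed-productivity cut ladder
(`03_seed_sensitivity.py`) and the seed-tree subsampling estimator
comparison (`04_estimator_comparison.py`).

A thin CLI wraps the same pipeline:

```bash
rdskit all --config run.yaml --seed 1 --out results/
```

with subcommands `simulate | estimate | diagnose | sensitivity | compare |
all` (exit codes: 0 ok, 2 configuration error, 3 stage failure).

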