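"""Seed-sensitivity experiments.

Two designs:

1. A ladder of seed-productivity cuts (full sample; drop unproductive
   seeds; drop chains of <= 1 wave; drop chains of <= 2 waves), with every
   estimator re-run per cut and a check whether each crude proportion lies
   inside the bootstrap 95% CI of every weighted estimate — the robustness
   signature of a sample whose estimates have escaped seed selection.
2. A seed-tree subsampling comparison: repeatedly draw a fraction of whole
   recruitment chains, recompute all estimators on the subsample, and
   examine the replicate-wise pairwise differences (mean, percentile
   interval, paired t-test).  A difference that is systematically one-sided
   marks estimators that genuinely disagree on these data.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from ._util import rng_from
from .data_model import (
    CutSummary,
    RecruitmentForest,
    cut_report,
    prune_by_min_depth,
)
from .estimators import (
    EstimatorUndefinedError,
    EstimateResult,
    bootstrap_ci,
    crude_proportion,
    estimate,
)

log = logging.getLogger(__name__)

__all__ = [
    "SensitivityReport",
    "ComparisonResult",
    "run_cut_analysis",
    "check_crude_within_cis",
    "compare_estimators_simulation",
    "CUT_LABELS",
]

CUT_LABELS = {-1: "overall", 0: ">0", 1: ">1", 2: ">2"}


def cut_label(c: int) -> str:
    return CUT_LABELS.get(c, f">{c}")


@dataclass
class SensitivityReport:
    """Everything the cut ladder produced, keyed by (cut, outcome, estimator)."""

    cuts: list[int]
    cut_summaries: list[CutSummary]
    crude: dict[tuple[str, str], EstimateResult]
    results: dict[tuple[str, str, str], EstimateResult]
    containment: dict[tuple[str, str, str], bool] = field(default_factory=dict)
    errors: dict[tuple[str, str, str], str] = field(default_factory=dict)
    empty_cuts: list[int] = field(default_factory=list)
    N: float | None = None
    B: int | None = None
    rng_seed: int | None = None

    def frame(self) -> pd.DataFrame:
        """Tidy estimates table (one row per cut/outcome/estimator/category)."""
        rows = []
        for (cut, outcome), res in self.crude.items():
            for cat, val in res.estimates.items():
                rows.append(
                    {
                        "cut": cut,
                        "outcome": outcome,
                        "estimator": "crude",
                        "category": cat,
                        "point": val,
                        "ci_low": math.nan,
                        "ci_high": math.nan,
                        "n": res.n_used,
                        "crude_within_ci": None,
                    }
                )
        for (cut, outcome, est), res in self.results.items():
            for cat, val in res.estimates.items():
                lo, hi = res.ci[cat] if res.ci else (math.nan, math.nan)
                rows.append(
                    {
                        "cut": cut,
                        "outcome": outcome,
                        "estimator": est,
                        "category": cat,
                        "point": val,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n": res.n_used,
                        "crude_within_ci": self.containment.get(
                            (cut, outcome, est)
                        ),
                    }
                )
        return pd.DataFrame(rows).sort_values(
            ["cut", "outcome", "estimator", "category"], kind="stable"
        ).reset_index(drop=True)


def _stable_seed(rng_seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(rng_seed, spawn_key=key).generate_state(1)[0]
        % (2**31)
    )


def run_cut_analysis(
    forest: RecruitmentForest,
    outcomes: Sequence[str],
    estimators: Sequence[str] = ("rds_i", "rds_ii", "rds_ss"),
    N: float | None = None,
    B: int = 1000,
    rng_seed: int = 0,
    *,
    cuts: Sequence[int] = (-1, 0, 1, 2),
    denominator_mode: str = "all_records",
    smoothing: bool = True,
) -> SensitivityReport:
    """Re-estimate everything on each seed-productivity cut.

    Crude proportions are computed per cut/outcome; every requested weighted
    estimator gets grouped-bootstrap CIs; containment booleans record
    whether the crude value lies inside each CI.  A cut that leaves no
    records is reported empty while the others proceed.
    """
    if "rds_ss" in estimators and N is None:
        raise ValueError("run_cut_analysis needs N when RDS-SS is requested")
    report = SensitivityReport(
        cuts=list(cuts),
        cut_summaries=[],
        crude={},
        results={},
        N=N,
        B=B,
        rng_seed=rng_seed,
    )
    cut_forests = []
    for ci_idx, c in enumerate(cuts):
        pruned = prune_by_min_depth(forest, c)
        cut_forests.append((c, pruned))
        label = cut_label(c)
        if pruned.n == 0:
            report.empty_cuts.append(c)
            continue
        for oi, outcome in enumerate(outcomes):
            try:
                report.crude[(label, outcome)] = crude_proportion(
                    pruned, outcome, denominator_mode
                )
            except EstimatorUndefinedError as exc:
                report.errors[(label, outcome, "crude")] = str(exc)
                continue
            for ei, est in enumerate(estimators):
                try:
                    report.results[(label, outcome, est)] = bootstrap_ci(
                        pruned,
                        outcome,
                        estimator=est,
                        B=B,
                        rng_seed=_stable_seed(rng_seed, ci_idx, oi, ei),
                        N=N,
                        smoothing=smoothing,
                    )
                except EstimatorUndefinedError as exc:
                    report.errors[(label, outcome, est)] = str(exc)
    report.cut_summaries = cut_report(forest, cut_forests)
    check_crude_within_cis(report)
    return report


def check_crude_within_cis(report: SensitivityReport) -> dict[tuple[str, str, str], bool]:
    """Is each crude proportion inside the weighted estimator's 95% CI?

    True only when every category's crude value lies inside the matching CI.
    Booleans are recomputable from the stored point/CI values.
    """
    out: dict[tuple[str, str, str], bool] = {}
    for (cut, outcome, est), res in report.results.items():
        if res.ci is None:
            continue
        crude_res = report.crude.get((cut, outcome))
        if crude_res is None:
            continue
        ok = True
        for cat, (lo, hi) in res.ci.items():
            cv = crude_res.estimates.get(cat, 0.0)
            if not (lo <= cv <= hi):
                ok = False
                break
        out[(cut, outcome, est)] = ok
    report.containment = out
    return out


@dataclass
class ComparisonResult:
    """Seed-tree subsampling comparison across estimators.

    ``estimates[(outcome, category, estimator)]`` holds one value per
    replicate; pairwise entries follow the sign convention
    ``"X-Y" = estimate(X) − estimate(Y)`` replicate-wise.
    """

    replicates: int
    tree_fraction: float
    alpha: float
    rng_seed: int
    estimators: tuple[str, ...]
    outcomes: tuple[str, ...]
    categories: dict[str, tuple[str, ...]]
    estimates: dict[tuple[str, str, str], np.ndarray]
    redraws: int = 0
    degenerate: bool = False

    def mean(self, outcome: str, category: str, estimator: str) -> float:
        return float(self.estimates[(outcome, category, estimator)].mean())

    def percentile_interval(
        self, outcome: str, category: str, estimator: str
    ) -> tuple[float, float]:
        v = self.estimates[(outcome, category, estimator)]
        lo, hi = np.percentile(v, [2.5, 97.5])
        return float(lo), float(hi)

    def difference(
        self, outcome: str, category: str, x: str, y: str
    ) -> dict[str, float]:
        """Replicate-wise ``x − y`` summary with a paired two-sided t-test.

        The p-value is descriptive (replicates share chains, so they are not
        independent); it is NaN-flagged when the differences are constant.
        """
        dx = self.estimates[(outcome, category, x)]
        dy = self.estimates[(outcome, category, y)]
        diff = dx - dy
        lo, hi = np.percentile(diff, [2.5, 97.5])
        if np.ptp(diff) == 0.0 or self.degenerate:
            p = math.nan
        else:
            p = float(scipy.stats.ttest_rel(dx, dy).pvalue)
        return {
            "mean": float(diff.mean()),
            "p2.5": float(lo),
            "p97.5": float(hi),
            "p_value": p,
            "significant": (p < self.alpha) if not math.isnan(p) else False,
        }

    def frame(self) -> pd.DataFrame:
        """One row per (outcome, category): estimator means/intervals and all
        pairwise differences — the published comparison-table shape."""
        rows = []
        for outcome in self.outcomes:
            for cat in self.categories[outcome]:
                row: dict = {"outcome": outcome, "category": cat}
                for est in self.estimators:
                    m = self.mean(outcome, cat, est)
                    lo, hi = self.percentile_interval(outcome, cat, est)
                    row[f"{est}_mean"] = m
                    row[f"{est}_p2.5"] = lo
                    row[f"{est}_p97.5"] = hi
                for y, x in combinations(self.estimators, 2):
                    d = self.difference(outcome, cat, x, y)
                    row[f"{x}-{y}_mean"] = d["mean"]
                    row[f"{x}-{y}_p"] = d["p_value"]
                rows.append(row)
        return pd.DataFrame(rows)


def compare_estimators_simulation(
    forest: RecruitmentForest,
    outcomes: Sequence[str],
    replicates: int = 100,
    tree_fraction: float = 0.5,
    alpha: float = 0.05,
    rng_seed: int = 0,
    *,
    estimators: Sequence[str] = ("crude", "rds_i", "rds_ii", "rds_ss"),
    N: float | None = None,
    smoothing: bool = True,
) -> ComparisonResult:
    """Estimator comparison over random subsamples of whole seed trees.

    Each replicate draws ``ceil(tree_fraction · #chains)`` chains without
    replacement (within the replicate), keeps them whole, and recomputes
    every estimator.  A replicate on which some estimator is undefined is
    redrawn (logged), up to 10 attempts.  With ``tree_fraction=1`` every
    replicate is the full sample: means reproduce the full-sample estimates
    exactly and the paired tests are degenerate (flagged, NaN p-values).
    """
    if "rds_ss" in estimators and N is None:
        raise ValueError("comparison needs N when RDS-SS is requested")
    seeds = list(forest.chains)
    if len(seeds) < 2:
        raise ValueError("need at least 2 recruitment chains to subsample")
    if not 0.0 < tree_fraction <= 1.0:
        raise ValueError("tree_fraction must be in (0, 1]")
    n_take = math.ceil(tree_fraction * len(seeds))
    degenerate = n_take == len(seeds)
    if degenerate:
        log.warning(
            "tree_fraction=%.3f selects every chain: replicates are "
            "identical and pairwise tests are degenerate",
            tree_fraction,
        )

    categories: dict[str, tuple[str, ...]] = {}
    for outcome in outcomes:
        vals = sorted(
            {v for v in forest.outcome_values(outcome) if v is not None}
        )
        categories[outcome] = tuple(vals)

    rng = rng_from(rng_seed, 3)
    store: dict[tuple[str, str, str], np.ndarray] = {
        (o, c, e): np.empty(replicates)
        for o in outcomes
        for c in categories[o]
        for e in estimators
    }
    redraws = 0
    for b in range(replicates):
        for attempt in range(10):
            chosen = rng.choice(len(seeds), size=n_take, replace=False)
            sub = forest.restrict_to_chains(seeds[j] for j in chosen)
            try:
                values = {}
                for outcome in outcomes:
                    for est in estimators:
                        res = estimate(
                            sub,
                            outcome,
                            est,
                            N=N,
                            smoothing=smoothing,
                            denominator_mode="non_missing",
                        )
                        for cat in categories[outcome]:
                            values[(outcome, cat, est)] = res.estimates.get(
                                cat, 0.0
                            )
            except EstimatorUndefinedError as exc:
                redraws += 1
                log.info("replicate %d redrawn (%s)", b, exc)
                continue
            for key, v in values.items():
                store[key][b] = v
            break
        else:
            raise EstimatorUndefinedError(
                f"replicate {b} still undefined after 10 redraws"
            )
    return ComparisonResult(
        replicates=replicates,
        tree_fraction=tree_fraction,
        alpha=alpha,
        rng_seed=rng_seed,
        estimators=tuple(estimators),
        outcomes=tuple(outcomes),
        categories=categories,
        estimates=store,
        redraws=redraws,
        degenerate=degenerate,
    )
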