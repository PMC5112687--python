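"""Graphical and analytic diagnostics of an RDS sample.

Convergence plots track the running estimate as recruits accumulate: a
series that flattens onto the full-sample value suggests the estimate has
escaped the purposive choice of seeds.  Bottleneck plots superimpose one
such series per seed tree: several distinct plateaus are the signature of
homophily-driven segregation.  The analytic counterparts quantify the same
ideas on the recruitment transition model: a per-group homophily index and
the number of Markov-chain steps ("waves") a start distribution needs to
come within a tolerance of equilibrium.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import RecruitmentForest
from .estimators import (
    EstimatorUndefinedError,
    TransitionModel,
    estimate,
)

__all__ = [
    "DiagnosticSeries",
    "EquilibriumReport",
    "convergence_series",
    "bottleneck_series",
    "homophily_index",
    "equilibrium_waves",
    "series_frame",
]

#: Running estimates over fewer than this many records are noise, not signal.
DEFAULT_K_MIN = 10


@dataclass(frozen=True)
class DiagnosticSeries:
    """Running estimate of one category versus number of recruits included."""

    outcome: str
    category: str
    estimator: str
    ordering: str
    k: tuple[int, ...]
    values: tuple[float, ...]
    seed_id: str | None = None  # set for per-seed (bottleneck) series
    skipped_k: tuple[int, ...] = ()

    @property
    def final_value(self) -> float:
        return self.values[-1]


@dataclass(frozen=True)
class EquilibriumReport:
    """Waves needed for a start distribution to reach equilibrium.

    ``waves`` maps start label -> smallest w with
    ``max_g |(start·T^w)_g − e_g| < epsilon`` (``inf`` when the chain never
    mixes, e.g. a reducible transition matrix started off the recurrent
    part).
    """

    epsilon: float
    start_mode: str
    waves: dict[str, float]
    distance_metric: str = "max_abs"
    ergodic: bool = True
    notes: tuple[str, ...] = ()

    @property
    def max_waves(self) -> float:
        return max(self.waves.values()) if self.waves else math.inf


def _ordered_ids(forest: RecruitmentForest, ordering: str) -> tuple[list[str], str]:
    have_order = all(r.enroll_order is not None for r in forest.records)
    if ordering == "auto":
        ordering = "enroll_order" if have_order else "wave"
    if ordering == "enroll_order":
        if not have_order:
            raise ValueError("enroll_order ordering requested but not recorded")
        ids = sorted(forest.ids, key=lambda i: (forest[i].enroll_order, i))
    elif ordering == "wave":
        wave = forest.wave
        ids = sorted(forest.ids, key=lambda i: (wave[i], i))
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    return ids, ordering


def _prefix_series(
    forest: RecruitmentForest,
    ids: list[str],
    outcome: str,
    category: str | None,
    estimator: str,
    k_min: int,
    N: float | None,
) -> tuple[str, list[int], list[float], list[int]]:
    ks, values, skipped = [], [], []
    chosen = category
    for k in range(min(k_min, len(ids)), len(ids) + 1):
        sub = RecruitmentForest(
            _as_prefix_record(forest, pid, set(ids[:k])) for pid in ids[:k]
        )
        try:
            res = estimate(
                forest=sub,
                outcome=outcome,
                estimator=estimator,
                N=N,
                denominator_mode="non_missing",
            )
        except (EstimatorUndefinedError, KeyError):
            skipped.append(k)
            continue
        if chosen is None:
            chosen = sorted(res.estimates)[0]
        ks.append(k)
        values.append(res.estimates.get(chosen, 0.0))
    if chosen is None:
        raise EstimatorUndefinedError(
            f"no usable prefix of length >= {k_min} for outcome {outcome!r}"
        )
    return chosen, ks, values, skipped


def _as_prefix_record(forest: RecruitmentForest, pid: str, present: set[str]):
    """Recruits whose recruiter is outside the prefix become prefix seeds."""
    rec = forest[pid]
    if rec.recruiter_id is not None and rec.recruiter_id not in present:
        return type(rec)(
            id=rec.id,
            degree=rec.degree,
            recruiter_id=None,
            enroll_order=rec.enroll_order,
            outcomes=rec.outcomes,
        )
    return rec


def convergence_series(
    forest: RecruitmentForest,
    outcome: str,
    estimator: str = "rds_ii",
    ordering: str = "auto",
    *,
    category: str | None = None,
    k_min: int = DEFAULT_K_MIN,
    N: float | None = None,
) -> DiagnosticSeries:
    """Running estimate on the first ``k`` enrollees, ``k = k_min..n``.

    Records are ordered by ``enroll_order`` when recorded for everyone,
    otherwise breadth-first by wave with stable id order.  The final point
    always equals the full-sample estimate.  Prefixes on which the estimator
    is undefined (e.g. RDS-I before both groups are linked) are skipped and
    reported in ``skipped_k``.
    """
    if forest.n < k_min:
        raise EstimatorUndefinedError(
            f"forest has {forest.n} records, fewer than k_min={k_min}"
        )
    ids, ordering = _ordered_ids(forest, ordering)
    chosen, ks, values, skipped = _prefix_series(
        forest, ids, outcome, category, estimator, k_min, N
    )
    return DiagnosticSeries(
        outcome=outcome,
        category=chosen,
        estimator=estimator,
        ordering=ordering,
        k=tuple(ks),
        values=tuple(values),
        skipped_k=tuple(skipped),
    )


def bottleneck_series(
    forest: RecruitmentForest,
    outcome: str,
    estimator: str = "rds_ii",
    ordering: str = "auto",
    *,
    category: str | None = None,
    k_min: int = DEFAULT_K_MIN,
    N: float | None = None,
) -> list[DiagnosticSeries]:
    """One convergence series per seed tree, over that tree's members only.

    Chains with fewer than ``k_min`` members are skipped (they carry no
    stable running estimate); values of one series depend only on that
    chain's records.
    """
    out: list[DiagnosticSeries] = []
    for seed in forest.chains:
        chain = forest.restrict_to_chains([seed])
        if chain.n < k_min:
            continue
        ids, used_ordering = _ordered_ids(chain, ordering)
        try:
            chosen, ks, values, skipped = _prefix_series(
                chain, ids, outcome, category, estimator, k_min, N
            )
        except EstimatorUndefinedError:
            continue
        out.append(
            DiagnosticSeries(
                outcome=outcome,
                category=chosen,
                estimator=estimator,
                ordering=used_ordering,
                k=tuple(ks),
                values=tuple(values),
                seed_id=seed,
                skipped_k=tuple(skipped),
            )
        )
    return out


def homophily_index(model: TransitionModel) -> dict[str, float]:
    """Per-group homophily index of a recruitment transition model.

    ``H_g = (T[g,g] − e_g) / (1 − e_g)`` when within-group recruitment
    exceeds the equilibrium share (over-selection, up to +1 for a group that
    only recruits itself), else ``(T[g,g] − e_g) / e_g`` (avoidance, down to
    −1).  NaN for groups whose equilibrium component is degenerate.
    """
    return dict(zip(model.groups, model.homophily.tolist()))


def equilibrium_waves(
    model: TransitionModel,
    epsilon: float = 0.01,
    start_mode: str = "worst-case-degenerate",
    *,
    max_waves: int = 100_000,
) -> EquilibriumReport:
    """Smallest number of recruitment waves to come within ``epsilon`` of
    equilibrium, by repeated application of the transition matrix.

    ``start_mode='worst-case-degenerate'`` iterates every one-hot start (all
    seeds in a single group) and reports each; ``'observed-seeds'`` starts
    from the observed seed-group distribution.  Distance is the maximum
    absolute component difference.  For a non-ergodic chain the unreachable
    starts report ``inf`` waves.
    """
    t = model.probs
    e = model.equilibrium
    notes: list[str] = []
    ergodic = not model.reducible and not model.zero_rows
    if not ergodic:
        notes.append(
            "transition matrix is reducible or has unobserved recruiter "
            "groups; waves from starts outside the recurrent part are inf"
        )
    if start_mode == "worst-case-degenerate":
        starts = {g: np.eye(len(e))[j] for j, g in enumerate(model.groups)}
    elif start_mode == "observed-seeds":
        if model.seed_distribution.sum() <= 0:
            raise ValueError("no observed seeds with a non-missing outcome")
        starts = {"observed-seeds": model.seed_distribution.copy()}
    else:
        raise ValueError(f"unknown start_mode {start_mode!r}")

    waves: dict[str, float] = {}
    for label, x in starts.items():
        w: float = math.inf
        cur = x.astype(float)
        for step in range(max_waves + 1):
            if np.max(np.abs(cur - e)) < epsilon:
                w = float(step)
                break
            cur = cur @ t
        waves[label] = w
        if math.isinf(w):
            notes.append(f"start {label!r} never reached equilibrium")
    return EquilibriumReport(
        epsilon=epsilon,
        start_mode=start_mode,
        waves=waves,
        ergodic=ergodic,
        notes=tuple(notes),
    )


def series_frame(series: Sequence[DiagnosticSeries]) -> pd.DataFrame:
    """Tidy export of diagnostic series (one row per plotted point)."""
    rows = []
    for s in series:
        for k, v in zip(s.k, s.values):
            rows.append(
                {
                    "outcome": s.outcome,
                    "category": s.category,
                    "estimator": s.estimator,
                    "seed_id": s.seed_id,
                    "k": k,
                    "value": v,
                }
            )
    return pd.DataFrame(
        rows, columns=["outcome", "category", "estimator", "seed_id", "k", "value"]
    )


def plot_series(
    overall: DiagnosticSeries,
    per_seed: Sequence[DiagnosticSeries] = (),
    ax=None,
):
    """Render convergence (and optionally bottleneck) series, Fig-2 style:
    proportion on the y-axis, number of recruits on the x-axis.

    Requires matplotlib (the ``plot`` extra); everything else in this module
    is plotting-free.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in per_seed:
        ax.plot(s.k, s.values, alpha=0.5, linewidth=0.8)
    ax.plot(overall.k, overall.values, color="black", linewidth=1.6)
    ax.axhline(overall.final_value, linestyle=":", color="grey")
    ax.set_xlabel("number of recruits")
    ax.set_ylabel(f"{overall.outcome} = {overall.category} (%)")
    ax.set_title(f"{overall.estimator} running estimate")
    return ax
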