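"""RDS prevalence estimators and their variance machinery.

Four point estimators for the population share of a categorical outcome:

* crude — unweighted sample proportion;
* RDS-I (Salganik–Heckathorn) — models recruitment as a Markov chain on
  outcome groups; combines the chain's equilibrium distribution with
  per-group harmonic-mean degrees, ``P_g ∝ e_g / D_g``;
* RDS-II (Volz–Heckathorn) — inverse-degree importance weighting,
  ``P_A = (Σ_{i∈A} 1/d_i) / (Σ_i 1/d_i)``, valid when sampling approximates
  a with-replacement random walk (small sample fraction);
* RDS-SS (Gile's successive sampling) — replaces ``1/d_i`` with ``1/π_{d_i}``
  where the inclusion probabilities ``π_d`` come from a finite-population
  successive-sampling (probability-proportional-to-degree, without
  replacement) approximation at a known population size ``N``.

Confidence intervals use the Salganik grouped chain bootstrap: replicates
are synthetic recruitment chains drawn with replacement from per-group
recruit pools, so the resampling respects the dependence structure of
chain referral.  All estimates are reported on the percent scale.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from ._util import rng_from
from .data_model import RecruitmentForest

__all__ = [
    "EstimateResult",
    "TransitionModel",
    "InclusionProbTable",
    "EstimatorUndefinedError",
    "crude_proportion",
    "rds_ii",
    "rds_i",
    "rds_ss",
    "build_transition_model",
    "ss_inclusion_probs",
    "bootstrap_ci",
    "ESTIMATORS",
]

_EQ_TOL = 1e-12
_EQ_MAX_ITER = 100_000


class EstimatorUndefinedError(ValueError):
    """The requested estimator has no defined value on these data."""


@dataclass
class EstimateResult:
    """Point estimates (percent) with optional bootstrap CIs.

    ``estimates`` maps category -> percent over the used records;
    ``weights`` maps participant id -> sampling weight (only for
    forest-level estimates, not bootstrap replicates).
    """

    estimator: str
    outcome: str
    estimates: dict[str, float]
    n_used: int
    weights: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None
    B: int | None = None
    rng_seed: int | None = None
    ci_method: str | None = None
    info: dict = field(default_factory=dict)

    @property
    def categories(self) -> list[str]:
        return list(self.estimates)

    def point(self, category: str) -> float:
        return self.estimates[category]


@dataclass(frozen=True)
class TransitionModel:
    """Recruiter->recruit Markov model of one outcome.

    ``counts[g, h]`` is the number of recruitments from a group-``g``
    recruiter to a group-``h`` recruit; ``probs`` is the row-normalized
    transition matrix, ``equilibrium`` its stationary distribution (solved on
    the recurrent part when the chain is reducible), ``harmonic_degrees`` the
    per-group harmonic-mean reported network sizes n_g / Σ 1/d_i.
    """

    outcome: str
    groups: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray
    equilibrium: np.ndarray
    harmonic_degrees: np.ndarray
    group_sizes: np.ndarray
    seed_distribution: np.ndarray
    smoothed: bool = False
    zero_rows: tuple[str, ...] = ()
    reducible: bool = False

    @property
    def homophily(self) -> np.ndarray:
        """Per-group homophily index in [-1, 1].

        ``H_g`` compares the within-group recruitment probability with the
        equilibrium share: positive when recruiters over-select their own
        group, 0 under proportionate mixing, negative for avoidance.
        Undefined (NaN) when the equilibrium component is degenerate.
        """
        e = self.equilibrium
        t = np.diag(self.probs)
        h = np.full(len(e), np.nan)
        for g in range(len(e)):
            if e[g] <= 0.0 or e[g] >= 1.0:
                continue
            if t[g] >= e[g]:
                h[g] = (t[g] - e[g]) / (1.0 - e[g])
            else:
                h[g] = (t[g] - e[g]) / e[g]
        return h


@dataclass(frozen=True)
class InclusionProbTable:
    """Successive-sampling inclusion probabilities per unique degree."""

    degrees: np.ndarray
    pop_counts: np.ndarray
    pi: np.ndarray
    draws: int
    converged: bool

    def pi_for(self, degree_values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.degrees, degree_values)
        return self.pi[idx]


# ---------------------------------------------------------------------------
# array-level cores (shared by forest-level API and the bootstrap)
# ---------------------------------------------------------------------------


def _pct_from_weights(codes: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    sums = np.bincount(codes, weights=w, minlength=k)
    total = sums.sum()
    if total <= 0:
        raise EstimatorUndefinedError("total weight is zero")
    return 100.0 * sums / total


def _solve_equilibrium(counts: np.ndarray) -> tuple[np.ndarray, dict]:
    """Stationary distribution of the chain defined by a count matrix.

    Zero-count rows are flagged and treated as absorbing; when the chain is
    reducible the equilibrium is solved on the terminal (recurrent) class
    carrying the most recruitment pairs, and zeros reported elsewhere.
    """
    k = counts.shape[0]
    row_sums = counts.sum(axis=1)
    zero_rows = np.flatnonzero(row_sums == 0)
    t = np.zeros_like(counts, dtype=float)
    pos = row_sums > 0
    t[pos] = counts[pos] / row_sums[pos, None]
    for g in zero_rows:
        t[g, g] = 1.0

    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(t > 0), connection="strong"
    )
    terminal = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        outside = np.flatnonzero(labels != comp)
        if outside.size == 0 or not np.any(t[np.ix_(members, outside)] > 0):
            terminal.append(members)
    # keep the recurrent class with the most observed pairs
    terminal.sort(key=lambda m: counts[m].sum(), reverse=True)
    recurrent = terminal[0]
    reducible = len(terminal) > 1 or recurrent.size < k

    sub = t[np.ix_(recurrent, recurrent)]
    sub = sub / sub.sum(axis=1, keepdims=True)
    e_sub = np.full(recurrent.size, 1.0 / recurrent.size)
    converged = False
    for _ in range(_EQ_MAX_ITER):
        nxt = e_sub @ sub
        if np.max(np.abs(nxt - e_sub)) < _EQ_TOL:
            e_sub = nxt
            converged = True
            break
        e_sub = nxt
    if not converged:
        # periodic or slowly-mixing chain: direct left-eigenvector solve
        vals, vecs = scipy.linalg.eig(sub.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, idx])
        v = np.abs(v)
        e_sub = v / v.sum()
    e = np.zeros(k)
    e[recurrent] = e_sub
    return e, {
        "zero_rows": tuple(int(g) for g in zero_rows),
        "reducible": bool(reducible),
        "probs": t,
    }


def _transition_from_counts(
    counts: np.ndarray, smoothing: bool
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Row-normalized transitions and equilibrium, optionally data-smoothed.

    Smoothing averages the two directed flow estimates of each unordered
    pair, ``S[g,h] = (e_g T[g,h] + e_h T[h,g]) / 2`` — the reciprocity of
    undirected network ties — then re-normalizes and recomputes the
    equilibrium on the smoothed matrix.
    """
    e, flags = _solve_equilibrium(counts)
    t = flags["probs"]
    if smoothing:
        flow = e[:, None] * t
        s = (flow + flow.T) / 2.0
        e, flags = _solve_equilibrium(s)
        t = flags["probs"]
    return t, e, flags


def _rds_i_core(
    codes: np.ndarray,
    degrees: np.ndarray,
    counts: np.ndarray,
    k: int,
    smoothing: bool,
) -> tuple[np.ndarray, dict]:
    t, e, flags = _transition_from_counts(counts, smoothing)
    sizes = np.bincount(codes, minlength=k).astype(float)
    inv_deg = np.bincount(codes, weights=1.0 / degrees, minlength=k)
    dhat = np.where(sizes > 0, sizes / np.where(inv_deg > 0, inv_deg, 1.0), np.nan)
    score = np.where(sizes > 0, e / dhat, 0.0)
    total = score.sum()
    if total <= 0:
        raise EstimatorUndefinedError(
            "RDS-I equilibrium places no mass on any observed group"
        )
    return 100.0 * score / total, {**flags, "equilibrium": e, "dhat": dhat}


def _ss_depletion(degrees: np.ndarray, pop_counts: np.ndarray, n: int) -> np.ndarray:
    """Expected remaining population mass per degree after ``n`` PPS draws.

    Each draw removes one unit of mass split over degree classes in
    proportion to ``d * m_d``.  A class cannot go negative: when its
    proportional share exceeds what remains, it is emptied and the excess is
    redistributed over the surviving classes, so every draw removes exactly
    one unit until the population is exhausted (hence a census depletes
    everything and all inclusion probabilities reach 1).
    """
    m = pop_counts.astype(float).copy()
    d = degrees.astype(float)
    for _ in range(n):
        need = 1.0
        for _ in range(len(m) + 1):
            active = m > 0
            total = float(d[active] @ m[active]) if active.any() else 0.0
            if total <= 0 or need <= 1e-12:
                break
            take = np.zeros_like(m)
            take[active] = need * d[active] * m[active] / total
            over = take > m
            if not over.any():
                m -= take
                break
            need -= float(m[over].sum())
            m[over] = 0.0
        if not np.any(m > 0):
            break
    return m


def _rds_ss_core(
    codes: np.ndarray,
    degrees: np.ndarray,
    k: int,
    N: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    n = len(codes)
    if N < n:
        raise EstimatorUndefinedError(f"population size N={N} smaller than n={n}")
    uniq, inv = np.unique(degrees, return_inverse=True)
    w = 1.0 / degrees
    pi_rec_old = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        shares = np.bincount(inv, weights=w, minlength=len(uniq))
        nd = N * shares / shares.sum()
        m = _ss_depletion(uniq, nd, n)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(nd > 0, (nd - m) / nd, 1.0)
        pi = np.clip(pi, 1e-300, 1.0)
        pi = np.maximum.accumulate(pi)  # enforce monotonicity in degree
        pi_rec = pi[inv]
        if pi_rec_old is not None and np.max(np.abs(pi_rec - pi_rec_old)) < tol:
            converged = True
            w = 1.0 / pi_rec
            break
        pi_rec_old = pi_rec
        w = 1.0 / pi_rec
    return (
        _pct_from_weights(codes, w, k),
        w,
        {"converged": converged, "iterations": iterations},
    )


# ---------------------------------------------------------------------------
# forest-level API
# ---------------------------------------------------------------------------


def _usable(forest: RecruitmentForest, outcome: str):
    """Ids, category codes and degrees of records non-missing on ``outcome``."""
    if outcome not in forest.outcome_names:
        raise KeyError(f"outcome {outcome!r} not present in table")
    vals = forest.outcome_values(outcome)
    ids = [i for i, v in zip(forest.ids, vals) if v is not None]
    if not ids:
        raise EstimatorUndefinedError(
            f"no records with a non-missing {outcome!r} value"
        )
    cats = sorted({v for v in vals if v is not None})
    index = {c: j for j, c in enumerate(cats)}
    codes = np.array(
        [index[v] for v in vals if v is not None], dtype=np.intp
    )
    degrees = np.array([forest[i].degree for i in ids], dtype=float)
    return ids, cats, codes, degrees


def crude_proportion(
    forest: RecruitmentForest,
    outcome: str,
    denominator_mode: str = "all_records",
) -> EstimateResult:
    """Unweighted sample percentages of each category.

    ``denominator_mode='all_records'`` divides by the full sample size (so
    percentages over categories need not reach 100 when non-response is
    present); ``'non_missing'`` divides by the responding records only.
    """
    if forest.n == 0:
        raise EstimatorUndefinedError("empty forest")
    if denominator_mode not in ("all_records", "non_missing"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    ids, cats, codes, _ = _usable(forest, outcome)
    denom = forest.n if denominator_mode == "all_records" else len(ids)
    counts = np.bincount(codes, minlength=len(cats))
    estimates = {c: float(100.0 * counts[j] / denom) for j, c in enumerate(cats)}
    return EstimateResult(
        estimator="crude",
        outcome=outcome,
        estimates=estimates,
        n_used=denom,
        weights={i: 1.0 for i in ids},
        info={"denominator_mode": denominator_mode},
    )


def rds_ii(forest: RecruitmentForest, outcome: str) -> EstimateResult:
    """Volz–Heckathorn inverse-degree weighted percentages."""
    ids, cats, codes, degrees = _usable(forest, outcome)
    w = 1.0 / degrees
    pct = _pct_from_weights(codes, w, len(cats))
    return EstimateResult(
        estimator="rds_ii",
        outcome=outcome,
        estimates=dict(zip(cats, pct.tolist())),
        n_used=len(ids),
        weights=dict(zip(ids, w.tolist())),
    )


def build_transition_model(
    forest: RecruitmentForest, outcome: str, smoothing: bool = False
) -> TransitionModel:
    """Recruiter->recruit transition model for one outcome.

    Counts come from resolved recruiter–recruit pairs with both outcomes
    non-missing.  With ``smoothing`` the counts are reciprocity-smoothed
    before the equilibrium is recomputed.
    """
    ids, cats, codes, degrees = _usable(forest, outcome)
    index = {c: j for j, c in enumerate(cats)}
    pairs = forest.recruiter_pairs(outcome)
    if not pairs:
        raise EstimatorUndefinedError(
            f"no recruiter–recruit pairs with non-missing {outcome!r}"
        )
    k = len(cats)
    counts = np.zeros((k, k))
    for g, h in pairs:
        counts[index[g], index[h]] += 1.0
    t, e, flags = _transition_from_counts(counts, smoothing)
    sizes = np.bincount(codes, minlength=k).astype(float)
    inv_deg = np.bincount(codes, weights=1.0 / degrees, minlength=k)
    dhat = np.where(sizes > 0, sizes / np.where(inv_deg > 0, inv_deg, 1.0), np.nan)
    seed_cats = [
        forest[s].outcomes.get(outcome)
        for s in forest.seeds
        if forest[s].outcomes.get(outcome) is not None
    ]
    seed_dist = np.zeros(k)
    for c in seed_cats:
        seed_dist[index[c]] += 1.0
    if seed_dist.sum() > 0:
        seed_dist /= seed_dist.sum()
    return TransitionModel(
        outcome=outcome,
        groups=tuple(cats),
        counts=counts,
        probs=t,
        equilibrium=e,
        harmonic_degrees=dhat,
        group_sizes=sizes.astype(int),
        seed_distribution=seed_dist,
        smoothed=smoothing,
        zero_rows=tuple(cats[g] for g in flags["zero_rows"]),
        reducible=flags["reducible"],
    )


def rds_i(
    forest: RecruitmentForest, outcome: str, smoothing: bool = True
) -> EstimateResult:
    """Salganik–Heckathorn estimator, multi-group form ``P_g ∝ e_g / D_g``.

    On two groups this reduces algebraically to the classic closed form
    ``P_A = C_BA D_B / (C_AB D_A + C_BA D_B)``.  Smoothing (reciprocity
    adjustment of the transition counts) is on by default.
    """
    ids, cats, codes, degrees = _usable(forest, outcome)
    index = {c: j for j, c in enumerate(cats)}
    pairs = forest.recruiter_pairs(outcome)
    if not pairs:
        raise EstimatorUndefinedError(
            f"no recruiter–recruit pairs with non-missing {outcome!r}"
        )
    k = len(cats)
    counts = np.zeros((k, k))
    for g, h in pairs:
        counts[index[g], index[h]] += 1.0
    involved = (counts.sum(axis=0) + counts.sum(axis=1)) > 0
    orphan = [c for j, c in enumerate(cats) if not involved[j]]
    if orphan:
        raise EstimatorUndefinedError(
            f"categories {orphan!r} of {outcome!r} never appear in "
            "recruiter–recruit pairs, so the RDS-I equilibrium cannot place "
            "mass on them; pool sparse categories or use RDS-II/RDS-SS"
        )
    pct, info = _rds_i_core(codes, degrees, counts, k, smoothing)
    return EstimateResult(
        estimator="rds_i",
        outcome=outcome,
        estimates=dict(zip(cats, pct.tolist())),
        n_used=len(ids),
        info={
            "smoothing": smoothing,
            "reducible": info["reducible"],
            "equilibrium": dict(zip(cats, info["equilibrium"].tolist())),
            "harmonic_degrees": dict(zip(cats, info["dhat"].tolist())),
        },
    )


def ss_inclusion_probs(
    degrees: Sequence[float] | np.ndarray,
    pop_counts: Sequence[float] | np.ndarray,
    n: int,
) -> InclusionProbTable:
    """Successive-sampling inclusion probabilities at a finite population.

    Deterministic expected-depletion approximation: start with ``pop_counts``
    units per unique degree, and for each of ``n`` draws remove from every
    degree class its expected share of one probability-proportional-to-degree
    draw.  ``pi_d`` is the depleted fraction of the class, increasing in
    ``d`` and satisfying ``Σ_d pop_counts_d · pi_d ≈ n``.
    """
    degrees = np.asarray(degrees, dtype=float)
    pop_counts = np.asarray(pop_counts, dtype=float)
    if np.any(degrees < 1):
        raise ValueError("all degrees must be >= 1")
    if n > pop_counts.sum() + 1e-9:
        raise ValueError(
            f"cannot draw n={n} from population of {pop_counts.sum():.1f}"
        )
    order = np.argsort(degrees)
    d_sorted = degrees[order]
    c_sorted = pop_counts[order]
    m = _ss_depletion(d_sorted, c_sorted, int(n))
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(c_sorted > 0, (c_sorted - m) / c_sorted, 1.0)
    pi = np.clip(pi, 0.0, 1.0)
    pi = np.maximum.accumulate(pi)
    taken = float(c_sorted @ pi)
    return InclusionProbTable(
        degrees=d_sorted,
        pop_counts=c_sorted,
        pi=pi,
        draws=int(n),
        converged=bool(abs(taken - n) <= 0.5),
    )


def rds_ss(
    forest: RecruitmentForest,
    outcome: str,
    N: float,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> EstimateResult:
    """Successive-sampling estimator at known population size ``N``.

    Self-consistent weights: starting from inverse-degree weights, the
    population degree distribution is estimated, inclusion probabilities are
    derived by expected depletion, and weights are reset to ``1/π_{d_i}``
    until the probabilities stabilize (max |Δπ| < ``tol``).
    """
    ids, cats, codes, degrees = _usable(forest, outcome)
    pct, w, info = _rds_ss_core(codes, degrees, len(cats), N, tol, max_iter)
    return EstimateResult(
        estimator="rds_ss",
        outcome=outcome,
        estimates=dict(zip(cats, pct.tolist())),
        n_used=len(ids),
        weights=dict(zip(ids, w.tolist())),
        info={"N": N, **info},
    )


ESTIMATORS = ("crude", "rds_i", "rds_ii", "rds_ss")


def estimate(
    forest: RecruitmentForest,
    outcome: str,
    estimator: str,
    *,
    N: float | None = None,
    smoothing: bool = True,
    denominator_mode: str = "all_records",
) -> EstimateResult:
    """Dispatch a point estimate by estimator name."""
    if estimator == "crude":
        return crude_proportion(forest, outcome, denominator_mode)
    if estimator == "rds_ii":
        return rds_ii(forest, outcome)
    if estimator == "rds_i":
        return rds_i(forest, outcome, smoothing=smoothing)
    if estimator == "rds_ss":
        if N is None:
            raise ValueError("RDS-SS requires a population size N")
        return rds_ss(forest, outcome, N)
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# grouped chain bootstrap
# ---------------------------------------------------------------------------


def _replicate_estimate(
    estimator: str,
    cats_arr: np.ndarray,
    degs_arr: np.ndarray,
    k: int,
    N: float | None,
    smoothing: bool,
) -> np.ndarray:
    if estimator == "crude":
        return _pct_from_weights(cats_arr, np.ones(len(cats_arr)), k)
    if estimator == "rds_ii":
        return _pct_from_weights(cats_arr, 1.0 / degs_arr, k)
    if estimator == "rds_ss":
        pct, _, _ = _rds_ss_core(cats_arr, degs_arr, k, N, 1e-6, 50)
        return pct
    if estimator == "rds_i":
        counts = np.zeros((k, k))
        np.add.at(counts, (cats_arr[:-1], cats_arr[1:]), 1.0)
        pct, _ = _rds_i_core(cats_arr, degs_arr, counts, k, smoothing)
        return pct
    raise ValueError(f"unknown estimator {estimator!r}")


def bootstrap_ci(
    forest: RecruitmentForest,
    outcome: str,
    estimator: str = "rds_ii",
    B: int = 1000,
    rng_seed: int = 0,
    method: str = "normal",
    *,
    N: float | None = None,
    smoothing: bool = True,
) -> EstimateResult:
    """Grouped chain-bootstrap 95% confidence intervals.

    Each replicate rebuilds a recruitment chain of the observed size: it
    starts at a uniformly drawn observed seed and repeatedly appends, with
    replacement, a participant from the pool of recruits whose recruiter
    shares the current participant's group.  The estimator is recomputed on
    every replicate chain; ``method='normal'`` reports point ± 1.96·SD of
    the replicates, ``'percentile'`` the 2.5/97.5 replicate percentiles.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    if method not in ("normal", "percentile"):
        raise ValueError(f"unknown CI method {method!r}")
    full = estimate(
        forest,
        outcome,
        estimator,
        N=N,
        smoothing=smoothing,
        denominator_mode="non_missing",
    )
    ids, cats, codes, degrees = _usable(forest, outcome)
    index = {c: j for j, c in enumerate(cats)}
    k = len(cats)
    id_pos = {pid: t for t, pid in enumerate(ids)}

    pools_c: list[list[int]] = [[] for _ in range(k)]
    pools_d: list[list[float]] = [[] for _ in range(k)]
    for pid in ids:
        rec = forest[pid]
        if rec.recruiter_id is None:
            continue
        g = forest[rec.recruiter_id].outcomes.get(outcome)
        if g is None:
            continue
        pools_c[index[g]].append(codes[id_pos[pid]])
        pools_d[index[g]].append(rec.degree)

    seed_states = [
        (codes[id_pos[s]], float(forest[s].degree))
        for s in forest.seeds
        if forest[s].outcomes.get(outcome) is not None
    ]
    if not seed_states:
        raise EstimatorUndefinedError(
            f"no seeds with a non-missing {outcome!r} value to start replicates"
        )
    reachable = {c for c, _ in seed_states}
    for g in range(k):
        reachable.update(pools_c[g])
    for g in sorted(reachable):
        if not pools_c[g]:
            raise EstimatorUndefinedError(
                f"group {cats[g]!r} is reachable in replicate chains but has "
                "an empty recruit pool; the chain bootstrap cannot continue "
                "past it"
            )

    pool_c_arr = [np.array(p, dtype=np.intp) for p in pools_c]
    pool_d_arr = [np.array(p, dtype=float) for p in pools_d]
    n = len(ids)
    rng = rng_from(rng_seed)
    replicates = np.empty((B, k))
    max_attempts = 10
    for b in range(B):
        value = None
        for _ in range(max_attempts):
            start = rng.integers(len(seed_states))
            pre = [
                rng.integers(0, max(len(pool_c_arr[g]), 1), size=n)
                for g in range(k)
            ]
            cats_arr = np.empty(n, dtype=np.intp)
            degs_arr = np.empty(n)
            g, d0 = seed_states[start]
            cats_arr[0], degs_arr[0] = g, d0
            counters = [0] * k
            pc, pd_ = pool_c_arr, pool_d_arr
            for t in range(1, n):
                i = pre[g][counters[g]]
                counters[g] += 1
                c = pc[g][i]
                cats_arr[t] = c
                degs_arr[t] = pd_[g][i]
                g = c
            try:
                value = _replicate_estimate(
                    estimator, cats_arr, degs_arr, k, N, smoothing
                )
                break
            except EstimatorUndefinedError:
                continue
        if value is None:
            raise EstimatorUndefinedError(
                f"bootstrap replicate for {estimator!r} undefined after "
                f"{max_attempts} redraws"
            )
        replicates[b] = value

    ci: dict[str, tuple[float, float]] = {}
    for j, c in enumerate(cats):
        point = full.estimates[c]
        if method == "normal":
            sd = float(np.std(replicates[:, j], ddof=1))
            lo, hi = point - 1.96 * sd, point + 1.96 * sd
        else:
            lo, hi = np.percentile(replicates[:, j], [2.5, 97.5])
        ci[c] = (max(0.0, min(float(lo), point)), min(100.0, max(float(hi), point)))
    full.ci = ci
    full.B = B
    full.rng_seed = rng_seed
    full.ci_method = method
    full.info = {**full.info, "bootstrap_sd": {
        c: float(np.std(replicates[:, j], ddof=1)) for j, c in enumerate(cats)
    }}
    return full
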