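"""Synthetic group-structured populations and coupon-based RDS recruitment.

The generator emulates the design of an urban hidden-population
biobehavioral survey: a population of ~34,000 individuals carrying
categorical outcomes (e.g. serostatus at ~27%, recent high-risk sex at
~37%, injection drug use at ~8%), heavy-tailed personal network sizes, a
tunable group-mixing (homophily) matrix, and peer recruitment in which each
enrollee receives up to six coupons, a minority of which are ever redeemed,
so that chains stay short and field staff keep injecting fresh seeds to
reach the target sample size.  Ground truth (prevalences, mixing, degrees)
is retained so estimator recovery can be tested.
"""

from __future__ import annotations

import logging
from collections import deque
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._util import rng_from
from .data_model import ParticipantRecord, RecruitmentForest

log = logging.getLogger(__name__)

__all__ = [
    "PopulationConfig",
    "RecruitmentConfig",
    "Population",
    "SyntheticTruth",
    "SimulationResult",
    "generate_population",
    "simulate_rds",
    "truth_report",
    "forest_from_chain_plan",
]


def forest_from_chain_plan(
    chains: Sequence[tuple[int, int]], degree: int = 2
) -> RecruitmentForest:
    """Deterministic forest with prescribed per-chain depth and size.

    ``chains`` is a sequence of ``(depth, size)`` pairs: each chain gets a
    recruitment spine reaching exactly ``depth`` waves and ``size`` members
    in total, extra members attached at wave 1.  Useful for reconstructing
    the wave bookkeeping of a published sample from its printed chain
    counts, without any outcome or degree data.
    """
    records = []
    for c, (depth, size) in enumerate(chains):
        if size < depth + 1:
            raise ValueError(
                f"chain {c}: size {size} cannot reach depth {depth}"
            )
        if depth == 0 and size > 1:
            raise ValueError(f"chain {c}: depth-0 chain must have size 1")
        seed_id = f"c{c}w0"
        records.append(ParticipantRecord(id=seed_id, degree=degree))
        prev = seed_id
        for w in range(1, depth + 1):
            pid = f"c{c}w{w}"
            records.append(
                ParticipantRecord(id=pid, degree=degree, recruiter_id=prev)
            )
            prev = pid
        for j in range(size - depth - 1):
            records.append(
                ParticipantRecord(
                    id=f"c{c}x{j}", degree=degree, recruiter_id=seed_id
                )
            )
    return RecruitmentForest(records)


def _study_outcomes() -> dict[str, dict[str, float]]:
    return {
        "hiv": {"positive": 0.27, "negative": 0.73},
        "high_risk_sex": {"yes": 0.37, "no": 0.63},
        "idu": {"yes": 0.08, "no": 0.92},
    }


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic population.

    ``mixing`` maps an outcome name to a row-stochastic matrix M (rows and
    columns in sorted category order): the probability that a network tie
    from a group-g individual attaches to group h.  Only ``mixing_outcome``
    (default: the first key of ``mixing``, else the first outcome) steers
    the wiring; other outcomes are assigned independently and therefore
    carry essentially zero homophily.  ``mixing=None`` wires ties
    proportionately to group stub shares, i.e. no homophily on any outcome.
    Degrees are negative-binomial shifted to a minimum of 1 (heavy right
    tail, as self-reported network sizes typically are).
    """

    N: int = 33_960
    outcomes: Mapping[str, Mapping[str, float]] = field(
        default_factory=_study_outcomes
    )
    degree_mean: float = 20.0
    degree_dispersion: float = 2.0
    degree_min: int = 1
    mixing: Mapping[str, Sequence[Sequence[float]]] | None = None
    mixing_outcome: str | None = None

    def validate(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.degree_mean <= self.degree_min:
            raise ValueError("degree_mean must exceed degree_min")
        for name, prev in self.outcomes.items():
            total = sum(prev.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"prevalences of outcome {name!r} sum to {total}, not 1"
                )
        if self.mixing is not None:
            for name, m in self.mixing.items():
                if name not in self.outcomes:
                    raise ValueError(f"mixing given for unknown outcome {name!r}")
                m = np.asarray(m, dtype=float)
                k = len(self.outcomes[name])
                if m.shape != (k, k):
                    raise ValueError(
                        f"mixing matrix for {name!r} must be {k}x{k}"
                    )
                if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-9):
                    raise ValueError(
                        f"mixing matrix rows for {name!r} must be "
                        "non-negative and sum to 1"
                    )


@dataclass(frozen=True)
class RecruitmentConfig:
    """Parameters of the coupon-based recruitment process.

    Defaults emulate the emulated study's field design: up to 6 coupons per
    enrollee, a per-coupon redemption probability low enough that chains are
    subcritical (6 x 0.14 ≈ 0.84 expected recruits per enrollee), 30 initial
    seeds, and automatic injection of fresh uniform seeds whenever the
    recruitment queue dies before the target sample size — mirroring the
    pragmatic addition of seeds during fieldwork.
    """

    n_seeds: int = 30
    seed_rule: str = "uniform"  # uniform | degree-biased | group-biased
    coupons_max: int = 6
    coupon_return_prob: float = 0.14
    target_n: int = 719
    replacement: str = "without"
    degree_noise_sd: float = 0.0  # sd of multiplicative lognormal report noise
    max_seed_injections: int = 100_000

    def validate(self, N: int) -> None:
        if self.coupons_max < 1:
            raise ValueError("coupons_max must be >= 1")
        if not 0.0 <= self.coupon_return_prob <= 1.0:
            raise ValueError("coupon_return_prob must be in [0, 1]")
        if self.seed_rule not in ("uniform", "degree-biased", "group-biased"):
            raise ValueError(f"unknown seed_rule {self.seed_rule!r}")
        if self.replacement not in ("without", "with"):
            raise ValueError(f"unknown replacement mode {self.replacement!r}")
        if self.replacement == "without" and self.target_n > N:
            raise ValueError(
                f"target_n={self.target_n} exceeds population N={N} "
                "in without-replacement mode"
            )
        if self.n_seeds < 1 or self.n_seeds > N:
            raise ValueError("n_seeds must be in [1, N]")


@dataclass
class SyntheticTruth:
    """Generator-side ground truth for recovery tests."""

    N: int
    prevalences: dict[str, dict[str, float]]
    mixing_outcome: str
    mixing_categories: list[str]
    mixing: np.ndarray  # realized degree-weighted tie transition matrix
    homophily: dict[str, float]
    degrees: np.ndarray  # realized degree of every node


@dataclass
class Population:
    """A wired synthetic population (simple graph, CSR adjacency)."""

    config: PopulationConfig
    labels: dict[str, np.ndarray]  # outcome -> per-node category code
    categories: dict[str, list[str]]  # outcome -> sorted category labels
    target_degrees: np.ndarray
    indptr: np.ndarray
    indices: np.ndarray
    mixing_outcome: str
    rng_seed: int | None = None

    @property
    def N(self) -> int:
        return self.config.N

    def realized_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, node: int) -> np.ndarray:
        return self.indices[self.indptr[node]: self.indptr[node + 1]]


def _pair_within_group(
    stub_nodes: np.ndarray,
    stub_groups: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Pair stubs with partners of their own group (odd stub dropped)."""
    edges = []
    for g in range(k):
        sel = rng.permutation(stub_nodes[stub_groups == g])
        half = len(sel) // 2
        if half:
            edges.append(np.column_stack([sel[:half], sel[half: 2 * half]]))
    return edges


def _pair_stubs(
    stub_nodes: np.ndarray,
    stub_groups: np.ndarray,
    m: np.ndarray,
    rng: np.random.Generator,
    rounds: int = 6,
) -> np.ndarray:
    """Match stubs into edges, steering cross-group ties by ``m``.

    Each stub draws a desired partner group from its row of ``m``; matched
    counts between two groups are limited by the smaller side; unmatched
    stubs re-draw over several rounds and are finally paired within their
    own group, so a hard-zero entry of ``m`` (e.g. identity mixing) never
    produces a cross-group edge.  Realized mixing therefore interpolates
    between ``m`` and what the group stub supply can support.
    Returns an (E, 2) array of node pairs (may contain self-loops/dupes).
    """
    k = m.shape[0]
    edges: list[np.ndarray] = []
    nodes, groups = stub_nodes, stub_groups
    for _ in range(rounds):
        if len(nodes) < 2:
            break
        targets = np.empty(len(nodes), dtype=np.intp)
        for g in range(k):
            sel = groups == g
            cnt = int(sel.sum())
            if cnt:
                targets[sel] = rng.choice(k, size=cnt, p=m[g])
        left_nodes, left_groups = [], []
        for g in range(k):
            within = nodes[(groups == g) & (targets == g)]
            within = rng.permutation(within)
            half = len(within) // 2
            if half:
                edges.append(
                    np.column_stack([within[:half], within[half: 2 * half]])
                )
            if len(within) % 2:
                left_nodes.append(within[-1:])
                left_groups.append(np.full(1, g, dtype=np.intp))
            for h in range(g + 1, k):
                a = nodes[(groups == g) & (targets == h)]
                b = nodes[(groups == h) & (targets == g)]
                a, b = rng.permutation(a), rng.permutation(b)
                c = min(len(a), len(b))
                if c:
                    edges.append(np.column_stack([a[:c], b[:c]]))
                if len(a) > c:
                    left_nodes.append(a[c:])
                    left_groups.append(np.full(len(a) - c, g, dtype=np.intp))
                if len(b) > c:
                    left_nodes.append(b[c:])
                    left_groups.append(np.full(len(b) - c, h, dtype=np.intp))
        if not left_nodes:
            nodes = np.empty(0, dtype=nodes.dtype)
            break
        nodes = np.concatenate(left_nodes)
        groups = np.concatenate(left_groups)
    if len(nodes) >= 2:
        edges.extend(_pair_within_group(nodes, groups, k, rng))
    return np.concatenate(edges) if edges else np.empty((0, 2), dtype=np.intp)


def _clean_edges(
    edges: np.ndarray,
    node_groups: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 8,
) -> np.ndarray:
    """Resolve self-loops and multi-edges by bounded stub rewiring.

    Offending stub endpoints are re-paired *within their structural group*
    for up to ``max_rounds`` rounds (so rewiring never creates cross-group
    ties that the mixing matrix forbade); whatever still clashes is dropped,
    a negligible fraction, so realized degrees stay close to their targets.
    """
    if len(edges) == 0:
        return np.empty((0, 2), dtype=np.int64)
    k = int(node_groups.max()) + 1
    cur = edges.astype(np.int64)
    base = int(cur.max()) + 1
    seen = np.empty(0, dtype=np.int64)
    good: list[np.ndarray] = []
    for _ in range(max_rounds):
        if len(cur) == 0:
            break
        canon = np.sort(cur, axis=1)
        keys = canon[:, 0] * base + canon[:, 1]
        self_loop = canon[:, 0] == canon[:, 1]
        _, first_idx = np.unique(keys, return_index=True)
        dup_in_batch = np.ones(len(keys), dtype=bool)
        dup_in_batch[first_idx] = False
        ok = ~self_loop & ~dup_in_batch & ~np.isin(keys, seen)
        good.append(canon[ok])
        seen = np.concatenate([seen, keys[ok]])
        bad_stubs = canon[~ok].ravel()
        if len(bad_stubs) < 2:
            break
        repaired = _pair_within_group(
            bad_stubs, node_groups[bad_stubs], k, rng
        )
        if not repaired:
            break
        cur = np.concatenate(repaired)
    return np.concatenate(good) if good else np.empty((0, 2), dtype=np.int64)


def generate_population(
    config: PopulationConfig | None = None, rng_seed: int = 0
) -> tuple[Population, SyntheticTruth]:
    """Build an explicit simple graph with group structure and known truth."""
    config = config or PopulationConfig()
    config.validate()
    rng = rng_from(rng_seed, 1)
    n = config.N

    categories = {
        name: sorted(prev) for name, prev in config.outcomes.items()
    }
    labels = {}
    for name, prev in config.outcomes.items():
        cats = categories[name]
        p = np.array([prev[c] for c in cats])
        labels[name] = rng.choice(len(cats), size=n, p=p)

    mu = config.degree_mean - config.degree_min
    r = config.degree_dispersion
    degrees = config.degree_min + rng.negative_binomial(r, r / (r + mu), size=n)

    if config.mixing_outcome is not None:
        mixing_outcome = config.mixing_outcome
    elif config.mixing:
        mixing_outcome = next(iter(config.mixing))
    else:
        mixing_outcome = next(iter(config.outcomes))
    k = len(categories[mixing_outcome])
    g = labels[mixing_outcome]
    if config.mixing is not None and mixing_outcome in config.mixing:
        m = np.asarray(config.mixing[mixing_outcome], dtype=float)
    else:
        # proportionate wiring: every row is the group stub-share vector
        stub_share = np.bincount(g, weights=degrees.astype(float), minlength=k)
        stub_share = stub_share / stub_share.sum()
        m = np.tile(stub_share, (k, 1))

    stub_nodes = np.repeat(np.arange(n), degrees)
    edges = _pair_stubs(stub_nodes, g[stub_nodes], m, rng)
    edges = _clean_edges(edges, g, rng)

    # CSR adjacency from the undirected edge list
    both = np.concatenate([edges, edges[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    realized = np.bincount(both[:, 0], minlength=n)
    indptr = np.concatenate([[0], np.cumsum(realized)])
    indices = both[:, 1].copy()

    pop = Population(
        config=config,
        labels=labels,
        categories=categories,
        target_degrees=degrees,
        indptr=indptr.astype(np.int64),
        indices=indices.astype(np.int64),
        mixing_outcome=mixing_outcome,
        rng_seed=rng_seed,
    )
    realized_mean = pop.realized_degrees().mean()
    if n >= 1000 and abs(realized_mean - config.degree_mean) > 0.1 * config.degree_mean:
        log.warning(
            "realized mean degree %.2f deviates >10%% from target %.2f",
            realized_mean,
            config.degree_mean,
        )
    return pop, truth_report(pop)


def truth_report(pop: Population) -> SyntheticTruth:
    """Exact recomputation of ground truth from the stored population."""
    n = pop.N
    prevalences = {
        name: {
            cat: float(np.mean(pop.labels[name] == j))
            for j, cat in enumerate(pop.categories[name])
        }
        for name in pop.categories
    }
    cats = pop.categories[pop.mixing_outcome]
    k = len(cats)
    g = pop.labels[pop.mixing_outcome]
    # directed tie transitions: every edge counted from both endpoints
    src = g[np.repeat(np.arange(n), np.diff(pop.indptr))]
    dst = g[pop.indices]
    counts = np.zeros((k, k))
    np.add.at(counts, (src, dst), 1.0)
    row = counts.sum(axis=1)
    t = np.divide(
        counts, row[:, None], out=np.full((k, k), np.nan), where=row[:, None] > 0
    )
    stub_share = row / row.sum() if row.sum() else np.full(k, np.nan)
    homophily = {}
    for j, cat in enumerate(cats):
        e_j, t_jj = stub_share[j], t[j, j]
        if not np.isfinite(e_j) or e_j <= 0 or e_j >= 1 or not np.isfinite(t_jj):
            homophily[cat] = float("nan")
        elif t_jj >= e_j:
            homophily[cat] = float((t_jj - e_j) / (1 - e_j))
        else:
            homophily[cat] = float((t_jj - e_j) / e_j)
    return SyntheticTruth(
        N=n,
        prevalences=prevalences,
        mixing_outcome=pop.mixing_outcome,
        mixing_categories=list(cats),
        mixing=t,
        homophily=homophily,
        degrees=pop.realized_degrees(),
    )


@dataclass
class SimulationResult:
    """A simulated recruitment sample plus its generating truth."""

    forest: RecruitmentForest
    truth: SyntheticTruth
    seeds_injected: int
    reached_target: bool
    node_of: dict[str, int]


def _select_seeds(
    pop: Population, rconfig: RecruitmentConfig, rng: np.random.Generator
) -> np.ndarray:
    n = pop.N
    if rconfig.seed_rule == "uniform":
        return rng.choice(n, size=rconfig.n_seeds, replace=False)
    if rconfig.seed_rule == "degree-biased":
        w = np.maximum(pop.realized_degrees(), 1).astype(float)
        return rng.choice(n, size=rconfig.n_seeds, replace=False, p=w / w.sum())
    # group-biased: spread seeds as evenly as possible over structural groups
    g = pop.labels[pop.mixing_outcome]
    k = len(pop.categories[pop.mixing_outcome])
    per = np.full(k, rconfig.n_seeds // k)
    per[: rconfig.n_seeds % k] += 1
    chosen = []
    for j in range(k):
        members = np.flatnonzero(g == j)
        take = min(per[j], len(members))
        if take:
            chosen.append(rng.choice(members, size=take, replace=False))
    out = np.concatenate(chosen)
    rng.shuffle(out)
    return out


def simulate_rds(
    pop: Population,
    rconfig: RecruitmentConfig | None = None,
    rng_seed: int = 0,
) -> SimulationResult:
    """Simulate coupon-based peer recruitment over the population graph.

    FIFO processing: each enrollee's coupons are resolved in enrollment
    order; a returned coupon enrolls a uniformly chosen not-yet-enrolled
    neighbor one wave below the recruiter.  When the queue empties before
    the target sample size, a fresh uniform seed is injected (and counted).
    Waves therefore equal BFS depth from the recruiting seed.  Reported
    network size is the true realized degree (optionally with multiplicative
    log-normal reporting noise), floored at 1.
    """
    rconfig = rconfig or RecruitmentConfig()
    rconfig.validate(pop.N)
    rng = rng_from(rng_seed, 2)
    n = pop.N
    without = rconfig.replacement == "without"

    enrolled = np.zeros(n, dtype=bool)
    recruiter: dict[str, str | None] = {}
    node_of: dict[str, int] = {}
    order: list[str] = []
    next_uid = 0

    def enroll(node: int, parent_uid: str | None) -> str:
        nonlocal next_uid
        uid = f"P{next_uid:05d}"
        next_uid += 1
        enrolled[node] = True
        recruiter[uid] = parent_uid
        node_of[uid] = int(node)
        order.append(uid)
        return uid

    queue: deque[tuple[str, int]] = deque()
    for node in _select_seeds(pop, rconfig, rng):
        if len(order) >= rconfig.target_n:
            break
        uid = enroll(int(node), None)
        queue.append((uid, int(node)))

    injected = 0
    while len(order) < rconfig.target_n:
        if not queue:
            pool = np.flatnonzero(~enrolled)
            if len(pool) == 0 or injected >= rconfig.max_seed_injections:
                break
            node = int(pool[rng.integers(len(pool))])
            uid = enroll(node, None)
            queue.append((uid, node))
            injected += 1
            continue
        uid, node = queue.popleft()
        for _ in range(rconfig.coupons_max):
            if len(order) >= rconfig.target_n:
                break
            if rng.random() >= rconfig.coupon_return_prob:
                continue
            nbrs = pop.neighbors(node)
            if without:
                nbrs = nbrs[~enrolled[nbrs]]
            if len(nbrs) == 0:
                continue
            child = int(nbrs[rng.integers(len(nbrs))])
            child_uid = enroll(child, uid)
            queue.append((child_uid, child))

    if injected:
        log.info("injected %d additional seeds to sustain recruitment", injected)
    reached = len(order) >= rconfig.target_n
    if not reached:
        log.warning(
            "recruitment exhausted at n=%d before target %d",
            len(order),
            rconfig.target_n,
        )

    realized = pop.realized_degrees()
    records = []
    for enroll_order, uid in enumerate(order):
        node = node_of[uid]
        degree = max(int(realized[node]), 1)
        if rconfig.degree_noise_sd > 0:
            degree = max(
                1,
                int(round(degree * rng.lognormal(0.0, rconfig.degree_noise_sd))),
            )
        outcomes = {
            name: pop.categories[name][pop.labels[name][node]]
            for name in pop.categories
        }
        records.append(
            ParticipantRecord(
                id=uid,
                degree=degree,
                recruiter_id=recruiter[uid],
                enroll_order=enroll_order,
                outcomes=outcomes,
            )
        )
    forest = RecruitmentForest(records)
    return SimulationResult(
        forest=forest,
        truth=truth_report(pop),
        seeds_injected=injected,
        reached_target=reached,
        node_of=node_of,
    )
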