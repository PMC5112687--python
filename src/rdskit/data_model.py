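"""Recruitment tables, recruitment forests, wave bookkeeping and chain pruning.

A respondent-driven sample is a *forest*: purposively chosen seeds at wave 0,
and every other participant linked to the peer who recruited them (wave =
recruiter's wave + 1).  All downstream machinery — estimators, diagnostics,
the seed-sensitivity cuts — consumes the :class:`RecruitmentForest` built
here from a flat CSV table with one row per participant.
"""

from __future__ import annotations

import logging
import statistics
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent, round_half_away

log = logging.getLogger(__name__)

#: Sentinel for a blank outcome cell (non-response).
MISSING = None

#: Recruiter-cell spellings that mark a participant as a seed.
SEED_TOKENS = frozenset({"", "seed"})

__all__ = [
    "MISSING",
    "ParticipantRecord",
    "RecruitmentForest",
    "CutSummary",
    "TableSchema",
    "ForestValidationError",
    "ForestConsistencyError",
    "read_recruitment_table",
    "forest_from_frame",
    "write_forest_csv",
    "write_edge_list",
    "prune_by_min_depth",
    "cut_report",
    "cut_report_frame",
]


class ForestValidationError(ValueError):
    """Raised when a recruitment table violates forest structure.

    Carries the full list of problems so a data manager can fix every
    offending row in one pass.
    """

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid recruitment table: " + "; ".join(self.problems)
        )


class ForestConsistencyError(ValueError):
    """Raised when a supposedly derived forest is not a subset of its parent."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One sampled individual.

    ``degree`` is the self-reported network size (the number of eligible
    peers the participant could hand a coupon to) — the weighting variable of
    every RDS estimator.  ``recruiter_id is None`` marks a seed.  ``outcomes``
    maps outcome name to a category label, with ``None`` for non-response.
    """

    id: str
    degree: int
    recruiter_id: str | None = None
    enroll_order: int | None = None
    outcomes: Mapping[str, str | None] = field(default_factory=dict)

    @property
    def is_seed(self) -> bool:
        return self.recruiter_id is None


class RecruitmentForest:
    """A validated set of recruitment chains with derived wave structure.

    Validation enforces: unique ids, degree >= 1, every recruiter resolves to
    a participant in the table, no cycles (including self-recruitment).
    Waves are then forced: seeds sit at wave 0 and each recruit one wave
    below its recruiter, so wave assignment is independent of row order.
    """

    def __init__(self, records: Iterable[ParticipantRecord]):
        records = list(records)
        problems: list[str] = []
        by_id: dict[str, ParticipantRecord] = {}
        for r in records:
            if r.id in by_id:
                problems.append(f"duplicate id {r.id!r}")
            else:
                by_id[r.id] = r
            if r.degree is None or r.degree < 1:
                problems.append(f"degree < 1 for id {r.id!r}")
            if r.recruiter_id == r.id:
                problems.append(f"cycle: id {r.id!r} is its own recruiter")
        for r in records:
            if (
                r.recruiter_id is not None
                and r.recruiter_id != r.id
                and r.recruiter_id not in by_id
            ):
                problems.append(
                    f"recruiter {r.recruiter_id!r} of id {r.id!r} not in table"
                )
        if problems:
            raise ForestValidationError(problems)

        wave: dict[str, int] = {}
        seed_of: dict[str, str] = {}
        for r in records:
            if r.id in wave:
                continue
            path: list[str] = []
            on_path: set[str] = set()
            cur = r.id
            while cur not in wave:
                if cur in on_path:
                    cycle = path[path.index(cur):]
                    raise ForestValidationError(
                        [f"cycle detected among ids {cycle!r}"]
                    )
                path.append(cur)
                on_path.add(cur)
                rec = by_id[cur]
                if rec.recruiter_id is None:
                    wave[cur] = 0
                    seed_of[cur] = cur
                    break
                cur = rec.recruiter_id
            # unwind the path: each id sits one wave below its recruiter
            for pid in reversed(path):
                if pid in wave:
                    continue
                rid = by_id[pid].recruiter_id
                wave[pid] = wave[rid] + 1
                seed_of[pid] = seed_of[rid]

        self._records = by_id
        self._order = [r.id for r in records]
        self._wave = wave
        self._seed_of = seed_of
        chains: dict[str, list[str]] = {}
        for pid in self._order:
            chains.setdefault(seed_of[pid], []).append(pid)
        self._chains = chains
        self._chain_depth = {
            s: max(wave[m] for m in members) for s, members in chains.items()
        }

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._order)

    @property
    def n(self) -> int:
        return len(self._order)

    @property
    def ids(self) -> list[str]:
        return list(self._order)

    @property
    def records(self) -> list[ParticipantRecord]:
        return [self._records[i] for i in self._order]

    def __getitem__(self, pid: str) -> ParticipantRecord:
        return self._records[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self._records

    @property
    def seeds(self) -> list[str]:
        return [i for i in self._order if self._records[i].is_seed]

    @property
    def n_seeds(self) -> int:
        return len(self._chains)

    @property
    def wave(self) -> dict[str, int]:
        return dict(self._wave)

    @property
    def seed_of(self) -> dict[str, str]:
        return dict(self._seed_of)

    @property
    def chains(self) -> dict[str, list[str]]:
        """Seed id -> member ids (seed included), in table order."""
        return {s: list(m) for s, m in self._chains.items()}

    @property
    def chain_depth(self) -> dict[str, int]:
        """Seed id -> deepest wave reached by that chain (0 = unproductive)."""
        return dict(self._chain_depth)

    @property
    def max_wave(self) -> int:
        return max(self._wave.values()) if self._order else 0

    @property
    def outcome_names(self) -> list[str]:
        names: dict[str, None] = {}
        for pid in self._order:
            for k in self._records[pid].outcomes:
                names.setdefault(k)
        return list(names)

    # -- array views used by the estimators --------------------------------

    def degrees(self) -> np.ndarray:
        return np.array(
            [self._records[i].degree for i in self._order], dtype=float
        )

    def outcome_values(self, outcome: str) -> list[str | None]:
        """Category per record in table order (``None`` for non-response)."""
        return [self._records[i].outcomes.get(outcome) for i in self._order]

    def recruiter_pairs(self, outcome: str) -> list[tuple[str, str]]:
        """(recruiter category, recruit category) for every resolved pair
        where both ends are non-missing on ``outcome``."""
        pairs = []
        for pid in self._order:
            rec = self._records[pid]
            if rec.recruiter_id is None:
                continue
            g = self._records[rec.recruiter_id].outcomes.get(outcome)
            h = rec.outcomes.get(outcome)
            if g is not None and h is not None:
                pairs.append((g, h))
        return pairs

    # -- derived forests ---------------------------------------------------

    def restrict_to_chains(self, seed_ids: Iterable[str]) -> "RecruitmentForest":
        """New forest containing exactly the chains of ``seed_ids``."""
        keep = set(seed_ids)
        unknown = keep - set(self._chains)
        if unknown:
            raise KeyError(f"not seed ids of this forest: {sorted(unknown)!r}")
        return RecruitmentForest(
            self._records[i] for i in self._order if self._seed_of[i] in keep
        )

    def edge_list(self) -> list[tuple[str, str]]:
        """(child, parent) pairs, for external tree drawing."""
        return [
            (i, self._records[i].recruiter_id)
            for i in self._order
            if self._records[i].recruiter_id is not None
        ]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-participant table including derived wave/seed columns."""
        rows = []
        for pid in self._order:
            r = self._records[pid]
            row = {
                "id": r.id,
                "recruiter_id": r.recruiter_id,
                "degree": r.degree,
                "enroll_order": r.enroll_order,
                "wave": self._wave[pid],
                "seed": self._seed_of[pid],
            }
            for k in self.outcome_names:
                row[k] = r.outcomes.get(k)
            rows.append(row)
        return pd.DataFrame(rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecruitmentForest):
            return NotImplemented
        return self._order == other._order and self._records == other._records

    def __repr__(self) -> str:
        return (
            f"<RecruitmentForest n={self.n} chains={self.n_seeds} "
            f"max_wave={self.max_wave}>"
        )


@dataclass(frozen=True)
class TableSchema:
    """Column-name configuration for flat recruitment CSV files."""

    id_col: str = "id"
    recruiter_col: str = "recruiter_id"
    degree_col: str = "degree"
    enroll_order_col: str = "enroll_order"
    outcome_cols: Sequence[str] | None = None  # None: every remaining column


def read_recruitment_table(
    source,
    schema: TableSchema | None = None,
    *,
    impute_degree: bool = False,
) -> RecruitmentForest:
    """Read a flat recruitment CSV into a validated forest.

    The file must have a header row and at least the id and degree columns.
    A blank recruiter cell (or the literal ``seed``, any case) marks a seed;
    blank outcome cells are recorded as :data:`MISSING`.  Rows with a missing
    or sub-1 degree are rejected unless ``impute_degree`` is set, in which
    case the median of the valid degrees is substituted with a warning.
    """
    schema = schema or TableSchema()
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    return forest_from_frame(df, schema, impute_degree=impute_degree)


def forest_from_frame(
    df: pd.DataFrame,
    schema: TableSchema | None = None,
    *,
    impute_degree: bool = False,
) -> RecruitmentForest:
    """Build a forest from an already-loaded string DataFrame."""
    schema = schema or TableSchema()
    for col in (schema.id_col, schema.degree_col):
        if col not in df.columns:
            raise ForestValidationError([f"required column {col!r} missing"])
    reserved = {
        schema.id_col,
        schema.recruiter_col,
        schema.degree_col,
        schema.enroll_order_col,
    }
    outcome_cols = (
        list(schema.outcome_cols)
        if schema.outcome_cols is not None
        else [c for c in df.columns if c not in reserved]
    )

    problems: list[str] = []
    parsed: list[dict] = []
    for _, row in df.iterrows():
        pid = str(row[schema.id_col]).strip()
        if not pid:
            problems.append("blank id")
            continue
        raw_recruiter = (
            str(row[schema.recruiter_col]).strip()
            if schema.recruiter_col in df.columns
            else ""
        )
        recruiter = (
            None if raw_recruiter.lower() in SEED_TOKENS else raw_recruiter
        )
        raw_degree = str(row[schema.degree_col]).strip()
        try:
            degree = int(float(raw_degree))
            if degree < 1 or float(raw_degree) != degree:
                degree = None
        except ValueError:
            degree = None
        order = None
        if schema.enroll_order_col in df.columns:
            raw_order = str(row[schema.enroll_order_col]).strip()
            if raw_order:
                try:
                    order = int(raw_order)
                    if order < 0:
                        problems.append(f"negative enroll_order for {pid!r}")
                except ValueError:
                    problems.append(f"malformed enroll_order for {pid!r}")
        outcomes = {}
        for col in outcome_cols:
            val = str(row[col]).strip()
            outcomes[col] = val if val else MISSING
        parsed.append(
            {
                "id": pid,
                "degree": degree,
                "recruiter_id": recruiter,
                "enroll_order": order,
                "outcomes": outcomes,
            }
        )

    bad_degree = [p["id"] for p in parsed if p["degree"] is None]
    if bad_degree:
        if impute_degree:
            valid = [p["degree"] for p in parsed if p["degree"] is not None]
            if not valid:
                problems.append("no valid degrees to impute from")
            else:
                imputed = int(round(statistics.median(valid)))
                log.warning(
                    "imputed degree %d for %d participant(s): %s",
                    imputed,
                    len(bad_degree),
                    bad_degree,
                )
                for p in parsed:
                    if p["degree"] is None:
                        p["degree"] = imputed
        else:
            problems.append(
                "degree missing or < 1 for ids " + repr(bad_degree)
            )
    if problems:
        raise ForestValidationError(problems)
    return RecruitmentForest(
        ParticipantRecord(
            id=p["id"],
            degree=p["degree"],
            recruiter_id=p["recruiter_id"],
            enroll_order=p["enroll_order"],
            outcomes=p["outcomes"],
        )
        for p in parsed
    )


def write_forest_csv(
    forest: RecruitmentForest, dest, schema: TableSchema | None = None
) -> None:
    """Serialize losslessly: read -> write -> read gives an equal forest.

    Seeds are written with a blank recruiter cell; MISSING outcomes as empty
    strings.  Derived columns (wave, seed) are not written — they are forced
    by the links and recomputed on read.
    """
    schema = schema or TableSchema()
    rows = []
    for r in forest.records:
        row = {
            schema.id_col: r.id,
            schema.recruiter_col: r.recruiter_id or "",
            schema.degree_col: r.degree,
            schema.enroll_order_col: (
                "" if r.enroll_order is None else r.enroll_order
            ),
        }
        for k in forest.outcome_names:
            row[k] = r.outcomes.get(k) or ""
        rows.append(row)
    cols = [
        schema.id_col,
        schema.recruiter_col,
        schema.degree_col,
        schema.enroll_order_col,
        *forest.outcome_names,
    ]
    pd.DataFrame(rows, columns=cols).to_csv(dest, index=False)


def write_edge_list(forest: RecruitmentForest, dest) -> None:
    """Child,parent CSV export for external recruitment-tree drawing."""
    pd.DataFrame(forest.edge_list(), columns=["child", "parent"]).to_csv(
        dest, index=False
    )


def prune_by_min_depth(forest: RecruitmentForest, c: int) -> RecruitmentForest:
    """Keep exactly the chains that produced more than ``c`` recruitment waves.

    ``c = 0`` drops unproductive seeds (depth-0 chains), ``c = 1`` drops
    chains of <= 1 wave, and so on; ``c = -1`` is the identity (overall
    sample).  Chains are kept or dropped whole; the input is not modified.
    """
    keep = [s for s, d in forest.chain_depth.items() if d >= c + 1]
    return forest.restrict_to_chains(keep)


@dataclass(frozen=True)
class CutSummary:
    """Bookkeeping for one seed-productivity cut.

    Percentages are display values, rounded half-away-from-zero to one
    decimal; wave statistics are over per-chain depths at full precision.
    """

    min_depth: int
    n_remaining: int
    n_seeds: int
    seeds_pct_of_sample: float
    n_removed_vs_overall: int
    removed_pct_of_overall: float
    wave_mean: float
    wave_median: float
    wave_min: float
    wave_max: float


def cut_report(
    overall: RecruitmentForest,
    cut_forests: Sequence[tuple[int, RecruitmentForest]],
) -> list[CutSummary]:
    """Summarize a ladder of seed-productivity cuts against the full sample."""
    overall_ids = set(overall.ids)
    out = []
    for c, f in cut_forests:
        extra = set(f.ids) - overall_ids
        if extra or any(f[i] != overall[i] for i in f.ids):
            raise ForestConsistencyError(
                f"cut c={c} is not derived from the overall forest"
            )
        depths = sorted(f.chain_depth.values())
        out.append(
            CutSummary(
                min_depth=c,
                n_remaining=f.n,
                n_seeds=f.n_seeds,
                seeds_pct_of_sample=(
                    round_half_away(percent(f.n_seeds, f.n), 1)
                    if f.n
                    else float("nan")
                ),
                n_removed_vs_overall=overall.n - f.n,
                removed_pct_of_overall=round_half_away(
                    percent(overall.n - f.n, overall.n), 1
                ),
                wave_mean=(
                    float(np.mean(depths)) if depths else float("nan")
                ),
                wave_median=(
                    float(np.median(depths)) if depths else float("nan")
                ),
                wave_min=float(depths[0]) if depths else float("nan"),
                wave_max=float(depths[-1]) if depths else float("nan"),
            )
        )
    return out


def cut_report_frame(summaries: Sequence[CutSummary]) -> pd.DataFrame:
    """Cut report as a tidy table (one row per cut)."""
    return pd.DataFrame([s.__dict__ for s in summaries])
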