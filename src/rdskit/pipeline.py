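"""End-to-end pipeline: configuration, stage orchestration, report bundle.

A :class:`RunConfig` (from a YAML mapping or keyword arguments) fully
determines a run: the input recruitment table (or a simulation block), the
outcomes and estimators, population size N, cut ladder, bootstrap and
comparison settings, and one master RNG seed.  ``run_pipeline`` executes the
requested stages and writes a bundle of RFC-4180 CSV tables plus JSON
metadata and a human-readable markdown summary; every output embeds the
config hash and seed, so two runs with equal configs produce byte-identical
table bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, sensitivity
from .data_model import (
    RecruitmentForest,
    cut_report_frame,
    read_recruitment_table,
    write_edge_list,
    write_forest_csv,
)
from .estimators import build_transition_model
from .synthetic import (
    PopulationConfig,
    RecruitmentConfig,
    generate_population,
    simulate_rds,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "render_summary"]

ALL_STAGES = ("data", "estimates", "diagnostics", "comparison")


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (maps to CLI exit code 3)."""


@dataclass
class RunConfig:
    input: str | None = None
    simulate: dict | None = None
    outcomes: list[str] | None = None
    estimators: list[str] = field(
        default_factory=lambda: ["rds_i", "rds_ii", "rds_ss"]
    )
    N: float | None = None
    cuts: list[int] = field(default_factory=lambda: [-1, 0, 1, 2])
    B: int = 1000
    replicates: int = 100
    tree_fraction: float = 0.5
    alpha: float = 0.05
    epsilon: float = 0.01
    k_min: int = 10
    rng_seed: int = 0
    outdir: str = "rdskit_out"
    quiet: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(data)

    def validate(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'input' (a recruitment CSV) or 'simulate' "
                "(a simulation block) must be given"
            )
        if "rds_ss" in self.estimators and self.N is None and self.simulate is None:
            raise ConfigError("RDS-SS requested but population size N missing")
        if self.B < 2:
            raise ConfigError("B must be >= 2")
        if not 0.0 < self.tree_fraction <= 1.0:
            raise ConfigError("tree_fraction must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if any(c < -1 for c in self.cuts):
            raise ConfigError("cuts must be >= -1 (-1 denotes the full sample)")
        for est in self.estimators:
            if est not in ("crude", "rds_i", "rds_ii", "rds_ss"):
                raise ConfigError(f"unknown estimator {est!r}")

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    """RFC-4180 body preceded by one provenance comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# rdskit config={cfg.config_hash} seed={cfg.rng_seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _load_forest(cfg: RunConfig) -> tuple[RecruitmentForest, dict | None]:
    if cfg.input is not None:
        return read_recruitment_table(cfg.input), None
    block = cfg.simulate or {}
    pop_cfg = PopulationConfig(**block.get("population", {}))
    rec_cfg = RecruitmentConfig(**block.get("recruitment", {}))
    pop, truth = generate_population(pop_cfg, rng_seed=cfg.rng_seed)
    sim = simulate_rds(pop, rec_cfg, rng_seed=cfg.rng_seed)
    truth_payload = {
        "N": truth.N,
        "prevalences": truth.prevalences,
        "mixing_outcome": truth.mixing_outcome,
        "mixing_categories": truth.mixing_categories,
        "mixing": np.asarray(truth.mixing).tolist(),
        "homophily": truth.homophily,
        "seeds_injected": sim.seeds_injected,
        "reached_target": sim.reached_target,
    }
    return sim.forest, truth_payload


def run_pipeline(cfg: RunConfig, stages=ALL_STAGES) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns an in-memory bundle: DataFrames/objects per stage plus the paths
    written.  Raises :class:`ConfigError` for invalid configuration and
    :class:`StageError` (with the stage name) for runtime failures.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg, "warnings": []}

    stage = "load"
    try:
        forest, truth = _load_forest(cfg)
        bundle["forest"] = forest
        if truth is not None:
            bundle["truth"] = truth
        outcomes = cfg.outcomes or forest.outcome_names
        missing = [o for o in outcomes if o not in forest.outcome_names]
        if missing:
            raise ConfigError(f"outcomes not present in the table: {missing}")
        N = cfg.N
        if N is None and truth is not None:
            N = float(truth["N"])
        bundle["N"] = N

        if "data" in stages:
            stage = "data"
            from .data_model import prune_by_min_depth, cut_report

            cut_forests = [
                (c, prune_by_min_depth(forest, c)) for c in cfg.cuts
            ]
            summaries = cut_report(forest, cut_forests)
            bundle["cut_report"] = summaries
            _write_csv(cut_report_frame(summaries), outdir / "cut_report.csv", cfg)
            write_forest_csv(forest, outdir / "forest.csv")
            write_edge_list(forest, outdir / "edge_list.csv")
            if truth is not None:
                (outdir / "truth.json").write_text(
                    json.dumps(
                        {"config": cfg.config_hash, "seed": cfg.rng_seed, **truth},
                        indent=2,
                        allow_nan=True,
                    )
                )

        if "estimates" in stages:
            stage = "estimates"
            report = sensitivity.run_cut_analysis(
                forest,
                outcomes,
                estimators=cfg.estimators,
                N=N,
                B=cfg.B,
                rng_seed=cfg.rng_seed,
                cuts=cfg.cuts,
            )
            bundle["sensitivity"] = report
            _write_csv(report.frame(), outdir / "estimates.csv", cfg)
            for key, msg in report.errors.items():
                bundle["warnings"].append(f"estimate {key}: {msg}")

        if "diagnostics" in stages:
            stage = "diagnostics"
            series = []
            homophily_rows = []
            equilibrium = {}
            for outcome in outcomes:
                try:
                    overall = diagnostics.convergence_series(
                        forest, outcome, k_min=cfg.k_min, N=N
                    )
                    per_seed = diagnostics.bottleneck_series(
                        forest, outcome, k_min=cfg.k_min, N=N
                    )
                    series.append(overall)
                    series.extend(per_seed)
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    bundle["warnings"].append(
                        f"diagnostic series for {outcome!r} skipped: {exc}"
                    )
                try:
                    model = build_transition_model(forest, outcome)
                    for grp, h in diagnostics.homophily_index(model).items():
                        homophily_rows.append(
                            {"outcome": outcome, "category": grp, "homophily": h}
                        )
                    rep = diagnostics.equilibrium_waves(
                        model, epsilon=cfg.epsilon
                    )
                    equilibrium[outcome] = {
                        "epsilon": rep.epsilon,
                        "start_mode": rep.start_mode,
                        "waves": {
                            k: (None if math.isinf(v) else v)
                            for k, v in rep.waves.items()
                        },
                        "ergodic": rep.ergodic,
                        "notes": list(rep.notes),
                    }
                except Exception as exc:  # noqa: BLE001
                    bundle["warnings"].append(
                        f"transition diagnostics for {outcome!r} skipped: {exc}"
                    )
            bundle["series"] = series
            bundle["homophily"] = homophily_rows
            bundle["equilibrium"] = equilibrium
            _write_csv(
                diagnostics.series_frame(series), outdir / "diagnostic_series.csv", cfg
            )
            _write_csv(
                pd.DataFrame(
                    homophily_rows, columns=["outcome", "category", "homophily"]
                ),
                outdir / "homophily.csv",
                cfg,
            )
            (outdir / "equilibrium.json").write_text(
                json.dumps(
                    {
                        "config": cfg.config_hash,
                        "seed": cfg.rng_seed,
                        "outcomes": equilibrium,
                    },
                    indent=2,
                )
            )

        if "comparison" in stages:
            stage = "comparison"
            comparison = sensitivity.compare_estimators_simulation(
                forest,
                outcomes,
                replicates=cfg.replicates,
                tree_fraction=cfg.tree_fraction,
                alpha=cfg.alpha,
                rng_seed=cfg.rng_seed,
                estimators=(
                    cfg.estimators
                    if "crude" in cfg.estimators
                    else ["crude", *cfg.estimators]
                ),
                N=N,
            )
            bundle["comparison"] = comparison
            _write_csv(comparison.frame(), outdir / "comparison.csv", cfg)
            if comparison.redraws:
                bundle["warnings"].append(
                    f"comparison: {comparison.redraws} replicate redraw(s)"
                )
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(
            f"stage {stage!r} failed: {exc}. Check the inputs this stage "
            "consumes (see the traceback above for the offending operation)."
        ) from exc

    meta = {
        "config_hash": cfg.config_hash,
        "rng_seed": cfg.rng_seed,
        "config": json.loads(cfg.canonical_json()),
        "stages": list(stages),
        "n": forest.n,
        "n_chains": forest.n_seeds,
        "max_wave": forest.max_wave,
        "warnings": bundle["warnings"],
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))
    (outdir / "summary.md").write_text(render_summary(bundle))
    bundle["outdir"] = outdir
    return bundle


def render_summary(bundle: dict) -> str:
    """Assemble the human-readable markdown report for a bundle."""
    cfg: RunConfig = bundle["config"]
    lines = [
        "# rdskit run summary",
        "",
        f"- config hash: `{cfg.config_hash}`  seed: {cfg.rng_seed}",
    ]
    forest = bundle.get("forest")
    if forest is not None:
        lines.append(
            f"- sample: n={forest.n}, chains={forest.n_seeds}, "
            f"max wave={forest.max_wave}"
        )
    if "cut_report" in bundle:
        lines += ["", "## Seed-productivity cuts", ""]
        lines.append(cut_report_frame(bundle["cut_report"]).to_markdown(index=False))
    if "sensitivity" in bundle:
        report = bundle["sensitivity"]
        lines += ["", "## Estimates by cut", ""]
        lines.append(report.frame().to_markdown(index=False))
        failures = [k for k, ok in report.containment.items() if not ok]
        if failures:
            lines += ["", "**Crude-outside-CI cells (check homophily!):**", ""]
            lines += [f"- {cut} / {outcome} / {est}" for cut, outcome, est in failures]
        else:
            lines += ["", "All crude proportions fall inside the weighted CIs."]
    if "homophily" in bundle and bundle["homophily"]:
        lines += ["", "## Homophily", ""]
        lines.append(
            pd.DataFrame(bundle["homophily"]).to_markdown(index=False)
        )
    if "equilibrium" in bundle and bundle["equilibrium"]:
        lines += ["", "## Waves to equilibrium", ""]
        for outcome, rep in bundle["equilibrium"].items():
            waves = ", ".join(
                f"{k}: {'∞' if v is None else int(v)}" for k, v in rep["waves"].items()
            )
            lines.append(f"- {outcome} (ε={rep['epsilon']}): {waves}")
    if "comparison" in bundle:
        lines += ["", "## Estimator comparison (seed-tree subsamples)", ""]
        lines.append(bundle["comparison"].frame().to_markdown(index=False))
    if bundle.get("warnings"):
        lines += ["", "## Warnings", ""]
        lines += [f"- {w}" for w in bundle["warnings"]]
    return "\n".join(lines) + "\n"
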