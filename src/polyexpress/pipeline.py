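"""End-to-end pipeline driver: simulate -> reconcile -> classify -> summarize.

A run is described by a single config (YAML on disk, dict in memory); every
output file records the hash of the config that produced it, so artifacts
can be traced back to their exact settings.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import polyexpress
from polyexpress.band_matrix import (
    ReconcileRule,
    Unit,
    read_band_tsv,
    reconcile_replicates,
    units_to_frame,
    write_band_tsv,
)
from polyexpress.classify import Category, classify_unit
from polyexpress.summarize import report_dict, tally
from polyexpress.synthetic_data import (
    SimulationConfig,
    assign_category_profiles,
    simulate_band_matrix,
    truth_to_rows,
)

logger = logging.getLogger("polyexpress")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Settings of one pipeline run.

    ``simulate=True`` generates the band matrix from ``simulation``;
    otherwise ``matrix_path`` must name an existing band-matrix TSV.
    """

    out_dir: Path
    simulate: bool = True
    matrix_path: Path | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reconcile_rule: ReconcileRule = ReconcileRule.ALL_PRESENT
    delta: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim_raw = dict(raw.get("simulation", {}))
        if "category_proportions" in sim_raw:
            sim_raw["category_proportions"] = {
                Category(k): float(v)
                for k, v in sim_raw["category_proportions"].items()
            }
        seed = int(raw.get("seed", 0))
        sim_raw.setdefault("seed", seed)
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "polyexpress_run")),
            simulate=bool(raw.get("simulate", True)),
            matrix_path=Path(raw["matrix_path"]) if raw.get("matrix_path") else None,
            simulation=SimulationConfig(**sim_raw),
            reconcile_rule=ReconcileRule(raw.get("reconcile_rule", "all_present")),
            delta=int(raw.get("delta", 0)),
            seed=seed,
        )
        return cfg

    def to_dict(self) -> dict:
        sim = self.simulation
        return {
            "out_dir": str(self.out_dir),
            "simulate": self.simulate,
            "matrix_path": str(self.matrix_path) if self.matrix_path else None,
            "simulation": {
                "n_units": sim.n_units,
                "n_no_change": sim.n_no_change,
                "category_proportions": {
                    str(c): p for c, p in sorted(
                        sim.category_proportions.items(), key=lambda kv: kv[0].value
                    )
                },
                "intensity_levels": sim.intensity_levels,
                "dropout_rate": sim.dropout_rate,
                "intensity_jitter_sd": sim.intensity_jitter_sd,
                "n_replicates": sim.n_replicates,
                "allocation": sim.allocation,
                "seed": sim.seed,
            },
            "reconcile_rule": self.reconcile_rule.value,
            "delta": self.delta,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# polyexpress config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def classify_units_frame(units: list[Unit], delta: int = 0) -> pd.DataFrame:
    """Classify reconciled units; returns the unit table plus a category column."""
    df = units_to_frame(units)
    df["category"] = [
        str(classify_unit(u.levels, delta=delta)) for u in units
    ]
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the summary report dict.

    Writes matrix.tsv (+ truth.tsv when simulating), units.tsv,
    categories.tsv, report.json and run_log.json under ``config.out_dir``.
    Any stage failure raises PipelineError after logging the cause; no
    partial stage output is left behind for the failed stage.
    """
    cfg_hash = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
                logger.info("stage %s finished in %.3fs", name, timings[name])

        return _T()

    if config.simulate:
        with stage("simulate"):
            truth = assign_category_profiles(config.simulation)
            matrix = simulate_band_matrix(truth, config.simulation)
            _write_tsv(
                pd.DataFrame(truth_to_rows(truth)), out / "truth.tsv", cfg_hash
            )
            with open(out / "matrix.tsv", "w") as fh:
                fh.write(f"# polyexpress config_hash={cfg_hash}\n")
                write_band_tsv(matrix, fh)
    else:
        with stage("load"):
            if config.matrix_path is None or not Path(config.matrix_path).exists():
                raise FileNotFoundError(
                    f"band matrix not found: {config.matrix_path}"
                )
            matrix = read_band_tsv(
                config.matrix_path, max_level=config.simulation.intensity_levels
            )

    with stage("reconcile"):
        units = reconcile_replicates(matrix, rule=config.reconcile_rule)
        _write_tsv(units_to_frame(units), out / "units.tsv", cfg_hash)

    with stage("classify"):
        cat_df = classify_units_frame(units, delta=config.delta)
        _write_tsv(cat_df, out / "categories.tsv", cfg_hash)

    with stage("summarize"):
        cats = [Category(c) for c in cat_df["category"]]
        report = report_dict(tally(cats))
        report["config_hash"] = cfg_hash
        report["seed"] = config.seed
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")

    run_log = {
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "seed": config.seed,
        "polyexpress_version": polyexpress.__version__,
        "stage_timings_s": timings,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
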