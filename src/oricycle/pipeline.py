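"""End-to-end pipeline: simulate -> render -> extract -> QC -> decompose
-> diagnose, with YAML configuration and deterministic seeding.

Every stochastic stage derives its seed from the single global seed plus
a fixed stage tag, so one integer reproduces the whole artifact
directory byte for byte.  Simulated tracks are formatted as the same
frame table a mother-machine experiment produces and sent through the
same extraction and analysis code, so real tabular data can be injected
at the extraction boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cycle_extraction import (
    QCThresholds,
    build_division_cycles,
    build_replication_cycles,
    qc_filter,
    true_division_cycles,
)
from .decomposition import get_pool, rank_decompositions
from .diagnostics import (
    compare_sim_to_reference,
    model_diagnostics_suite,
    mother_daughter_birth_correlation,
)
from .simulator import (
    LineageEventLog,
    ModelParams,
    SimConfig,
    default_params,
    simulate_lineages,
)
from .synthetic_microscopy import ObsConfig, render_frames, write_frame_table

__all__ = [
    "ConfigError",
    "PipelineError",
    "PipelineConfig",
    "load_config",
    "dump_config",
    "stage_seed",
    "run_pipeline",
    "events_to_frame",
    "trajectory_to_frame",
]

logger = logging.getLogger("oricycle")

_STAGE_TAGS = {"simulate": 11, "render": 23}


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(
        entropy=int(global_seed), spawn_key=(_STAGE_TAGS[stage],)
    )
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Nested configuration of the whole pipeline.

    ``pool_mode`` selects the headline ranking; both full pools are
    always written.  The nested ``sim.seed``/``obs.seed`` values are
    derived from the single global ``seed`` at run time.
    """

    seed: int = 0
    pool_mode: str = "replication_centric_full"
    model: ModelParams = field(default_factory=ModelParams)
    sim: SimConfig = field(default_factory=SimConfig)
    obs: ObsConfig = field(default_factory=ObsConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)

    def resolve_seeds(self) -> None:
        self.sim.seed = stage_seed(self.seed, "simulate")
        self.obs.seed = stage_seed(self.seed, "render")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "pool_mode": self.pool_mode,
            "model": dataclasses.asdict(self.model),
            "sim": dataclasses.asdict(self.sim),
            "obs": dataclasses.asdict(self.obs),
            "qc": dataclasses.asdict(self.qc),
        }
        # nested seeds are derived, not configuration
        d["sim"].pop("seed", None)
        d["obs"].pop("seed", None)
        for key in ("lambda_dist", "dLif_dist", "dLid_dist", "ratio_dist"):
            if d["model"].get(key) is None:
                d["model"].pop(key, None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTION_TYPES = {
    "model": ModelParams,
    "sim": SimConfig,
    "obs": ObsConfig,
    "qc": QCThresholds,
}


def _build_section(name: str, cls, data: dict, base=None):
    obj = base if base is not None else cls()
    valid = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key {name}.{key!r}")
        f = valid[key]
        current = getattr(obj, key)
        if f.type in ("float", float) or isinstance(current, float):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(
                    f"key {name}.{key!r} expects a number, got {value!r}"
                )
            value = float(value)
        elif isinstance(current, bool):
            if not isinstance(value, bool):
                raise ConfigError(
                    f"key {name}.{key!r} expects a boolean, got {value!r}"
                )
        elif isinstance(current, int):
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(
                    f"key {name}.{key!r} expects an integer, got {value!r}"
                )
        elif isinstance(current, str):
            if not isinstance(value, str):
                raise ConfigError(
                    f"key {name}.{key!r} expects a string, got {value!r}"
                )
        setattr(obj, key, value)
    return obj


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration.

    Absent keys take their defaults (variant-aware for the model
    section); unknown keys are rejected with the offending key named.
    An empty file yields the full default configuration.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = PipelineConfig()
    known_top = {"seed", "pool_mode", "model", "sim", "obs", "qc"}
    for key in data:
        if key not in known_top:
            raise ConfigError(f"unknown key {key!r}")
    if "seed" in data:
        if not isinstance(data["seed"], int) or isinstance(data["seed"], bool):
            raise ConfigError("key 'seed' expects an integer")
        cfg.seed = data["seed"]
    if "pool_mode" in data:
        if not isinstance(data["pool_mode"], str):
            raise ConfigError("key 'pool_mode' expects a string")
        get_pool(data["pool_mode"])  # validates the mode
        cfg.pool_mode = data["pool_mode"]
    model_data = data.get("model") or {}
    if not isinstance(model_data, dict):
        raise ConfigError("section 'model' must be a mapping")
    variant = model_data.get("model_variant", "double_adder")
    cfg.model = _build_section(
        "model", ModelParams, model_data, base=default_params(variant)
    )
    for section in ("sim", "obs", "qc"):
        sec_data = data.get(section) or {}
        if not isinstance(sec_data, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        setattr(
            cfg,
            section,
            _build_section(section, _SECTION_TYPES[section], sec_data),
        )
    cfg.model.validate()
    cfg.sim.validate()
    cfg.obs.validate()
    return cfg


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Event-log serialization
# ---------------------------------------------------------------------------


def events_to_frame(logs: list[LineageEventLog]) -> pd.DataFrame:
    """Tidy table of all initiation and division events."""
    rows = []
    for log in logs:
        for ev in log.initiations:
            rows.append(
                {
                    "lane_id": log.lineage_id,
                    "event": "initiation",
                    "time": ev.time,
                    "generation": ev.generation,
                    "length": ev.length,
                    "n_pre": ev.n_pre,
                    "n_post": ev.n_post,
                    "ratio": np.nan,
                    "control_draw": ev.d_lif_drawn,
                    "new_growth_rate": np.nan,
                    "burn_in": ev.generation < log.burn_in_generations,
                }
            )
        for ev in log.divisions:
            rows.append(
                {
                    "lane_id": log.lineage_id,
                    "event": "division",
                    "time": ev.time,
                    "generation": ev.generation,
                    "length": ev.mother_length,
                    "n_pre": ev.n_before,
                    "n_post": ev.n_after,
                    "ratio": ev.ratio,
                    "control_draw": ev.d_lid_drawn,
                    "new_growth_rate": ev.new_growth_rate,
                    "burn_in": ev.generation < log.burn_in_generations,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["lane_id", "time"]).reset_index(drop=True)
    return df


def trajectory_to_frame(
    logs: list[LineageEventLog], every: int = 1
) -> pd.DataFrame:
    """Sampled (time, length, n_ori) trajectory of every lineage."""
    parts = []
    for log in logs:
        sl = slice(None, None, every)
        parts.append(
            pd.DataFrame(
                {
                    "lane_id": log.lineage_id,
                    "time": np.asarray(log.times)[sl],
                    "length": np.asarray(log.lengths)[sl],
                    "n_ori": np.asarray(log.n_oris)[sl],
                    "generation": np.asarray(log.generations)[sl],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _write_csv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full pipeline and write every intermediate artifact.

    Returns a dict of artifact paths plus headline numbers.  Any stage
    error is re-raised as :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.resolve_seeds()
    provenance = [
        f"oricycle {__version__}",
        f"seed={config.seed} config_hash={config.config_hash()}",
    ]
    dump_config(config, outdir / "config.yaml")
    artifacts: dict = {"outdir": str(outdir)}

    def _stage(name, fn, *args, **kwargs):
        t0 = _time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info(
            "stage=%s elapsed=%.1fs", name, _time.perf_counter() - t0
        )
        return result

    logs = _stage("simulate", simulate_lineages, config.model, config.sim)
    n_aborted = sum(log.aborted for log in logs)
    logger.info(
        "stage=simulate lineages=%d aborted=%d premature_divisions=%d",
        len(logs),
        n_aborted,
        sum(log.premature_divisions for log in logs),
    )
    _write_csv(events_to_frame(logs), outdir / "events.csv", provenance)
    step = max(1, int(round(config.obs.frame_interval / config.sim.dt)))
    _write_csv(
        trajectory_to_frame(logs, every=step),
        outdir / "trajectory.csv",
        provenance,
    )

    frames = _stage("render", render_frames, logs, config.obs)
    write_frame_table(frames, outdir / "frames.csv")
    logger.info("stage=render frames=%d", len(frames))

    division = _stage("extract", build_division_cycles, frames)
    replication = _stage("extract", build_replication_cycles, frames)
    _write_csv(division, outdir / "division_cycles.csv", provenance)
    _write_csv(replication, outdir / "replication_cycles.csv", provenance)

    div_f, div_report = _stage("qc", qc_filter, division, config.qc)
    rep_f, rep_report = _stage("qc", qc_filter, replication, config.qc)
    logger.info(
        "stage=qc division in=%d kept=%d replication in=%d kept=%d",
        div_report.n_input,
        div_report.n_kept,
        rep_report.n_input,
        rep_report.n_kept,
    )
    _write_csv(div_f, outdir / "division_cycles_qc.csv", provenance)
    _write_csv(rep_f, outdir / "replication_cycles_qc.csv", provenance)
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(
            {
                "division": div_report.to_dict(),
                "replication": rep_report.to_dict(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    rankings = {}
    for mode, table in (
        ("replication_centric_full", rep_f),
        ("division_centric_full", div_f),
    ):
        report = _stage("decompose", rank_decompositions, table, get_pool(mode))
        rankings[mode] = report
        _write_csv(
            report.ranking, outdir / f"ranking_{mode}.csv", provenance
        )
    with open(outdir / "ranking.txt", "w") as fh:
        for mode in rankings:
            fh.write(rankings[mode].to_text() + "\n\n")

    diag = _stage(
        "diagnose",
        model_diagnostics_suite,
        div_f,
        rep_f,
        config.model.model_variant,
    )
    md_r, md_p, md_n = mother_daughter_birth_correlation(div_f)
    comparison = compare_sim_to_reference(div_f, true_division_cycles(logs))
    _write_csv(diag.to_frame(), outdir / "diagnostics.csv", provenance)
    with open(outdir / "diagnostics.txt", "w") as fh:
        fh.write(diag.to_text() + "\n")
        fh.write(
            f"mother-daughter birth-length correlation: r={md_r:.3f} "
            f"p={md_p:.2e} n={md_n}\n"
        )
        fh.write(
            "extracted-vs-exact comparison: "
            + json.dumps(
                {
                    k: v
                    for k, v in comparison.items()
                    if not k.startswith("origins_at_birth_hist")
                },
                sort_keys=True,
            )
            + "\n"
        )

    headline = rankings[config.pool_mode].ranking
    artifacts.update(
        {
            "n_lineages": len(logs),
            "n_division_cycles": len(div_f),
            "n_replication_cycles": len(rep_f),
            "top_decomposition": (
                headline["variables"].iloc[0] if len(headline) else None
            ),
            "top_independence": (
                float(headline["independence"].iloc[0])
                if len(headline)
                else None
            ),
            "mother_daughter_birth_r": md_r,
            "rankings": rankings,
            "diagnostics": diag,
            "qc": {
                "division": div_report.to_dict(),
                "replication": rep_report.to_dict(),
            },
        }
    )
    return artifacts
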