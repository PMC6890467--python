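"""Render exact lineage event logs into noisy mother-machine observations.

The extraction pipeline downstream consumes tabular per-frame records
(cell length and fluorescent-spot counts), the same contract produced by
segmentation/spot-detection of real time-lapse data.  This module
emulates that contract directly from simulated trajectories: frame
sampling at a fixed interval, multiplicative log-normal length noise,
origins placed at mid-cell/quarter positions with jitter, per-origin
detection failures, and fusion of spots closer than a merge radius
(mimicking the delayed apparent splitting caused by origin cohesion).
Pixel-level image synthesis is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import LineageEventLog

__all__ = [
    "ObsConfig",
    "FRAME_COLUMNS",
    "SchemaError",
    "ValidationError",
    "render_frames",
    "write_frame_table",
    "read_frame_table",
]

#: Fixed column order of the frame table (the MoMA-style export surrogate).
FRAME_COLUMNS = [
    "lane_id",
    "cell_id",
    "parent_id",
    "frame_index",
    "time",
    "length",
    "n_spots",
    "spot_positions",
]


class SchemaError(ValueError):
    """A required frame-table column is missing."""


class ValidationError(ValueError):
    """Frame-table contents violate an invariant."""


@dataclass
class ObsConfig:
    """Observation model for rendering.

    ``frame_interval`` must be an integer multiple of the simulator
    sampling step.  ``length_noise_cv`` is the SD of the log-normal
    multiplicative length noise.  Each origin is detected independently
    with ``spot_detect_prob`` per frame (at least one spot is always
    reported for a live cell); detected spots closer than
    ``merge_radius`` along the cell axis read as a single spot.
    """

    frame_interval: float = 3.0  # minutes
    length_noise_cv: float = 0.015
    spot_detect_prob: float = 0.98
    merge_radius: float = 0.25  # micrometres
    position_jitter_sd: float = 0.05  # micrometres
    seed: int = 0

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not (0.0 < self.spot_detect_prob <= 1.0):
            raise ValueError("spot_detect_prob must be in (0, 1]")
        if min(
            self.length_noise_cv, self.merge_radius, self.position_jitter_sd
        ) < 0:
            raise ValueError("noise parameters must be >= 0")


def _merge_positions(positions: np.ndarray, radius: float) -> list[float]:
    """Fuse sorted positions closer than ``radius`` into cluster means."""
    merged: list[float] = []
    cluster: list[float] = [positions[0]]
    for p in positions[1:]:
        if p - cluster[-1] < radius:
            cluster.append(p)
        else:
            merged.append(float(np.mean(cluster)))
            cluster = [p]
    merged.append(float(np.mean(cluster)))
    return merged


def render_frames(
    logs: list[LineageEventLog], obs: ObsConfig, drop_burn_in: bool = True
) -> pd.DataFrame:
    """Render event logs into a frame table.

    Each lineage becomes one lane; each generation one cell, chained by
    ``parent_id``.  True origins are placed at the ``(2i+1)/(2n)``
    fractional positions along the cell axis (the observed localisation
    of origins at future division sites) with Gaussian jitter.  With
    ``drop_burn_in`` the pre-equilibration generations of each lineage
    are omitted.
    """
    obs.validate()
    if not logs:
        raise ValueError("no event logs to render")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=obs.seed, spawn_key=(1,))
    )

    out: dict[str, list] = {c: [] for c in FRAME_COLUMNS}
    for log in logs:
        times = np.asarray(log.times)
        if len(times) < 2:
            continue
        dt = times[1] - times[0]
        step_f = obs.frame_interval / dt
        step = int(round(step_f))
        if abs(step_f - step) > 1e-9 or step < 1:
            raise ValueError(
                "frame_interval must be an integer multiple of the "
                f"simulator dt (got {obs.frame_interval} vs dt={dt})"
            )
        idx = np.arange(0, len(times), step)
        if drop_burn_in:
            gens_all = np.asarray(log.generations)
            idx = idx[gens_all[idx] >= log.burn_in_generations]
        if len(idx) < 2:
            raise ValueError("logs must cover at least one frame interval")
        t = times[idx]
        true_len = np.asarray(log.lengths)[idx]
        n_ori = np.asarray(log.n_oris)[idx]
        gen = np.asarray(log.generations)[idx]

        if obs.length_noise_cv > 0:
            obs_len = true_len * np.exp(
                obs.length_noise_cv * rng.standard_normal(len(idx))
            )
        else:
            obs_len = true_len.copy()

        lane = log.lineage_id
        for j in range(len(idx)):
            n = int(n_ori[j])
            positions = (2 * np.arange(n) + 1) / (2 * n) * true_len[j]
            if obs.position_jitter_sd > 0:
                positions = positions + obs.position_jitter_sd * (
                    rng.standard_normal(n)
                )
            if obs.spot_detect_prob < 1.0:
                keep = rng.random(n) < obs.spot_detect_prob
                if not keep.any():
                    keep[rng.integers(n)] = True  # a live cell shows a spot
                positions = positions[keep]
            positions = np.sort(positions)
            if obs.merge_radius > 0 and len(positions) > 1:
                merged = _merge_positions(positions, obs.merge_radius)
            else:
                merged = [float(p) for p in positions]

            g = int(gen[j])
            out["lane_id"].append(lane)
            out["cell_id"].append(f"l{lane}c{g}")
            out["parent_id"].append(f"l{lane}c{g - 1}" if g > 0 else "")
            out["frame_index"].append(int(round(t[j] / obs.frame_interval)))
            out["time"].append(float(t[j]))
            out["length"].append(float(obs_len[j]))
            out["n_spots"].append(len(merged))
            out["spot_positions"].append(
                ";".join(f"{p:.4f}" for p in merged)
            )

    return pd.DataFrame(out, columns=FRAME_COLUMNS)


def write_frame_table(frames: pd.DataFrame, path) -> None:
    """Write a frame table as CSV with the documented column order."""
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise SchemaError(f"missing frame-table column(s): {missing}")
    frames.loc[:, FRAME_COLUMNS].to_csv(path, index=False)


def read_frame_table(path) -> pd.DataFrame:
    """Read and validate a frame-table CSV."""
    frames = pd.read_csv(path, comment="#")
    for col in FRAME_COLUMNS:
        if col not in frames.columns:
            raise SchemaError(f"missing frame-table column: {col!r}")
    frames = frames[FRAME_COLUMNS].copy()
    frames["parent_id"] = frames["parent_id"].fillna("").astype(str)
    frames["spot_positions"] = frames["spot_positions"].fillna("").astype(str)
    if (frames["length"] <= 0).any():
        raise ValidationError("length must be > 0 for every frame")
    for cell, grp in frames.groupby("cell_id", sort=False):
        fi = grp["frame_index"].to_numpy()
        if not (np.diff(fi) > 0).all():
            raise ValidationError(
                f"non-monotone frame_index within cell {cell!r}"
            )
    return frames
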