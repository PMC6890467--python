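"""From frame-level tracks to division- and replication-centric cycle tables.

Two views of the cell cycle are extracted:

* **Division-centric**: one record per birth-to-division span, with sizes
  at birth (``Lb``), division (``Ld``) and replication initiation
  (``Li``) read off an exponential elongation fit of the cell's frames
  (ordinary least squares of log-length on time).  Because all sizes come
  from the same log-linear fit, the textbook identities
  ``dL = Ld - Lb``, ``Rbd = Ld/Lb`` and ``lambda = log(Rbd)/Tbd`` hold
  exactly on every record.

* **Replication-centric**: one pseudo-cycle per pair of consecutive
  initiation events along the lineage, concatenating the mother segment
  (initiation to division) with the daughter segment (birth to next
  initiation).  The fit is performed on the log *per-origin* size
  ``Lambda = L / n_ori``, which is continuous across division, and the
  per-origin sizes ``Lambda_i`` (post-duplication count), ``Lambda_f``
  (pre-duplication count) and ``Lambda_b`` are evaluated from that fit.

Initiation events are assigned from the spot-count track: the event is
the first frame where the *persistent* spot count increases, single-frame
blips being ignored.  Cycles with incoherent origin tracks (persistent
decreases, non-doubling jumps, parent/daughter count mismatches) are
flagged and removed by :func:`qc_filter`, together with cycles whose
elongation fit deviates strongly from a single exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import LineageEventLog

__all__ = [
    "ExpFit",
    "QCThresholds",
    "QCReport",
    "DIVISION_COLUMNS",
    "REPLICATION_COLUMNS",
    "INCOHERENT_FLAGS",
    "fit_exponential",
    "persistent_spot_counts",
    "assign_initiation_events",
    "build_division_cycles",
    "build_replication_cycles",
    "qc_filter",
    "true_division_cycles",
    "true_replication_cycles",
]

DIVISION_COLUMNS = [
    "lane_id",
    "cell_id",
    "generation",
    "Lb",
    "Ld",
    "Tbd",
    "Li",
    "Tbi",
    "lambda",
    "dL",
    "dLbi",
    "Rbd",
    "Rbi",
    "n_ori_birth",
    "fit_residual_sd",
    "qc_flags",
]

REPLICATION_COLUMNS = [
    "lane_id",
    "cell_id",
    "generation",
    "Lambda_i",
    "Lambda_f",
    "Lambda_b",
    "Tif",
    "Tib",
    "alpha",
    "dLif",
    "dLib",
    "Rif",
    "Rib",
    "Tid",
    "dLid",
    "n_ori_init",
    "fit_residual_sd",
    "qc_flags",
]

#: Flags that mark a cycle as incoherent (discarded by the QC filter).
INCOHERENT_FLAGS = frozenset(
    {
        "count_decrease",
        "non_doubling_jump",
        "parent_count_mismatch",
        "multi_initiation",
        "division_count",
        "short_track",
    }
)


# ---------------------------------------------------------------------------
# Exponential elongation fit
# ---------------------------------------------------------------------------


@dataclass
class ExpFit:
    """OLS fit of log(length) on time: ``length(t) = L0 * exp(rate*(t-t0))``."""

    rate: float
    length_at_start: float
    t0: float
    residual_sd: float

    def predict(self, t: float) -> float:
        return self.length_at_start * math.exp(self.rate * (t - self.t0))


def fit_exponential(times, lengths) -> ExpFit:
    """Fit exponential elongation by least squares on log-length.

    ``residual_sd`` is the standard deviation of the log residuals
    (two fitted parameters removed from the degrees of freedom).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and lengths must be 1-D of equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 points for an exponential fit")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input to fit_exponential")
    if (y <= 0).any():
        raise ValueError("lengths must be > 0")
    t0 = t[0]
    x = t - t0
    ly = np.log(y)
    slope, intercept = np.polyfit(x, ly, 1)
    resid = ly - (intercept + slope * x)
    dof = max(len(t) - 2, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    return ExpFit(
        rate=float(slope),
        length_at_start=float(np.exp(intercept)),
        t0=float(t0),
        residual_sd=residual_sd,
    )


# ---------------------------------------------------------------------------
# Initiation assignment from spot tracks
# ---------------------------------------------------------------------------


def persistent_spot_counts(counts) -> np.ndarray:
    """Persistent spot count per frame.

    A raw count becomes the persistent value only once it is confirmed by
    the following frame; single-frame blips are carried over from the
    previous persistent value.
    """
    c = np.asarray(counts, dtype=int)
    p = np.empty_like(c)
    current = c[0]
    n = len(c)
    for i in range(n):
        if i + 1 < n and c[i] == c[i + 1]:
            current = c[i]
        p[i] = current
    return p


def assign_initiation_events(counts) -> tuple[list[tuple[int, int, int]], set]:
    """Initiation events from a per-frame spot-count series.

    Returns ``(events, flags)`` where each event is
    ``(frame_offset, n_pre, n_post)`` — the first frame where the
    persistent spot count increases — and ``flags`` collects track
    incoherences (persistent decreases, non-doubling jumps).
    """
    p = persistent_spot_counts(counts)
    events: list[tuple[int, int, int]] = []
    flags: set[str] = set()
    for i in range(1, len(p)):
        if p[i] > p[i - 1]:
            events.append((i, int(p[i - 1]), int(p[i])))
            if p[i] != 2 * p[i - 1]:
                flags.add("non_doubling_jump")
        elif p[i] < p[i - 1]:
            flags.add("count_decrease")
    return events, flags


# ---------------------------------------------------------------------------
# Per-cell bookkeeping shared by both cycle builders
# ---------------------------------------------------------------------------


@dataclass
class _Cell:
    cell_id: str
    parent_id: str
    times: np.ndarray
    lengths: np.ndarray
    counts: np.ndarray
    persistent: np.ndarray = field(default=None)
    events: list = field(default_factory=list)
    flags: set = field(default_factory=set)
    fit: ExpFit | None = None

    @property
    def t_birth(self) -> float:
        return float(self.times[0])


def _lane_cells(lane_frames: pd.DataFrame) -> list[_Cell]:
    """Cells of one lane in lineage order, with counts, events and fits."""
    cells: list[_Cell] = []
    for cell_id, grp in lane_frames.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame_index")
        cells.append(
            _Cell(
                cell_id=str(cell_id),
                parent_id=str(grp["parent_id"].iloc[0]),
                times=grp["time"].to_numpy(dtype=float),
                lengths=grp["length"].to_numpy(dtype=float),
                counts=grp["n_spots"].to_numpy(dtype=int),
            )
        )
    cells.sort(key=lambda c: c.times[0])
    # verify the parent chain
    for prev, cur in zip(cells, cells[1:]):
        if cur.parent_id and cur.parent_id != prev.cell_id:
            raise ValueError(
                f"broken parent chain in lane: {cur.cell_id!r} expects "
                f"parent {cur.parent_id!r}, found {prev.cell_id!r}"
            )
    for c in cells:
        c.persistent = persistent_spot_counts(c.counts)
        c.events, c.flags = assign_initiation_events(c.counts)
        if len(c.times) >= 3:
            c.fit = fit_exponential(c.times, c.lengths)
        else:
            c.flags.add("short_track")
    # parent/daughter origin-count coherence across divisions
    for prev, cur in zip(cells, cells[1:]):
        if 2 * cur.persistent[0] != prev.persistent[-1]:
            cur.flags.add("parent_count_mismatch")
    return cells


# ---------------------------------------------------------------------------
# Division-centric cycles
# ---------------------------------------------------------------------------


def build_division_cycles(frames: pd.DataFrame) -> pd.DataFrame:
    """One record per complete birth-to-division span.

    ``Lb`` and ``Ld`` are the fitted exponential evaluated at the birth
    and division times (division time = first frame of the daughter);
    ``Li`` is the fit at the assigned initiation time.  Cells whose
    replication round started in the mother carry the
    ``inherited_initiation`` flag with empty ``Li`` fields.  First and
    last (incomplete) cells of each lane are dropped.
    """
    rows: list[dict] = []
    for lane_id, lane_frames in frames.groupby("lane_id", sort=False):
        cells = _lane_cells(lane_frames)
        for g in range(1, len(cells) - 1):
            cell, child = cells[g], cells[g + 1]
            flags = set(cell.flags)
            row = {
                "lane_id": lane_id,
                "cell_id": cell.cell_id,
                "generation": g,
                "n_ori_birth": int(cell.persistent[0]),
            }
            if cell.fit is None:
                rows.append(_finish_row(row, flags, np.nan, DIVISION_COLUMNS))
                continue
            t_b = cell.t_birth
            t_d = child.t_birth
            lb = cell.fit.predict(t_b)
            ld = cell.fit.predict(t_d)
            tbd = t_d - t_b
            lam = math.log(ld / lb) / tbd
            row.update(
                Lb=lb,
                Ld=ld,
                Tbd=tbd,
                dL=ld - lb,
                Rbd=ld / lb,
                **{"lambda": lam},
            )
            if len(cell.events) >= 1:
                if len(cell.events) > 1:
                    flags.add("multi_initiation")
                i_frame, _, _ = cell.events[0]
                t_i = float(cell.times[i_frame])
                li = cell.fit.predict(t_i)
                row.update(
                    Li=li,
                    Tbi=t_i - t_b,
                    dLbi=li - lb,
                    Rbi=li / lb,
                )
            else:
                flags.add("inherited_initiation")
            rows.append(
                _finish_row(row, flags, cell.fit.residual_sd, DIVISION_COLUMNS)
            )
    return pd.DataFrame(rows, columns=DIVISION_COLUMNS)


def _finish_row(row: dict, flags: set, residual_sd: float, columns) -> dict:
    row["fit_residual_sd"] = residual_sd
    row["qc_flags"] = ",".join(sorted(flags))
    for col in columns:
        row.setdefault(col, np.nan)
    return row


# ---------------------------------------------------------------------------
# Replication-centric pseudo-cycles
# ---------------------------------------------------------------------------


def build_replication_cycles(frames: pd.DataFrame) -> pd.DataFrame:
    """One pseudo-cycle per pair of consecutive initiation events.

    The pseudo-cycle concatenates the mother segment (initiation to
    division) with the daughter segment (birth to next initiation).  Each
    segment's log per-origin size is fit separately; the pseudo-cycle
    growth rate ``alpha`` is the time-weighted mean of the two slopes,
    i.e. the continuous log-growth of the per-origin size *excluding* the
    division jump caused by imprecise division placement (a single fit
    across the jump would leak division noise into the growth rate).
    Anchor sizes are evaluated from their own segment's fit:
    ``Lambda_i`` (post-duplication origin count) and ``Lambda_f``
    (pre-duplication count) at the two initiation times, ``Lambda_b`` at
    the daughter's birth.
    """
    rows: list[dict] = []
    for lane_id, lane_frames in frames.groupby("lane_id", sort=False):
        cells = _lane_cells(lane_frames)
        # lane-wide chronological list of initiation events
        events: list[tuple[int, int, float, int, int]] = []
        for g, cell in enumerate(cells):
            for i_frame, n_pre, n_post in cell.events:
                events.append(
                    (g, i_frame, float(cell.times[i_frame]), n_pre, n_post)
                )
        for k in range(len(events) - 1):
            g0, f0, t0, _, n_post0 = events[k]
            g1, f1, t1, n_pre1, _ = events[k + 1]
            mother, child = cells[g0], cells[g1]
            flags = set(mother.flags) | set(cells[g1].flags)
            row = {
                "lane_id": lane_id,
                "cell_id": child.cell_id,
                "generation": g1,
                "n_ori_init": n_post0,
            }
            if g1 - g0 != 1:
                flags.add("division_count")
                rows.append(
                    _finish_row(row, flags, np.nan, REPLICATION_COLUMNS)
                )
                continue
            if 2 * n_pre1 != n_post0:
                flags.add("parent_count_mismatch")
            # per-origin size, one fit per segment
            tm = mother.times[f0:]
            ym = mother.lengths[f0:] / n_post0
            tc = child.times[:f1]
            yc = child.lengths[:f1] / n_pre1
            if len(tm) < 3 or len(tc) < 3:
                flags.add("short_track")
                rows.append(
                    _finish_row(row, flags, np.nan, REPLICATION_COLUMNS)
                )
                continue
            fit_m = fit_exponential(tm, ym)
            fit_c = fit_exponential(tc, yc)
            tif = t1 - t0
            tib = child.t_birth - t0
            lam_i = fit_m.predict(t0)
            lam_f = fit_c.predict(t1)
            lam_b = fit_c.predict(child.t_birth)
            alpha = (fit_m.rate * tib + fit_c.rate * (tif - tib)) / tif
            residual_sd = math.sqrt(
                (
                    fit_m.residual_sd**2 * len(tm)
                    + fit_c.residual_sd**2 * len(tc)
                )
                / (len(tm) + len(tc))
            )
            row.update(
                Lambda_i=lam_i,
                Lambda_f=lam_f,
                Lambda_b=lam_b,
                Tif=tif,
                Tib=tib,
                alpha=alpha,
                dLif=lam_f - lam_i,
                dLib=lam_b - lam_i,
                Rif=lam_f / lam_i,
                Rib=lam_b / lam_i,
                Tid=tib,
                dLid=lam_b - lam_i,
            )
            rows.append(
                _finish_row(row, flags, residual_sd, REPLICATION_COLUMNS)
            )
    return pd.DataFrame(rows, columns=REPLICATION_COLUMNS)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass
class QCThresholds:
    """Configurable discard rules.

    ``max_residual_sd`` (log-length units) bounds the deviation from a
    single-exponential elongation fit; cycles carrying any incoherence
    flag are always discarded.
    """

    max_residual_sd: float = 0.04


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    discarded: dict[str, int]

    @property
    def discard_fraction(self) -> float:
        return 0.0 if self.n_input == 0 else 1.0 - self.n_kept / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "discard_fraction": self.discard_fraction,
            "discarded_by_reason": dict(self.discarded),
        }


def qc_filter(
    table: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Discard incoherent and badly fitting cycles.

    A cycle is discarded if its elongation fit deviates from a single
    exponential (``residual_sd > max_residual_sd``) or if any incoherence
    flag is set (incoherent origin counts, broken parent chains, missing
    frames).  Returns the filtered table and a per-reason report.
    """
    thresholds = thresholds or QCThresholds()
    if table.empty:
        return table.copy(), QCReport(0, 0, {})
    flags = table["qc_flags"].fillna("").astype(str)
    incoherent = flags.map(
        lambda s: bool(set(s.split(",")) & INCOHERENT_FLAGS) if s else False
    )
    resid = pd.to_numeric(table["fit_residual_sd"], errors="coerce")
    deviating = (resid > thresholds.max_residual_sd) & ~incoherent
    keep = ~(incoherent | deviating.fillna(False))
    report = QCReport(
        n_input=len(table),
        n_kept=int(keep.sum()),
        discarded={
            "incoherent_origin_count": int(incoherent.sum()),
            "fit_deviation": int(deviating.fillna(False).sum()),
        },
    )
    return table.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Exact cycle tables straight from event logs (ground truth)
# ---------------------------------------------------------------------------


def true_division_cycles(
    logs: list[LineageEventLog], drop_burn_in: bool = True
) -> pd.DataFrame:
    """Division-centric table computed exactly from simulator events."""
    rows = []
    for log in logs:
        divs = log.divisions
        for j in range(len(divs) - 1):
            born, died = divs[j], divs[j + 1]
            g = born.generation + 1
            if drop_burn_in and g < log.burn_in_generations:
                continue
            lb = born.daughter_length
            ld = died.mother_length
            tbd = died.time - born.time
            lam = math.log(ld / lb) / tbd
            inits = [
                ev
                for ev in log.initiations
                if born.time < ev.time <= died.time and ev.generation == g
            ]
            row = {
                "lane_id": log.lineage_id,
                "cell_id": f"l{log.lineage_id}c{g}",
                "generation": g,
                "Lb": lb,
                "Ld": ld,
                "Tbd": tbd,
                "lambda": lam,
                "dL": ld - lb,
                "Rbd": ld / lb,
                "n_ori_birth": born.n_after,
                "fit_residual_sd": 0.0,
                "qc_flags": "",
            }
            if inits:
                ev = inits[0]
                row.update(
                    Li=ev.length,
                    Tbi=ev.time - born.time,
                    dLbi=ev.length - lb,
                    Rbi=ev.length / lb,
                )
            else:
                row["qc_flags"] = "inherited_initiation"
            for col in DIVISION_COLUMNS:
                row.setdefault(col, np.nan)
            rows.append(row)
    return pd.DataFrame(rows, columns=DIVISION_COLUMNS)


def true_replication_cycles(
    logs: list[LineageEventLog], drop_burn_in: bool = True
) -> pd.DataFrame:
    """Replication-centric table computed exactly from simulator events.

    ``alpha`` is the time-weighted mean growth rate over the two
    pseudo-cycle segments (the continuous per-origin log-growth excluding
    the division jump), matching the frame-based extractor.
    """
    rows = []
    for log in logs:
        inits = log.initiations
        for k in range(len(inits) - 1):
            ev0, ev1 = inits[k], inits[k + 1]
            if drop_burn_in and ev0.generation < log.burn_in_generations:
                continue
            between = [
                d for d in log.divisions if ev0.time < d.time <= ev1.time
            ]
            if len(between) != 1:
                continue  # clash or truncated lineage: no coherent cycle
            div = between[0]
            lam_i = ev0.length / ev0.n_post
            lam_f = ev1.length / ev1.n_pre
            lam_b = div.daughter_length / div.n_after
            lam_div = div.mother_length / div.n_before
            tif = ev1.time - ev0.time
            tib = div.time - ev0.time
            # continuous per-origin log-growth, division jump excluded
            alpha = (
                math.log(lam_div / lam_i) + math.log(lam_f / lam_b)
            ) / tif
            rows.append(
                {
                    "lane_id": log.lineage_id,
                    "cell_id": f"l{log.lineage_id}c{ev1.generation}",
                    "generation": ev1.generation,
                    "Lambda_i": lam_i,
                    "Lambda_f": lam_f,
                    "Lambda_b": lam_b,
                    "Tif": tif,
                    "Tib": tib,
                    "alpha": alpha,
                    "dLif": lam_f - lam_i,
                    "dLib": lam_b - lam_i,
                    "Rif": lam_f / lam_i,
                    "Rib": lam_b / lam_i,
                    "Tid": tib,
                    "dLid": lam_b - lam_i,
                    "n_ori_init": ev0.n_post,
                    "fit_residual_sd": 0.0,
                    "qc_flags": "",
                }
            )
    return pd.DataFrame(rows, columns=REPLICATION_COLUMNS)
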