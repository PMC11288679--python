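"""Detection records, capsule-overlap interaction inference and time budgets.

Detections are per-frame tag records (time, ant, position, orientation,
arena).  A pairwise interaction is inferred whenever the two ants' head
capsules — 2-D capsules (segments with a radius) placed along each body axis
— overlap; an interaction *event* is a maximal run of overlapping frames,
optionally bridging interruptions of at most ``max_gap_frames`` frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataFormatError

__all__ = [
    "DETECTION_COLUMNS",
    "CapsuleSpec",
    "InteractionEvent",
    "read_detections",
    "write_detections",
    "capsules_intersect",
    "detect_interactions",
    "foraging_proportion",
    "low_detection_filter",
]

DETECTION_COLUMNS = ["time_s", "ant_id", "x", "y", "angle_rad", "arena"]
ARENAS = ("nest", "forage")


@dataclass(frozen=True)
class CapsuleSpec:
    """Head capsule of one ant: a segment along the heading with a radius.

    Offsets are signed distances (body lengths) from the tag centre along
    the body axis; default head segment runs from 0.3 to 0.5 body lengths
    in front of the tag with radius 0.2.
    """

    ant_id: object
    head_offset_start: float = 0.3
    head_offset_end: float = 0.5
    radius: float = 0.2

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigError("capsule radius must be positive")
        if not self.head_offset_start < self.head_offset_end:
            raise ConfigError("head_offset_start must be < head_offset_end")


@dataclass(frozen=True)
class InteractionEvent:
    """One pairwise interaction: a maximal run of overlapping frames."""

    ant_i: object
    ant_j: object
    start_s: float
    end_s: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.start_s > self.end_s:
            raise DataFormatError("event start after end")
        if self.n_frames < 1:
            raise DataFormatError("event must span at least one frame")


# -- detection table IO ----------------------------------------------------


def _validate_detections(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"detection table missing columns {missing}")
    df = df[DETECTION_COLUMNS].copy()
    if len(df):
        if (df["time_s"] < 0).any():
            raise DataFormatError("negative time_s")
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise DataFormatError("non-finite positions")
        bad = set(df["arena"].unique()) - set(ARENAS)
        if bad:
            raise DataFormatError(f"unknown arena labels {sorted(bad)}")
        if df.duplicated(subset=["time_s", "ant_id"]).any():
            raise DataFormatError("duplicate (time_s, ant_id) rows")
    return df


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV, validating columns and basic invariants."""
    df = pd.read_csv(path)
    if df.empty and list(df.columns) == DETECTION_COLUMNS:
        return df
    return _validate_detections(df).sort_values(
        ["time_s", "ant_id"], kind="stable"
    ).reset_index(drop=True)


def write_detections(table: pd.DataFrame, path) -> None:
    _validate_detections(table).to_csv(path, index=False)


# -- capsule geometry ------------------------------------------------------


def _segment_endpoints(pose, capsule: CapsuleSpec) -> tuple[np.ndarray, np.ndarray]:
    x, y, theta = pose
    d = np.array([np.cos(theta), np.sin(theta)])
    p = np.array([x, y], dtype=float)
    return p + capsule.head_offset_start * d, p + capsule.head_offset_end * d


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2 (2-D)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-30 and e <= 1e-30:
        return float(np.hypot(*r))
    if a <= 1e-30:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= 1e-30:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-30 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.hypot(*(closest1 - closest2)))


def capsules_intersect(pose1, capsule1: CapsuleSpec, pose2, capsule2: CapsuleSpec) -> bool:
    """True iff the two placed head capsules overlap (boundary inclusive).

    ``pose`` is (x, y, angle_rad).
    """
    p1, q1 = _segment_endpoints(pose1, capsule1)
    p2, q2 = _segment_endpoints(pose2, capsule2)
    return _segment_distance(p1, q1, p2, q2) <= capsule1.radius + capsule2.radius


# -- interaction events ----------------------------------------------------


def _runs_with_gaps(true_frames: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Split sorted frame indices into runs bridging gaps <= max_gap."""
    if true_frames.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(true_frames) > max_gap + 1)
    return np.split(true_frames, breaks + 1)


def detect_interactions(
    detections: pd.DataFrame,
    capsules: Mapping[object, CapsuleSpec] | Iterable[CapsuleSpec] | pd.DataFrame,
    max_gap_frames: int = 0,
) -> tuple[list[InteractionEvent], pd.DataFrame]:
    """Infer pairwise interaction events from per-frame capsule overlap.

    Frames are the sorted distinct ``time_s`` values.  Ants must share an
    arena in a frame to interact; a missing detection counts as non-overlap.
    Returns the event list and a symmetric event-count matrix (DataFrame
    indexed by ant id).
    """
    detections = _validate_detections(detections)
    caps = _as_capsule_map(capsules)
    ants = sorted(detections["ant_id"].unique(), key=str)
    unknown = [a for a in ants if a not in caps]
    if unknown:
        raise ConfigError(f"no capsule spec for ants {unknown}")

    times = np.sort(detections["time_s"].unique())
    frame_of = {t: f for f, t in enumerate(times)}
    # pose lookup: (frame, ant) -> (x, y, angle, arena)
    pose: dict[tuple[int, object], tuple] = {}
    for row in detections.itertuples(index=False):
        pose[(frame_of[row.time_s], row.ant_id)] = (
            row.x, row.y, row.angle_rad, row.arena
        )

    events: list[InteractionEvent] = []
    counts = pd.DataFrame(0, index=ants, columns=ants, dtype=int)
    for ai in range(len(ants)):
        for aj in range(ai + 1, len(ants)):
            a, b = ants[ai], ants[aj]
            overlap_frames = []
            for f in range(len(times)):
                pa = pose.get((f, a))
                pb = pose.get((f, b))
                if pa is None or pb is None or pa[3] != pb[3]:
                    continue
                if capsules_intersect(pa[:3], caps[a], pb[:3], caps[b]):
                    overlap_frames.append(f)
            for run in _runs_with_gaps(np.array(overlap_frames, dtype=int),
                                       max_gap_frames):
                events.append(
                    InteractionEvent(
                        ant_i=a, ant_j=b,
                        start_s=float(times[run[0]]),
                        end_s=float(times[run[-1]]),
                        n_frames=int(run.size),
                    )
                )
                counts.loc[a, b] += 1
                counts.loc[b, a] += 1
    return events, counts


def _as_capsule_map(capsules) -> dict:
    if isinstance(capsules, Mapping):
        return dict(capsules)
    if isinstance(capsules, pd.DataFrame):
        return {
            row.ant_id: CapsuleSpec(
                ant_id=row.ant_id,
                head_offset_start=row.start,
                head_offset_end=row.end,
                radius=row.radius,
            )
            for row in capsules.itertuples(index=False)
        }
    return {c.ant_id: c for c in capsules}


def read_capsules(path) -> dict:
    """Capsule spec CSV: columns ant_id, start, end, radius."""
    df = pd.read_csv(path)
    missing = [c for c in ("ant_id", "start", "end", "radius") if c not in df.columns]
    if missing:
        raise DataFormatError(f"capsule table missing columns {missing}")
    return _as_capsule_map(df)


def write_events(events: list[InteractionEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "ant_i": e.ant_i, "ant_j": e.ant_j,
                "start_s": e.start_s, "end_s": e.end_s, "n_frames": e.n_frames,
            }
            for e in events
        ],
        columns=["ant_i", "ant_j", "start_s", "end_s", "n_frames"],
    ).to_csv(path, index=False)


def read_events(path) -> list[InteractionEvent]:
    df = pd.read_csv(path)
    return [
        InteractionEvent(
            ant_i=r.ant_i, ant_j=r.ant_j, start_s=float(r.start_s),
            end_s=float(r.end_s), n_frames=int(r.n_frames),
        )
        for r in df.itertuples(index=False)
    ]


# -- time budgets and exclusion -------------------------------------------


def foraging_proportion(
    detections: pd.DataFrame, roster: Iterable | None = None
) -> pd.Series:
    """Per-ant fraction of detections in the foraging arena.

    Roster ants with zero detections are excluded with a warning.
    """
    detections = _validate_detections(detections)
    frac = (
        detections.assign(forage=detections["arena"].eq("forage"))
        .groupby("ant_id")["forage"]
        .mean()
    )
    if roster is not None:
        missing = [a for a in roster if a not in frac.index]
        if missing:
            warnings.warn(
                f"ants with zero detections excluded from foraging proportion: {missing}"
            )
        frac = frac.reindex([a for a in roster if a in frac.index])
    frac.name = "foraging_proportion"
    frac.index.name = "ant_id"
    return frac


def low_detection_filter(detection_counts: pd.Series | Mapping) -> set:
    """Ids detected less than 2 sample standard deviations below the mean.

    Uses the sample (n-1) standard deviation.  The queen is subject to the
    same rule as workers.
    """
    counts = pd.Series(detection_counts, dtype=float)
    if len(counts) < 2:
        raise DataFormatError("low-detection filter needs at least 2 ants")
    threshold = counts.mean() - 2.0 * counts.std(ddof=1)
    return set(counts.index[counts < threshold])
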