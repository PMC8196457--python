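"""Male-female interaction events (MFIEs): detection, dynamic interaction, filtering.

The liberal rule flags dyad fix pairs within 100 m and builds events from runs of
at least two consecutive close fixes; separate close runs are merged into one
event unless the pair spent more than two hours apart (> 100 m) between them.
A merged candidate is accepted only if the mean distance over all its fixes is
still within the threshold. The conservative rule then keeps events whose mean
dynamic-interaction statistic (DI) exceeds 0.5 — cohesive co-movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import DyadSeries

__all__ = [
    "InteractionEvent",
    "detect_events",
    "dynamic_interaction",
    "conservative_filter",
    "events_to_frame",
]


@dataclass
class InteractionEvent:
    male_id: str
    female_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    fixes: pd.DataFrame  # paired-fix rows from the DyadSeries, time-ordered
    mean_distance: float
    duration_h: float
    mean_DI: float = np.nan
    classification: str = "liberal"

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def _close_runs(close: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [start, end] index pairs (inclusive)."""
    runs = []
    i = 0
    n = len(close)
    while i < n:
        if close[i]:
            j = i
            while j + 1 < n and close[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _make_event(dyad: DyadSeries, lo: int, hi: int) -> InteractionEvent:
    fixes = dyad.pairs.iloc[lo : hi + 1].reset_index(drop=True)
    start = fixes["timestamp"].iloc[0]
    end = fixes["timestamp"].iloc[-1]
    return InteractionEvent(
        male_id=dyad.id_a,
        female_id=dyad.id_b,
        start=start,
        end=end,
        fixes=fixes,
        mean_distance=float(fixes["distance"].mean()),
        duration_h=float((end - start).total_seconds() / 3600.0),
    )


def detect_events(
    dyad: DyadSeries,
    dist_threshold: float = 100.0,
    min_run: int = 2,
    gap_hours: float = 2.0,
) -> list[InteractionEvent]:
    """Liberal MFIE detection on a time-ordered dyad series.

    1. Fix pairs with distance <= ``dist_threshold`` are "close".
    2. Consecutive close runs whose separating far interval lasts at most
       ``gap_hours`` (close-fix to close-fix) are merged into one candidate;
       the far fixes inside the merged span stay part of the event.
    3. A candidate is kept if it contains a run of >= ``min_run`` consecutive
       close fixes and its mean distance over all event fixes is
       <= ``dist_threshold``. A merged candidate failing the mean test is
       split back into its constituent close runs, each re-checked alone.

    Events are disjoint in time per dyad. Empty input yields an empty list.
    """
    if dist_threshold <= 0 or min_run <= 0 or gap_hours < 0:
        raise ValueError("thresholds must be positive")
    if len(dyad) == 0:
        return []
    dist = dyad.pairs["distance"].to_numpy(dtype=float)
    times = dyad.pairs["timestamp"].astype("int64").to_numpy() / 1e9 / 3600.0  # hours
    close = dist <= dist_threshold
    runs = _close_runs(close)
    if not runs:
        return []

    # Merge runs across short far-gaps into candidate groups of runs.
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        prev_end = groups[-1][-1][1]
        gap = times[run[0]] - times[prev_end]
        if gap <= gap_hours:
            groups[-1].append(run)
        else:
            groups.append([run])

    events = []
    for group in groups:
        lo, hi = group[0][0], group[-1][1]
        has_min_run = any(b - a + 1 >= min_run for a, b in group)
        if not has_min_run:
            continue
        if dist[lo : hi + 1].mean() <= dist_threshold:
            events.append(_make_event(dyad, lo, hi))
        else:
            # A far excursion inside the merged span pushed the mean over the
            # threshold: fall back to the individual close runs.
            for a, b in group:
                if b - a + 1 >= min_run and dist[a : b + 1].mean() <= dist_threshold:
                    events.append(_make_event(dyad, a, b))
    return events


def dynamic_interaction(event_fixes: pd.DataFrame, alpha: float = 1.0) -> float:
    """Mean dynamic-interaction statistic over an event's simultaneous steps.

    For each consecutive pair of paired fixes, with step lengths d_a, d_b and
    azimuths theta_a, theta_b::

        f_t = cos(theta_a - theta_b)                    # direction agreement
        g_t = 1 - (|d_a - d_b| / (d_a + d_b)) ** alpha  # displacement similarity
        DI_t = f_t * g_t

    Conventions at degenerate steps: both animals stationary -> DI_t = 1
    (perfect cohesion); exactly one stationary -> DI_t = 0. Each DI_t lies in
    [-1, 1], as does the returned mean. Returns NaN when the event has no
    simultaneous step (fewer than two paired fixes): the event cannot be
    conservatively classified.
    """
    if len(event_fixes) < 2:
        return float("nan")
    xa = event_fixes["xa"].to_numpy(dtype=float)
    ya = event_fixes["ya"].to_numpy(dtype=float)
    xb = event_fixes["xb"].to_numpy(dtype=float)
    yb = event_fixes["yb"].to_numpy(dtype=float)
    dxa, dya = np.diff(xa), np.diff(ya)
    dxb, dyb = np.diff(xb), np.diff(yb)
    da = np.hypot(dxa, dya)
    db = np.hypot(dxb, dyb)
    di = np.empty(len(da))
    both_zero = (da == 0) & (db == 0)
    one_zero = ((da == 0) | (db == 0)) & ~both_zero
    ok = ~both_zero & ~one_zero
    di[both_zero] = 1.0
    di[one_zero] = 0.0
    if ok.any():
        f = np.cos(np.arctan2(dya[ok], dxa[ok]) - np.arctan2(dyb[ok], dxb[ok]))
        g = 1.0 - (np.abs(da[ok] - db[ok]) / (da[ok] + db[ok])) ** alpha
        di[ok] = f * g
    return float(di.mean())


def attach_di(events: list[InteractionEvent], alpha: float = 1.0) -> list[InteractionEvent]:
    """Compute and store mean_DI on each event (in place; returns the list)."""
    for ev in events:
        ev.mean_DI = dynamic_interaction(ev.fixes, alpha=alpha)
    return events


def conservative_filter(
    events: list[InteractionEvent], di_threshold: float = 0.5
) -> list[InteractionEvent]:
    """Events with mean_DI strictly greater than ``di_threshold``.

    Output is a subset of the input (the conservative set nests inside the
    liberal set); retained events are relabeled ``classification='conservative'``.
    Events with undefined DI (NaN) are never retained.
    """
    kept = []
    for ev in events:
        if np.isfinite(ev.mean_DI) and ev.mean_DI > di_threshold:
            kept.append(
                InteractionEvent(
                    male_id=ev.male_id,
                    female_id=ev.female_id,
                    start=ev.start,
                    end=ev.end,
                    fixes=ev.fixes,
                    mean_distance=ev.mean_distance,
                    duration_h=ev.duration_h,
                    mean_DI=ev.mean_DI,
                    classification="conservative",
                )
            )
    return kept


def events_to_frame(events: list[InteractionEvent]) -> pd.DataFrame:
    """Tabular event summary (one row per event) for CSV export."""
    return pd.DataFrame(
        {
            "male_id": [e.male_id for e in events],
            "female_id": [e.female_id for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "n_fixes": [e.n_fixes for e in events],
            "duration_h": [e.duration_h for e in events],
            "mean_distance_m": [e.mean_distance for e in events],
            "mean_DI": [e.mean_DI for e in events],
            "classification": [e.classification for e in events],
        }
    )
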