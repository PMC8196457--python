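"""Assessment layer: do single-sex space use or movement states flag MFIEs?

Two diagnostics mirror the two single-sex methods under evaluation. The UD
side asks whether the percent-volume values of locations inside interaction
events concentrate below (male convention: core-area use) or above (female
convention: excursions) some contour threshold — a sweep over candidate
thresholds reports the fraction of event locations captured by each. The HMM
side asks whether decoded behavioral states are consistent across events: the
modal-state agreement index is the largest fraction of events sharing one
modal state, and a permutation baseline (event spans re-placed uniformly at
random in time) gives the agreement expected when states carry no event
signal at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bbmm import VolumeGrid, volume_at
from .hmm import StateSequence
from .interaction import InteractionEvent
from .regularize import RegularTrack

__all__ = [
    "EventUDSummary",
    "EventStateSummary",
    "label_event_hours",
    "event_ud_summary",
    "event_state_summary",
    "consistency_report",
    "permutation_baseline",
]


@dataclass
class EventUDSummary:
    event_id: int
    animal_id: str
    sex: str
    scope: str  # "season" or a phase name
    volumes: np.ndarray  # percent, one per event location (NaN = outside grid)
    mean_volume: float
    mean_distance: float
    duration_h: float


@dataclass
class EventStateSummary:
    event_id: int
    animal_id: str
    n_states: int
    proportions: np.ndarray  # fraction of event hours per state, sums to 1
    modal_state: int  # 1-based; ties -> lower index


def label_event_hours(event: InteractionEvent, reg: RegularTrack) -> np.ndarray:
    """Boolean flag per hourly location: inside [event.start, event.end].

    Endpoints inclusive (every hourly location between the start and end time
    of an event counts as an event location). Raises if the event lies outside
    the regular track's span.
    """
    ts = reg.timestamps
    if event.start < ts.iloc[0] or event.end > ts.iloc[-1]:
        raise ValueError(
            f"event {event.start}..{event.end} outside regular track span "
            f"{ts.iloc[0]}..{ts.iloc[-1]}"
        )
    return ((ts >= event.start) & (ts <= event.end)).to_numpy()


def _event_coords(event: InteractionEvent, sex: str) -> np.ndarray:
    cols = ("xa", "ya") if sex == "male" else ("xb", "yb")
    return event.fixes[list(cols)].to_numpy(dtype=float)


def event_ud_summary(
    events: list[InteractionEvent],
    volume_grids: dict[str, VolumeGrid],
    sex: str = "male",
    scope: str = "season",
) -> list[EventUDSummary]:
    """UD-volume values at each event's fixes for one sex.

    ``volume_grids`` maps animal id to the VolumeGrid of the requested scope
    (the full season or one breeding phase). Fixes falling outside a grid are
    recorded as NaN with a warning and excluded from the event mean.
    """
    out = []
    for i, ev in enumerate(events):
        animal = ev.male_id if sex == "male" else ev.female_id
        grid = volume_grids[animal]
        coords = _event_coords(ev, sex)
        vols = np.array([volume_at(grid, (x, y)) for x, y in coords])
        n_out = int(np.isnan(vols).sum())
        if n_out:
            warnings.warn(f"event {i}: {n_out} fix(es) outside {animal}'s {scope} grid")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_vol = float(np.nanmean(vols))
        out.append(
            EventUDSummary(
                event_id=i,
                animal_id=animal,
                sex=sex,
                scope=scope,
                volumes=vols,
                mean_volume=mean_vol,
                mean_distance=ev.mean_distance,
                duration_h=ev.duration_h,
            )
        )
    return out


def _proportions_and_mode(states: np.ndarray, n_states: int) -> tuple[np.ndarray, int]:
    counts = np.bincount(states, minlength=n_states + 1)[1:]
    props = counts / counts.sum()
    return props, int(np.argmax(counts)) + 1  # argmax takes first max: lower index


def event_state_summary(
    events: list[InteractionEvent],
    state_sequences: dict[str, StateSequence],
    n_states: int,
    sex: str = "male",
) -> list[EventStateSummary]:
    """Per event: fraction of event hours decoded into each state, and the
    modal state (ties broken toward the lower state index)."""
    out = []
    for i, ev in enumerate(events):
        animal = ev.male_id if sex == "male" else ev.female_id
        seq = state_sequences[animal]
        ts = seq.timestamps
        mask = ((ts >= ev.start) & (ts <= ev.end)).to_numpy()
        if not mask.any():
            raise ValueError(f"event {i}: no decoded hours inside its span")
        props, modal = _proportions_and_mode(seq.states[mask], n_states)
        out.append(EventStateSummary(i, animal, n_states, props, modal))
    return out


def modal_state_agreement(summaries: list[EventStateSummary]) -> float:
    """Largest fraction of events sharing one modal state."""
    modes = np.array([s.modal_state for s in summaries])
    n_states = summaries[0].n_states
    return float(max((modes == s).mean() for s in range(1, n_states + 1)))


def permutation_baseline(
    events: list[InteractionEvent],
    state_sequences: dict[str, StateSequence],
    n_states: int,
    sex: str = "male",
    n_permutations: int = 999,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of modal-state agreement.

    Each permutation re-places every event as a contiguous block of the same
    hour count at a uniformly random position in its animal's decoded
    sequence, then recomputes the agreement index. Returns the
    ``n_permutations`` null agreement values.
    """
    rng = np.random.default_rng(seed)
    lengths = []
    for ev in events:
        animal = ev.male_id if sex == "male" else ev.female_id
        seq = state_sequences[animal]
        ts = seq.timestamps
        n_hours = int(((ts >= ev.start) & (ts <= ev.end)).sum())
        lengths.append((animal, max(n_hours, 1)))
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        modes = []
        for animal, L in lengths:
            states = state_sequences[animal].states
            start = rng.integers(0, max(len(states) - L, 0) + 1)
            _, modal = _proportions_and_mode(states[start : start + L], n_states)
            modes.append(modal)
        modes = np.array(modes)
        null[p] = max((modes == s).mean() for s in range(1, n_states + 1))
    return null


def consistency_report(
    ud_summaries: list[EventUDSummary] | None = None,
    state_summaries: list[EventStateSummary] | None = None,
    thresholds: np.ndarray | None = None,
) -> dict:
    """Consistency summary across events.

    UD side: the span of per-location volumes and, for each candidate contour
    threshold v, the fraction of event locations with volume <= v (male
    convention, core-area use) and >= v (female convention, excursion use).
    HMM side: modal-state agreement and the mean within-event majority-state
    proportion. Covariates: per-event mean volume / modal state against mean
    dyad distance and event duration. The threshold sweep and agreement index
    are this package's operationalization of the visual expected-pattern
    check; they are labeled as such in the report.
    """
    report: dict = {"note": "threshold sweep, agreement index and permutation "
                            "baseline are artifact extensions beyond the "
                            "original graphical assessment"}
    if ud_summaries:
        vols = np.concatenate([s.volumes for s in ud_summaries])
        vols = vols[np.isfinite(vols)]
        if thresholds is None:
            thresholds = np.arange(5, 100, 5)
        report["ud"] = {
            "n_events": len(ud_summaries),
            "n_locations": int(len(vols)),
            "volume_min": float(vols.min()),
            "volume_max": float(vols.max()),
            "event_mean_min": float(min(s.mean_volume for s in ud_summaries)),
            "event_mean_max": float(max(s.mean_volume for s in ud_summaries)),
            "threshold_sweep": [
                {
                    "v": int(v),
                    "frac_le": float((vols <= v).mean()),
                    "frac_ge": float((vols >= v).mean()),
                }
                for v in thresholds
            ],
            "covariates": [
                {
                    "event_id": s.event_id,
                    "mean_volume": s.mean_volume,
                    "mean_distance_m": s.mean_distance,
                    "duration_h": s.duration_h,
                }
                for s in ud_summaries
            ],
        }
    if state_summaries:
        agreement = modal_state_agreement(state_summaries)
        majority = float(np.mean([s.proportions.max() for s in state_summaries]))
        report["hmm"] = {
            "n_events": len(state_summaries),
            "n_states": state_summaries[0].n_states,
            "modal_state_agreement": agreement,
            "mean_majority_proportion": majority,
            "modal_states": [int(s.modal_state) for s in state_summaries],
        }
    if not ud_summaries and not state_summaries:
        raise ValueError("nothing to report: both summary lists empty")
    return report
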