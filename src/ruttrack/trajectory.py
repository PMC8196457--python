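"""Relocation data model, CSV I/O, dyad time-alignment, and breeding calendars.

Coordinates must arrive projected in meters (easting/northing); no geographic
reprojection is performed because every distance threshold downstream is metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "DyadSeries",
    "BreedingCalendar",
    "DEFAULT_CALENDAR",
    "read_tracks",
    "write_tracks",
    "align_dyad",
    "assign_phase",
]

TRACK_COLUMNS = ["animal_id", "sex", "study_area", "timestamp", "x", "y"]

#: Study areas mapped to the calendar region they fall in.
AREA_REGION = {"SN": "north", "SS": "north", "RR": "south", "BE": "south"}


class TrackValidationError(ValueError):
    """A track violates an invariant (duplicate timestamps, non-finite coords...)."""


@dataclass
class Track:
    """One animal's time-ordered relocations.

    Parameters
    ----------
    animal_id : str
    sex : {"male", "female"}
    study_area : str
        Study-area label, e.g. "SN", "SS", "RR", "BE" or user-defined.
    fixes : pandas.DataFrame
        Columns ``timestamp`` (UTC datetime), ``x``, ``y`` (meters, projected).
        Sorted by timestamp, strictly increasing.
    """

    animal_id: str
    sex: str
    study_area: str
    fixes: pd.DataFrame
    region: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise TrackValidationError(
                f"track {self.animal_id}: sex must be 'male' or 'female', got {self.sex!r}"
            )
        f = self.fixes.reset_index(drop=True)
        f["timestamp"] = pd.to_datetime(f["timestamp"])
        f = f.sort_values("timestamp").reset_index(drop=True)
        ts = f["timestamp"].to_numpy()
        if len(ts) > 1 and (np.diff(ts.astype("datetime64[s]").astype(np.int64)) <= 0).any():
            raise TrackValidationError(
                f"track {self.animal_id}: duplicate or non-increasing timestamps"
            )
        if not np.isfinite(f[["x", "y"]].to_numpy(dtype=float)).all():
            raise TrackValidationError(f"track {self.animal_id}: non-finite coordinates")
        self.fixes = f
        if self.region is None:
            self.region = AREA_REGION.get(self.study_area)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> np.ndarray:
        """Timestamps as seconds since epoch (float64)."""
        return self.fixes["timestamp"].astype("int64").to_numpy() / 1e9

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in meters."""
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray, suffix: str = "") -> "Track":
        """Track restricted to rows where ``mask`` is True (e.g. one breeding phase)."""
        return Track(
            animal_id=self.animal_id + suffix,
            sex=self.sex,
            study_area=self.study_area,
            fixes=self.fixes.loc[mask].reset_index(drop=True),
            region=self.region,
        )


@dataclass
class DyadSeries:
    """Time-aligned simultaneous fixes for one male-female pair.

    ``pairs`` columns: ``timestamp`` (midpoint of the two matched fix times),
    ``t_a``, ``t_b``, ``xa``, ``ya``, ``xb``, ``yb``, ``distance``.
    """

    id_a: str
    id_b: str
    study_area: str
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.pairs)


def read_tracks(path, format: str = "csv", column_map: dict | None = None) -> list[Track]:
    """Read relocation CSV into one :class:`Track` per animal.

    The canonical header is ``animal_id,sex,study_area,timestamp,x,y``
    (timestamp ISO-8601, x/y projected meters). ``column_map`` renames
    dialect columns onto the canonical names (Movebank-style files).
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    tracks = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        dup = grp["timestamp"].duplicated()
        if dup.any():
            raise TrackValidationError(
                f"animal {animal_id}: duplicate timestamp(s) "
                f"{grp.loc[dup, 'timestamp'].iloc[0]}"
            )
        tracks.append(
            Track(
                animal_id=str(animal_id),
                sex=str(grp["sex"].iloc[0]),
                study_area=str(grp["study_area"].iloc[0]),
                fixes=grp[["timestamp", "x", "y"]],
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks back to the canonical CSV layout."""
    frames = []
    for t in tracks:
        f = t.fixes.copy()
        f.insert(0, "animal_id", t.animal_id)
        f.insert(1, "sex", t.sex)
        f.insert(2, "study_area", t.study_area)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def align_dyad(track_a: Track, track_b: Track, tolerance: float = 300.0) -> DyadSeries:
    """Match fixes of two tracks into simultaneous pairs.

    Greedy nearest-time matching: candidate fix pairs with |dt| <= ``tolerance``
    seconds are accepted in order of increasing |dt|, each fix used at most once.
    Returns an empty series (not an error) when the tracks never overlap in time.
    The result is symmetric in the two tracks up to column naming.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if track_a.study_area != track_b.study_area:
        raise ValueError(
            f"tracks from different study areas: {track_a.study_area} vs {track_b.study_area}"
        )
    ta, tb = track_a.times, track_b.times
    xya, xyb = track_a.xy, track_b.xy

    # All candidate pairs within tolerance, via a sorted two-pointer sweep.
    cands: list[tuple[float, int, int]] = []
    j0 = 0
    for i in range(len(ta)):
        while j0 < len(tb) and tb[j0] < ta[i] - tolerance:
            j0 += 1
        j = j0
        while j < len(tb) and tb[j] <= ta[i] + tolerance:
            cands.append((abs(ta[i] - tb[j]), i, j))
            j += 1
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    matches.sort()

    rows = {
        "timestamp": [], "t_a": [], "t_b": [],
        "xa": [], "ya": [], "xb": [], "yb": [], "distance": [],
    }
    for i, j in matches:
        rows["timestamp"].append(0.5 * (ta[i] + tb[j]))
        rows["t_a"].append(ta[i])
        rows["t_b"].append(tb[j])
        rows["xa"].append(xya[i, 0])
        rows["ya"].append(xya[i, 1])
        rows["xb"].append(xyb[j, 0])
        rows["yb"].append(xyb[j, 1])
        rows["distance"].append(float(np.hypot(xya[i, 0] - xyb[j, 0], xya[i, 1] - xyb[j, 1])))
    pairs = pd.DataFrame(rows)
    if len(pairs):
        pairs["timestamp"] = pd.to_datetime(pairs["timestamp"], unit="s")
    else:
        pairs = pairs.astype({"timestamp": "datetime64[ns]"})
    return DyadSeries(track_a.animal_id, track_b.animal_id, track_a.study_area, pairs)


@dataclass
class BreedingCalendar:
    """Year-agnostic breeding-phase calendar: per region, three dated intervals
    (early, peak, late) defined by (month, day) endpoints, inclusive.

    Intervals must be ordered, non-overlapping and contiguous within a region.
    """

    regions: dict[str, dict[str, tuple[tuple[int, int], tuple[int, int]]]]

    def __post_init__(self) -> None:
        for region, phases in self.regions.items():
            keys = list(phases)
            if keys != ["early", "peak", "late"]:
                raise ValueError(f"region {region}: phases must be early, peak, late in order")
            bounds = [phases[k] for k in keys]
            for (_, e1), (s2, _) in zip(bounds, bounds[1:]):
                d1 = date(2000, *e1)
                d2 = date(2000, *s2)
                if (d2 - d1).days != 1:
                    raise ValueError(
                        f"region {region}: phases must be contiguous and non-overlapping"
                    )

    def season_span(self, region: str) -> tuple[tuple[int, int], tuple[int, int]]:
        phases = self.regions[region]
        return phases["early"][0], phases["late"][1]


#: Published phase dates for the northern and southern study regions.
DEFAULT_CALENDAR = BreedingCalendar(
    {
        "north": {
            "early": ((10, 18), (11, 7)),
            "peak": ((11, 8), (11, 28)),
            "late": ((11, 29), (12, 19)),
        },
        "south": {
            "early": ((10, 16), (11, 5)),
            "peak": ((11, 6), (11, 29)),
            "late": ((11, 30), (12, 20)),
        },
    }
)


def assign_phase(timestamp, region: str, calendar: BreedingCalendar = DEFAULT_CALENDAR) -> str:
    """Breeding phase ('early'/'peak'/'late') of a timestamp, or 'outside'.

    Interval endpoints are inclusive; the calendar is applied year-agnostically
    by (month, day). Phases never span the new year here, so no wrap handling.
    """
    if region not in calendar.regions:
        raise KeyError(f"unknown region: {region!r}")
    ts = pd.Timestamp(timestamp)
    md = (ts.month, ts.day)
    for phase, (start, end) in calendar.regions[region].items():
        if start <= md <= end:
            return phase
    return "outside"
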