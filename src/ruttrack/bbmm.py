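"""Brownian bridge movement model: motion variance, UD raster, volume transform.

The utilization distribution (UD) is built from Brownian bridges between
consecutive GPS fixes. One motion-variance parameter ``sigma2_m`` (m^2/s)
governs bridge spread; GPS measurement error enters as a fixed per-coordinate
standard deviation ``delta`` (meters). The UD-volume transform converts the
density raster into percent-volume contour values: a cell with volume v% lies
inside every probability contour >= v% and outside all smaller ones, so small
values mark core use areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .trajectory import Track

__all__ = [
    "BBMMParams",
    "UDGrid",
    "VolumeGrid",
    "fit_sigma2_m",
    "compute_ud",
    "ud_volume",
    "volume_at",
]


@dataclass
class BBMMParams:
    sigma2_m: float  # motion variance, m^2 per second
    delta: float = 10.0  # measurement-error SD, meters
    max_lag: float | None = None  # hours; bridges spanning longer gaps excluded

    def __post_init__(self) -> None:
        if self.sigma2_m < 0 or self.delta < 0:
            raise ValueError("sigma2_m and delta must be >= 0")


@dataclass
class UDGrid:
    """Rasterized utilization density: probability mass per cell, summing to 1.

    ``origin`` is the lower-left corner of cell (0, 0); ``mass`` has shape
    (n_x, n_y) indexed [ix, iy].
    """

    origin: tuple[float, float]
    cell_size: float
    mass: np.ndarray

    @property
    def n_x(self) -> int:
        return self.mass.shape[0]

    @property
    def n_y(self) -> int:
        return self.mass.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.origin[0] + (np.arange(self.n_x) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(self.n_y) + 0.5) * self.cell_size
        return cx, cy


@dataclass
class VolumeGrid:
    """Percent-volume transform of a UDGrid; values in (0, 100] per cell."""

    origin: tuple[float, float]
    cell_size: float
    volume: np.ndarray  # shape (n_x, n_y)


class OutOfExtentWarning(UserWarning):
    pass


def _triplets(track: Track, max_lag_s: float | None):
    """Odd-indexed interior fixes k with flanking neighbors, as leave-one-out
    triplets (alpha, T seconds, squared residual given straight-line prediction
    uses the fitted sigma2 only through the variance, so residuals are fixed)."""
    t = track.times
    z = track.xy
    out = []
    for k in range(1, len(t) - 1, 2):
        T = t[k + 1] - t[k - 1]
        if T <= 0:
            continue
        if max_lag_s is not None and T > max_lag_s:
            continue
        a = (t[k] - t[k - 1]) / T
        mu = z[k - 1] + a * (z[k + 1] - z[k - 1])
        r2 = float(np.sum((z[k] - mu) ** 2))  # both coordinates
        out.append((a, T, r2))
    return out


def fit_sigma2_m(
    track: Track,
    delta: float = 10.0,
    bounds: tuple[float, float] = (1e-12, 1e4),
    max_lag: float | None = None,
    interior: str = "odd",
) -> float:
    """Motion variance by leave-one-out maximum likelihood.

    Every second interior fix z_k (odd indices by default; ``interior='even'``
    selects the complementary set) is predicted from its neighbors under a
    Brownian bridge: z_k ~ N(z_{k-1} + a (z_{k+1} - z_{k-1}), s^2 I) with
    a = (t_k - t_{k-1}) / T, T = t_{k+1} - t_{k-1} and per-coordinate variance
    s^2 = a (1 - a) T sigma2_m + (1 - a)^2 delta^2 + a^2 delta^2. The product
    of these densities is maximized over sigma2_m by bounded 1-D search.

    Returns sigma2_m in m^2/s (track timestamps are converted to seconds).
    """
    if len(track) < 3:
        raise ValueError(f"track {track.animal_id}: need >= 3 fixes to fit sigma2_m")
    if interior not in ("odd", "even"):
        raise ValueError("interior must be 'odd' or 'even'")
    max_lag_s = None if max_lag is None else max_lag * 3600.0
    trips = _triplets(track, max_lag_s)
    if interior == "even":
        t = track.times
        z = track.xy
        trips = []
        for k in range(2, len(t) - 1, 2):
            T = t[k + 1] - t[k - 1]
            if T <= 0 or (max_lag_s is not None and T > max_lag_s):
                continue
            a = (t[k] - t[k - 1]) / T
            mu = z[k - 1] + a * (z[k + 1] - z[k - 1])
            trips.append((a, T, float(np.sum((z[k] - mu) ** 2))))
    if not trips:
        raise ValueError(f"track {track.animal_id}: no usable leave-one-out triplets")

    a = np.array([x[0] for x in trips])
    T = np.array([x[1] for x in trips])
    r2 = np.array([x[2] for x in trips])
    err = delta**2 * ((1 - a) ** 2 + a**2)

    def nll(sigma2: float) -> float:
        s2 = a * (1 - a) * T * sigma2 + err
        # bivariate normal: two independent coordinates with common variance
        return float(np.sum(np.log(s2) + r2 / (2 * s2)))

    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


def _bridge_points(times, xy, sigma2, delta, n_integration, max_lag_s):
    """Per integration point: (weight, mean_x, mean_y, sd). Weight is the bridge
    duration share divided equally among its integration points."""
    frac = (np.arange(1, n_integration + 1)) / (n_integration + 1)  # interior
    pts = []
    total_T = 0.0
    for i in range(len(times) - 1):
        T = times[i + 1] - times[i]
        if T <= 0:
            continue  # zero-duration bridge skipped
        if max_lag_s is not None and T > max_lag_s:
            continue
        total_T += T
        for al in frac:
            mu = xy[i] + al * (xy[i + 1] - xy[i])
            s2 = al * (1 - al) * T * sigma2 + ((1 - al) ** 2 + al**2) * delta**2
            pts.append((T / n_integration, mu[0], mu[1], np.sqrt(s2)))
    if total_T == 0:
        raise ValueError("track has no positive-duration bridges")
    return [(w / total_T, mx, my, sd) for w, mx, my, sd in pts]


def compute_ud(
    track: Track,
    params: BBMMParams,
    cell_size: float = 30.0,
    buffer: float | None = None,
    n_integration: int = 10,
) -> UDGrid:
    """Rasterize the Brownian-bridge UD on a regular grid.

    The density is the time-weighted average over bridges of the bridge's
    Gaussian law, discretized with ``n_integration`` equally spaced interior
    time points per bridge and evaluated at cell centers; cell masses are
    renormalized to sum to one. The grid covers the track bounding box plus
    ``buffer`` meters (default: max(300, 3.5 x the largest bridge SD)).
    """
    if len(track) < 2:
        raise ValueError("need >= 2 fixes for a UD")
    max_lag_s = None if params.max_lag is None else params.max_lag * 3600.0
    pts = _bridge_points(track.times, track.xy, params.sigma2_m, params.delta,
                         n_integration, max_lag_s)
    max_sd = max(sd for _, _, _, sd in pts)
    if buffer is None:
        buffer = max(300.0, 3.5 * max_sd)
    elif buffer < 3.5 * max_sd:
        warnings.warn(
            f"buffer {buffer:.0f} m is smaller than 3.5 bridge SDs "
            f"({3.5 * max_sd:.0f} m); UD mass may be clipped at the edges"
        )
    xy = track.xy
    x0 = xy[:, 0].min() - buffer
    y0 = xy[:, 1].min() - buffer
    n_x = int(np.ceil((xy[:, 0].max() + buffer - x0) / cell_size))
    n_y = int(np.ceil((xy[:, 1].max() + buffer - y0) / cell_size))
    cx = x0 + (np.arange(n_x) + 0.5) * cell_size
    cy = y0 + (np.arange(n_y) + 0.5) * cell_size

    dens = np.zeros((n_x, n_y))
    for w, mx, my, sd in pts:
        # Separable Gaussian, truncated at 5 SD for speed.
        lo_x = np.searchsorted(cx, mx - 5 * sd)
        hi_x = np.searchsorted(cx, mx + 5 * sd)
        lo_y = np.searchsorted(cy, my - 5 * sd)
        hi_y = np.searchsorted(cy, my + 5 * sd)
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        gx = np.exp(-0.5 * ((cx[lo_x:hi_x] - mx) / sd) ** 2)
        gy = np.exp(-0.5 * ((cy[lo_y:hi_y] - my) / sd) ** 2)
        dens[lo_x:hi_x, lo_y:hi_y] += (w / (2 * np.pi * sd**2)) * np.outer(gx, gy)

    mass = dens * cell_size**2
    total = mass.sum()
    if total <= 0:
        raise ValueError("UD mass vanished on the grid; enlarge the buffer")
    return UDGrid(origin=(x0, y0), cell_size=cell_size, mass=mass / total)


def ud_volume(ud: UDGrid) -> VolumeGrid:
    """Percent-volume transform of the UD.

    Cells are ranked by density (mass) descending; a cell's volume is 100 times
    the cumulative mass of all cells with density greater than or equal to its
    own, so the densest cell gets the smallest value and ties share one value
    (inclusive cumulative semantics).
    """
    flat = ud.mass.ravel()
    order = np.argsort(flat)[::-1]
    sorted_mass = flat[order]
    cum = np.cumsum(sorted_mass)
    # ties share the inclusive (last) cumulative value of their density class
    vol_sorted = np.empty_like(cum)
    i = 0
    n = len(sorted_mass)
    while i < n:
        j = i
        while j + 1 < n and sorted_mass[j + 1] == sorted_mass[i]:
            j += 1
        vol_sorted[i : j + 1] = cum[j]
        i = j + 1
    vol = np.empty_like(flat)
    vol[order] = 100.0 * vol_sorted
    return VolumeGrid(ud.origin, ud.cell_size, vol.reshape(ud.mass.shape))


def volume_at(vol: VolumeGrid, point: tuple[float, float]) -> float:
    """Volume value of the cell containing ``point``.

    Cells are half-open intervals [edge, edge + cell_size) in both axes, so a
    point on a shared edge belongs to the cell on its upper side. Points
    outside the grid extent return NaN with a warning (reported, not fatal).
    """
    ix = int(np.floor((point[0] - vol.origin[0]) / vol.cell_size))
    iy = int(np.floor((point[1] - vol.origin[1]) / vol.cell_size))
    if not (0 <= ix < vol.volume.shape[0] and 0 <= iy < vol.volume.shape[1]):
        warnings.warn(f"point {point} outside grid extent", OutOfExtentWarning)
        return float("nan")
    return float(vol.volume[ix, iy])
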