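"""Synthetic paired male-female trajectories with known interaction events.

Each animal follows a discrete-time home-range-anchored random walk (an
Ornstein-Uhlenbeck-like process at hourly resolution),

    x_{t+1} = x_t + beta (c - x_t) + Normal(0, sigma^2 I),

with attraction strength ``beta`` toward a home-range center ``c`` and hourly
diffusion ``sigma`` per coordinate. Observed fixes add isotropic GPS error
(SD 10 m by default). Scheduled interaction events couple the pair in one of
three modes:

* ``cohesive-distinct`` — the pair isolates together: the female anchors near
  her event-entry point with reduced diffusion, the male holds a slowly
  varying ~25 m tether to her. Proximity AND changed movement statistics:
  every stage of the pipeline should succeed here.
* ``cohesive-null`` — proximity without movement change: the male keeps his
  baseline dynamics untouched and the female tethers to him, so the male's
  event-hour step distribution is identical to his non-event hours by
  construction. Space-use/state detectors working on male data alone should
  find nothing — the negative control.
* ``stationary-female`` — the female freezes at her current position and the
  male orbits her within 50 m (tending a sit-and-wait female at her range
  core).

Default scales emulate breeding-season deer telemetry: hourly fixes over a
nine-week season, season-scale 95% home ranges around 1-3 km^2, event
durations log-normal with median 7 h truncated to [1, 79] h. All randomness
flows from one seed through named SeedSequence spawns (schedule, paths,
noise), so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Track

__all__ = ["Scenario", "simulate_pair", "simulate_hmm_series", "default_event_schedule"]

MODES = ("cohesive-distinct", "cohesive-null", "stationary-female")


@dataclass
class Scenario:
    """Generator configuration for one male-female dyad."""

    season_days: int = 63  # ~9-week breeding season
    start: str = "2015-10-18"  # first fix timestamp (northern early-rut onset)
    female_center: tuple[float, float] = (0.0, 0.0)
    beta_f: float = 0.1
    sigma_f: float = 130.0  # hourly per-coordinate diffusion SD (m)
    male_center: tuple[float, float] = (500.0, 0.0)
    beta_m: float = 0.1
    sigma_m: float = 130.0
    delta: float = 10.0  # GPS error SD (m)
    events: list[tuple[float, float]] | None = None  # (start_h, duration_h)
    n_events: int = 10  # used when events is None
    mode: str = "cohesive-distinct"
    # event-time dynamics
    event_sigma_f: float = 40.0  # female diffusion during distinct events (tending pace)
    event_beta_f: float = 0.05
    tether_sd: float = 25.0  # stationary SD of the male-female tether
    tether_phi: float = 0.95  # AR(1) persistence of the tether
    orbit_radius: float = 50.0  # stationary-female mode
    study_area: str = "SN"
    male_id: str = "M1"
    female_id: str = "F1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for v in (self.sigma_f, self.sigma_m, self.delta, self.event_sigma_f, self.tether_sd):
            if v < 0:
                raise ValueError("all SDs must be >= 0")

    @property
    def n_hours(self) -> int:
        return self.season_days * 24

    def validate_schedule(self, events: list[tuple[float, float]]) -> None:
        evs = sorted(events)
        for (s1, d1), (s2, _) in zip(evs, evs[1:]):
            if s1 + d1 > s2:
                raise ValueError(f"overlapping scheduled events at hours {s1} and {s2}")
        for s, d in evs:
            # the event's last hour s + d must land on an existing fix index
            if s < 0 or d <= 0 or s + d > self.n_hours - 1:
                raise ValueError(f"event ({s}, {d}) outside the season span")


def default_event_schedule(
    scenario: Scenario, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Non-overlapping (start_h, duration_h) schedule.

    Durations are log-normal with median 7 h (sigma 0.9 on the log scale),
    truncated to [1, 79] h and rounded to whole hours; starts are drawn
    uniformly with a 6 h separation buffer between events.
    """
    durations = []
    while len(durations) < scenario.n_events:
        d = rng.lognormal(np.log(7.0), 0.9)
        if 1.0 <= d <= 79.0:
            durations.append(float(np.round(d)))
    placed: list[tuple[float, float]] = []
    attempts = 0
    for d in sorted(durations, reverse=True):  # place long events first
        while attempts < 10_000:
            attempts += 1
            s = float(rng.integers(0, scenario.n_hours - int(d)))
            if all(s + d + 6 <= s2 or s2 + d2 + 6 <= s for s2, d2 in placed):
                placed.append((s, d))
                break
        else:
            raise RuntimeError("could not place the scheduled events without overlap")
    return sorted(placed)


def _ou_step(pos, center, beta, sigma, rng):
    return pos + beta * (np.asarray(center) - pos) + rng.normal(0.0, sigma, 2)


def simulate_pair(scenario: Scenario):
    """Simulate one dyad; returns (male Track, female Track, truth DataFrame).

    The truth table has one row per scheduled event with columns
    male_id, female_id, start, end, mode (end = timestamp of the last event
    hour, matching inclusive event-fix endpoints downstream). Bit-identical
    for a given scenario (all randomness derives from ``scenario.seed``).
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_sched, rng_path, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]
    events = scenario.events
    if events is None:
        events = default_event_schedule(scenario, rng_sched)
    scenario.validate_schedule(events)

    n = scenario.n_hours
    in_event = np.full(n, -1)  # event index per hour, -1 outside
    for k, (s, d) in enumerate(events):
        in_event[int(s) : int(s + d) + 1] = k

    f = np.empty((n, 2))
    m = np.empty((n, 2))
    f[0] = scenario.female_center
    m[0] = scenario.male_center
    tether = rng_path.normal(0.0, scenario.tether_sd, 2)
    tau = scenario.tether_sd * np.sqrt(1 - scenario.tether_phi**2)
    anchor = np.asarray(scenario.female_center, dtype=float)
    orbit_phase = 0.0
    prev_ev = -1
    for t in range(1, n):
        ev = in_event[t]
        if ev >= 0 and ev != prev_ev:  # event entry
            anchor = f[t - 1].copy()
            tether = rng_path.normal(0.0, scenario.tether_sd, 2)
            orbit_phase = rng_path.uniform(0, 2 * np.pi)
        if ev < 0:
            f[t] = _ou_step(f[t - 1], scenario.female_center, scenario.beta_f,
                            scenario.sigma_f, rng_path)
            m[t] = _ou_step(m[t - 1], scenario.male_center, scenario.beta_m,
                            scenario.sigma_m, rng_path)
        elif scenario.mode == "cohesive-distinct":
            f[t] = _ou_step(f[t - 1], anchor, scenario.event_beta_f,
                            scenario.event_sigma_f, rng_path)
            tether = scenario.tether_phi * tether + rng_path.normal(0.0, tau, 2)
            m[t] = f[t] + tether
        elif scenario.mode == "cohesive-null":
            # male untouched: identical dynamics in and out of events
            m[t] = _ou_step(m[t - 1], scenario.male_center, scenario.beta_m,
                            scenario.sigma_m, rng_path)
            tether = scenario.tether_phi * tether + rng_path.normal(0.0, tau, 2)
            f[t] = m[t] + tether
        else:  # stationary-female
            f[t] = anchor
            orbit_phase += 2 * np.pi / 12.0  # one loop per 12 h
            m[t] = (
                anchor
                + scenario.orbit_radius * np.array([np.cos(orbit_phase), np.sin(orbit_phase)])
                + rng_path.normal(0.0, 5.0, 2)
            )
        prev_ev = ev

    obs_m = m + rng_noise.normal(0.0, scenario.delta, (n, 2))
    obs_f = f + rng_noise.normal(0.0, scenario.delta, (n, 2))
    t0 = pd.Timestamp(scenario.start)
    times = t0 + pd.to_timedelta(np.arange(n), unit="h")

    def _track(animal_id, sex, xy):
        return Track(
            animal_id=animal_id,
            sex=sex,
            study_area=scenario.study_area,
            fixes=pd.DataFrame({"timestamp": times, "x": xy[:, 0], "y": xy[:, 1]}),
        )

    truth = pd.DataFrame(
        {
            "male_id": scenario.male_id,
            "female_id": scenario.female_id,
            "start": [times[int(s)] for s, _ in events],
            "end": [times[int(s + d)] for s, d in events],
            "mode": scenario.mode,
        }
    )
    return _track(scenario.male_id, "male", obs_m), _track(scenario.female_id, "female", obs_f), truth


def simulate_hmm_series(
    mu, sigma, zero_mass, angle_mean, kappa, tpm, n_steps: int, seed: int | None = None,
    animal_id: str = "sim",
):
    """Simulate a step/turn series from known HMM parameters.

    Returns (StepAngleSeries, true state array with 1-based labels). The
    state path starts from the stationary distribution of ``tpm``; steps come
    from each state's zero-inflated gamma and angles from its von Mises.
    """
    from .hmm import StateSequence, StepAngleSeries, stationary_distribution  # noqa: F401

    tpm = np.asarray(tpm, dtype=float)
    if tpm.ndim != 2 or tpm.shape[0] != tpm.shape[1] or not np.allclose(tpm.sum(1), 1.0):
        raise ValueError("tpm must be square with rows summing to 1")
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    zero_mass = np.asarray(zero_mass, float)
    angle_mean = np.asarray(angle_mean, float)
    kappa = np.asarray(kappa, float)
    N = len(mu)
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(N, p=stationary_distribution(tpm))
    for t in range(1, n_steps):
        states[t] = rng.choice(N, p=tpm[states[t - 1]])
    steps = np.empty(n_steps)
    angles = np.empty(n_steps)
    for t in range(n_steps):
        s = states[t]
        if rng.random() < zero_mass[s]:
            steps[t] = 0.0
        else:
            shape = (mu[s] / sigma[s]) ** 2
            steps[t] = rng.gamma(shape, sigma[s] ** 2 / mu[s])
        angles[t] = rng.vonmises(angle_mean[s], kappa[s])
    series = StepAngleSeries(animal_id, steps, angles)
    return series, states + 1
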