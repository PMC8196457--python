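"""Hidden Markov models for hourly step lengths and turning angles.

States emit step lengths from a zero-inflated gamma (a point mass at exactly
zero plus a gamma density on (0, inf)) and turning angles from a von Mises
distribution on (-pi, pi]. Models are fit jointly across individuals — all
state-dependent and transition parameters are shared, each series contributing
an independent forward-likelihood term started at the stationary distribution
of the transition matrix. Fitting maximizes the exact forward log-likelihood
numerically (multi-start quasi-Newton on working-scale parameters); decoding
uses the Viterbi algorithm. States are canonically ordered by ascending step
mean so labels are comparable across fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0e

from .regularize import RegularTrack

__all__ = [
    "StepAngleSeries",
    "HMMFit",
    "StateSequence",
    "make_series",
    "fit_hmm",
    "viterbi_decode",
    "forward_loglik",
]


@dataclass
class StepAngleSeries:
    """Per hourly transition: step length (m, >= 0) and turning angle
    (radians in (-pi, pi], NaN where undefined). ``timestamps`` are the n+1
    hourly locations the n steps connect."""

    animal_id: str
    steps: np.ndarray
    angles: np.ndarray
    timestamps: pd.Series | None = None

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.steps) != len(self.angles):
            raise ValueError("steps and angles must have equal length")
        if (self.steps < 0).any():
            raise ValueError("step lengths must be >= 0")

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class HMMFit:
    """Fitted joint HMM. States ordered by ascending step mean ``mu``."""

    n_states: int
    mu: np.ndarray  # gamma step mean per state (m)
    sigma: np.ndarray  # gamma step SD per state (m)
    zero_mass: np.ndarray  # point mass at step 0 per state
    angle_mean: np.ndarray  # von Mises mean per state (rad)
    kappa: np.ndarray  # von Mises concentration per state
    tpm: np.ndarray  # transition matrix, rows sum to 1
    stationary: np.ndarray
    log_likelihood: float
    converged: bool
    restart_logliks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.n_states),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "angle_mean": self.angle_mean.tolist(),
            "kappa": self.kappa.tolist(),
            "tpm": self.tpm.tolist(),
            "stationary": self.stationary.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "restart_logliks": [float(v) for v in self.restart_logliks],
        }


@dataclass
class StateSequence:
    """Decoded state per hourly location (1-based labels).

    Each location carries the Viterbi state of its outgoing step; the final
    location repeats the last step's state so the sequence covers every hour.
    """

    animal_id: str
    timestamps: pd.Series
    states: np.ndarray  # 1..n_states, length = n hourly locations

    def __len__(self) -> int:
        return len(self.states)


def make_series(reg: RegularTrack) -> StepAngleSeries:
    """Step lengths and turning angles from a regular hourly track.

    step_t is the Euclidean distance between consecutive hourly locations;
    the turning angle at step t is the signed change of movement azimuth from
    step t-1 to step t wrapped to (-pi, pi] (left turns positive). Angles are
    NaN at the first step and wherever either adjacent step has zero length.
    """
    if len(reg) < 3:
        raise ValueError(f"track {reg.animal_id}: need >= 3 hourly locations")
    xy = reg.xy
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    az = np.arctan2(d[:, 1], d[:, 0])
    angles = np.full(len(steps), np.nan)
    turn = az[1:] - az[:-1]
    turn = np.mod(turn + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
    turn[turn == -np.pi] = np.pi
    valid = (steps[:-1] > 0) & (steps[1:] > 0)
    angles[1:][valid] = turn[valid]
    return StepAngleSeries(reg.animal_id, steps, angles, reg.timestamps)


# ---------------------------------------------------------------------------
# likelihood machinery


def _gamma_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    return (shape - 1) * np.log(x) - x / scale - shape * np.log(scale) - gammaln(shape)


def _vonmises_logpdf(x: np.ndarray, mean: float, kappa: float) -> np.ndarray:
    # log I0(kappa) = log i0e(kappa) + kappa  (overflow-safe)
    return kappa * np.cos(x - mean) - np.log(2 * np.pi) - (np.log(i0e(kappa)) + kappa)


def emission_logprobs(
    series: StepAngleSeries,
    mu: np.ndarray,
    sigma: np.ndarray,
    zero_mass: np.ndarray,
    angle_mean: np.ndarray,
    kappa: np.ndarray,
) -> np.ndarray:
    """(T, N) matrix of per-step log emission probabilities.

    Zero steps take the state's point mass; positive steps the continuous
    gamma density scaled by (1 - zero mass). Missing angles contribute a
    factor of one (their log term is dropped).
    """
    T, N = len(series), len(mu)
    logb = np.empty((T, N))
    steps, angles = series.steps, series.angles
    pos = steps > 0
    has_angle = np.isfinite(angles)
    tiny = 1e-300
    for s in range(N):
        col = np.empty(T)
        col[~pos] = np.log(zero_mass[s] + tiny)
        col[pos] = np.log1p(-zero_mass[s]) + _gamma_logpdf(steps[pos], mu[s], sigma[s])
        col[has_angle] += _vonmises_logpdf(angles[has_angle], angle_mean[s], kappa[s])
        logb[:, s] = col
    return logb


@njit(cache=True)
def _forward_core(logb: np.ndarray, tpm: np.ndarray, init: np.ndarray) -> float:
    """Scaled forward algorithm; returns the log-likelihood."""
    T, N = logb.shape
    alpha = np.empty(N)
    c = -np.inf
    for s in range(N):
        if logb[0, s] > c:
            c = logb[0, s]
    tot = 0.0
    for s in range(N):
        alpha[s] = init[s] * np.exp(logb[0, s] - c)
        tot += alpha[s]
    if tot <= 0.0 or not np.isfinite(tot):
        return -np.inf
    ll = c + np.log(tot)
    for s in range(N):
        alpha[s] /= tot
    new = np.empty(N)
    for t in range(1, T):
        c = -np.inf
        for s in range(N):
            if logb[t, s] > c:
                c = logb[t, s]
        tot = 0.0
        for j in range(N):
            acc = 0.0
            for i in range(N):
                acc += alpha[i] * tpm[i, j]
            new[j] = acc * np.exp(logb[t, j] - c)
            tot += new[j]
        if tot <= 0.0 or not np.isfinite(tot):
            return -np.inf
        ll += c + np.log(tot)
        for s in range(N):
            alpha[s] = new[s] / tot
    return ll


@njit(cache=True)
def _viterbi_core(logb: np.ndarray, log_tpm: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    """Exact joint-MAP path; ties broken toward the lower state index."""
    T, N = logb.shape
    score = np.empty((T, N))
    back = np.zeros((T, N), dtype=np.int64)
    for s in range(N):
        score[0, s] = log_init[s] + logb[0, s]
    for t in range(1, T):
        for j in range(N):
            best = score[t - 1, 0] + log_tpm[0, j]
            arg = 0
            for i in range(1, N):
                v = score[t - 1, i] + log_tpm[i, j]
                if v > best:  # strict: ties keep the lower index
                    best = v
                    arg = i
            score[t, j] = best + logb[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = score[T - 1, 0]
    arg = 0
    for s in range(1, N):
        if score[T - 1, s] > best:
            best = score[T - 1, s]
            arg = s
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix with eigenvalue 1,
    normalized to a probability vector (solves delta @ tpm = delta)."""
    n = tpm.shape[0]
    A = np.vstack([tpm.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    delta = np.clip(delta, 0, None)
    return delta / delta.sum()


def forward_loglik(fit_or_params, series: StepAngleSeries) -> float:
    """Forward log-likelihood of one series under a fit (or HMMFit-shaped dict)."""
    p = fit_or_params if isinstance(fit_or_params, HMMFit) else HMMFit(**fit_or_params)
    logb = emission_logprobs(
        series,
        np.asarray(p.mu, dtype=float),
        np.asarray(p.sigma, dtype=float),
        np.asarray(p.zero_mass, dtype=float),
        np.asarray(p.angle_mean, dtype=float),
        np.asarray(p.kappa, dtype=float),
    )
    tpm = np.asarray(p.tpm, dtype=float)
    return float(_forward_core(logb, tpm, stationary_distribution(tpm)))


# ---------------------------------------------------------------------------
# working-scale parameterization


def _unpack(theta: np.ndarray, N: int):
    """Working -> natural parameters.

    Layout: log mu (N) | log sigma (N) | logit zero-mass (N) |
    angle mean as (a, b) pairs -> atan2(b, a) (2N) | log kappa (N) |
    off-diagonal multinomial logits of the TPM row-wise (N(N-1)).
    """
    i = 0
    mu = np.exp(theta[i : i + N]); i += N
    sigma = np.exp(theta[i : i + N]); i += N
    zero_mass = 1.0 / (1.0 + np.exp(-theta[i : i + N])); i += N
    a = theta[i : i + N]; i += N
    b = theta[i : i + N]; i += N
    angle_mean = np.arctan2(b, a)
    kappa = np.exp(theta[i : i + N]); i += N
    tpm = np.eye(N)
    for r in range(N):
        eta = np.zeros(N)
        for c in range(N):
            if c != r:
                eta[c] = theta[i]
                i += 1
        eta -= eta.max()
        w = np.exp(eta)
        tpm[r] = w / w.sum()
    return mu, sigma, zero_mass, angle_mean, kappa, tpm


def _pack(mu, sigma, zero_mass, angle_mean, kappa, tpm) -> np.ndarray:
    N = len(mu)
    zm = np.clip(zero_mass, 1e-6, 1 - 1e-6)
    parts = [np.log(mu), np.log(sigma),
             np.log(zm / (1 - zm)),
             np.cos(angle_mean), np.sin(angle_mean), np.log(kappa)]
    eta = []
    for r in range(N):
        row = np.clip(tpm[r], 1e-8, None)
        for c in range(N):
            if c != r:
                eta.append(np.log(row[c] / row[r]))
    return np.concatenate(parts + [np.array(eta)])


def _order_states(mu, sigma, zero_mass, angle_mean, kappa, tpm):
    order = np.argsort(mu)
    return (mu[order], sigma[order], zero_mass[order], angle_mean[order],
            kappa[order], tpm[np.ix_(order, order)])


def _joint_nll(theta: np.ndarray, series_list: list[StepAngleSeries], N: int) -> float:
    mu, sigma, zero_mass, angle_mean, kappa, tpm = _unpack(theta, N)
    delta = stationary_distribution(tpm)
    ll = 0.0
    for series in series_list:
        logb = emission_logprobs(series, mu, sigma, zero_mass, angle_mean, kappa)
        ll += _forward_core(logb, tpm, delta)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _initial_values(series_list, N, rng):
    steps = np.concatenate([s.steps for s in series_list])
    pos = steps[steps > 0]
    if len(pos) == 0:
        pos = np.array([1.0])
    # random quantile anchors: rare tail states (e.g. brief travel bouts) are
    # only reachable if some restarts seed a mean far out in the distribution
    qs = np.quantile(pos, np.sort(rng.uniform(0.02, 0.998, N)))
    zero_frac = np.mean(steps == 0)
    mu = qs * rng.lognormal(0.0, 0.3, N)
    sigma = mu * rng.lognormal(0.0, 0.3, N)
    zero_mass = np.full(N, max(zero_frac, 1e-3)) * rng.uniform(0.5, 1.5, N)
    zero_mass = np.clip(zero_mass, 1e-4, 0.5)
    angle_mean = rng.uniform(-0.5, 0.5, N)
    kappa = rng.lognormal(0.0, 0.5, N)
    diag = rng.uniform(0.7, 0.95)
    tpm = np.full((N, N), (1 - diag) / (N - 1))
    np.fill_diagonal(tpm, diag)
    return _pack(mu, sigma, zero_mass, angle_mean, kappa, tpm)


def fit_hmm(
    series: list[StepAngleSeries] | StepAngleSeries,
    n_states: int,
    n_restarts: int = 25,
    seed: int | None = None,
    x0: np.ndarray | None = None,
) -> HMMFit:
    """Fit a joint HMM by direct maximization of the forward log-likelihood.

    ``n_restarts`` seeded perturbed initializations are run through L-BFGS-B
    on the working scale; the best optimum is returned with states reordered
    by ascending step mean. ``x0`` adds one extra start from user-supplied
    natural parameters (mu, sigma, zero_mass, angle_mean, kappa, tpm tuple).
    Pooled steps should number at least ~50 per state (warned otherwise).
    """
    if isinstance(series, StepAngleSeries):
        series = [series]
    series = [s for s in series if len(s) > 0]
    if not series:
        raise ValueError("no non-empty series to fit")
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    n_total = sum(len(s) for s in series)
    if n_total < 50 * n_states:
        import warnings

        warnings.warn(
            f"only {n_total} pooled steps for {n_states} states; fit may be unstable"
        )
    rng = np.random.default_rng(seed)
    starts = [_initial_values(series, n_states, rng) for _ in range(n_restarts)]
    if x0 is not None:
        starts.append(_pack(*x0) if isinstance(x0, tuple) else np.asarray(x0))

    best = None
    logliks = []
    for theta0 in starts:
        res = minimize(
            _joint_nll,
            theta0,
            args=(series, n_states),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        logliks.append(-res.fun)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"all {len(starts)} restarts failed to produce a finite likelihood"
        )
    mu, sigma, zero_mass, angle_mean, kappa, tpm = _order_states(
        *_unpack(best.x, n_states)
    )
    return HMMFit(
        n_states=n_states,
        mu=mu,
        sigma=sigma,
        zero_mass=zero_mass,
        angle_mean=angle_mean,
        kappa=kappa,
        tpm=tpm,
        stationary=stationary_distribution(tpm),
        log_likelihood=float(-best.fun),
        converged=bool(best.success),
        restart_logliks=logliks,
    )


def viterbi_decode(fit: HMMFit, series: StepAngleSeries) -> StateSequence:
    """Most likely joint state path under the fitted model (1-based labels).

    The per-step path is mapped to hourly locations by giving each location
    the state of its outgoing step and repeating the final state for the last
    location. Steps with missing angles drop the angle emission factor.
    """
    logb = emission_logprobs(
        series, fit.mu, fit.sigma, fit.zero_mass, fit.angle_mean, fit.kappa
    )
    with np.errstate(divide="ignore"):
        log_tpm = np.log(fit.tpm)
        log_init = np.log(fit.stationary)
    path = _viterbi_core(logb, log_tpm, log_init)
    states = np.append(path, path[-1]) + 1
    if series.timestamps is not None:
        ts = series.timestamps.reset_index(drop=True)
    else:
        ts = pd.Series(pd.to_datetime(np.arange(len(states)), unit="h"))
    return StateSequence(series.animal_id, ts, states)
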