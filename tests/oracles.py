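"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (exhaustive enumeration, direct
trigonometry, plain sorting) and shares no code with the implementation
it checks.
"""

from itertools import product

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises as vonmises_dist


def nearest_time_pairs(ta, tb, tolerance):
    """All-pairs nearest-time matching: repeatedly take the globally closest
    unused (i, j) pair with |ta_i - tb_j| <= tolerance."""
    pairs = []
    used_a, used_b = set(), set()
    cands = sorted(
        (abs(ta[i] - tb[j]), i, j)
        for i in range(len(ta))
        for j in range(len(tb))
        if abs(ta[i] - tb[j]) <= tolerance
    )
    for _, i, j in cands:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j))
    return sorted(pairs)


def event_segments(distances, hours, dist_threshold=100.0, min_run=2, gap_hours=2.0):
    """Expected event index ranges [(lo, hi), ...] from first principles.

    Scan for maximal runs of close fixes; join runs whose close-to-close time
    separation is <= gap_hours; accept a joined span if some constituent run
    has >= min_run fixes and the span mean distance is <= the threshold,
    otherwise accept its qualifying constituent runs individually.
    """
    close = [d <= dist_threshold for d in distances]
    runs = []
    i = 0
    while i < len(close):
        if close[i]:
            j = i
            while j + 1 < len(close) and close[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and hours[run[0]] - hours[merged[-1][-1][1]] <= gap_hours:
            merged[-1].append(run)
        else:
            merged.append([run])
    out = []
    for group in merged:
        lo, hi = group[0][0], group[-1][1]
        if not any(b - a + 1 >= min_run for a, b in group):
            continue
        if np.mean(distances[lo : hi + 1]) <= dist_threshold:
            out.append((lo, hi))
        else:
            for a, b in group:
                if b - a + 1 >= min_run and np.mean(distances[a : b + 1]) <= dist_threshold:
                    out.append((a, b))
    return out


def turning_angles(xy):
    """Signed azimuth changes, wrapped to (-pi, pi], NaN where undefined."""
    xy = np.asarray(xy, dtype=float)
    az, lengths = [], []
    for k in range(len(xy) - 1):
        dx, dy = xy[k + 1] - xy[k]
        lengths.append(np.hypot(dx, dy))
        az.append(np.arctan2(dy, dx))
    out = [np.nan]
    for k in range(1, len(az)):
        if lengths[k - 1] == 0 or lengths[k] == 0:
            out.append(np.nan)
            continue
        a = az[k] - az[k - 1]
        while a <= -np.pi:
            a += 2 * np.pi
        while a > np.pi:
            a -= 2 * np.pi
        out.append(a)
    return np.array(out)


def zig_emission(step, angle, mu, sigma, zero_mass, angle_mean, kappa):
    """Zero-inflated gamma x von Mises emission probability (scipy-based)."""
    if step == 0:
        p = zero_mass
    else:
        shape = (mu / sigma) ** 2
        p = (1 - zero_mass) * gamma_dist.pdf(step, shape, scale=sigma**2 / mu)
    if np.isfinite(angle):
        p *= vonmises_dist.pdf(angle, kappa, loc=angle_mean)
    return p


def exhaustive_loglik(steps, angles, mu, sigma, zero_mass, angle_mean, kappa, tpm, init):
    """Likelihood by summing over every state path (only feasible for tiny T)."""
    T, N = len(steps), len(mu)
    total = 0.0
    for path in product(range(N), repeat=T):
        p = init[path[0]]
        for t in range(T):
            p *= zig_emission(steps[t], angles[t], mu[path[t]], sigma[path[t]],
                              zero_mass[path[t]], angle_mean[path[t]], kappa[path[t]])
            if t > 0:
                p *= tpm[path[t - 1], path[t]]
        total += p
    return np.log(total)


def exhaustive_viterbi(steps, angles, mu, sigma, zero_mass, angle_mean, kappa, tpm, init):
    """argmax over every state path; ties resolved toward the lexicographically
    smallest path (matches the lower-state-index tie rule)."""
    T, N = len(steps), len(mu)
    best_p, best_path = -np.inf, None
    for path in product(range(N), repeat=T):
        p = np.log(init[path[0]])
        for t in range(T):
            p += np.log(
                zig_emission(steps[t], angles[t], mu[path[t]], sigma[path[t]],
                             zero_mass[path[t]], angle_mean[path[t]], kappa[path[t]])
            )
            if t > 0:
                p += np.log(tpm[path[t - 1], path[t]])
        if p > best_p:  # strict: first (lexicographically smallest) path wins ties
            best_p, best_path = p, path
    return np.array(best_path)


def volume_by_sorting(mass):
    """Percent-volume per cell by explicit sort-and-cumsum with inclusive ties."""
    flat = mass.ravel()
    vol = np.empty_like(flat)
    for i, m in enumerate(flat):
        vol[i] = 100.0 * flat[flat >= m].sum()
    return vol.reshape(mass.shape)
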