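"""Multivariate SPIKE-distance (Kreuz et al., 2013).

The SPIKE-distance S is a parameter-free, time-resolved dissimilarity
between spike trains.  For a pair of trains, at each time t the four corner
spikes (preceding/following spike of each train) define local quantities:

    x_P(t) = t - t_prev,  x_F(t) = t_next - t,  x_ISI(t) = t_next - t_prev

and each corner spike contributes its distance to the nearest spike of the
other train, Delta t_P and Delta t_F.  The per-train term

    S_n(t) = (Delta t_P^n * x_F^n + Delta t_F^n * x_P^n) / x_ISI^n

interpolates those corner distances, and the pairwise profile is

    S(t) = (S_1 x_ISI^2 + S_2 x_ISI^1) / (2 * mean(x_ISI)^2).

S is the time average of the profile; it is 0 for identical trains and
bounded by 1.  The multivariate distance over a set of trains is the average
of the pairwise distances (profile averaging and time integration commute).

Edge handling: auxiliary spikes are placed at both ends of the observation
interval on every train and participate in the nearest-spike searches, the
convention of the published reference implementations.

Between consecutive spikes (of either train) the profile is linear in t, so
the exact time average is obtained by evaluating the profile at the midpoint
of every inter-spike segment and weighting by segment length — no sampling
error is involved.
"""

from __future__ import annotations

import numpy as np


def _with_aux(train: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    """Clip a train to the interval and add auxiliary end spikes."""
    t = np.asarray(train, dtype=float)
    t = t[(t >= t_start) & (t <= t_end)]
    if t.size == 0:
        raise ValueError("each spike train needs at least one spike in the interval")
    parts = [t]
    if t[0] > t_start:
        parts.insert(0, np.array([t_start]))
    if t[-1] < t_end:
        parts.append(np.array([t_end]))
    return np.concatenate(parts)


def _nearest_distance(ref: float, other: np.ndarray) -> float:
    """Distance from one spike to the nearest spike of the other train."""
    idx = np.searchsorted(other, ref)
    best = np.inf
    if idx < other.size:
        best = other[idx] - ref
    if idx > 0:
        best = min(best, ref - other[idx - 1])
    return best


def _pair_profile_at(t: float, s1: np.ndarray, s2: np.ndarray) -> float:
    """Pairwise SPIKE-profile value at an interior time t."""
    terms = []
    isis = []
    for a, b in ((s1, s2), (s2, s1)):
        idx = np.searchsorted(a, t, side="right")
        t_prev = a[idx - 1]
        t_next = a[idx]
        x_p = t - t_prev
        x_f = t_next - t
        x_isi = t_next - t_prev
        d_p = _nearest_distance(t_prev, b)
        d_f = _nearest_distance(t_next, b)
        terms.append((d_p * x_f + d_f * x_p) / x_isi)
        isis.append(x_isi)
    mean_isi = 0.5 * (isis[0] + isis[1])
    return (terms[0] * isis[1] + terms[1] * isis[0]) / (2.0 * mean_isi ** 2)


def bivariate_spike_distance(
    train1: np.ndarray, train2: np.ndarray, t_start: float, t_end: float
) -> float:
    """Time-averaged SPIKE-distance between two trains on [t_start, t_end]."""
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    s1 = _with_aux(train1, t_start, t_end)
    s2 = _with_aux(train2, t_start, t_end)
    corners = np.unique(np.concatenate([s1, s2]))
    acc = 0.0
    for a, b in zip(corners[:-1], corners[1:]):
        width = b - a
        if width <= 0:
            continue
        acc += _pair_profile_at(0.5 * (a + b), s1, s2) * width
    return acc / (t_end - t_start)


def multivariate_spike_distance(
    trains: list[np.ndarray], t_start: float, t_end: float
) -> float:
    """Average pairwise SPIKE-distance over all train pairs."""
    m = len(trains)
    if m < 2:
        raise ValueError("need at least two spike trains")
    acc = 0.0
    n_pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            acc += bivariate_spike_distance(trains[i], trains[j], t_start, t_end)
            n_pairs += 1
    return acc / n_pairs
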