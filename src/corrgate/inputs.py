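"""Background and stimulus input generation.

Every neuron receives excitatory background activity as a Poisson event
train of rate ``nu0`` and synaptic strength ``j0``.  Spatial correlations of
level ``lam`` between the background trains of different neurons are induced
by a common-source construction: each neuron merges an independent Poisson
channel of rate ``(1 - lam) * nu0`` with a channel of rate ``lam * nu0``
shared (event-for-event, with no jitter) by all target neurons.  The merged
per-neuron rate is ``nu0`` for every ``lam``, and the pairwise
cross-covariance of two merged trains is a delta at zero lag with integral
``lam`` times the rate, so the integrated rate-normalized cross-covariance
equals ``lam`` exactly.

The estimator :func:`correlation_level_estimate` inverts that construction
from data: covariance of binned spike counts, summed over a lag window and
normalized by the mean count per bin.

Stimulus inputs are Poisson trains of rate ``nu1`` and strength ``j1``
confined to an epoch window, generated independently for every target
neuron (a sensory afferent volley; correlating the stimulus across targets
would confound the background-correlation manipulation).

All times are in ms and rates in Hz (events/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BackgroundConfig:
    """Background-input parameters for one population.

    ``lam`` is the baseline correlation level; time-varying values are set by
    the simulation schedule, which overrides this default.
    """

    nu0: float
    j0: float
    lam: float = 0.0
    n_targets: int = 1

    def __post_init__(self) -> None:
        if self.nu0 < 0:
            raise ValueError(f"nu0 must be non-negative, got {self.nu0}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if self.n_targets < 1:
            raise ValueError("n_targets must be at least 1")


@dataclass(frozen=True)
class StimulusEpoch:
    """A Poisson stimulus of rate ``nu1`` and strength ``j1`` on [t_on, t_off).

    With ``shared=True`` one event train drives every target neuron
    simultaneously (an afferent volley from a single source); by default each
    target receives an independent realization.
    """

    population: str
    t_on: float
    t_off: float
    nu1: float
    j1: float
    shared: bool = False

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError(
                f"t_on must precede t_off, got [{self.t_on}, {self.t_off})"
            )
        if self.nu1 < 0:
            raise ValueError(f"nu1 must be non-negative, got {self.nu1}")


@dataclass
class InputEnsemble:
    """Decomposed background event trains for a group of target neurons."""

    independent: list[np.ndarray]
    common: np.ndarray
    rate_independent: float
    rate_common: float
    duration: float

    def merged(self, i: int) -> np.ndarray:
        """Full background train (independent + common events) of neuron ``i``."""
        return np.sort(np.concatenate([self.independent[i], self.common]))


def poisson_train(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Sorted event times of a homogeneous Poisson process on [0, duration).

    ``rate`` is in Hz, ``duration`` in ms.
    """
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if not duration > 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def correlated_background(
    cfg: BackgroundConfig, duration: float, rng: np.random.Generator
) -> InputEnsemble:
    """Generate the common-source background ensemble for ``cfg.n_targets`` neurons.

    Each target's merged train has total rate ``cfg.nu0``; the shared channel
    carries the fraction ``cfg.lam`` of it.  ``lam = 0`` reduces exactly to
    independent Poisson trains; ``lam = 1`` makes all targets' trains
    identical.
    """
    rate_common = cfg.lam * cfg.nu0
    rate_indep = (1.0 - cfg.lam) * cfg.nu0
    common = poisson_train(rate_common, duration, rng)
    independent = [
        poisson_train(rate_indep, duration, rng) for _ in range(cfg.n_targets)
    ]
    return InputEnsemble(
        independent=independent,
        common=common,
        rate_independent=rate_indep,
        rate_common=rate_common,
        duration=duration,
    )


def correlation_level_estimate(
    train_i: np.ndarray,
    train_j: np.ndarray,
    duration: float,
    bin_width: float = 1.0,
    max_lag: float = 50.0,
) -> float:
    """Estimate the correlation level of two spike trains.

    Implements the integrated, rate-normalized cross-covariance: spike counts
    are binned at ``bin_width`` ms, the count covariance is estimated at every
    lag with ``|lag| <= max_lag`` ms, summed, and divided by the mean count
    per bin of ``train_i``.  For two trains built by the common-source
    construction the cross-covariance is a delta at zero lag, so the result is
    insensitive to the lag window; for independent Poisson trains it converges
    to 0, and for identical trains to 1, as the observation window grows.

    Raises
    ------
    ValueError
        If either train is empty (zero-rate trains make the normalization
        undefined).
    """
    train_i = np.asarray(train_i, dtype=float)
    train_j = np.asarray(train_j, dtype=float)
    if train_i.size == 0 or train_j.size == 0:
        raise ValueError("correlation level is undefined for an empty train")
    n_bins = int(np.floor(duration / bin_width))
    if n_bins < 2:
        raise ValueError("observation window too short for the chosen bin width")
    edges_i = np.minimum((train_i / bin_width).astype(np.int64), n_bins - 1)
    edges_j = np.minimum((train_j / bin_width).astype(np.int64), n_bins - 1)
    x = np.bincount(edges_i, minlength=n_bins).astype(float)
    y = np.bincount(edges_j, minlength=n_bins).astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    n_lags = int(round(max_lag / bin_width))
    total = 0.0
    for lag in range(-n_lags, n_lags + 1):
        if lag >= 0:
            total += float(np.dot(xc[: n_bins - lag], yc[lag:])) / (n_bins - lag)
        else:
            total += float(np.dot(xc[-lag:], yc[: n_bins + lag])) / (n_bins + lag)
    return total / x.mean()


def write_ensemble_tsv(ensemble: InputEnsemble, path) -> None:
    """Write a background ensemble as two-column TSV (channel_id, time_ms).

    Channel 0..n-1 are the per-neuron independent channels; channel -1 is
    the shared common channel.  A header line documents the layout.
    """
    with open(path, "w") as fh:
        fh.write("# corrgate input ensemble: channel_id\ttime_ms "
                 "(channel -1 = common source)\n")
        for t in ensemble.common:
            fh.write(f"-1\t{t:.6f}\n")
        for i, train in enumerate(ensemble.independent):
            for t in train:
                fh.write(f"{i}\t{t:.6f}\n")


def read_ensemble_tsv(path, duration: float) -> InputEnsemble:
    """Read an ensemble written by :func:`write_ensemble_tsv`."""
    channels: dict[int, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cid, t = line.split("\t")
            channels.setdefault(int(cid), []).append(float(t))
    common = np.sort(np.array(channels.pop(-1, []), dtype=float))
    n = max(channels, default=-1) + 1
    independent = [np.sort(np.array(channels.get(i, []), dtype=float))
                   for i in range(n)]
    dur_s = duration / 1000.0
    return InputEnsemble(
        independent=independent,
        common=common,
        rate_independent=(np.mean([t.size for t in independent]) / dur_s
                          if independent else 0.0),
        rate_common=common.size / dur_s,
        duration=duration,
    )


def stimulus_train(
    epoch: StimulusEpoch, n_targets: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Independent Poisson stimulus trains, one per target neuron.

    Events are restricted to ``[epoch.t_on, epoch.t_off)``.
    """
    window = epoch.t_off - epoch.t_on
    trains = []
    for _ in range(n_targets):
        trains.append(epoch.t_on + poisson_train(epoch.nu1, window, rng))
    return trains
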