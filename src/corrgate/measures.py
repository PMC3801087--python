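"""Trial classification, regime probabilities, timing, and synchrony measures.

All rate-based criteria operate on the 10-ms-binned population rate trace.
A window criterion such as "rate below 5 Hz during 400-500 ms" is evaluated,
by default, on the mean rate over the window (``mode="mean"``); the stricter
every-bin reading is available with ``mode="all_bins"`` for sensitivity
checks.

The two bistable-state transition probabilities are

* erasing probability P_e — an established persistent state (rate above
  5 Hz during 400-500 ms) has decayed below 5 Hz during 800-900 ms after the
  correlation level was raised; trials that never reached the persistent
  state are discarded from the estimate;
* blocking probability P_b — under a constant correlation level, the
  transient stimulus failed to ignite the persistent state (rate below 5 Hz
  during 400-500 ms).

From these, the regime probabilities are composed: gate-in
P_gi = (1-P_e)(1-P_b), selective-gate P_sg = (1-P_e) P_b, and gate-out
P_go = P_e P_b; the operating regime is named after the largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spike_distance import multivariate_spike_distance

RATE_THRESHOLD = 5.0  # Hz; boundary between quiescent and persistent state
PEAK_THRESHOLD = 20.0  # Hz; minimum height of a pre-termination rate peak

#: (load, protect, clear) measurement windows in ms, per network family
DMS_WINDOWS = {
    "wta": ((350.0, 450.0), (750.0, 850.0), (1150.0, 1250.0)),
    "two_unit": ((350.0, 450.0), (700.0, 800.0), (1050.0, 1150.0)),
}


def _window_stat(trace: np.ndarray, window: tuple[float, float],
                 bin_width: float) -> np.ndarray:
    lo = int(round(window[0] / bin_width))
    hi = int(round(window[1] / bin_width))
    if hi > trace.size:
        raise ValueError(
            f"trace of {trace.size} bins does not cover window {window}"
        )
    return trace[lo:hi]


def _below(trace, window, bin_width, mode):
    vals = _window_stat(trace, window, bin_width)
    if mode == "mean":
        return float(vals.mean()) < RATE_THRESHOLD
    if mode == "all_bins":
        return bool(np.all(vals < RATE_THRESHOLD))
    raise ValueError(f"unknown criterion mode {mode!r}")


@dataclass(frozen=True)
class TrialClassification:
    """Outcome flags of one trial; ``None`` marks a flag that was not assessed."""

    persistent_at_check: bool | None = None
    erased: bool | None = None
    blocked: bool | None = None


def classify_erasing_trial(
    rate_trace: np.ndarray,
    bin_width: float = 10.0,
    persist_window: tuple[float, float] = (400.0, 500.0),
    erase_window: tuple[float, float] = (800.0, 900.0),
    mode: str = "mean",
) -> TrialClassification:
    """Classify one erasing-protocol trial.

    The trial counts toward P_e only if the network was in the persistent
    state in the check window; ``erased`` is None on discarded trials.
    """
    persistent = not _below(rate_trace, persist_window, bin_width, mode)
    erased = _below(rate_trace, erase_window, bin_width, mode) if persistent else None
    return TrialClassification(persistent_at_check=persistent, erased=erased)


def classify_blocking_trial(
    rate_trace: np.ndarray,
    bin_width: float = 10.0,
    window: tuple[float, float] = (400.0, 500.0),
    mode: str = "mean",
) -> TrialClassification:
    """Classify one blocking-protocol trial (stimulus failed to ignite)."""
    return TrialClassification(blocked=_below(rate_trace, window, bin_width, mode))


@dataclass(frozen=True)
class RegimeProbabilities:
    """P_e and P_b with their binomial standard errors and derived regimes."""

    p_e: float
    p_b: float
    se_e: float
    se_b: float
    n_valid: int
    n_total: int

    @property
    def p_go(self) -> float:
        return self.p_e * self.p_b

    @property
    def p_gi(self) -> float:
        return (1.0 - self.p_e) * (1.0 - self.p_b)

    @property
    def p_sg(self) -> float:
        return (1.0 - self.p_e) * self.p_b

    @property
    def regime(self) -> str:
        probs = {"gate-in": self.p_gi, "selective-gate": self.p_sg,
                 "gate-out": self.p_go}
        return max(probs, key=probs.get)


def _binomial(successes: int, n: int) -> tuple[float, float]:
    p = successes / n
    return p, float(np.sqrt(p * (1.0 - p) / n))


def estimate_probabilities(trials: list[TrialClassification]) -> RegimeProbabilities:
    """Estimate P_e and P_b from a mixed list of classified trials.

    P_e is the fraction of erased trials among those persistent at check;
    P_b the fraction of blocked trials among those assessed for blocking.

    Raises
    ------
    ValueError
        If no trial is available for one of the probabilities.
    """
    valid = [t for t in trials if t.persistent_at_check]
    assessed_b = [t for t in trials if t.blocked is not None]
    if not valid and not assessed_b:
        raise ValueError("no classified trials")
    p_e = se_e = 0.0
    if valid:
        p_e, se_e = _binomial(sum(bool(t.erased) for t in valid), len(valid))
    elif any(t.persistent_at_check is not None for t in trials):
        raise ValueError("all erasing trials were discarded (none persistent)")
    p_b = se_b = 0.0
    if assessed_b:
        p_b, se_b = _binomial(sum(bool(t.blocked) for t in assessed_b),
                              len(assessed_b))
    return RegimeProbabilities(
        p_e=p_e, p_b=p_b, se_e=se_e, se_b=se_b,
        n_valid=len(valid), n_total=len(trials),
    )


@dataclass(frozen=True)
class TimingResult:
    """Termination timing of one erasing trial; None marks an absent event."""

    t_corr: float
    t_stop: float | None
    t_peak: float | None

    @property
    def dt_corr_peak(self) -> float | None:
        return None if self.t_peak is None else self.t_peak - self.t_corr

    @property
    def dt_peak_stop(self) -> float | None:
        if self.t_peak is None or self.t_stop is None:
            return None
        return self.t_stop - self.t_peak


def timing_analysis(
    rate_trace: np.ndarray, t_corr: float, bin_width: float = 10.0
) -> TimingResult:
    """Locate the termination time and the last preceding activity peak.

    ``t_stop`` is the start of the first bin at or after ``t_corr`` whose
    rate falls below 5 Hz; ``t_peak`` the start of the last bin before
    ``t_stop`` (and not before ``t_corr``) that is a local maximum in time
    and exceeds 20 Hz.  Plateau ties resolve to the later bin.  Absent events
    are encoded as ``None``, never raised.
    """
    f = np.asarray(rate_trace, dtype=float)
    ic = int(round(t_corr / bin_width))
    k_stop = None
    for k in range(ic, f.size):
        if f[k] < RATE_THRESHOLD:
            k_stop = k
            break
    if k_stop is None:
        return TimingResult(t_corr=t_corr, t_stop=None, t_peak=None)
    k_peak = None
    for j in range(ic, k_stop):
        if f[j] <= PEAK_THRESHOLD:
            continue
        left = f[j - 1] if j > 0 else -np.inf
        right = f[j + 1] if j + 1 < f.size else -np.inf
        # >= on the left neighbour resolves plateau ties to the later bin
        if f[j] >= left and f[j] > right:
            k_peak = j
    return TimingResult(
        t_corr=t_corr,
        t_stop=k_stop * bin_width,
        t_peak=None if k_peak is None else k_peak * bin_width,
    )


def running_mean_pearson(
    currents: np.ndarray,
    window: float = 5.0,
    interval: tuple[float, float] | None = None,
    bin_width: float = 1.0,
) -> float:
    """Mean pairwise Pearson correlation of smoothed per-neuron input traces.

    ``currents`` has shape (n_time_bins, n_neurons) at ``bin_width`` ms
    resolution (the decomposed current record of the simulator).  Each trace
    is smoothed with a ``window``-ms running mean over the requested interval
    and the Pearson coefficient is averaged over all neuron pairs.  Pairs
    involving a zero-variance trace are excluded from the average with a
    warning.
    """
    x = np.asarray(currents, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a (time, neurons) array with at least 2 neurons")
    if interval is not None:
        lo = int(round(interval[0] / bin_width))
        hi = int(round(interval[1] / bin_width))
        x = x[lo:hi]
    w = max(int(round(window / bin_width)), 1)
    if x.shape[0] < w + 1:
        raise ValueError("interval shorter than the smoothing window")
    kernel = np.ones(w) / w
    smooth = np.empty((x.shape[0] - w + 1, x.shape[1]))
    for i in range(x.shape[1]):
        smooth[:, i] = np.convolve(x[:, i], kernel, mode="valid")
    sd = smooth.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} zero-variance trace(s) "
            "from the Pearson average",
            stacklevel=2,
        )
    if np.count_nonzero(keep) < 2:
        raise ValueError("fewer than two non-constant traces in the interval")
    r = np.corrcoef(smooth[:, keep], rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def spike_synchrony(
    trains: list[np.ndarray], interval: tuple[float, float]
) -> float:
    """Spike synchrony 1 - S from the multivariate SPIKE-distance.

    1 means perfectly synchronous (identical) trains, 0 no synchrony.
    Every train must carry at least one spike in the interval.
    """
    t0, t1 = interval
    return 1.0 - multivariate_spike_distance(list(trains), t0, t1)


def dms_outcome(
    rate_b: np.ndarray,
    rate_r: np.ndarray,
    family: str = "wta",
    bin_width: float = 10.0,
    mode: str = "mean",
) -> dict[str, bool]:
    """Score the three DMS operations from the two populations' rate traces.

    load:    target population B active, R quiescent, before the distractor;
    protect: B still active and R quiescent, before the match (for the
             two-unit family this also reports the independent
             sub-operations ``maintain`` — B active — and ``block`` — R
             quiescent);
    clear:   both populations quiescent after the match.
    """
    if family not in DMS_WINDOWS:
        raise ValueError(f"unknown network family {family!r}")
    w_load, w_protect, w_clear = DMS_WINDOWS[family]

    def active(trace, win):
        return not _below(trace, win, bin_width, mode)

    b_load = active(rate_b, w_load)
    r_load = active(rate_r, w_load)
    b_prot = active(rate_b, w_protect)
    r_prot = active(rate_r, w_protect)
    b_clear = active(rate_b, w_clear)
    r_clear = active(rate_r, w_clear)
    out = {
        "load": b_load and not r_load,
        "protect": b_prot and not r_prot,
        "clear": (not b_clear) and (not r_clear),
    }
    if family == "two_unit":
        out["maintain"] = b_prot
        out["block"] = not r_prot
    return out
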