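"""Figure-level experiments: erasing/blocking sweeps, tuning curves, regime
maps, and the delayed match-to-sample (DMS) tasks.

Every experiment is a Monte-Carlo design over random connectivity matrices
and noise realizations, fully determined by a single integer seed: per-point
connectivity and trial seeds are derived with ``numpy.random.SeedSequence``
so re-runs reproduce tables bit-identically.  Trial counts default to a
desk-scale design (a handful of connectivity matrices times a few dozen
noise realizations per matrix); results carry binomial standard errors so
undersized designs are visible.

Conventions shared by the single-unit protocols: the stimulus is applied
during 50-100 ms at the network's default strength; the persistent-state
check window is 400-500 ms, the erasure window 800-900 ms; in the erasing
protocol the correlation level switches from 0 to the probed value at
500 ms (800 ms in the termination-timing study), while in the blocking
protocol it is constant from t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .inputs import StimulusEpoch
from .measures import (
    RegimeProbabilities,
    TrialClassification,
    classify_blocking_trial,
    classify_erasing_trial,
    dms_outcome,
    estimate_probabilities,
)
from .networks import Network, build_single_unit, build_two_unit, build_wta, scaled_j
from .simulate import Schedule, run_simulation

NetworkFactory = Callable[[np.random.Generator], Network]


@dataclass(frozen=True)
class MonteCarloDesign:
    """Trial design: connectivity realizations x noise realizations each."""

    n_connectivity: int = 5
    n_noise: int = 20

    @property
    def n_trials(self) -> int:
        return self.n_connectivity * self.n_noise


def _point_seeds(seed: int, tag: int, design: MonteCarloDesign) -> list[list[int]]:
    """Independent 31-bit seed blocks, one per connectivity realization.

    Block k holds the connectivity seed followed by the per-trial noise
    seeds, all derived from (seed, tag) so distinct grid points never share
    randomness.
    """
    ss = np.random.SeedSequence([int(seed), int(tag)])
    words = ss.generate_state(
        design.n_connectivity * (design.n_noise + 1), dtype=np.uint32
    )
    words = (words % (2 ** 31)).astype(np.int64)
    blocks = []
    for k in range(design.n_connectivity):
        lo = k * (design.n_noise + 1)
        blocks.append([int(w) for w in words[lo: lo + design.n_noise + 1]])
    return blocks


def _default_stimulus(network: Network, t_on: float, t_off: float,
                      population: str = "E",
                      nu1: float | None = None, j1: float | None = None
                      ) -> StimulusEpoch:
    return StimulusEpoch(
        population=population,
        t_on=t_on,
        t_off=t_off,
        nu1=network.stim_defaults["nu1"] if nu1 is None else nu1,
        j1=network.stim_defaults["j1"] if j1 is None else j1,
    )


def erasing_trials(
    lam: float,
    factory: NetworkFactory,
    *,
    design: MonteCarloDesign,
    seed: int,
    tag: int = 0,
    t_switch: float = 500.0,
    duration: float = 1000.0,
    dt: float = 0.1,
    stim_window: tuple[float, float] = (50.0, 100.0),
    nu1: float | None = None,
) -> list[TrialClassification]:
    """Run the erasing protocol: ignite at lam=0, raise lam at ``t_switch``."""
    trials = []
    for block in _point_seeds(seed, tag, design):
        net = factory(np.random.default_rng(block[0]))
        pop = net.populations[0].name
        schedule = Schedule(
            duration=duration,
            dt=dt,
            lam={pop: [(0.0, 0.0), (t_switch, lam)]},
            stimuli=[_default_stimulus(net, *stim_window, population=pop, nu1=nu1)],
        )
        for trial_seed in block[1:]:
            res = run_simulation(net, schedule, trial_seed)
            trials.append(classify_erasing_trial(res.rate(pop)))
    return trials


def blocking_trials(
    lam: float,
    factory: NetworkFactory,
    *,
    design: MonteCarloDesign,
    seed: int,
    tag: int = 0,
    duration: float = 500.0,
    dt: float = 0.1,
    stim_window: tuple[float, float] = (50.0, 100.0),
    nu1: float | None = None,
    j1: float | None = None,
) -> list[TrialClassification]:
    """Run the blocking protocol: lam constant from t = 0, stimulate, test."""
    trials = []
    for block in _point_seeds(seed, tag, design):
        net = factory(np.random.default_rng(block[0]))
        pop = net.populations[0].name
        schedule = Schedule(
            duration=duration,
            dt=dt,
            lam={pop: [(0.0, lam)]},
            stimuli=[_default_stimulus(net, *stim_window, population=pop,
                                       nu1=nu1, j1=j1)],
        )
        for trial_seed in block[1:]:
            res = run_simulation(net, schedule, trial_seed)
            trials.append(classify_blocking_trial(res.rate(pop)))
    return trials


def _single_unit_factory(**kwargs) -> NetworkFactory:
    return lambda rng: build_single_unit(rng, **kwargs)


def run_erasing_protocol(
    lams: Sequence[float],
    cs: Sequence[float] = (0.2,),
    *,
    n: int = 100,
    cjn: float | None = None,
    design: MonteCarloDesign = MonteCarloDesign(),
    seed: int = 0,
    t_switch: float = 500.0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Erasing probability P_e over a (lambda, c) grid for the single-unit net.

    With ``cjn`` given, J is rescaled per grid point to hold cJN fixed;
    otherwise the default J=0.26 is used.
    """
    rows = []
    tag = 0
    for c in cs:
        j = scaled_j(cjn, c, n) if cjn is not None else 0.26
        factory = _single_unit_factory(n=n, c=c, j=j)
        for lam in lams:
            tag += 1
            trials = erasing_trials(
                lam, factory, design=design, seed=seed, tag=tag,
                t_switch=t_switch, dt=dt,
            )
            probs = estimate_probabilities(trials)
            rows.append({
                "lambda": lam, "c": c, "N": n, "J": j,
                "P_e": probs.p_e, "SE": probs.se_e,
                "n_valid": probs.n_valid, "n_trials": probs.n_total,
            })
    return pd.DataFrame(rows)


def run_blocking_protocol(
    lams: Sequence[float],
    cs: Sequence[float] = (0.2,),
    *,
    n: int = 100,
    cjn: float | None = None,
    design: MonteCarloDesign = MonteCarloDesign(),
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Blocking probability P_b over a (lambda, c) grid for the single-unit net."""
    rows = []
    tag = 10_000
    for c in cs:
        j = scaled_j(cjn, c, n) if cjn is not None else 0.26
        factory = _single_unit_factory(n=n, c=c, j=j)
        for lam in lams:
            tag += 1
            trials = blocking_trials(
                lam, factory, design=design, seed=seed, tag=tag, dt=dt,
            )
            probs = estimate_probabilities(trials)
            rows.append({
                "lambda": lam, "c": c, "N": n, "J": j,
                "P_b": probs.p_b, "SE": probs.se_b, "n_trials": probs.n_total,
            })
    return pd.DataFrame(rows)


def loading_curve(
    nu1_values: Sequence[float],
    lams: Sequence[float] = (0.4,),
    js: Sequence[float] = (0.26,),
    *,
    n: int = 100,
    c: float = 0.2,
    design: MonteCarloDesign = MonteCarloDesign(),
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Loading probability (1 - P_b) versus stimulus rate nu1.

    Swept for each combination of correlation level and recurrent strength
    to probe whether the stimulus tuning shifts with lambda or J.
    """
    rows = []
    tag = 20_000
    for lam in lams:
        for j in js:
            factory = _single_unit_factory(n=n, c=c, j=j)
            for nu1 in nu1_values:
                tag += 1
                trials = blocking_trials(
                    lam, factory, design=design, seed=seed, tag=tag,
                    dt=dt, nu1=nu1,
                )
                probs = estimate_probabilities(trials)
                rows.append({
                    "nu1": nu1, "lambda": lam, "J": j, "N": n, "c": c,
                    "P_load": 1.0 - probs.p_b, "SE": probs.se_b,
                    "n_trials": probs.n_total,
                })
    return pd.DataFrame(rows)


def termination_timing_study(
    lam: float,
    *,
    design: MonteCarloDesign = MonteCarloDesign(n_connectivity=2, n_noise=20),
    seed: int = 0,
    t_corr: float = 800.0,
    duration: float = 1400.0,
    dt: float = 0.1,
    n_synchrony_neurons: int = 30,
    network_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Termination timing plus input-correlation and synchrony measures.

    Ignites the single-unit network at lambda=0, raises the correlation level
    to ``lam`` at ``t_corr``, and for every trial that was persistent at the
    onset locates the termination time and the last preceding activity peak.
    For trials whose peak falls at least 100 ms after the onset, the mean
    pairwise Pearson correlation of the smoothed background and recurrent
    inputs is measured in the 100 ms before the onset (uncorrelated epoch)
    and the 100 ms before the peak (correlated epoch), together with the
    spike synchrony 1 - S of ``n_synchrony_neurons`` representative neurons
    in the same windows.
    """
    from .measures import (
        classify_erasing_trial,
        running_mean_pearson,
        spike_synchrony,
        timing_analysis,
    )

    factory = _single_unit_factory(**(network_kwargs or {}))
    rows = []
    for block in _point_seeds(seed, 80_000 + int(lam * 1000), design):
        net = factory(np.random.default_rng(block[0]))
        pop = net.populations[0].name
        n_neurons = net.populations[0].size
        schedule = Schedule(
            duration=duration,
            dt=dt,
            lam={pop: [(0.0, 0.0), (t_corr, lam)]},
            stimuli=[_default_stimulus(net, 50.0, 100.0, population=pop)],
        )
        for trial_seed in block[1:]:
            res = run_simulation(net, schedule, trial_seed, record_currents=True)
            trace = res.rate(pop)
            persistent = classify_erasing_trial(
                trace, erase_window=(duration - 100.0, duration)
            ).persistent_at_check
            if not persistent:
                continue
            timing = timing_analysis(trace, t_corr)
            row = {
                "lambda": lam, "seed": trial_seed,
                "t_stop": timing.t_stop, "t_peak": timing.t_peak,
                "dt_corr_peak": timing.dt_corr_peak,
                "dt_peak_stop": timing.dt_peak_stop,
            }
            if timing.t_peak is not None and timing.dt_corr_peak >= 100.0:
                pre = (t_corr - 100.0, t_corr)
                corr = (timing.t_peak - 100.0, timing.t_peak)
                for kind, label in (("background", "bg"), ("recurrent", "rec")):
                    cur = res.currents[kind]
                    row[f"rho_{label}_pre"] = running_mean_pearson(cur, interval=pre)
                    row[f"rho_{label}_corr"] = running_mean_pearson(cur, interval=corr)
                times, ids = res.raster_for(pop)
                step = max(1, n_neurons // n_synchrony_neurons)
                subset = range(0, n_neurons, step)
                trains = [times[ids == i] for i in subset]
                try:
                    row["sync_pre"] = spike_synchrony(
                        [t for t in trains if t[(t >= pre[0]) & (t <= pre[1])].size],
                        pre,
                    )
                    row["sync_corr"] = spike_synchrony(
                        [t for t in trains if t[(t >= corr[0]) & (t <= corr[1])].size],
                        corr,
                    )
                except ValueError:
                    pass  # too few active trains in a window
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regime map


def regime_map(
    lams: Sequence[float],
    *,
    n: int = 1000,
    c: float = 0.2,
    cjn: float = 5.2,
    design: MonteCarloDesign = MonteCarloDesign(),
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Regime probabilities P_gi, P_sg, P_go over a lambda grid.

    Runs both the erasing and the blocking protocol at every lambda for a
    single excitatory population of size ``n`` with J scaled to keep cJN
    fixed, then composes the joint regime probabilities.
    """
    j = scaled_j(cjn, c, n)
    factory = _single_unit_factory(n=n, c=c, j=j)
    rows = []
    for idx, lam in enumerate(sorted(lams)):
        e_trials = erasing_trials(
            lam, factory, design=design, seed=seed, tag=30_000 + idx, dt=dt,
        )
        b_trials = blocking_trials(
            lam, factory, design=design, seed=seed, tag=40_000 + idx, dt=dt,
        )
        if not any(t.persistent_at_check for t in e_trials):
            # no trial ignited at this grid point: P_e is unobservable here;
            # score it from the blocking trials alone and flag with n_valid=0
            probs = estimate_probabilities(b_trials)
        else:
            probs = estimate_probabilities(e_trials + b_trials)
        rows.append({
            "lambda": lam,
            "P_e": probs.p_e, "SE_e": probs.se_e, "n_valid": probs.n_valid,
            "P_b": probs.p_b, "SE_b": probs.se_b, "n_trials": len(b_trials),
            "P_gi": probs.p_gi, "P_sg": probs.p_sg, "P_go": probs.p_go,
            "regime": probs.regime,
        })
    return pd.DataFrame(rows)


def _downcrossings(x: np.ndarray, margin: np.ndarray) -> list[float]:
    """Linearly interpolated roots where ``margin`` crosses from > 0 to <= 0."""
    roots = []
    for i in range(len(x) - 1):
        a, b = margin[i], margin[i + 1]
        if a > 0 >= b:
            roots.append(float(x[i] + (x[i + 1] - x[i]) * a / (a - b)))
    return roots


def _parabolic_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Argmax refined by a parabola through the top grid point and neighbours."""
    k = int(np.argmax(y))
    if k == 0 or k == len(x) - 1:
        return float(x[k])
    x0, x1, x2 = x[k - 1: k + 2]
    y0, y1, y2 = y[k - 1: k + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:  # degenerate / flat: keep the grid point
        return float(x[k])
    # uniform-grid vertex formula generalized to (possibly) uneven spacing
    a = (y2 - y0) / ((x2 - x0))
    b = ((y2 - y1) / (x2 - x1) - (y1 - y0) / (x1 - x0)) / (x2 - x0) * 2
    return float(x1 - a / b)


def regime_boundaries(table: pd.DataFrame) -> dict[str, float | None]:
    """Regime crossover points from a regime-map table.

    Returns the lambda where the gate-in probability stops dominating
    (``gate_in_end``), where the selective-gate probability stops dominating
    (``selective_gate_end``), and the interpolated argmax of P_sg
    (``p_sg_max``).  Crossings outside the grid come back as None.
    """
    df = table.sort_values("lambda")
    lam = df["lambda"].to_numpy(float)
    p_gi = df["P_gi"].to_numpy(float)
    p_sg = df["P_sg"].to_numpy(float)
    p_go = df["P_go"].to_numpy(float)
    gi_margin = p_gi - np.maximum(p_sg, p_go)
    sg_margin = p_sg - np.maximum(p_gi, p_go)
    gi_roots = _downcrossings(lam, gi_margin)
    sg_roots = _downcrossings(lam, sg_margin)
    return {
        "gate_in_end": gi_roots[0] if gi_roots else None,
        "selective_gate_end": sg_roots[-1] if sg_roots else None,
        "p_sg_max": _parabolic_argmax(lam, p_sg),
    }


# ---------------------------------------------------------------------------
# delayed match-to-sample tasks

#: stimulus windows (sample to B, distractor to R, match to B) in ms
WTA_STIMULI = ((50.0, 150.0), (450.0, 550.0), (850.0, 950.0))
TWO_UNIT_STIMULI = ((100.0, 150.0), (450.0, 500.0), (800.0, 850.0))


def dms_wta_trial(
    nu1: float,
    *,
    correlated: bool,
    seed: int,
    conn_seed: int,
    lam_high: float = 0.9,
    dt: float = 0.1,
    duration: float = 1300.0,
) -> dict[str, bool]:
    """One winner-take-all DMS trial.

    All three stimuli share the same strength ``nu1``.  In the correlated
    arm the background of the distractor population R becomes correlated
    (lambda -> lam_high) right after the sample has been loaded (150 ms) and
    that of B after the match (950 ms); the uncorrelated arm keeps lambda=0
    throughout, so protection relies on mutual inhibition only.
    """
    net = build_wta(np.random.default_rng(conn_seed))
    j1 = net.stim_defaults["j1"]
    (s_on, s_off), (d_on, d_off), (m_on, m_off) = WTA_STIMULI
    stimuli = [
        StimulusEpoch("B", s_on, s_off, nu1, j1),
        StimulusEpoch("R", d_on, d_off, nu1, j1),
        StimulusEpoch("B", m_on, m_off, nu1, j1),
    ]
    if correlated:
        lam = {"R": [(0.0, 0.0), (s_off, lam_high)],
               "B": [(0.0, 0.0), (m_off, lam_high)]}
    else:
        lam = {}
    schedule = Schedule(duration=duration, dt=dt, lam=lam, stimuli=stimuli)
    res = run_simulation(net, schedule, seed)
    return dms_outcome(res.rate("B"), res.rate("R"), family="wta")


def run_dms_wta(
    nu1_values: Sequence[float],
    *,
    correlated: bool = True,
    design: MonteCarloDesign = MonteCarloDesign(),
    seed: int = 0,
    lam_high: float = 0.9,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Success rates of load/protect/clear versus stimulus strength."""
    rows = []
    for idx, nu1 in enumerate(nu1_values):
        counts = {"load": 0, "protect": 0, "clear": 0, "load_and_protect": 0}
        n_tot = 0
        tag = (50_000 if correlated else 60_000) + idx
        for block in _point_seeds(seed, tag, design):
            for trial_seed in block[1:]:
                out = dms_wta_trial(
                    nu1, correlated=correlated, seed=trial_seed,
                    conn_seed=block[0], lam_high=lam_high, dt=dt,
                )
                for op in ("load", "protect", "clear"):
                    counts[op] += out[op]
                counts["load_and_protect"] += out["load"] and out["protect"]
                n_tot += 1
        row = {"nu1": nu1, "correlated": correlated, "n_trials": n_tot}
        for op, cnt in counts.items():
            row[op] = cnt / n_tot
        rows.append(row)
    return pd.DataFrame(rows)


def dms_two_unit_trial(
    *,
    seed: int,
    conn_seed: int,
    lam_sg: float = 0.07,
    t_sg: float = 300.0,
    nu1: float | None = None,
    dt: float = 0.1,
    duration: float = 1200.0,
) -> dict[str, bool]:
    """One two-unit DMS trial with time-modulated global correlations.

    The network starts in the gate-in regime (lambda=0); from ``t_sg`` the
    shared noise source switches it to the selective-gate regime
    (lambda=``lam_sg``).  The match stimulus both reads out and erases the
    memory: it transiently drives B, whose persistent state then collapses
    under the correlated background.
    """
    net = build_two_unit(np.random.default_rng(conn_seed))
    j1 = net.stim_defaults["j1"]
    nu1 = net.stim_defaults["nu1"] if nu1 is None else nu1
    (s_on, s_off), (d_on, d_off), (m_on, m_off) = TWO_UNIT_STIMULI
    stimuli = [
        StimulusEpoch("B", s_on, s_off, nu1, j1),
        StimulusEpoch("R", d_on, d_off, nu1, j1),
        StimulusEpoch("B", m_on, m_off, nu1, j1),
    ]
    lam_sched = [(0.0, 0.0), (t_sg, lam_sg)]
    schedule = Schedule(
        duration=duration, dt=dt,
        lam={"B": lam_sched, "R": lam_sched},
        stimuli=stimuli,
    )
    res = run_simulation(net, schedule, seed)
    return dms_outcome(res.rate("B"), res.rate("R"), family="two_unit")


def run_dms_two_unit(
    *,
    design: MonteCarloDesign = MonteCarloDesign(n_connectivity=2, n_noise=15),
    seed: int = 0,
    lam_sg: float = 0.07,
    nu1: float | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Success rates of load/maintain/block/clear for the two-unit DMS task."""
    ops = {"load": 0, "maintain": 0, "block": 0, "clear": 0}
    n_tot = 0
    for block in _point_seeds(seed, 70_000, design):
        for trial_seed in block[1:]:
            out = dms_two_unit_trial(
                seed=trial_seed, conn_seed=block[0], lam_sg=lam_sg,
                nu1=nu1, dt=dt,
            )
            for op in ops:
                ops[op] += out[op]
            n_tot += 1
    rows = [{"operation": op, "success_rate": cnt / n_tot, "n_trials": n_tot}
            for op, cnt in ops.items()]
    return pd.DataFrame(rows)
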