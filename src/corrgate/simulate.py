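"""Euler simulation of QIF networks under scheduled background correlations.

The integration is plain explicit Euler with step ``dt`` (0.1 ms by
default).  Within each step the deterministic QIF update is applied together
with the summed weight of all synaptic events falling in that step; a neuron
crossing threshold is reset and its spike is delivered to its targets in the
*next* step (one-step synaptic delay, preserving explicit-Euler causality).

Background events are generated on the fly.  Per population and step, the
independent channels are pooled: a single Poisson count with mean
``N (1 - lam(t)) nu0 dt`` is drawn and the events are assigned to uniformly
random neurons of the population — by the superposition property this is
statistically identical to N independent per-neuron channels.  Each common
group draws one Poisson count with mean ``lam(t) nu0 dt`` and delivers every
event simultaneously to all member neurons.  The correlation level is a
piecewise-constant function of time per population; a schedule switch simply
re-partitions the channel rates at the step boundary.

Optionally the delivered synaptic weight is recorded per neuron in 1-ms bins,
decomposed into recurrent, background, and stimulus components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .inputs import StimulusEpoch
from .networks import Network

#: sentinel returned by the kernel on numerical blow-up
_ERR_NONFINITE = -1


@dataclass(frozen=True)
class Schedule:
    """Stimulus epochs plus a piecewise-constant correlation level per population.

    ``lam`` maps a population name to a sequence of ``(t_start, value)``
    pairs sorted in time; the value holds from its start time until the next
    entry.  Populations absent from the mapping use the baseline ``lam`` of
    their background config (0 for an uncorrelated background).  Populations
    sharing a common group must be given identical schedules.
    """

    duration: float
    dt: float = 0.1
    lam: Mapping[str, Sequence[tuple[float, float]]] = field(default_factory=dict)
    stimuli: Sequence[StimulusEpoch] = ()

    def __post_init__(self) -> None:
        if not self.duration > 0 or not self.dt > 0:
            raise ValueError("duration and dt must be positive")
        for name, pieces in self.lam.items():
            times = [t for t, _ in pieces]
            if sorted(times) != list(times):
                raise ValueError(f"lam schedule for {name!r} is not time-sorted")
            for _, v in pieces:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"lam values must lie in [0, 1], got {v}")
        for ep in self.stimuli:
            if ep.t_on < 0 or ep.t_off > self.duration:
                raise ValueError(
                    f"stimulus epoch [{ep.t_on}, {ep.t_off}) outside "
                    f"[0, {self.duration})"
                )


@dataclass
class SimulationResult:
    """Spike raster plus optional decomposed current traces.

    ``spike_neurons`` holds global neuron ids, ``spike_times`` the matching
    times in ms (a spike detected during a step is stamped at the end of the
    step).  ``currents`` (if recorded) maps ``{"recurrent", "background",
    "stimulus"}`` to float32 arrays of shape (n_ms_bins, n_neurons) holding
    the summed delivered weight per 1-ms bin.
    """

    spike_neurons: np.ndarray
    spike_times: np.ndarray
    network: Network
    schedule: Schedule
    seed: int
    currents: dict[str, np.ndarray] | None = None

    def raster_for(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, local neuron ids) of one population's spikes."""
        sl = self.network.pop_slice(name)
        mask = (self.spike_neurons >= sl.start) & (self.spike_neurons < sl.stop)
        return self.spike_times[mask], self.spike_neurons[mask] - sl.start

    def rate(self, name: str, bin_width: float = 10.0) -> np.ndarray:
        """Population firing-rate trace in Hz (10-ms bins by default)."""
        times, _ = self.raster_for(name)
        return population_rate(
            times, self.network.population(name).size, self.schedule.duration,
            bin_width,
        )


def population_rate(
    spike_times: np.ndarray, n_neurons: int, duration: float, bin_width: float = 10.0
) -> np.ndarray:
    """Mean population firing rate per time bin.

    ``f(t_k) = count in [t_k, t_k + bin) / (N * bin)`` converted to Hz.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(duration / bin_width))
    counts = np.zeros(n_bins)
    if len(spike_times):
        idx = np.minimum((np.asarray(spike_times) / bin_width).astype(np.int64),
                         n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts / (n_neurons * bin_width / 1000.0)


@njit(cache=True)
def _euler_kernel(
    seed, n_steps, dt,
    tau, b2, v_t, v_r, v,
    pop_start, pop_end, j0_pop, group_of_pop,
    indep_mean, common_mean,
    stim_pop, stim_on, stim_off, stim_pool_mean, stim_w, stim_shared,
    out_ptr, out_idx, out_w, out_d, max_delay_steps,
    record, cur_rec, cur_bg, cur_st,
    spk_neuron, spk_step,
):  # pragma: no cover - exercised through run_simulation
    np.random.seed(seed)
    n = v.shape[0]
    n_pops = pop_start.shape[0]
    n_groups = common_mean.shape[0]
    n_epochs = stim_pop.shape[0]
    # ring buffer of pending recurrent deliveries, one row per delay step
    pending = np.zeros((max_delay_steps, n))
    bg = np.zeros(n)
    st = np.zeros(n)
    spiking = np.empty(n, np.int64)
    cap = spk_neuron.shape[0]
    nspk = 0
    for step in range(n_steps):
        for i in range(n):
            bg[i] = 0.0
            st[i] = 0.0
        # independent background channels, pooled per population
        for p in range(n_pops):
            m = indep_mean[p, step]
            if m > 0.0:
                k = np.random.poisson(m)
                size = pop_end[p] - pop_start[p]
                for _ in range(k):
                    i = pop_start[p] + np.random.randint(0, size)
                    bg[i] += j0_pop[p]
        # common channels: every event hits all members of the group
        for g in range(n_groups):
            m = common_mean[g, step]
            if m > 0.0:
                k = np.random.poisson(m)
                if k > 0:
                    for p in range(n_pops):
                        if group_of_pop[p] == g:
                            w = k * j0_pop[p]
                            for i in range(pop_start[p], pop_end[p]):
                                bg[i] += w
        # stimuli: pooled assignment for independent trains, broadcast for shared
        for e in range(n_epochs):
            if stim_on[e] <= step < stim_off[e]:
                k = np.random.poisson(stim_pool_mean[e])
                p = stim_pop[e]
                if stim_shared[e]:
                    if k > 0:
                        w = k * stim_w[e]
                        for i in range(pop_start[p], pop_end[p]):
                            st[i] += w
                else:
                    size = pop_end[p] - pop_start[p]
                    for _ in range(k):
                        i = pop_start[p] + np.random.randint(0, size)
                        st[i] += stim_w[e]
        # Euler update + threshold/reset
        row = step % max_delay_steps
        n_new = 0
        for i in range(n):
            vi = v[i]
            vi = vi + (dt / tau[i]) * (vi * vi - b2[i]) + pending[row, i] + bg[i] + st[i]
            if vi >= v_t[i]:
                vi = v_r[i]
                if nspk < cap:
                    spk_neuron[nspk] = i
                    spk_step[nspk] = step
                nspk += 1
                spiking[n_new] = i
                n_new += 1
            v[i] = vi
        if record:
            mb = int(step * dt)
            for i in range(n):
                cur_bg[mb, i] += bg[i]
                cur_st[mb, i] += st[i]
                cur_rec[mb, i] += pending[row, i]
        # recurrent delivery after each edge's delay (ring-buffer row per step)
        for i in range(n):
            pending[row, i] = 0.0  # freed slot now represents step + max_delay
        for s_idx in range(n_new):
            s = spiking[s_idx]
            for q in range(out_ptr[s], out_ptr[s + 1]):
                pending[(step + out_d[q]) % max_delay_steps, out_idx[q]] += out_w[q]
        if step % 256 == 0:
            ok = True
            for i in range(n):
                if not np.isfinite(v[i]):
                    ok = False
            if not ok:
                return _ERR_NONFINITE - step
    return nspk


def _lambda_per_step(network: Network, schedule: Schedule, n_steps: int) -> np.ndarray:
    """Per-population lambda value for every step, from the piecewise schedule."""
    n_pops = len(network.populations)
    lam = np.zeros((n_pops, n_steps))
    t_start = np.arange(n_steps) * schedule.dt
    for p_idx, pop in enumerate(network.populations):
        if pop.background is None:
            continue
        pieces = list(schedule.lam.get(pop.name, ()))
        if not pieces:
            pieces = [(0.0, pop.background.lam)]
        if pieces[0][0] > 0.0:
            pieces = [(0.0, pop.background.lam)] + pieces
        times = np.array([t for t, _ in pieces])
        values = np.array([v for _, v in pieces])
        lam[p_idx] = values[np.searchsorted(times, t_start, side="right") - 1]
    return lam


def _check_shared_groups(network: Network, lam_steps: np.ndarray) -> None:
    groups: dict[int, int] = {}
    for p_idx, pop in enumerate(network.populations):
        g = pop.common_group
        if g is None or pop.background is None:
            continue
        if g in groups:
            ref = groups[g]
            if not np.array_equal(lam_steps[ref], lam_steps[p_idx]):
                raise ValueError(
                    "populations sharing a common background group must have "
                    "identical lambda schedules"
                )
            ref_pop = network.populations[ref]
            if ref_pop.background.nu0 != pop.background.nu0:
                raise ValueError(
                    "populations sharing a common background group must have "
                    "the same background rate"
                )
        else:
            groups[g] = p_idx


def run_simulation(
    network: Network,
    schedule: Schedule,
    seed: int,
    *,
    record_currents: bool = False,
    init: str | np.ndarray = "uniform",
    recurrent_delay: float | tuple[float, float] | None = None,
    tau_jitter: float = 0.0,
) -> SimulationResult:
    """Simulate the network under the given schedule.

    Identical ``(network, schedule, seed)`` triples give bit-identical
    rasters.  ``init`` chooses the initial membrane potentials: ``"uniform"``
    draws each v(0) uniformly in [-b, b] (near-rest, unbiased between the
    two attractors), ``"rest"`` sets every neuron exactly to -b, or an
    explicit array may be given.

    Raises
    ------
    RuntimeError
        On numerical blow-up (with the failing step index) or spike-buffer
        overflow.
    """
    dt = schedule.dt
    n_steps = int(round(schedule.duration / dt))
    n = network.n_neurons
    n_pops = len(network.populations)

    tau = np.empty(n)
    b2 = np.empty(n)
    v_t = np.empty(n)
    v_r = np.empty(n)
    pop_start = np.empty(n_pops, np.int64)
    pop_end = np.empty(n_pops, np.int64)
    j0_pop = np.zeros(n_pops)
    group_ids = sorted(
        {p.common_group for p in network.populations
         if p.common_group is not None and p.background is not None}
    )
    group_index = {g: i for i, g in enumerate(group_ids)}
    group_of_pop = np.full(n_pops, -1, np.int64)
    for p_idx, pop in enumerate(network.populations):
        sl = network.pop_slice(pop.name)
        pop_start[p_idx], pop_end[p_idx] = sl.start, sl.stop
        tau[sl] = pop.neuron.tau
        b2[sl] = pop.neuron.b ** 2
        v_t[sl] = pop.neuron.v_t
        v_r[sl] = pop.neuron.v_r
        if pop.background is not None:
            j0_pop[p_idx] = pop.background.j0
            if pop.common_group is not None:
                group_of_pop[p_idx] = group_index[pop.common_group]

    lam_steps = _lambda_per_step(network, schedule, n_steps)
    _check_shared_groups(network, lam_steps)

    indep_mean = np.zeros((n_pops, n_steps))
    n_groups = max(len(group_ids), 1)
    common_mean = np.zeros((n_groups, n_steps))
    group_done = set()
    for p_idx, pop in enumerate(network.populations):
        if pop.background is None:
            continue
        per_event = pop.background.nu0 * dt / 1000.0
        indep_mean[p_idx] = pop.size * (1.0 - lam_steps[p_idx]) * per_event
        g = group_of_pop[p_idx]
        if g >= 0 and g not in group_done:
            common_mean[g] = lam_steps[p_idx] * per_event
            group_done.add(g)

    pop_index = {p.name: i for i, p in enumerate(network.populations)}
    n_epochs = len(schedule.stimuli)
    stim_pop = np.zeros(n_epochs, np.int64)
    stim_on = np.zeros(n_epochs, np.int64)
    stim_off = np.zeros(n_epochs, np.int64)
    stim_pool_mean = np.zeros(n_epochs)
    stim_w = np.zeros(n_epochs)
    stim_shared = np.zeros(n_epochs, np.bool_)
    for e, ep in enumerate(schedule.stimuli):
        p_idx = pop_index[ep.population]
        stim_pop[e] = p_idx
        stim_on[e] = int(round(ep.t_on / dt))
        stim_off[e] = int(round(ep.t_off / dt))
        n_pool = 1 if ep.shared else network.populations[p_idx].size
        stim_pool_mean[e] = n_pool * ep.nu1 * dt / 1000.0
        stim_w[e] = ep.j1
        stim_shared[e] = ep.shared

    # out-adjacency in CSR form over global neuron ids
    degree = np.zeros(n, np.int64)
    for proj in network.projections:
        src_off = network.pop_slice(proj.source).start
        counts = np.bincount(proj.adjacency.ravel(),
                             minlength=network.population(proj.source).size)
        degree[src_off:src_off + counts.size] += counts
    out_ptr = np.zeros(n + 1, np.int64)
    np.cumsum(degree, out=out_ptr[1:])
    out_idx = np.empty(out_ptr[-1], np.int64)
    out_w = np.empty(out_ptr[-1])
    fill = out_ptr[:-1].copy()
    for proj in network.projections:
        src_off = network.pop_slice(proj.source).start
        tgt_off = network.pop_slice(proj.target).start
        adj = proj.adjacency
        for t_local in range(adj.shape[0]):
            tgt = tgt_off + t_local
            for s_local in adj[t_local]:
                s = src_off + s_local
                out_idx[fill[s]] = tgt
                out_w[fill[s]] = proj.j
                fill[s] += 1

    if tau_jitter > 0.0:
        jit_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0x7A11]).generate_state(1)
        )
        tau = tau * (1.0 + tau_jitter * jit_rng.standard_normal(n))

    rng = np.random.default_rng(seed)
    if isinstance(init, str):
        if init == "uniform":
            b_arr = np.sqrt(b2)
            v0 = rng.uniform(-b_arr, b_arr)
        elif init == "rest":
            v0 = -np.sqrt(b2)
        else:
            raise ValueError(f"unknown init mode {init!r}")
    else:
        v0 = np.array(init, dtype=float)
        if v0.shape != (n,):
            raise ValueError("init array must have one entry per neuron")

    n_ms = int(np.ceil(n_steps * dt)) + 1
    if record_currents:
        cur_rec = np.zeros((n_ms, n), np.float32)
        cur_bg = np.zeros((n_ms, n), np.float32)
        cur_st = np.zeros((n_ms, n), np.float32)
    else:
        cur_rec = cur_bg = cur_st = np.zeros((1, 1), np.float32)

    # per-edge conduction delays in Euler steps (minimum one step for causality)
    delay_rng = np.random.default_rng(
        np.random.SeedSequence([seed, 0xD31A]).generate_state(1)
    )
    if recurrent_delay is None:
        out_d = np.ones(out_ptr[-1], np.int64)
    elif np.isscalar(recurrent_delay):
        out_d = np.full(out_ptr[-1],
                        max(1, int(round(recurrent_delay / dt))), np.int64)
    else:
        lo, hi = recurrent_delay
        draws = delay_rng.uniform(lo, hi, size=out_ptr[-1])
        out_d = np.maximum(1, np.rint(draws / dt)).astype(np.int64)
    max_delay_steps = int(out_d.max())

    cap = int(n * n_steps * dt / 1000.0 * 500.0) + 10_000  # generous: 500 Hz mean
    spk_neuron = np.empty(cap, np.int64)
    spk_step = np.empty(cap, np.int64)

    kernel_seed = int(np.random.SeedSequence(seed).generate_state(1)[0])
    nspk = _euler_kernel(
        kernel_seed, n_steps, dt,
        tau, b2, v_t, v_r, v0.copy(),
        pop_start, pop_end, j0_pop, group_of_pop,
        indep_mean, common_mean,
        stim_pop, stim_on, stim_off, stim_pool_mean, stim_w, stim_shared,
        out_ptr, out_idx, out_w, out_d, max_delay_steps,
        record_currents, cur_rec, cur_bg, cur_st,
        spk_neuron, spk_step,
    )
    if nspk < 0:
        step = _ERR_NONFINITE - nspk
        raise RuntimeError(
            f"non-finite membrane potential detected near step {step} "
            f"(t ~ {step * dt:.1f} ms); check parameters"
        )
    if nspk > cap:
        raise RuntimeError("spike buffer overflow; network firing is pathological")

    currents = None
    if record_currents:
        currents = {"recurrent": cur_rec, "background": cur_bg, "stimulus": cur_st}
    return SimulationResult(
        spike_neurons=spk_neuron[:nspk].copy(),
        spike_times=(spk_step[:nspk] + 1) * dt,
        network=network,
        schedule=schedule,
        seed=seed,
        currents=currents,
    )
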