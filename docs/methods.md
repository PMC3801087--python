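# Methods

## Model

`corrgate` simulates recurrent networks of quadratic integrate-and-fire
(QIF) neurons,

    tau dv/dt = v^2 - b^2 + I_syn(t),        v -> V_r  when  v >= V_t,

with dimensionless voltage, stable rest at `-b`, spike-initiation threshold
at `+b`, and deep reset (`V_r = -20`, `V_t = 20`, `b = 1`, `tau = 20` ms by
default).  The deep reset provides effective refractoriness; no explicit
refractory period is modelled.  All synapses are instantaneous delta
pulses: a presynaptic event of strength `J` increments the target voltage
by exactly `J` inside the Euler step in which it arrives.  The synaptic
input decomposes into recurrent, stimulus, and background components, and
the simulator can record each component per neuron in 1-ms bins.

Background input to every neuron is an excitatory Poisson train of rate
`nu0` and strength `J0`.  Its spatial correlation level `lam` is set by a
common-source construction: each neuron merges a private channel of rate
`(1 - lam) nu0` with a channel of rate `lam nu0` shared event-for-event by
all neurons of its group.  The merged per-neuron rate is `nu0` for every
`lam`, and the integrated rate-normalized cross-covariance of two merged
trains equals `lam` exactly, which is what `correlation_level_estimate`
measures from data (1-ms count bins, lags up to ±50 ms; the construction's
cross-covariance is a delta at zero lag, so the result is insensitive to
the lag window).

Three architectures are built with fixed in-degree random connectivity
(every target draws exactly `round(c N_source)` distinct partners, no
autapses): the single-unit network (N=100, c=0.2, J=0.26, J0=0.151,
nu0=106 Hz), a winner-take-all circuit (two excitatory populations of 40
neurons competing through 20 inhibitory neurons, with per-population common
noise sources), and a two-unit network (two unconnected populations of
N=1000, J=0.026, sharing one common noise source).  The single-unit
defaults give mean recurrent drive cJN = 5.2, for which a quiescent state
(< 5 Hz) and a persistent state (~20 Hz, the self-consistent rate of
f = F(I_bg + tau c J N f / 1000)) coexist.

## Numerics

Plain explicit Euler with `dt = 0.1` ms.  Events falling within a step are
summed into one increment; threshold is tested after the full update, the
reset discards any overshoot, and the spike is stamped at the end of the
step.  Recurrent spikes are delivered with a one-step delay (0.1 ms),
preserving explicit-Euler causality.  Per-neuron independent Poisson
channels are realized by drawing one pooled count per population per step
and assigning events to uniform random neurons, which is statistically
identical by the superposition property and dominates the speedup of the
compiled (numba) kernel.  Correlation-level switches take effect at the
step boundary by re-partitioning the channel rates.  Initial voltages are
drawn uniformly in `[-b, b]` (near rest, unbiased between attractors)
unless overridden.  Halving `dt` changes the transition-probability
estimates by less than their Monte-Carlo standard error at the trial counts
used (see the test suite).

The firing-rate trace is the population spike count in 10-ms bins divided
by `N * bin`.  Window criteria ("rate below 5 Hz during 400-500 ms") are
evaluated on the window mean by default; an all-bins mode exists for
sensitivity checks.  The closed-form QIF period under constant drive,
`T = tau/a (atan(V_t/a) - atan(V_r/a))` with `a = sqrt(I - b^2)`, serves as
the integrator oracle: at `dt = 0.1` ms the Euler inter-spike interval
agrees to well under 1%.

## Measures

* **Erasing probability P_e** — after igniting the network at `lam = 0`
  (stimulus 50–100 ms) the correlation level jumps to `lam` at 500 ms; a
  trial counts as erased when the mean rate in 800–900 ms is below 5 Hz.
  Trials not persistent during 400–500 ms are discarded.
* **Blocking probability P_b** — `lam` is constant from t = 0 and the
  trial counts as blocked when the stimulus fails to ignite (rate below
  5 Hz during 400–500 ms).
* **Regime probabilities** — gate-in `P_gi = (1-P_e)(1-P_b)`,
  selective-gate `P_sg = (1-P_e) P_b`, gate-out `P_go = P_e P_b`; the
  identity `P_gi + P_sg + P_go + P_e (1-P_b) = 1` holds exactly.  Regime
  boundaries on a `lam` grid are located by piecewise-linear interpolation
  of the dominance margins, and the `P_sg` maximum by a parabola through
  the top grid point and its neighbours.
* **Termination timing** — `t_stop` is the first 10-ms bin after the
  correlation onset below 5 Hz; `t_peak` the last bin before `t_stop` that
  is a local maximum above 20 Hz (plateau ties resolve to the later bin).
* **Input correlation** — mean pairwise Pearson coefficient of per-neuron
  currents smoothed with a 5-ms running mean; zero-variance traces are
  excluded with a warning.
* **Spike synchrony** — `1 - S` with `S` the time-averaged multivariate
  SPIKE-distance (Kreuz et al. 2013), implemented from the published
  definition with auxiliary end spikes; the profile is piecewise linear
  between spikes, so midpoint evaluation per segment integrates it exactly.
  The test suite cross-checks it against an independent second
  implementation to 1e-6.

## Monte-Carlo design and problem sizes

Following the averaging scheme of the source model (connectivity
realizations × noise realizations), all experiments take a
`MonteCarloDesign(n_connectivity, n_noise)` and a single integer seed from
which all per-trial seeds derive via `SeedSequence`, making every table
bit-reproducible.  The shipped defaults are desk-scale (hundreds of trials
per grid point rather than the 3000 of the original protocol); binomial
standard errors are reported alongside every probability so that
under-powered comparisons are visible.  The acceptance script uses 100
trials for the bistability rates and 300 trials per correlation-level grid
point for the regime map.

## Design choices made where the design was open

* **Delta-pulse amplitude.** With dimensionless voltage, each event
  increments `v` by exactly `J`.  This is validated at network level: it
  yields the stated quiescent/persistent bistability with the persistent
  state at ~20 Hz, and the mean-field self-consistency
  `f = F(0.32 + 0.104 f) ≈ 19.6 Hz` at single-unit defaults.
* **Stimulus sharing.** Stimulus trains are independent per target neuron;
  a shared afferent volley would confound the background-correlation
  manipulation (an optional `shared` flag exists and was used for
  sensitivity analysis).
* **In-degree rounding.** Nearest integer (`c_IE N_E = 13.6 -> 14`,
  `c_EI N_I = 7`).
* **WTA background wiring.** Background and stimulus project to the
  excitatory populations only; inhibitory neurons are driven purely by
  recurrent input.
* **Window criteria.** Mean-over-window by default (single-bin excursions
  would make classifications needlessly noisy); all-bins mode behind a
  flag.
* **Regime boundary interpolation.** The reported boundaries are finer
  than any affordable grid spacing, hence the linear/parabolic
  interpolation described above.

## Known limitations

* **Large-N memory loading.** With the stated parameters and integration
  scheme, the persistent state of the N=1000 / J=0.026 network is a stable
  attractor — phase-dispersed ensembles prepared on limit cycles with total
  drive up to I ≈ 3 relax to a robust asynchronous ~18-Hz state, which
  shows graded erasure by background correlations and match-stimulus
  suppression — but the default 56-Hz/50-ms stimulus overshoots it: the
  stimulus-driven transient lands on a faster cycle (I ≈ 6) outside the
  attractor's basin and collapses, so stimulus loading succeeds in only
  ~5-10% of trials.  Consequently the blocking probability of the N=1000
  network is dominated by this loading failure rather than by the
  correlation level, the gate-in regime does not dominate at any `lam`,
  and the selective-gate probability is maximal at `lam = 0` rather than
  at a small positive `lam`.  An extensive sensitivity analysis (smaller
  `dt`, reset overshoot carry-over, shared stimulus volleys, membrane
  time-constant heterogeneity, uniform and heterogeneous recurrent
  conduction delays — all exposed as simulation parameters) found that only
  conduction delays of ≥ 2 ms restore reliable large-N loading, at the
  cost of damping the correlation-gating effects elsewhere (the stimulus
  tuning structure and the winner-take-all task degrade), so the default
  remains the minimal one-step delay.  The erasing side of the N=1000
  phenomenology, measured on the trials that do ignite, is unaffected:
  `P_e` crosses 0.5 near `lam ≈ 0.1`.
* The fine position of the winner-take-all joint load-and-protect optimum
  inside the weak-stimulus plateau (1.5–7 Hz) is not resolved at
  desk-scale trial counts.
* Synthetic inputs only: homogeneous Poisson backgrounds with purely
  spatial correlations.  Temporally structured (oscillatory) backgrounds,
  conductance synapses, and read-out mechanisms are out of scope.  Passing
  tests demonstrate internal consistency of the model and its statistics,
  not properties of biological recordings.
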