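"""Network architectures with fixed-in-degree random connectivity.

Three architectures are provided:

* ``build_single_unit`` — one homogeneous excitatory population encoding a
  single memory item (N=100, c=0.2, J=0.26 by default).
* ``build_wta`` — a winner-take-all circuit: two item-selective excitatory
  populations ``B`` and ``R`` coupled only through a shared inhibitory
  population, each excitatory population with its own common background
  noise source so the correlation level is controlled per population.
* ``build_two_unit`` — two excitatory populations with no mutual synapses
  that share a single common background source (N=1000 each, J=0.026, so the
  mean recurrent drive cJN=5.2 matches the single-unit network).

Connectivity is random with a fixed in-degree: every target neuron receives
exactly ``round(c * N_source)`` distinct presynaptic partners drawn
uniformly, with autapses excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dynamics import NeuronParams
from .inputs import BackgroundConfig


@dataclass(frozen=True)
class PopulationSpec:
    """One homogeneous population.

    ``common_group`` identifies the shared background channel this population
    listens to; populations with the same group id receive the same common
    event train (the two-unit architecture puts both populations in one
    group).  ``None`` means no background input at all.
    """

    name: str
    size: int
    neuron: NeuronParams
    background: BackgroundConfig | None = None
    common_group: int | None = None
    sign: int = 1

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population size must be >= 1, got {self.size}")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 (excitatory) or -1 (inhibitory)")


@dataclass(frozen=True)
class Projection:
    """A fixed-in-degree projection between two populations.

    ``adjacency`` has shape (n_target, in_degree) and holds source-local
    neuron indices; every row lists the presynaptic partners of one target
    neuron.  ``j`` is signed (negative for inhibitory sources).
    """

    source: str
    target: str
    c: float
    j: float
    adjacency: np.ndarray

    @property
    def in_degree(self) -> int:
        return self.adjacency.shape[1]


class Network:
    """Populations plus projections, with global neuron indexing.

    Neurons are numbered globally in population order; ``pop_slice`` maps a
    population name to its global index range.
    """

    def __init__(
        self,
        populations: list[PopulationSpec],
        projections: list[Projection],
        stim_defaults: dict | None = None,
        meta: dict | None = None,
    ):
        names = [p.name for p in populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        self.populations = list(populations)
        self.projections = list(projections)
        self.stim_defaults = dict(stim_defaults or {})
        self.meta = dict(meta or {})
        offsets = np.cumsum([0] + [p.size for p in populations])
        self._offset = {p.name: int(o) for p, o in zip(populations, offsets)}
        self.n_neurons = int(offsets[-1])
        for proj in projections:
            if proj.source not in self._offset or proj.target not in self._offset:
                raise ValueError(
                    f"projection {proj.source}->{proj.target} references an "
                    "unknown population"
                )

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def pop_slice(self, name: str) -> slice:
        start = self._offset[name]
        return slice(start, start + self.population(name).size)

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        """Serialize parameters and adjacency to a documented JSON string."""
        doc = {
            "format": "corrgate-network-v1",
            "stim_defaults": self.stim_defaults,
            "meta": self.meta,
            "populations": [
                {
                    "name": p.name,
                    "size": p.size,
                    "sign": p.sign,
                    "common_group": p.common_group,
                    "neuron": vars(p.neuron) | {},
                    "background": (
                        None
                        if p.background is None
                        else {
                            "nu0": p.background.nu0,
                            "j0": p.background.j0,
                            "lam": p.background.lam,
                        }
                    ),
                }
                for p in self.populations
            ],
            "projections": [
                {
                    "source": pr.source,
                    "target": pr.target,
                    "c": pr.c,
                    "j": pr.j,
                    "adjacency": pr.adjacency.tolist(),
                }
                for pr in self.projections
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        if doc.get("format") != "corrgate-network-v1":
            raise ValueError("not a corrgate network document")
        pops = []
        for p in doc["populations"]:
            bg = p["background"]
            pops.append(
                PopulationSpec(
                    name=p["name"],
                    size=p["size"],
                    sign=p["sign"],
                    common_group=p["common_group"],
                    neuron=NeuronParams(**{
                        k: p["neuron"][k] for k in ("tau", "b", "v_t", "v_r")
                    }),
                    background=None
                    if bg is None
                    else BackgroundConfig(
                        nu0=bg["nu0"], j0=bg["j0"], lam=bg["lam"], n_targets=p["size"]
                    ),
                )
            )
        projs = [
            Projection(
                source=pr["source"],
                target=pr["target"],
                c=pr["c"],
                j=pr["j"],
                adjacency=np.asarray(pr["adjacency"], dtype=np.int64),
            )
            for pr in doc["projections"]
        ]
        return cls(pops, projs, doc.get("stim_defaults"), doc.get("meta"))


def fixed_indegree_connectivity(
    n_source: int,
    n_target: int,
    c: float,
    rng: np.random.Generator,
    exclude_self: bool = False,
) -> np.ndarray:
    """Random adjacency where every target has exactly round(c * n_source) inputs.

    Sources are drawn uniformly without replacement per target.  With
    ``exclude_self`` (recurrent projections) source index ``i`` is excluded
    for target ``i`` — no autapses.
    """
    if not 0 < c <= 1:
        raise ValueError(f"connection probability must lie in (0, 1], got {c}")
    k = int(np.rint(c * n_source))
    available = n_source - 1 if exclude_self else n_source
    if k > available:
        raise ValueError(
            f"requested in-degree {k} exceeds available sources ({available})"
        )
    adjacency = np.empty((n_target, k), dtype=np.int64)
    for t in range(n_target):
        if exclude_self:
            pool = np.concatenate(
                [np.arange(t, dtype=np.int64), np.arange(t + 1, n_source, dtype=np.int64)]
            )
        else:
            pool = np.arange(n_source, dtype=np.int64)
        adjacency[t] = rng.choice(pool, size=k, replace=False)
    return adjacency


def scaled_j(cjn: float, c: float, n: int) -> float:
    """Recurrent strength keeping the mean recurrent drive cJN fixed."""
    return cjn / (c * n)


def build_single_unit(
    rng: np.random.Generator,
    *,
    n: int = 100,
    c: float = 0.2,
    j: float = 0.26,
    j0: float = 0.151,
    nu0: float = 106.0,
    j1: float = 1.5,
    nu1: float = 56.0,
    neuron: NeuronParams | None = None,
) -> Network:
    """Homogeneous excitatory network encoding one memory item.

    Defaults give cJN = 5.2, the regime where a quiescent state (< 5 Hz) and
    a persistent state (~20 Hz) coexist.  Scaling families are obtained by
    overriding: hold cJN with ``j=scaled_j(5.2, c, n)`` while varying ``c`` or
    ``n``, or hold the in-degree with ``c=20/n`` at fixed ``j``.
    """
    neuron = neuron or NeuronParams()
    pop = PopulationSpec(
        name="E",
        size=n,
        neuron=neuron,
        background=BackgroundConfig(nu0=nu0, j0=j0, n_targets=n),
        common_group=0,
    )
    adj = fixed_indegree_connectivity(n, n, c, rng, exclude_self=True)
    proj = Projection(source="E", target="E", c=c, j=j, adjacency=adj)
    return Network(
        [pop],
        [proj],
        stim_defaults={"j1": j1, "nu1": nu1},
        meta={"family": "single_unit", "cjn": c * j * n},
    )


def build_wta(
    rng: np.random.Generator,
    *,
    n_e: int = 40,
    n_i: int = 20,
    c_ee: float = 0.45,
    j_ee: float = 0.3,
    c_ei: float = 0.35,
    j_ei: float = -0.25,
    c_ie: float = 0.34,
    j_ie: float = 0.05,
    j0: float = 0.4,
    nu0: float = 60.0,
    j1: float = 1.5,
    nu1: float = 17.0,
    neuron: NeuronParams | None = None,
) -> Network:
    """Winner-take-all network: populations B and R compete via inhibition.

    There is no direct synapse between B and R; each excitatory population
    has its own common background source (groups 0 and 1), so the correlation
    level is set independently per population.  Inhibitory neurons receive
    only recurrent drive from the excitatory populations.
    """
    neuron = neuron or NeuronParams()
    pops = [
        PopulationSpec(
            "B", n_e, neuron,
            background=BackgroundConfig(nu0=nu0, j0=j0, n_targets=n_e),
            common_group=0,
        ),
        PopulationSpec(
            "R", n_e, neuron,
            background=BackgroundConfig(nu0=nu0, j0=j0, n_targets=n_e),
            common_group=1,
        ),
        PopulationSpec("I", n_i, neuron, background=None, common_group=None, sign=-1),
    ]
    projs = []
    for exc in ("B", "R"):
        projs.append(
            Projection(exc, exc, c_ee, j_ee,
                       fixed_indegree_connectivity(n_e, n_e, c_ee, rng, exclude_self=True))
        )
        projs.append(
            Projection("I", exc, c_ei, j_ei,
                       fixed_indegree_connectivity(n_i, n_e, c_ei, rng))
        )
        projs.append(
            Projection(exc, "I", c_ie, j_ie,
                       fixed_indegree_connectivity(n_e, n_i, c_ie, rng))
        )
    return Network(
        pops,
        projs,
        stim_defaults={"j1": j1, "nu1": nu1},
        meta={"family": "wta"},
    )


def build_two_unit(
    rng: np.random.Generator,
    *,
    n: int = 1000,
    c: float = 0.2,
    j: float = 0.026,
    j0: float = 0.151,
    nu0: float = 106.0,
    j1: float = 1.5,
    nu1: float = 56.0,
    neuron: NeuronParams | None = None,
) -> Network:
    """Two excitatory populations without mutual synapses sharing one noise source.

    Each population has single-unit parameters scaled to N=1000 (J=0.026
    keeps cJN=5.2).  Both populations are in common group 0: one shared
    background channel, so the correlation level is necessarily identical
    across all 2N neurons.
    """
    neuron = neuron or NeuronParams()
    pops = [
        PopulationSpec(
            name, n, neuron,
            background=BackgroundConfig(nu0=nu0, j0=j0, n_targets=n),
            common_group=0,
        )
        for name in ("B", "R")
    ]
    projs = [
        Projection(name, name, c, j,
                   fixed_indegree_connectivity(n, n, c, rng, exclude_self=True))
        for name in ("B", "R")
    ]
    return Network(
        pops,
        projs,
        stim_defaults={"j1": j1, "nu1": nu1},
        meta={"family": "two_unit", "cjn": c * j * n},
    )
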