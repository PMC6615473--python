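"""Clock-driven leaky integrate-and-fire (LIF) network simulator.

The neuron model is the discrete-time LIF unit

    V(t) = beta * V(t-1) + V_in(t)          while V < V_th
    spike and V(t) = V_reset                when V >= V_th

with a fixed time step of 1 ms. Synapses carry a weight in [0, 100] and a
positive integer conduction delay: a spike emitted by the presynaptic
neuron at step t contributes its weight to the postsynaptic input at step
t + delay. Input-layer neurons act as spike sources driven directly by an
injected spike sequence.

Pair-based STDP with nearest-neighbor spike pairing can be switched on
during a run: a presynaptic spike at t1 and a postsynaptic spike at t2
potentiate the synapse by A_plus * exp(-(t2-t1)/tau_plus) when t1 < t2,
depress it by A_minus * exp(-(t1-t2)/tau_minus) when t1 > t2, and leave it
unchanged when t1 == t2. Weights are clipped to [0, w_max] throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

WEIGHT_MIN = 0.0
WEIGHT_MAX = 100.0

LAYER_INPUT = "input"
LAYER_MEMORY = "memory"
LAYER_OUTPUT = "output"


@dataclass(frozen=True)
class LIFParams:
    """Leak factor, firing threshold and reset state of the LIF unit.

    Defaults: ``beta=0.9`` per-ms leak, ``v_th=45`` so that a single spike
    over a weight-50 synapse is suprathreshold (the initial input-to-memory
    weight must provoke a response on its own), ``v_reset=0``.
    """

    beta: float = 0.9
    v_th: float = 45.0
    v_reset: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if self.beta == 1.0:
            raise ValueError("beta=1 (no leak) must be enabled explicitly "
                             "via LIFParams.allow_no_leak")
        if not self.v_reset < self.v_th:
            raise ValueError("v_reset must be below v_th")

    @classmethod
    def allow_no_leak(cls, v_th: float = 45.0, v_reset: float = 0.0) -> "LIFParams":
        p = cls.__new__(cls)
        object.__setattr__(p, "beta", 1.0)
        object.__setattr__(p, "v_th", v_th)
        object.__setattr__(p, "v_reset", v_reset)
        return p


@dataclass
class NeuronState:
    """Membrane state and spike history of a single neuron."""

    v: float = 0.0
    last_spike_times: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class STDPParams:
    """Pair-based STDP window: amplitudes, decay constants and weight cap.

    With ``soft_bound`` (default), weight updates are multiplicative in the
    distance to the bounds: potentiation scales with ``1 - w/w_max`` and
    depression with ``w/w_max``, giving each synapse a stable equilibrium
    set by its pairing statistics instead of the runaway/bimodal behavior
    of purely additive updates.
    """

    a_plus: float = 0.1
    a_minus: float = 0.12
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_max: float = 30.0
    #: Optional distinct cap for synapses onto the output layer. The
    #: memory->output weights live on a much smaller scale (a shared budget
    #: divided across hundreds of synapses) than memory-memory weights, so
    #: a common ceiling would let potentiation inflate output drive without
    #: bound; a tight output cap makes every output neuron saturate to the
    #: same ceiling during its training, keeping the competition fair.
    w_max_out: float | None = 1.0
    soft_bound: bool = True

    def __post_init__(self):
        for name in ("a_plus", "a_minus", "tau_plus", "tau_minus", "w_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Synapse:
    """Directed, weighted, delayed connection between two neurons."""

    pre: int
    post: int
    weight: float
    delay: int = 1
    plastic: bool = False

    def __post_init__(self):
        if self.pre == self.post:
            raise ValueError("self-loop synapses are not allowed")
        if self.delay < 1 or int(self.delay) != self.delay:
            raise ValueError("delay must be a positive integer number of steps")
        self.delay = int(self.delay)
        self.weight = float(np.clip(self.weight, WEIGHT_MIN, WEIGHT_MAX))


@dataclass(frozen=True)
class SpikeRecord:
    """Time-sorted log of (neuron_id, time_ms) firing events."""

    events: list[tuple[int, float]]

    def spikes_of(self, neuron: int) -> list[float]:
        return [t for n, t in self.events if n == neuron]

    def first_spike_times(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for n, t in self.events:
            if n not in out:
                out[n] = t
        return out

    def fired(self) -> set[int]:
        return {n for n, _ in self.events}

    def __len__(self) -> int:
        return len(self.events)


class Network:
    """Layered graph of LIF neurons and directed, delayed synapses.

    Neurons are identified by dense integer ids. Each neuron carries a
    layer tag (``input``/``memory``/``output``), a kernel-part index and a
    2D coordinate (part/x/y are -1 for output neurons, which have labels
    instead of positions).
    """

    def __init__(self):
        self.layer: list[str] = []
        self.part: list[int] = []
        self.x: list[int] = []
        self.y: list[int] = []
        self.synapses: list[Synapse] = []
        self._edge_index: dict[tuple[int, int], int] = {}

    # -- construction ------------------------------------------------------

    def add_neuron(self, layer: str, part: int = -1, x: int = -1, y: int = -1) -> int:
        if layer not in (LAYER_INPUT, LAYER_MEMORY, LAYER_OUTPUT):
            raise ValueError(f"unknown layer {layer!r}")
        self.layer.append(layer)
        self.part.append(part)
        self.x.append(x)
        self.y.append(y)
        return len(self.layer) - 1

    def add_synapse(self, syn: Synapse) -> bool:
        """Add ``syn`` unless an edge pre->post already exists.

        Returns True if the synapse was added. Duplicate wiring attempts
        keep the first synapse.
        """
        n = self.n_neurons
        if not (0 <= syn.pre < n and 0 <= syn.post < n):
            raise ValueError(
                f"synapse endpoints ({syn.pre}, {syn.post}) out of range")
        key = (syn.pre, syn.post)
        if key in self._edge_index:
            return False
        self._edge_index[key] = len(self.synapses)
        self.synapses.append(syn)
        return True

    def has_synapse(self, pre: int, post: int) -> bool:
        return (pre, post) in self._edge_index

    def get_synapse(self, pre: int, post: int) -> Synapse:
        return self.synapses[self._edge_index[(pre, post)]]

    def remove_synapses(self, keys: set[tuple[int, int]]) -> int:
        """Delete every synapse whose (pre, post) pair is in ``keys``."""
        if not keys:
            return 0
        kept = [s for s in self.synapses if (s.pre, s.post) not in keys]
        removed = len(self.synapses) - len(kept)
        self.synapses = kept
        self._edge_index = {(s.pre, s.post): i for i, s in enumerate(kept)}
        return removed

    # -- queries -----------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.layer)

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    def neurons_in_layer(self, layer: str) -> list[int]:
        return [i for i, l in enumerate(self.layer) if l == layer]

    def output_label(self, neuron: int) -> int:
        """Label of an output neuron = its rank within the output layer."""
        outs = self.neurons_in_layer(LAYER_OUTPUT)
        return outs.index(neuron)

    def copy(self) -> "Network":
        dup = Network()
        dup.layer = list(self.layer)
        dup.part = list(self.part)
        dup.x = list(self.x)
        dup.y = list(self.y)
        dup.synapses = [replace(s) for s in self.synapses]
        dup._edge_index = dict(self._edge_index)
        return dup

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self._edge_index)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "neurons": [
                {"id": i, "layer": self.layer[i], "x": self.x[i],
                 "y": self.y[i], "part": self.part[i]}
                for i in range(self.n_neurons)
            ],
            "synapses": [
                {"pre": s.pre, "post": s.post, "weight": s.weight,
                 "delay": s.delay, "plastic": s.plastic}
                for s in self.synapses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Network":
        net = cls()
        neurons = sorted(d["neurons"], key=lambda n: n["id"])
        if [n["id"] for n in neurons] != list(range(len(neurons))):
            raise ValueError("neuron ids must be dense 0..N-1")
        for n in neurons:
            net.add_neuron(n["layer"], n.get("part", -1),
                           n.get("x", -1), n.get("y", -1))
        for s in d["synapses"]:
            net.add_synapse(Synapse(s["pre"], s["post"], s["weight"],
                                    s["delay"], bool(s["plastic"])))
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Network":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- single-step / single-synapse primitives -------------------------------


def step_neuron(state: NeuronState, v_in: float, p: LIFParams,
                t: float | None = None) -> tuple[NeuronState, bool]:
    """Advance one neuron by one time step; returns (new state, fired)."""
    if not math.isfinite(v_in):
        raise ValueError("non-finite synaptic input")
    v = p.beta * state.v + v_in
    fired = v >= p.v_th
    if fired:
        v = p.v_reset
    times = list(state.last_spike_times)
    if fired and t is not None:
        times.append(t)
    return NeuronState(v=v, last_spike_times=times), fired


def stdp_update(syn: Synapse, t_pre: float, t_post: float,
                p: STDPParams) -> Synapse:
    """Apply one STDP pairing to a synapse; returns an updated copy."""
    w = syn.weight
    if t_pre < t_post:
        w += p.a_plus * math.exp(-(t_post - t_pre) / p.tau_plus)
    elif t_pre > t_post:
        w -= p.a_minus * math.exp(-(t_pre - t_post) / p.tau_minus)
    w = float(np.clip(w, WEIGHT_MIN, min(p.w_max, WEIGHT_MAX)))
    return replace(syn, weight=w)


# -- network simulation ----------------------------------------------------


def _injection_times(injected, n_input: int) -> list[tuple[int, int]]:
    """Map an injected spike sequence to (input neuron, integer step)."""
    if injected is None:
        return []
    events = injected.events if hasattr(injected, "events") else injected
    out = []
    for channel, t in events:
        if not (0 <= channel < n_input):
            raise ValueError(
                f"injected channel {channel} has no input neuron (n_input={n_input})")
        out.append((int(channel), int(round(t))))
    return out


def run(net: Network, injected=None, duration: int = 300,
        stdp_on: bool = False, lif: LIFParams | None = None,
        stdp: STDPParams | None = None) -> SpikeRecord:
    """Simulate the network for ``duration`` 1-ms steps.

    ``injected`` is an :class:`~memnet.encode.InputSpikeSequence` (or bare
    list of ``(channel, time_ms)`` pairs) mapped one-to-one onto the
    input-layer neurons, which fire exactly at the injected times. All
    other neurons follow the LIF dynamics. When ``stdp_on`` is set, every
    plastic synapse is updated online under nearest-neighbor pair-based
    STDP and the new weights are written back into ``net``.

    Returns the complete time-sorted spike record. The simulation is fully
    deterministic: identical network, injection and parameters give an
    identical record.
    """
    lif = lif or LIFParams()
    stdp = stdp or STDPParams()
    n = net.n_neurons
    layers = np.asarray(net.layer)
    is_input = layers == LAYER_INPUT
    n_input = int(is_input.sum())

    syns = net.synapses
    m = len(syns)
    pre = np.fromiter((s.pre for s in syns), dtype=np.int64, count=m)
    post = np.fromiter((s.post for s in syns), dtype=np.int64, count=m)
    for endpoint in (pre, post):
        if m and (endpoint.min() < 0 or endpoint.max() >= n):
            raise ValueError("dangling synapse endpoint")
    w = np.fromiter((s.weight for s in syns), dtype=float, count=m)
    delay = np.fromiter((s.delay for s in syns), dtype=np.int64, count=m)
    plastic = np.fromiter((s.plastic for s in syns), dtype=bool, count=m)

    # CSR-style grouping of synapses by presynaptic neuron
    order = np.argsort(pre, kind="stable")
    indptr = np.searchsorted(pre[order], np.arange(n + 1))

    max_delay = int(delay.max()) if m else 1
    arrivals = np.zeros((duration + max_delay + 1, n))
    forced: dict[int, list[int]] = {}
    for channel, t in _injection_times(injected, n_input):
        if 0 <= t < duration:
            forced.setdefault(t, []).append(channel)

    v = np.zeros(n)
    last_spike = np.full(n, -np.inf)
    # STDP pairs on delay-compensated (arrival) times, so the timing seen
    # by the rule matches the causal influence on the postsynaptic neuron
    last_arrival = np.full(m, -np.inf)
    landing: dict[int, list[np.ndarray]] = {}
    events: list[tuple[int, float]] = []
    w_cap = np.full(m, min(stdp.w_max, WEIGHT_MAX), dtype=float)
    if stdp.w_max_out is not None and m:
        w_cap[layers[post] == LAYER_OUTPUT] = min(stdp.w_max_out, WEIGHT_MAX)

    for t in range(duration):
        v = lif.beta * v + arrivals[t]
        fired_mask = v >= lif.v_th
        fired_mask[is_input] = False
        if t in forced:
            fired_mask[np.asarray(forced[t])] = True
        fired = np.flatnonzero(fired_mask)
        v[fired_mask & ~is_input] = lif.v_reset

        if stdp_on and m:
            land = landing.pop(t, None)
            land = np.concatenate(land) if land else None
            if land is not None:
                last_arrival[land] = t
            if fired.size:
                fired_set_mask = np.zeros(n, dtype=bool)
                fired_set_mask[fired] = True
                # potentiation: postsynaptic spike now, nearest earlier (or
                # simultaneous, i.e. causally driving) synaptic arrival
                pot = plastic & fired_set_mask[post] & (last_arrival > -np.inf)
                if pot.any():
                    dt = t - last_arrival[pot]
                    dw = stdp.a_plus * np.exp(-dt / stdp.tau_plus)
                    if stdp.soft_bound:
                        dw *= 1.0 - w[pot] / w_cap[pot]
                    w[pot] = np.clip(w[pot] + dw, WEIGHT_MIN, w_cap[pot])
            if land is not None:
                # depression: arrival landing strictly after the latest
                # postsynaptic spike weakens the (acausal) synapse
                dep = land[plastic[land]
                           & ~fired_mask[post[land]]
                           & (last_spike[post[land]] > -np.inf)]
                if dep.size:
                    dt = t - last_spike[post[dep]]
                    dw = stdp.a_minus * np.exp(-dt / stdp.tau_minus)
                    if stdp.soft_bound:
                        dw *= w[dep] / w_cap[dep]
                    w[dep] = np.clip(w[dep] - dw, WEIGHT_MIN, w_cap[dep])

        if fired.size == 0:
            continue

        # propagate spikes along outgoing synapses
        for nid in fired:
            sl = order[indptr[nid]:indptr[nid + 1]]
            if sl.size:
                np.add.at(arrivals, (t + delay[sl], post[sl]), w[sl])
                if stdp_on:
                    for d in np.unique(delay[sl]):
                        landing.setdefault(int(t + d), []).append(
                            sl[delay[sl] == d])

        last_spike[fired] = t
        events.extend((int(nid), float(t)) for nid in sorted(fired))

    if stdp_on:
        for i, s in enumerate(syns):
            if plastic[i]:
                s.weight = float(w[i])

    return SpikeRecord(events=events)


def write_spike_record_csv(record: SpikeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("neuron_id,time_ms\n")
        for nid, t in record.events:
            fh.write(f"{nid},{t}\n")
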