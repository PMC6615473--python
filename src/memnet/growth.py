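"""Structure Formation: Hebbian growth of memory-layer connectivity.

After a stimulus has been played through the network once, the recorded
memory-layer firing pattern drives two kinds of wiring:

* :func:`grow_connections` adds a directed synapse between every pair of
  memory neurons of the same kernel part that fired near-coincidentally
  (0 < |t1 - t2| < time threshold) and lie closer than a Euclidean
  distance threshold, from the earlier-firing to the later-firing neuron,
  at weight 10. Neurons that fire together wire together — with the spike
  order fixing the direction of causality.
* :func:`wire_output` connects every memory neuron that fired to the
  output neuron of the stimulus label, splitting a fixed weight budget
  equally (weight/n each) and using the temporal-to-spatial delay so all
  direct pathways keep equal total conduction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .simcore import LAYER_MEMORY, LAYER_OUTPUT, Network, SpikeRecord, Synapse
from .topology import LayerSpec, delay_mem_to_out, memory_delay_im


@dataclass(frozen=True)
class GrowthConfig:
    """Thresholds and weights of the structural-growth rule.

    time_threshold:
        Coincidence window in ms; a pair connects only when
        ``0 < |t1 - t2| < time_threshold`` (strict on both sides: exactly
        simultaneous spikes never connect). Default 5 ms.
    dist_threshold:
        Euclidean distance bound within a part, strict; default 2, which
        admits the 8-neighborhood (distances 1 and sqrt(2)) and nothing
        farther. Controls sparsity of the grown memory layer.
    grown_weight:
        Initial weight of a grown memory-memory synapse (10).
    grown_delay:
        Conduction delay of grown synapses in steps; 1 keeps the neighbor
        coupling inside the coincidence window.
    output_weight_constant:
        Budget split across the memory->output synapses of one stimulus
        (each new synapse gets budget/n for n fired neurons).
    all_pairs_spikes:
        When True, coincidence is evaluated over all spike pairs of the
        two neurons; default False uses first spikes only, matching the
        time-to-first-spike code.
    """

    time_threshold: float = 5.0
    dist_threshold: float = 2.0
    grown_weight: float = 10.0
    grown_delay: int = 1
    output_weight_constant: float = 400.0
    all_pairs_spikes: bool = False

    def __post_init__(self):
        for name in ("time_threshold", "dist_threshold", "grown_weight",
                     "grown_delay", "output_weight_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class EmptyResponseError(RuntimeError):
    """The stimulus produced no memory-layer spikes to wire from."""


def _firing_times(record: SpikeRecord, net: Network,
                  cfg: GrowthConfig) -> dict[int, list[float]]:
    """Per-memory-neuron spike times used by the pair scan."""
    n = net.n_neurons
    times: dict[int, list[float]] = {}
    for nid, t in record.events:
        if not (0 <= nid < n):
            raise ValueError(f"spike record references unknown neuron {nid}")
        if net.layer[nid] == LAYER_MEMORY:
            times.setdefault(nid, []).append(t)
    if not cfg.all_pairs_spikes:
        times = {nid: [min(ts)] for nid, ts in times.items()}
    return times


def grow_connections(record: SpikeRecord, net: Network,
                     cfg: GrowthConfig | None = None) -> Network:
    """Grow memory-memory synapses from one presentation's spike record.

    Scans every ordered pair of same-part memory neurons that both fired.
    A pair at Euclidean distance strictly below ``dist_threshold`` whose
    firing times satisfy ``0 < |t1 - t2| < time_threshold`` gains a
    plastic synapse from the earlier to the later firer (weight
    ``grown_weight``, delay ``grown_delay``) unless that edge already
    exists. Cross-part pairs never connect (parts are separate feature
    maps). The scan is repeated until no new pair qualifies; since the
    record is fixed, one full pass reaches that fixed point. Existing
    synapses are never modified, so the edge set grows monotonically and
    a second call with the same record is a no-op.

    Returns ``net`` (modified in place) for chaining.
    """
    cfg = cfg or GrowthConfig()
    times = _firing_times(record, net, cfg)
    fired = sorted(times)
    # bucket by part; growth is strictly part-local
    by_part: dict[int, list[int]] = {}
    for nid in fired:
        by_part.setdefault(net.part[nid], []).append(nid)

    for part_neurons in by_part.values():
        for i, n1 in enumerate(part_neurons):
            for n2 in part_neurons[i + 1:]:
                dist = math.hypot(net.x[n1] - net.x[n2], net.y[n1] - net.y[n2])
                if dist >= cfg.dist_threshold:
                    continue
                for t1 in times[n1]:
                    for t2 in times[n2]:
                        if 0 < abs(t1 - t2) < cfg.time_threshold:
                            src, dst = (n1, n2) if t1 < t2 else (n2, n1)
                            net.add_synapse(Synapse(
                                pre=src, post=dst, weight=cfg.grown_weight,
                                delay=cfg.grown_delay, plastic=True))
    return net


def wire_output(record: SpikeRecord, net: Network, label: int,
                cfg: GrowthConfig | None = None,
                spec: LayerSpec | None = None) -> Network:
    """Wire every fired memory neuron to the output neuron of ``label``.

    Each new synapse gets weight ``output_weight_constant / n`` where n is
    the number of memory neurons that fired during the run, is plastic,
    and uses the temporal-to-spatial delay. Wiring attempts onto an edge
    that already exists keep the first synapse.
    """
    cfg = cfg or GrowthConfig()
    spec = spec or LayerSpec()
    outputs = net.neurons_in_layer(LAYER_OUTPUT)
    if not (0 <= label < len(outputs)):
        raise ValueError(f"label {label} outside output layer of size {len(outputs)}")
    target = outputs[label]
    fired = sorted({nid for nid, _ in record.events
                    if net.layer[nid] == LAYER_MEMORY})
    if not fired:
        raise EmptyResponseError(
            "input produced no memory-layer activity; nothing to wire")
    w = cfg.output_weight_constant / len(fired)
    for nid in fired:
        d = delay_mem_to_out(memory_delay_im(net, nid, spec),
                             spec.n_memory_scope)
        net.add_synapse(Synapse(pre=nid, post=target, weight=w,
                                delay=d, plastic=True))
    return net
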