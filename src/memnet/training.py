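"""Parameter Training: recall testing and reinforcement weight shrinkage.

Recall plays a spike sequence through the network and reads the output
layer as an ordered firing sequence of labels; the recalled memory is the
label that fires most often (majority vote, ties broken by earliest first
occurrence). When recall is wrong, every synapse from a memory neuron
that fired (set S_M) onto a wrong-label output neuron that fired (set
S_O) is multiplicatively shrunk by ``Shrink_Coeff``, weakening the
miscausal pathways, and the stimulus is replayed until the vote comes out
right. STDP stays on throughout training, sculpting the plastic weights
toward each stimulus' spike-timing profile; input->memory weights are
non-plastic and never change in this phase.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .simcore import (LAYER_MEMORY, LAYER_OUTPUT, LIFParams, Network,
                      SpikeRecord, STDPParams, run)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the training loop.

    shrink_coeff:
        Multiplicative factor in (0,1) applied to miscausal
        memory->output weights after each failed recall (default 0.9).
    max_iters:
        Safety cap on presentations per stimulus; hitting it is reported,
        not raised.
    sim_duration:
        Presentation length in ms; must cover the encoding window plus
        the longest total conduction path so late output spikes land.
    """

    shrink_coeff: float = 0.9
    max_iters: int = 60
    sim_duration: int = 300
    stdp_on: bool = True

    def __post_init__(self):
        if not (0.0 < self.shrink_coeff < 1.0):
            raise ValueError("shrink_coeff must lie strictly in (0, 1)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass(frozen=True)
class RecallResult:
    """Output-layer reading for one presentation."""

    firing_sequence: list[int]
    decoded_label: int | None
    correct: bool | None
    record: SpikeRecord | None = field(default=None, repr=False, compare=False)


def decode_majority(seq: list[int]) -> int | None:
    """Majority-vote decoding of an output firing sequence.

    Returns the most frequent label; among equally frequent labels the
    one whose first occurrence is earliest wins. Empty sequence -> None.
    """
    if not seq:
        return None
    counts = Counter(seq)
    best = max(counts.values())
    for label in seq:  # earliest first occurrence among the tied maxima
        if counts[label] == best:
            return label
    raise AssertionError("unreachable")


def recall(net: Network, spikes, duration: int = 300, stdp_on: bool = False,
           expected: int | None = None, lif: LIFParams | None = None,
           stdp: STDPParams | None = None) -> RecallResult:
    """Present ``spikes`` and decode the output layer's firing sequence.

    The firing sequence lists output-neuron labels in spike-time order
    (simultaneous spikes ordered by ascending neuron id) and ends when
    output spiking ceases within the presentation window.
    """
    record = run(net, spikes, duration=duration, stdp_on=stdp_on,
                 lif=lif, stdp=stdp)
    outputs = net.neurons_in_layer(LAYER_OUTPUT)
    label_of = {nid: i for i, nid in enumerate(outputs)}
    seq = [label_of[nid] for nid, _ in record.events if nid in label_of]
    decoded = decode_majority(seq)
    return RecallResult(
        firing_sequence=seq,
        decoded_label=decoded,
        correct=None if expected is None else decoded == expected,
        record=record)


def reinforce_shrink(net: Network, s_m: set[int], s_o: set[int],
                     coeff: float) -> Network:
    """Shrink every existing synapse from S_M into S_O by ``coeff``.

    S_M is the set of memory neurons that fired during the failed recall;
    S_O the set of incorrectly firing output neurons. Only synapses that
    already exist are touched (W <- W * coeff); everything else is left
    bit-identical. Returns ``net`` for chaining.
    """
    if not (0.0 < coeff):
        raise ValueError("coeff must be positive")
    if not s_o or not s_m:
        return net
    s_m, s_o = set(s_m), set(s_o)
    for syn in net.synapses:
        if syn.pre in s_m and syn.post in s_o:
            syn.weight *= coeff
    return net


def _miscausal_sets(net: Network, record: SpikeRecord,
                    expected: int) -> tuple[set[int], set[int]]:
    """(S_M, S_O) from a failed recall's spike record."""
    outputs = net.neurons_in_layer(LAYER_OUTPUT)
    label_of = {nid: i for i, nid in enumerate(outputs)}
    fired = record.fired()
    s_m = {nid for nid in fired if net.layer[nid] == LAYER_MEMORY}
    s_o = {nid for nid in fired
           if nid in label_of and label_of[nid] != expected}
    return s_m, s_o


@dataclass
class TrainReport:
    """Per-stimulus convergence log of one training run."""

    iterations: dict[int, int] = field(default_factory=dict)
    converged: dict[int, bool] = field(default_factory=dict)
    final_sequences: dict[int, list[int]] = field(default_factory=dict)

    @property
    def all_converged(self) -> bool:
        return all(self.converged.values()) if self.converged else True


def train_on_set(net: Network, dataset, cfg: TrainConfig | None = None,
                 lif: LIFParams | None = None,
                 stdp: STDPParams | None = None) -> tuple[Network, TrainReport]:
    """Train until every stimulus in ``dataset`` is recalled correctly.

    ``dataset`` is a sequence of ``(spike_sequence, label)`` pairs. Each
    stimulus is presented (STDP on by default); a correct majority vote
    removes it from the working set, a wrong one triggers one
    reinforcement shrink of the miscausal memory->output weights followed
    by an immediate replay of the same stimulus. A stimulus that does not
    converge within ``max_iters`` presentations is logged as failed and
    training proceeds; the (partially) trained network is always
    returned together with the per-stimulus iteration report.
    """
    cfg = cfg or TrainConfig()
    report = TrainReport()
    for spikes, label in dataset:
        iters = 0
        ok = False
        while iters < cfg.max_iters:
            iters += 1
            res = recall(net, spikes, duration=cfg.sim_duration,
                         stdp_on=cfg.stdp_on, expected=label,
                         lif=lif, stdp=stdp)
            if res.correct:
                ok = True
                break
            s_m, s_o = _miscausal_sets(net, res.record, label)
            reinforce_shrink(net, s_m, s_o, cfg.shrink_coeff)
        report.iterations[label] = iters
        report.converged[label] = ok
        report.final_sequences[label] = res.firing_sequence
        if not ok:
            log.warning("stimulus %s failed to converge after %d presentations",
                        label, iters)
        else:
            log.info("stimulus %s recalled correctly after %d presentations",
                     label, iters)
    return net, report
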