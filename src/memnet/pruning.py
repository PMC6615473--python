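"""Post-training pruning of weak synapses and orphaned pathways.

Biological networks prune for energy efficiency; here that is modelled as
two deletion rules applied after training: (1) every synapse whose weight
is strictly below a threshold (default 3) is deleted; (2) any non-output
neuron left without outgoing synapses has all its incoming synapses
deleted as well, and this orphan rule cascades until a fixed point — a
neuron that no longer leads anywhere cannot contribute to recall, so the
pathway feeding it is dead weight. Neurons themselves persist; only
synapses are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .simcore import LAYER_OUTPUT, Network


@dataclass(frozen=True)
class PruneConfig:
    weight_threshold: float = 3.0

    def __post_init__(self):
        if self.weight_threshold < 0:
            raise ValueError("weight_threshold must be >= 0")


@dataclass
class PruneReport:
    """What was deleted, for inspection and CSV export."""

    weak_deleted: int = 0
    orphan_deleted: int = 0
    deleted_edges: list[tuple[int, int, float, str]] = field(default_factory=list)

    @property
    def total_deleted(self) -> int:
        return self.weak_deleted + self.orphan_deleted

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pre,post,weight,reason\n")
            for pre, post, w, reason in self.deleted_edges:
                fh.write(f"{pre},{post},{w},{reason}\n")


def prune(net: Network, cfg: PruneConfig | None = None) -> tuple[Network, PruneReport]:
    """Return a pruned copy of ``net`` plus a deletion report.

    Deletes sub-threshold synapses (strict ``<``: a weight exactly at the
    threshold survives), then cascades the orphan rule — a non-output
    neuron with zero outgoing synapses loses all incoming synapses — to a
    fixed point. Idempotent: pruning a pruned network changes nothing.
    """
    cfg = cfg or PruneConfig()
    out = net.copy()
    report = PruneReport()

    weak = {(s.pre, s.post) for s in out.synapses
            if s.weight < cfg.weight_threshold}
    for s in out.synapses:
        if (s.pre, s.post) in weak:
            report.deleted_edges.append((s.pre, s.post, s.weight, "weak"))
    report.weak_deleted = out.remove_synapses(weak)

    while True:
        has_out = set()
        for s in out.synapses:
            has_out.add(s.pre)
        orphaned = {(s.pre, s.post) for s in out.synapses
                    if s.post not in has_out
                    and out.layer[s.post] != LAYER_OUTPUT}
        if not orphaned:
            break
        for s in out.synapses:
            if (s.pre, s.post) in orphaned:
                report.deleted_edges.append((s.pre, s.post, s.weight, "orphan"))
        report.orphan_deleted += out.remove_synapses(orphaned)

    return out, report
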