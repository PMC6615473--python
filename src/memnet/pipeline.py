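"""End-to-end orchestration of the two-phase build procedure.

The full procedure takes a labeled image set and produces a trained,
pruned associative-memory network:

1. encode every image into a latency spike sequence;
2. build the initial three-layer network (one-to-one input->memory
   wiring, empty memory layer, unconnected outputs);
3. Structure Formation: present every sequence, grow memory-layer
   synapses between near-coincident same-part neighbors, and wire fired
   memory neurons to the stimulus' output neuron; the whole pass over
   the set is repeated ``sf_turns`` times (default 2) so that activity
   unlocked by first-turn growth can be wired in too;
4. Parameter Training: recall each sequence with STDP on and shrink
   miscausal memory->output weights until the majority vote is correct;
5. Pruning: delete weak synapses and orphaned pathways.

STDP is off during Structure Formation (growth is driven by the raw
latency code) and on during Training; both are config switches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace

import yaml

from .encode import EncoderConfig, image_to_spikes
from .growth import GrowthConfig, grow_connections, wire_output
from .pruning import PruneConfig, PruneReport, prune
from .simcore import LIFParams, Network, STDPParams, run
from .topology import LayerSpec, build_initial_network
from .training import TrainConfig, TrainReport, recall, train_on_set

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of the full pipeline, grouped per stage."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    prune: PruneConfig = field(default_factory=PruneConfig)
    layers: LayerSpec = field(default_factory=LayerSpec)
    sf_turns: int = 2
    sf_stdp_on: bool = False
    duration_slack: int = 55
    seed: int = 0

    def __post_init__(self):
        if self.sf_turns < 1:
            raise ValueError("sf_turns must be >= 1")

    @property
    def sim_duration(self) -> int:
        """Presentation length covering the encoding window plus the
        longest direct conduction path plus slack."""
        return int(self.encoder.t_max) + self.layers.n_memory_scope + 1 \
            + self.duration_slack


@dataclass
class RunReport:
    """Structured record of one full pipeline run."""

    edges_initial: int = 0
    edges_after_sf: list[int] = field(default_factory=list)
    edges_memory_after_sf: int = 0
    train: TrainReport | None = None
    recall_sequences: dict[int, list[int]] = field(default_factory=dict)
    recall_labels: dict[int, int | None] = field(default_factory=dict)
    prune_report: PruneReport | None = None
    recall_labels_pruned: dict[int, int | None] = field(default_factory=dict)
    pruned_agreement: float | None = None

    def to_dict(self) -> dict:
        d = {
            "edges_initial": self.edges_initial,
            "edges_after_sf": self.edges_after_sf,
            "edges_memory_after_sf": self.edges_memory_after_sf,
            "recall_sequences": self.recall_sequences,
            "recall_labels": self.recall_labels,
            "recall_labels_pruned": self.recall_labels_pruned,
            "pruned_agreement": self.pruned_agreement,
        }
        if self.train is not None:
            d["train_iterations"] = self.train.iterations
            d["train_converged"] = self.train.converged
        if self.prune_report is not None:
            d["pruned_weak"] = self.prune_report.weak_deleted
            d["pruned_orphan"] = self.prune_report.orphan_deleted
        return d


def encode_dataset(images, cfg: RunConfig):
    """Encode labeled ``(image, label)`` pairs into spike sequences."""
    return [(image_to_spikes(img, cfg=cfg.encoder), label)
            for img, label in images]


def structure_formation(net: Network, dataset, cfg: RunConfig,
                        report: RunReport | None = None) -> Network:
    """Run ``sf_turns`` Structure Formation passes over the dataset.

    Each presentation simulates the stimulus, grows memory-layer synapses
    from the spike record, and wires the fired memory neurons to the
    stimulus' output neuron. Growth is a fixed point per record, so extra
    turns only add edges where earlier growth changed the activity.
    """
    for turn in range(cfg.sf_turns):
        for spikes, label in dataset:
            record = run(net, spikes, duration=cfg.sim_duration,
                         stdp_on=cfg.sf_stdp_on, lif=cfg.lif, stdp=cfg.stdp)
            grow_connections(record, net, cfg.growth)
            wire_output(record, net, label, cfg.growth, cfg.layers)
        log.info("structure formation turn %d: %d synapses",
                 turn + 1, net.n_synapses)
        if report is not None:
            report.edges_after_sf.append(net.n_synapses)
    return net


def run_full(images, cfg: RunConfig | None = None):
    """Full build: encode, initialize, form structure, train, prune.

    ``images`` is a sequence of ``(28x28 image, label)`` pairs with labels
    dense in ``0..n-1``. Returns ``(trained_net, pruned_net, report)``:
    the trained network is the procedure's primary product; the pruned
    copy additionally has weak/orphaned synapses removed, and the report
    records whether pruning preserved the recall labels.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one labeled image")
    labels = sorted({label for _, label in images})
    if labels != list(range(len(labels))):
        raise ValueError("labels must be dense in 0..n_output-1")

    cfg = cfg or RunConfig()
    cfg = replace(cfg, layers=replace(cfg.layers, n_output=len(labels)))
    report = RunReport()

    dataset = encode_dataset(images, cfg)
    net = build_initial_network(cfg.layers)
    report.edges_initial = net.n_synapses

    structure_formation(net, dataset, cfg, report)
    report.edges_memory_after_sf = sum(
        1 for s in net.synapses
        if net.layer[s.pre] == "memory" and net.layer[s.post] == "memory")

    net, train_report = train_on_set(net, dataset, cfg.train,
                                     lif=cfg.lif, stdp=cfg.stdp)
    report.train = train_report

    for spikes, label in dataset:
        res = recall(net, spikes, duration=cfg.sim_duration, stdp_on=False,
                     expected=label, lif=cfg.lif, stdp=cfg.stdp)
        report.recall_sequences[label] = res.firing_sequence
        report.recall_labels[label] = res.decoded_label

    pruned, report.prune_report = prune(net, cfg.prune)
    agree = 0
    for spikes, label in dataset:
        res = recall(pruned, spikes, duration=cfg.sim_duration,
                     stdp_on=False, lif=cfg.lif, stdp=cfg.stdp)
        report.recall_labels_pruned[label] = res.decoded_label
        agree += res.decoded_label == report.recall_labels[label]
    report.pruned_agreement = agree / len(dataset)
    if report.pruned_agreement < 1.0:
        log.warning("pruning changed recall labels on %.0f%% of stimuli",
                    100 * (1 - report.pruned_agreement))

    return net, pruned, report


def experiment_per_digit(images, cfg: RunConfig | None = None):
    """Build one single-target network per image (memory-layout study).

    Each image gets its own freshly initialized network and Structure
    Formation passes; returns the list of networks plus per-image
    memory-layer edge counts. Deterministic: the same image always yields
    the same network.
    """
    cfg = cfg or RunConfig()
    cfg = replace(cfg, layers=replace(cfg.layers, n_output=1))
    nets, rows = [], []
    for i, (img, label) in enumerate(images):
        dataset = encode_dataset([(img, 0)], cfg)
        net = build_initial_network(cfg.layers)
        structure_formation(net, dataset, cfg)
        mem_edges = sum(1 for s in net.synapses
                        if net.layer[s.pre] == "memory"
                        and net.layer[s.post] == "memory")
        nets.append(net)
        rows.append({"image": i, "label": label,
                     "memory_edges": mem_edges,
                     "total_edges": net.n_synapses})
    return nets, rows


# -- configuration files ---------------------------------------------------

_SECTIONS = {
    "encoder": EncoderConfig,
    "lif": LIFParams,
    "stdp": STDPParams,
    "growth": GrowthConfig,
    "train": TrainConfig,
    "prune": PruneConfig,
    "layers": LayerSpec,
}


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Sections ``encoder/lif/stdp/growth/train/prune/layers`` map onto the
    stage configs; a ``run`` section holds ``sf_turns``, ``sf_stdp_on``,
    ``duration_slack`` and ``seed``. Missing sections and keys keep their
    defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs[section] = cls(**raw[section])
    kwargs.update(raw.get("run", {}))
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    d = {section: asdict(getattr(cfg, section)) for section in _SECTIONS}
    d["run"] = {"sf_turns": cfg.sf_turns, "sf_stdp_on": cfg.sf_stdp_on,
                "duration_slack": cfg.duration_slack, "seed": cfg.seed}
    for sec in d.values():
        for k, v in sec.items():
            if isinstance(v, tuple):
                sec[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def write_report(report: RunReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, default=str)
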