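"""Initial three-layer network layout and the two delay mappings.

The network has 576 input neurons, 576 memory neurons (four 12x12 parts,
one per convolution kernel) and one output neuron per memorization target.
Input neurons are wired one-to-one to their homologous memory neurons at
weight 50 (strong enough that every input spike provokes a memory-layer
response); the memory layer starts with no internal connections and the
output layer starts unconnected.

Two complementary delay rules carry spatial structure through the
latency code:

* spatial-to-temporal (input -> memory): ``delay = x*p + y + 1`` turns a
  neuron's grid coordinate into a conduction delay, so position becomes
  arrival time;
* temporal-to-spatial (memory -> output): ``delay = (N_m - delay_im) + 1``
  undoes that stagger, so the two legs of every memory pathway sum to the
  constant ``N_m + 1`` and output arrivals are not smeared by the leak.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simcore import (LAYER_INPUT, LAYER_MEMORY, LAYER_OUTPUT, Network,
                      Synapse)


@dataclass(frozen=True)
class LayerSpec:
    """Layer sizes and per-part geometry of the standard network."""

    n_parts: int = 4
    part_rows: int = 12
    part_cols: int = 12
    n_output: int = 10
    #: Whether Eq.-style delays are computed per 12x12 part (default) or
    #: over the whole 576-neuron memory layer.
    delay_total_scope: str = "part"

    def __post_init__(self):
        if self.n_output < 1:
            raise ValueError("need at least one output neuron")
        if self.delay_total_scope not in ("part", "layer"):
            raise ValueError("delay_total_scope must be 'part' or 'layer'")

    @property
    def part_size(self) -> int:
        return self.part_rows * self.part_cols

    @property
    def n_input(self) -> int:
        return self.n_parts * self.part_size

    @property
    def n_memory(self) -> int:
        return self.n_input

    @property
    def n_memory_scope(self) -> int:
        """N_m used by the memory->output delay rule under the configured scope."""
        return self.part_size if self.delay_total_scope == "part" else self.n_memory


@dataclass(frozen=True)
class Coordinate:
    """Position of an input/memory neuron: kernel part plus (row, col)."""

    part: int
    x: int
    y: int


def delay_in_to_mem(c: Coordinate, p: int = 12, q: int = 12) -> int:
    """Spatial-to-temporal delay for the input->memory connection at ``c``.

    Row-major ranking plus one: ``x*p + y + 1``, giving delays 1..p*q that
    are distinct for distinct coordinates within a part.
    """
    if not (0 <= c.x < p and 0 <= c.y < q):
        raise ValueError(f"coordinate {c} outside {p}x{q} grid")
    return c.x * p + c.y + 1


def delay_mem_to_out(delay_im: int, n_m: int) -> int:
    """Temporal-to-spatial delay complementing ``delay_im``.

    ``(N_m - delay_im) + 1``, so that ``delay_im + delay_mo = N_m + 1``
    for every memory neuron: all direct input->memory->output pathways
    have equal total conduction time.
    """
    if not (1 <= delay_im <= n_m):
        raise ValueError(f"delay_im {delay_im} outside [1, {n_m}]")
    return (n_m - delay_im) + 1


def coordinate_of(net: Network, neuron: int) -> Coordinate:
    return Coordinate(net.part[neuron], net.x[neuron], net.y[neuron])


def memory_delay_im(net: Network, neuron: int, spec: LayerSpec) -> int:
    """Input->memory delay associated with a memory neuron's coordinate."""
    c = coordinate_of(net, neuron)
    d = delay_in_to_mem(c, spec.part_rows, spec.part_cols)
    if spec.delay_total_scope == "layer":
        d += c.part * spec.part_size
    return d


def build_initial_network(spec: LayerSpec | None = None,
                          w_init: float = 50.0) -> Network:
    """Create the initial network: one-to-one input->memory wiring only.

    Each of the ``n_parts * p * q`` input neurons projects to its
    homologous memory neuron with weight ``w_init`` (default 50) and the
    spatial-to-temporal delay of its coordinate; these synapses are
    non-plastic. Memory-internal and memory->output synapses do not exist
    yet — they are grown and trained later.
    """
    spec = spec or LayerSpec()
    net = Network()
    coords = [(k, x, y)
              for k in range(spec.n_parts)
              for x in range(spec.part_rows)
              for y in range(spec.part_cols)]
    input_ids = [net.add_neuron(LAYER_INPUT, part=k, x=x, y=y)
                 for k, x, y in coords]
    memory_ids = [net.add_neuron(LAYER_MEMORY, part=k, x=x, y=y)
                  for k, x, y in coords]
    for _ in range(spec.n_output):
        net.add_neuron(LAYER_OUTPUT)
    for i, mem in zip(input_ids, memory_ids):
        d = memory_delay_im(net, mem, spec)
        net.add_synapse(Synapse(pre=i, post=mem, weight=w_init,
                                delay=d, plastic=False))
    return net
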