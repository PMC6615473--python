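# memnet

Associative-memory spiking neural networks built in two phases: Hebbian
**structure formation** grows the memory, then STDP plus reinforcement
**parameter training** tunes the recall.

`memnet` is for computational-neuroscience and neuromorphic-modelling work
that asks how a spiking network can *store* specific stimuli in its wiring
rather than in trained parameters. A grayscale image is converted to a
time-to-first-spike code (stronger feature ⇒ earlier spike), played through
a three-layer leaky integrate-and-fire (LIF) network, and memorized by
growing directed synapses between memory-layer neurons that fire
near-coincidentally — neurons that fire together wire together, with spike
order fixing the direction. Recall reads the output layer as an ordered
firing sequence and decodes it by majority vote.

## The model in brief

* **Encoding** — four 4×4 oriented kernels + 2×2 max-pooling turn a 28×28
  image into 4×12×12 = 576 feature values; joint min–max normalization
  `R(d) = (d − d_min)/(d_max − d_min)` and the power latency code
  `S = (R−1)²·(T_max−T_min) + T_min` map each value to one spike in
  [0, 100] ms.
* **Network** — 576 input → 576 memory (one-to-one, weight 50, delay
  `x·p + y + 1`) → one output neuron per target (delay `(N_m − d) + 1`,
  so every direct path has equal total conduction time). LIF dynamics
  `V ← β·V + V_in`, spike when `V ≥ V_th`.
* **Growth rule** — same-part memory pairs at Euclidean distance < 2 whose
  first spikes satisfy `0 < |t₁ − t₂| < 5 ms` get a synapse (weight 10)
  from the earlier to the later firer; fired neurons are wired to the
  stimulus' output neuron at `weight/n`.
* **Training** — present each stimulus; on a wrong majority vote, every
  synapse from a fired memory neuron onto a wrong-label fired output
  neuron is multiplied by `Shrink_Coeff = 0.9` and the stimulus is
  replayed; pair-based STDP (delay-compensated, soft-bounded) stays on.
* **Pruning** — delete synapses with weight < 3 and cascade-remove inputs
  of neurons left without outputs.

See `docs/methods.md` for every parameter, default, and known limitation —
including an honest account of when multi-target recall degrades.

## Worked example

```python
import memnet as mn
from memnet.encode import image_to_spikes
from memnet.fixtures import perturb
from memnet.training import recall

img = mn.glyph_set()[6]                      # synthetic "6" glyph
trained, pruned, report = mn.run_full([(img, 0)])
print(report.edges_memory_after_sf)          # 336
print(report.recall_sequences[0])            # [0, 0, 0] -> decoded 0

noisy = perturb(img, "occlude", 0.10, seed=1)
cfg = mn.RunConfig()
res = recall(trained, image_to_spikes(noisy), duration=cfg.sim_duration,
             expected=0, lif=cfg.lif, stdp=cfg.stdp)
print(res.firing_sequence, res.decoded_label)   # [0, 0, 0] 0
```

Memorizing the "6" glyph grows 336 memory-layer synapses — the stored
memory is this wiring pattern, different for every digit:

```python
nets, rows = mn.experiment_per_digit(
    [(g, d) for d, g in enumerate(mn.glyph_set())])
print([r["memory_edges"] for r in rows])
# [265, 314, 327, 316, 320, 328, 336, 370, 301, 342]
```

Recall of the memorized image decodes to its label, and the same network
*associates*: a copy with 10 % of its pixels occluded — an image it has
never seen — still recalls the same label.

## Command line

```
memnet fixtures --out glyphs/ --seed 42
memnet preprocess --image glyphs/digit_3.png --method power --out spikes.csv
memnet init --targets 10 --out net.json
memnet grow --net net.json --spikes spikes.csv --label 3 --out net2.json
memnet run --out results/          # full pipeline on the built-in glyphs
memnet prune --net results/trained.json --threshold 3 --out pruned.json
```

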