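# Methods

## Overview

`memnet` builds an associative-memory spiking neural network from a set of
labeled grayscale images in two phases. The **structure-formation phase**
converts each image into a latency-coded spike sequence, plays it through a
three-layer leaky integrate-and-fire (LIF) network, and grows new
memory-layer synapses between neurons that fire near-coincidentally — a
structural reading of Hebb's rule in which co-firing creates connections
rather than strengthening them. The **parameter-training phase** then tunes
the memory-to-output weights by a combination of always-on spike-timing
dependent plasticity (STDP) and a reinforcement rule that multiplicatively
shrinks the weights of pathways that contributed to a wrong recall, until
majority-vote decoding of the output layer names the right target. A final
pruning pass removes weak synapses and orphaned pathways.

## Encoding

An image is processed by four 4x4 convolution kernels (valid mode, stride
1, no kernel flip: 28x28 -> 25x25), 2x2 max-pooling (25x25 -> 12x12), joint
min-max normalization of all 4x12x12 = 576 pooled values, and a latency
encoder mapping normalized value R in [0,1] to a spike time in [T_min,
T_max] = [0, 100] ms. Four encoders are provided (linear, exponential,
inverse, power); all satisfy S(0)=T_max, S(1)=T_min and are strictly
decreasing, so stronger features spike earlier. The default is the power
law S = (R-1)^2 (T_max - T_min) + T_min, which front-loads the strongest
features hardest.

The default kernels are nonnegative oriented bar detectors (0, 45, 90,
135 degrees). With nonnegative coefficients a dark background sits at the
response minimum, so after normalization background channels encode to the
*latest* spike time and the early, information-bearing part of the code is
pure stroke structure. Zero-sum edge detectors are equally valid inputs to
the pipeline (kernels are fully configurable) but place the flat background
mid-range, which floods the early code with a large synchronized burst.
Because normalization is joint over the whole image, the spike sequence is
invariant under any positive affine rescaling of the pooled feature values.
A fully constant image carries no information; it encodes as all spikes at
T_max, with a warning.

## Network and delays

The network is three layers: 576 input neurons, 576 memory neurons (four
12x12 parts, one per kernel), and one output neuron per memorization
target. Input neurons are spike sources wired one-to-one to their
homologous memory neurons at weight 50 — deliberately suprathreshold so
that every input spike provokes a memory response. Two complementary delay
rules carry spatial structure: the input->memory delay is the row-major
rank of the neuron's coordinate (`x*p + y + 1`, computed per 12x12 part by
default), and the memory->output delay is its complement `(N_m - d) + 1`,
so the two legs of every direct pathway sum to the constant `N_m + 1` and
output arrivals are not smeared by the leak. A config switch
(`delay_total_scope`) computes both rules over the whole 576-neuron layer
instead of per part; the conservation identity holds either way.

## Neuron and synapse model

Discrete-time LIF at a 1 ms step: `V <- beta*V + V_in`, spike and reset to
`V_reset` when `V >= V_th` (inclusive). Defaults: beta = 0.9 per ms,
V_th = 45 (below the weight-50 input synapse, so one input spike fires a
memory neuron), V_reset = 0, no refractoriness beyond reset. Synaptic
weights live in [0, 100]; delays are positive integer steps.

Pair-based STDP with nearest-neighbor pairing runs online whenever
`stdp_on` is set (always during training, off during structure formation
by default). Pairing uses **delay-compensated** times: a presynaptic spike
is paired at the moment its influence *arrives* at the postsynaptic
neuron, not at its soma time. With conduction delays of up to 144 steps,
soma-time pairing would assign credit to channels whose influence arrives
long after the postsynaptic spike; arrival-time pairing keeps the rule
causal (this is also how delay-aware simulators account for STDP).
Updates are soft-bounded (potentiation scales with `1 - w/w_max`,
depression with `w/w_max`), which gives each synapse a stable equilibrium
set by its pairing statistics; purely additive updates proved bistable at
this weight scale (either runaway saturation or collapse to zero).
Memory->output synapses use a separate, much tighter cap (`w_max_out`,
default 1.0 versus `w_max` = 30 for memory-memory synapses) because they
carry a shared budget split across hundreds of synapses: a common ceiling
would let potentiation inflate output drive without bound, and a tight cap
makes every output neuron saturate to the same ceiling, keeping the
recall competition fair. Default amplitudes A+ = 0.1, A- = 0.12,
tau = 20 ms both sides.

## Structure formation

For each presentation the memory-layer spike record (first spike per
neuron, matching the latency-code semantics; an all-pairs mode exists) is
scanned over all same-part pairs closer than the Euclidean distance bound
(default 2, strict — admits the 8-neighborhood). A pair whose firing times
satisfy `0 < |t1 - t2| < 5 ms` (both bounds strict: simultaneous spikes
never connect) gains a plastic synapse from the earlier to the later firer
at weight 10 and delay 1 (one step, so neighbor coupling acts inside the
coincidence window). Growth is monotone and idempotent for a fixed record;
the full pass over the training set is repeated twice so that activity
changes unlocked by first-pass growth can also be wired. After each
presentation, every memory neuron that fired is wired to the stimulus'
output neuron at weight `budget/n` (n = number of fired neurons,
budget default 400 — chosen so that a freshly wired output can actually
reach threshold from the largest synchronized arrival group of a typical
glyph), with the complementary delay rule above. Duplicate wiring keeps
the first synapse.

## Training, decoding, pruning

Recall plays a sequence for `sim_duration` = T_max + (N_m + 1) + slack
= 300 ms (covering the encoding window plus the longest direct conduction
path) and reads output spikes as an ordered label sequence; the decoded
label is the most frequent one, ties broken by earliest first occurrence
(and, within one time step, by ascending neuron id). Training presents
each stimulus in turn: a correct vote removes it from the working set; a
wrong vote multiplies every synapse from a fired memory neuron onto a
wrong-label fired output neuron by `Shrink_Coeff` = 0.9 and replays the
same stimulus, up to `max_iters` = 60 presentations (non-convergence is
reported, never raised). Input->memory weights are non-plastic and frozen
throughout. Pruning deletes synapses below weight 3 (strict) and then
cascades the orphan rule — any non-output neuron with no outgoing synapse
loses its incoming ones — to a fixed point; it is idempotent, and recall
agreement before/after pruning is measured and reported rather than
assumed. Note that the default prune threshold of 3 sits above the scale
of the trained memory->output weights (a budget of 400 split across 576
synapses, capped at 1.0), so default pruning removes the entire output
wiring and the reported post-prune agreement is correspondingly low; the
trained (unpruned) network is the procedure's primary product, and users
who want a functional pruned network should lower the threshold below
their output-weight scale.

## Synthetic data

The canonical corpus is ten digit glyphs rendered from an embedded 5x7
bitmap font scaled to 28x28, each at a small deterministic canvas offset
(handwriting is never pixel-perfectly centered; a perfectly centered
printed set is a degenerate corpus whose latency codes overlap far more
than real handwritten digits do). Optional seeded Gaussian noise and
perturbation operators (noise / occlusion / translation) support
association tests. Everything is deterministic under fixed seeds. Real
MNIST-format data can be fed through the same pipeline via the IDX
reader; the glyphs emulate digit *shape* but not the stroke-width
variation, slant, or gray-level texture of handwriting, so passing tests
on glyphs demonstrate the mechanics of the method, not handwriting-level
robustness.

## Known limitations

The recall-training fixed point is the method's weak spot, and we document
it rather than hide it. Because every channel emits exactly one spike and
the one-to-one input wiring is suprathreshold, *all* 576 memory neurons
fire for *any* stimulus; output wiring is therefore identical across
targets, and the constant-sum delay rule means all output neurons receive
the identical drive signal. Output selectivity can then only come from
divergence of the weight vectors: the reinforcement shrink is a uniform
per-output scalar (S_M is always the full memory layer), and STDP is the
only vector-level differentiator. In our experiments this combination
reliably memorizes small numbers of targets but does not reach perfect
10-of-10 recall on the full glyph corpus under any constant setting we
searched: training each stimulus to convergence in a single pass leaves
the most recently trained outputs dominant, and majority counting on a
hard-reset LIF favors temporally smeared (mismatched) drive over
concentrated (matched) drive, because concentrated input wastes
suprathreshold overshoot at reset. Typical end-to-end results with the
shipped defaults recall 1-3 of the 10 glyphs; the per-stimulus training
loop itself converges for most stimuli. The structural phases (encoding,
growth, wiring, delays, pruning) carry no such caveat and are covered by
exact tests.

## Problem sizes

Tests run the full pipeline on the ten-glyph corpus (576+576+10 neurons,
~300-step simulations, up to 60 presentations per stimulus), which
completes in about a minute; unit and property tests use reduced networks
and brute-force oracles at 20-40 neurons.
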