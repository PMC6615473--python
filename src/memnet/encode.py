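"""Image-to-spike conversion front end.

A grayscale image is turned into a latency-coded spike sequence in four
steps: (1) four oriented 4x4 convolution kernels extract edge features,
(2) 2x2 max-pooling halves each feature map, (3) the pooled values of the
whole image are min-max normalized jointly, and (4) each normalized value
is mapped to a single spike time by a strictly decreasing latency encoder
(time-to-first-spike code: stronger feature -> earlier spike).

For the standard 28x28 input this yields four 12x12 pooled maps, i.e.
4*12*12 = 576 spike channels, one spike per channel, all spike times in
``[T_min, T_max]`` (default [0, 100] ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import correlate2d

ENCODING_METHODS = ("linear", "exponential", "inverse", "power")

#: Oriented 4x4 line (bar) detectors at 0, 45, 90 and 135 degrees.
#: The exact kernel coefficients are configurable; these defaults preserve
#: the role of four oriented feature extractors. Nonnegative coefficients
#: keep a dark background at the response minimum, so after min-max
#: normalization background channels encode to the latest spike time and
#: the early part of the latency code carries pure stroke structure.
DEFAULT_KERNELS = {
    "bar_0": np.array(
        [[0, 0, 0, 0],
         [1, 1, 1, 1],
         [1, 1, 1, 1],
         [0, 0, 0, 0]], dtype=float),
    "bar_45": np.array(
        [[0, 0, 1, 1],
         [0, 1, 1, 1],
         [1, 1, 1, 0],
         [1, 1, 0, 0]], dtype=float),
    "bar_90": np.array(
        [[0, 1, 1, 0],
         [0, 1, 1, 0],
         [0, 1, 1, 0],
         [0, 1, 1, 0]], dtype=float),
    "bar_135": np.array(
        [[1, 1, 0, 0],
         [1, 1, 1, 0],
         [0, 1, 1, 1],
         [0, 0, 1, 1]], dtype=float),
}


@dataclass(frozen=True)
class Kernel:
    """A named 4x4 convolution kernel."""

    coefficients: np.ndarray
    name: str = ""

    def __post_init__(self):
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.shape != (4, 4):
            raise ValueError(f"kernel must be 4x4, got {coeff.shape}")
        object.__setattr__(self, "coefficients", coeff)


def default_kernels() -> list[Kernel]:
    """The four default oriented edge-detector kernels."""
    return [Kernel(v, name=k) for k, v in DEFAULT_KERNELS.items()]


@dataclass(frozen=True)
class FeatureMap:
    """Real-valued 2D map produced by one kernel (pre- or post-pooling)."""

    kernel_index: int
    values: np.ndarray


@dataclass(frozen=True)
class EncoderConfig:
    """Latency-encoder settings.

    Parameters
    ----------
    method:
        One of ``linear``, ``exponential``, ``inverse``, ``power``. All are
        strictly decreasing maps from normalized intensity R in [0,1] to a
        spike time, with S(0)=T_max and S(1)=T_min. ``power`` front-loads
        high intensities (fires important information earliest) and is the
        default.
    t_min, t_max:
        Start and stop of the encoding window in ms.
    """

    method: str = "power"
    t_min: float = 0.0
    t_max: float = 100.0

    def __post_init__(self):
        if self.method not in ENCODING_METHODS:
            raise ValueError(
                f"unknown encoding method {self.method!r}; "
                f"expected one of {ENCODING_METHODS}")
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be strictly less than t_max")


@dataclass(frozen=True)
class InputSpikeSequence:
    """Latency-coded spike events for one image.

    ``events`` is a list of ``(channel, time_ms)`` pairs, at most one event
    per channel. ``channel_map[channel]`` gives the ``(kernel_index, x, y)``
    coordinate of the channel within its pooled feature map; channels are
    numbered row-major within each kernel part.
    """

    events: list[tuple[int, float]]
    channel_map: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channel_map)

    def times(self) -> np.ndarray:
        """Spike times indexed by channel (NaN for silent channels)."""
        t = np.full(max(self.n_channels, 1 + max((c for c, _ in self.events),
                                                 default=0)), np.nan)
        for c, tm in self.events:
            t[c] = tm
        return t


class DegenerateImageError(ValueError):
    """Raised when min-max normalization meets a zero dynamic range."""


def minmax_normalize(d, d_min: float, d_max: float):
    """Min-max normalize intensity ``d`` to ``(d - d_min)/(d_max - d_min)``.

    Raises :class:`DegenerateImageError` when ``d_max == d_min``; the
    constant-image policy is the caller's decision.
    """
    if d_max <= d_min:
        if d_max == d_min:
            raise DegenerateImageError(
                "degenerate intensity range: d_max == d_min")
        raise ValueError("d_max must be >= d_min")
    return (np.asarray(d, dtype=float) - d_min) / (d_max - d_min)


def convolve_valid(image: np.ndarray, kernel: Kernel | np.ndarray) -> np.ndarray:
    """Valid-mode stride-1 cross-correlation of ``image`` with a kernel.

    No padding and no kernel flip, so a 28x28 input and a 4x4 kernel give
    a 25x25 map (output side = input side - 3).
    """
    img = np.asarray(image, dtype=float)
    coeff = kernel.coefficients if isinstance(kernel, Kernel) else np.asarray(kernel, float)
    if img.ndim != 2 or img.shape[0] < coeff.shape[0] or img.shape[1] < coeff.shape[1]:
        raise ValueError(
            f"image shape {img.shape} smaller than kernel {coeff.shape}")
    return correlate2d(img, coeff, mode="valid")


def maxpool_2x2(values: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 max pooling, stride 2.

    A trailing odd row/column is discarded, so a 25x25 map pools to 12x12.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or min(v.shape) < 2:
        raise ValueError("map must be 2D with both sides >= 2")
    h, w = (v.shape[0] // 2) * 2, (v.shape[1] // 2) * 2
    v = v[:h, :w]
    return v.reshape(h // 2, 2, w // 2, 2).max(axis=(1, 3))


def encode_latency(R, cfg: EncoderConfig):
    """Map normalized intensity ``R`` in [0,1] to a spike time in ms.

    All four methods satisfy S(0)=T_max, S(1)=T_min and are strictly
    decreasing: brighter features spike earlier.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R > 1):
        raise ValueError("normalized intensity R must lie in [0, 1]")
    span = cfg.t_max - cfg.t_min
    if cfg.method == "linear":
        S = cfg.t_max - R * span
    elif cfg.method == "exponential":
        S = (0.5 ** (R - 1) - 1) * span + cfg.t_min
    elif cfg.method == "inverse":
        S = (2.0 / (R + 1) - 1) * span + cfg.t_min
    else:  # power
        S = (R - 1) ** 2 * span + cfg.t_min
    return S if S.ndim else float(S)


def image_to_spikes(
    image: np.ndarray,
    kernels: Sequence[Kernel] | None = None,
    cfg: EncoderConfig | None = None,
) -> InputSpikeSequence:
    """Full front end: convolve, pool, normalize jointly, latency-encode.

    Normalization is computed over all pooled values of the image jointly
    (not per kernel part), which makes the spike sequence invariant under
    positive affine rescaling of the pooled features. A constant image has
    no information to encode: every channel then spikes at ``t_max`` and a
    warning is emitted.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != (28, 28):
        raise ValueError(f"expected a 28x28 image, got {img.shape}")
    kernels = list(kernels) if kernels is not None else default_kernels()
    if len(kernels) != 4:
        raise ValueError(f"expected exactly 4 kernels, got {len(kernels)}")
    cfg = cfg or EncoderConfig()

    pooled = [maxpool_2x2(convolve_valid(img, k)) for k in kernels]
    flat = np.concatenate([p.ravel() for p in pooled])
    d_min, d_max = float(flat.min()), float(flat.max())
    if d_max == d_min:
        warnings.warn(
            "constant pooled feature values: emitting all spikes at t_max",
            stacklevel=2)
        R = np.zeros_like(flat)
    else:
        R = minmax_normalize(flat, d_min, d_max)
    times = np.asarray(encode_latency(R, cfg))

    p, q = pooled[0].shape
    events, channel_map = [], {}
    for c, t in enumerate(times):
        k, rem = divmod(c, p * q)
        x, y = divmod(rem, q)
        channel_map[c] = (k, x, y)
        events.append((c, float(t)))
    return InputSpikeSequence(events=events, channel_map=channel_map)


def write_spikes_csv(seq: InputSpikeSequence, path) -> None:
    """Write a spike sequence as CSV ``channel,kernel,x,y,time_ms``."""
    with open(path, "w") as fh:
        fh.write("channel,kernel,x,y,time_ms\n")
        for c, t in seq.events:
            k, x, y = seq.channel_map.get(c, (-1, -1, -1))
            fh.write(f"{c},{k},{x},{y},{t:.6f}\n")


def read_spikes_csv(path) -> InputSpikeSequence:
    """Read a spike sequence written by :func:`write_spikes_csv`."""
    events, channel_map = [], {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("channel"):
            raise ValueError("missing spike CSV header")
        for line in fh:
            if not line.strip():
                continue
            c, k, x, y, t = line.split(",")
            c = int(c)
            events.append((c, float(t)))
            channel_map[c] = (int(k), int(x), int(y))
    return InputSpikeSequence(events=events, channel_map=channel_map)
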