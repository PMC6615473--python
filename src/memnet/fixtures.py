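"""Synthetic digit glyphs and standard-format readers.

The canonical test corpus is generated, not downloaded: each digit 0-9 is
rendered from an embedded 5x7 bitmap font scaled onto a 28x28 8-bit
grayscale canvas, optionally with seeded Gaussian noise and translation.
This stands in for a handwritten-digit image set while keeping every test
fully deterministic and self-contained. Real MNIST-style data can be fed
through the same pipeline via the IDX (ubyte) reader.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from PIL import Image

# 5x7 bitmap font, one string row per scanline, '1' = stroke
_FONT = {
    0: ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    1: ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    3: ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    4: ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    6: ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    7: ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    8: ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    9: ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
}

IDX_IMAGES_MAGIC = 2051
IDX_LABELS_MAGIC = 2049


@dataclass(frozen=True)
class GlyphSpec:
    """Parameters of one rendered digit glyph."""

    digit: int
    stroke_intensity: int = 255
    background: int = 0
    jitter_seed: int = 0
    noise_sd: float = 0.0
    translation: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.digit not in _FONT:
            raise ValueError("digit must be 0-9")
        for v in (self.stroke_intensity, self.background):
            if not (0 <= v <= 255):
                raise ValueError("intensities must lie in [0, 255]")


def generate_digit(spec: GlyphSpec) -> np.ndarray:
    """Render a 28x28 uint8 glyph for ``spec.digit``.

    The 5x7 font cell is scaled x4 (rows fill the canvas exactly; columns
    are centered), optionally translated, then seeded Gaussian noise of
    sd ``noise_sd`` is added and the result clipped to [0, 255].
    Deterministic for a fixed spec.
    """
    bitmap = np.array([[c == "1" for c in row] for row in _FONT[spec.digit]])
    img = np.full((28, 28), spec.background, dtype=float)
    block = np.kron(bitmap, np.ones((4, 4), dtype=bool))  # 28 x 20
    img[:, 4:24][block] = spec.stroke_intensity
    dx, dy = spec.translation
    if dx or dy:
        img = np.roll(img, (dx, dy), axis=(0, 1))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.jitter_seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


#: Deterministic per-digit canvas offsets for the canonical corpus; they
#: emulate the positional variability of handwritten digits, which are
#: never pixel-perfectly centered the way a printed font is.
DEFAULT_OFFSETS = [(-3, -2), (2, 3), (-1, 3), (3, -3), (0, 0),
                   (-3, 1), (1, -2), (3, 2), (-2, -3), (2, 0)]


def glyph_set(noise_sd: float = 0.0, seed: int = 0,
              stroke: int = 255, background: int = 0,
              offsets=None) -> list[np.ndarray]:
    """The ten digit glyphs 0-9 rendered under a common spec.

    Each digit is drawn at its own small canvas offset (handwriting is not
    perfectly centered); pass ``offsets=[(0, 0)] * 10`` for a centered set.
    """
    if offsets is None:
        offsets = DEFAULT_OFFSETS
    return [generate_digit(GlyphSpec(d, stroke_intensity=stroke,
                                     background=background,
                                     jitter_seed=seed + d,
                                     noise_sd=noise_sd,
                                     translation=offsets[d]))
            for d in range(10)]


def perturb(img: np.ndarray, mode: str, magnitude: float,
            seed: int = 0) -> np.ndarray:
    """Seeded perturbation of an image; ``magnitude`` 0 is the identity.

    Modes: ``noise`` adds Gaussian noise of sd ``magnitude``; ``occlude``
    sets a ``magnitude`` fraction of pixels (chosen uniformly without
    replacement) to 0; ``translate`` shifts by ``magnitude`` pixels along
    both axes, filling with 0.
    """
    arr = np.asarray(img)
    if magnitude == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    if mode == "noise":
        out = arr.astype(float) + rng.normal(0.0, magnitude, arr.shape)
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if mode == "occlude":
        n_pix = int(round(magnitude * arr.size))
        idx = rng.choice(arr.size, size=n_pix, replace=False)
        out = arr.copy().reshape(-1)
        out[idx] = 0
        return out.reshape(arr.shape)
    if mode == "translate":
        shift = int(round(magnitude))
        out = np.zeros_like(arr)
        src = arr[max(0, -shift):arr.shape[0] - max(0, shift),
                  max(0, -shift):arr.shape[1] - max(0, shift)]
        out[max(0, shift):max(0, shift) + src.shape[0],
            max(0, shift):max(0, shift) + src.shape[1]] = src
        return out
    raise ValueError(f"unknown perturbation mode {mode!r}")


# -- IDX (ubyte) format ----------------------------------------------------


def read_idx(path):
    """Read a big-endian IDX ubyte file (magic 2051: images, 2049: labels).

    Returns a list of 2D uint8 images, or a 1D array of labels.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 8:
        raise ValueError("truncated IDX file")
    magic, n = struct.unpack(">ii", data[:8])
    if magic == IDX_LABELS_MAGIC:
        if len(data) != 8 + n:
            raise ValueError("IDX label file length mismatch")
        return np.frombuffer(data, dtype=np.uint8, offset=8).copy()
    if magic == IDX_IMAGES_MAGIC:
        if len(data) < 16:
            raise ValueError("truncated IDX image header")
        rows, cols = struct.unpack(">ii", data[8:16])
        expected = 16 + n * rows * cols
        if len(data) != expected:
            raise ValueError("IDX image file length mismatch")
        flat = np.frombuffer(data, dtype=np.uint8, offset=16)
        return [a.copy() for a in flat.reshape(n, rows, cols)]
    raise ValueError(f"bad IDX magic {magic}")


def write_idx_images(images, path) -> None:
    images = [np.asarray(im, dtype=np.uint8) for im in images]
    rows, cols = images[0].shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">iiii", IDX_IMAGES_MAGIC, len(images), rows, cols))
        for im in images:
            if im.shape != (rows, cols):
                raise ValueError("inconsistent image shapes")
            fh.write(im.tobytes())


def write_idx_labels(labels, path) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">ii", IDX_LABELS_MAGIC, len(labels)))
        fh.write(labels.tobytes())


def read_labeled_idx(image_path, label_path):
    """Read matching IDX image/label files, checking count consistency."""
    images = read_idx(image_path)
    labels = read_idx(label_path)
    if len(images) != len(labels):
        raise ValueError(
            f"image/label count mismatch: {len(images)} vs {len(labels)}")
    return images, labels


# -- plain image files -----------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a PNG/PGM (or any Pillow-readable) image as 8-bit grayscale."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_image(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)
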