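"""Finite ridgelet transform: FRAT + per-direction 1-D wavelet.

The finite Radon transform (FRAT) of a p x p image, p prime, sums pixels over
the p + 1 families of mod-p lines

    L(k, l) = {(i, j) : j = k*i + l (mod p)},  k = 0..p-1,
    L(p, l) = {(i, j) : i = l}                 (the "vertical" family),

each family partitioning the grid, so every direction's offset sums add up to
the total pixel sum exactly. The ridgelet coefficients are obtained by running
an orthonormal 1-D discrete wavelet transform along the offset axis of each
direction. Because p is odd, each projection is zero-padded to the next power
of two before a periodized DWT; zero padding leaves the energy untouched and
the periodized DWT on a power-of-two length is exactly orthonormal, so
per-direction energy is conserved to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

from .image_io import BrainImage, ValidationError


def is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


def next_prime(n: int) -> int:
    """Smallest prime >= n."""
    candidate = max(n, 2)
    while not is_prime(candidate):
        candidate += 1
    return candidate


@dataclass(frozen=True)
class RadonProjections:
    """FRAT output: (p+1) directions x p offsets, integer line sums."""

    p: int
    proj: np.ndarray  # shape (p + 1, p), int64

    def __post_init__(self) -> None:
        if self.proj.shape != (self.p + 1, self.p):
            raise ValidationError(
                f"projection grid must be {(self.p + 1, self.p)}, got {self.proj.shape}"
            )

    @property
    def direction_labels(self) -> list[str]:
        return [f"slope_{k}" for k in range(self.p)] + ["vertical"]


@dataclass(frozen=True)
class RidgeletCoefficients:
    """Per-direction wavelet coefficients of the FRAT projections.

    ``flat_view`` is the (p+1) x padded-length grid of concatenated
    (approximation, detail_L, ..., detail_1) coefficients that the feature
    formulas consume as R(i, j). ``slices`` maps band names to column ranges
    of flat_view.
    """

    p: int
    wavelet: str
    level: int
    flat_view: np.ndarray  # shape (p + 1, padded_len)
    slices: dict

    @property
    def n_directions(self) -> int:
        return self.flat_view.shape[0]

    def band(self, name: str) -> np.ndarray:
        return self.flat_view[:, self.slices[name]]

    def to_records(self):
        """Flat (direction, band, index, value) rows for CSV export."""
        rows = []
        for name, sl in self.slices.items():
            block = self.flat_view[:, sl]
            for d in range(block.shape[0]):
                for idx in range(block.shape[1]):
                    rows.append((d, name, idx, float(block[d, idx])))
        return rows


def pad_to_prime(image: BrainImage) -> BrainImage:
    """Zero-pad to a square whose side is the smallest prime >= max(h, w).

    Original content stays at the top-left; padding is 0 (black, like the air
    background of an MRI slice), which keeps the FRAT partition sums exact.
    """
    side = next_prime(max(image.height, image.width))
    if image.height == side and image.width == side:
        return image
    out = np.zeros((side, side), dtype=np.uint8)
    out[: image.height, : image.width] = image.pixels
    return BrainImage(out, source_id=image.source_id)


def frat(image: BrainImage) -> RadonProjections:
    """Finite Radon transform of a prime-side square image."""
    if image.height != image.width:
        raise ValidationError(
            f"frat requires a square image, got {image.height}x{image.width}"
        )
    p = image.height
    if not is_prime(p):
        raise ValidationError(
            f"frat requires a prime side, got {p}; apply pad_to_prime first"
        )
    px = image.pixels.astype(np.int64)
    proj = np.empty((p + 1, p), dtype=np.int64)
    rows = np.arange(p)
    offsets = np.arange(p)
    for k in range(p):
        # columns hit by line j = k*i + l (mod p), one per (row, offset)
        cols = (k * rows[:, None] + offsets[None, :]) % p
        proj[k] = px[rows[:, None], cols].sum(axis=0)
    proj[p] = px.sum(axis=1)  # lines of constant i
    return RadonProjections(p=p, proj=proj)


def _padded_length(p: int) -> int:
    return 1 << max(1, math.ceil(math.log2(p)))


def ridgelet_forward(
    image: BrainImage, wavelet: str = "haar", level: int | None = None
) -> RidgeletCoefficients:
    """Finite ridgelet transform of any non-empty image.

    Pads to prime side internally, takes the FRAT, zero-pads each projection
    to the next power of two and applies a periodized 1-D DWT along the
    offset axis (depth floor(log2 p) by default).
    """
    padded = pad_to_prime(image)
    projections = frat(padded)
    p = projections.p
    if level is None:
        level = int(math.floor(math.log2(p)))
    n = _padded_length(p)
    level = min(level, int(math.log2(n)))
    data = np.zeros((p + 1, n), dtype=np.float64)
    data[:, :p] = projections.proj
    coeffs = pywt.wavedec(data, wavelet, mode="periodization", level=level, axis=1)
    names = ["approx"] + [f"detail_{level - i}" for i in range(level)]
    slices = {}
    start = 0
    for name, block in zip(names, coeffs):
        slices[name] = slice(start, start + block.shape[1])
        start += block.shape[1]
    flat = np.concatenate(coeffs, axis=1)
    return RidgeletCoefficients(
        p=p, wavelet=wavelet, level=level, flat_view=flat, slices=slices
    )
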