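"""Five pixel-intensity features of the ridgelet coefficient grid.

For a real matrix R with C1 rows and C2 columns and 1-based indices i, j:

    PIF = sum R(i,j)^2                      / (C1^2 * C2^2)
    PVF = [sum (R-i)^2 + sum (R-j)^2]       / (C1 * C2)
    PMF = sum R(i,j)                        / (C1 * C2)
    FIF = sum R(i,j) * i * j                / ((C1+1) * (C2+1))
    SIF = sum R(i,j) * i^2 * j^2            / ((C1+1)^2 * (C2+1)^2)

The index terms in the denominators are evaluated at the matrix extents, which
turns each formula into a single normalized global statistic of R. PVF mixes
coefficient values with raw indices, so it is sensitive to the orientation of
R; rows are directions and columns are coefficient indices throughout this
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image_io import ValidationError
from .ridgelet import RidgeletCoefficients

FEATURE_NAMES = ("pif", "pvf", "pmf", "fif", "sif")


def _as_matrix(R) -> np.ndarray:
    R = np.asarray(R, dtype=np.float64)
    if R.ndim != 2 or R.size == 0:
        raise ValidationError(f"feature input must be a non-empty 2-D matrix, got shape {R.shape}")
    return R


def _index_grids(c1: int, c2: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, c1 + 1, dtype=np.float64)[:, None]
    j = np.arange(1, c2 + 1, dtype=np.float64)[None, :]
    return i, j


def pif(R) -> float:
    """Pixel Intensity Feature: mean-square energy normalized by (C1*C2)^2."""
    R = _as_matrix(R)
    c1, c2 = R.shape
    return float((R**2).sum() / (c1**2 * c2**2))


def pvf(R) -> float:
    """Pixel Variation Feature: squared deviation from the index ramps."""
    R = _as_matrix(R)
    c1, c2 = R.shape
    i, j = _index_grids(c1, c2)
    num = ((R - i) ** 2).sum() + ((R - j) ** 2).sum()
    return float(num / (c1 * c2))


def pmf(R) -> float:
    """Pixel Mean Feature: the plain mean of R."""
    R = _as_matrix(R)
    return float(R.mean())


def fif(R) -> float:
    """First-order Intensity Feature: index-weighted sum over (C1+1)(C2+1)."""
    R = _as_matrix(R)
    c1, c2 = R.shape
    i, j = _index_grids(c1, c2)
    return float((R * i * j).sum() / ((c1 + 1) * (c2 + 1)))


def sif(R) -> float:
    """Second-order Intensity Feature: squared-index weighting."""
    R = _as_matrix(R)
    c1, c2 = R.shape
    i, j = _index_grids(c1, c2)
    return float((R * i**2 * j**2).sum() / ((c1 + 1) ** 2 * (c2 + 1) ** 2))


_FEATURE_FUNCS = {"pif": pif, "pvf": pvf, "pmf": pmf, "fif": fif, "sif": sif}


@dataclass(frozen=True)
class FeatureVector:
    """The five scalars, in the canonical (pif, pvf, pmf, fif, sif) order."""

    pif: float
    pvf: float
    pmf: float
    fif: float
    sif: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("feature values must be finite")
        if self.pvf < 0:
            raise ValidationError("pvf is a sum of squares and cannot be negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.pif, self.pvf, self.pmf, self.fif, self.sif])

    def subset(self, names) -> np.ndarray:
        return np.array([getattr(self, n) for n in names])


def feature_vector(coeffs: RidgeletCoefficients) -> FeatureVector:
    """Compute all five features on the flat coefficient grid."""
    R = coeffs.flat_view
    return FeatureVector(pif(R), pvf(R), pmf(R), fif(R), sif(R))


@dataclass(frozen=True)
class FeatureMap:
    """Aligned 2-D feature channels computed on sliding blocks of flat_view."""

    channels: np.ndarray  # (n_features, U, V)
    feature_names: tuple
    block: int
    stride: int

    def __post_init__(self) -> None:
        if self.channels.shape[0] != len(self.feature_names):
            raise ValidationError("one channel per feature name required")


def _batched_features(blocks: np.ndarray, names) -> np.ndarray:
    """Features of a stack of b x b blocks, shape (..., b, b) -> (F, ...).

    Uses the same direct double-sum formulas as the scalar functions, applied
    over the trailing two axes.
    """
    b1, b2 = blocks.shape[-2:]
    i, j = _index_grids(b1, b2)
    out = []
    for name in names:
        if name == "pif":
            out.append((blocks**2).sum(axis=(-2, -1)) / (b1**2 * b2**2))
        elif name == "pvf":
            num = ((blocks - i) ** 2).sum(axis=(-2, -1)) + ((blocks - j) ** 2).sum(
                axis=(-2, -1)
            )
            out.append(num / (b1 * b2))
        elif name == "pmf":
            out.append(blocks.mean(axis=(-2, -1)))
        elif name == "fif":
            out.append((blocks * (i * j)).sum(axis=(-2, -1)) / ((b1 + 1) * (b2 + 1)))
        elif name == "sif":
            out.append(
                (blocks * (i**2 * j**2)).sum(axis=(-2, -1))
                / ((b1 + 1) ** 2 * (b2 + 1) ** 2)
            )
        else:
            raise ValidationError(f"unknown feature {name!r}")
    return np.stack(out, axis=0)


def blockwise_feature_maps(
    coeffs: RidgeletCoefficients,
    block: int = 8,
    stride: int = 4,
    features=FEATURE_NAMES,
) -> FeatureMap:
    """Evaluate each feature on a sliding block grid of flat_view.

    Channel f at cell (u, v) is feature f of the block x block window with
    top-left corner (u*stride, v*stride). This turns the scalar features into
    a multi-channel 2-D input for the convolutional classifier.
    """
    if block < 2:
        raise ValidationError("block must be >= 2")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    R = coeffs.flat_view
    if block > R.shape[0] or block > R.shape[1]:
        raise ValidationError(
            f"block {block} larger than flat_view {R.shape}"
        )
    windows = sliding_window_view(R, (block, block))[::stride, ::stride]
    channels = _batched_features(windows, tuple(features))
    return FeatureMap(
        channels=np.ascontiguousarray(channels),
        feature_names=tuple(features),
        block=block,
        stride=stride,
    )
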