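"""Image and manifest IO.

Everything downstream works on 8-bit grayscale slices, so this module owns the
normalisation contract: whatever comes in (8-bit PNG, 16-bit PNG, floating-point
NIfTI volume) leaves as a :class:`BrainImage` with integer intensities in
[0, 255].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from PIL import Image as PILImage

MENINGIOMA = "meningioma"
NON_MENINGIOMA = "non_meningioma"
LABELS = (MENINGIOMA, NON_MENINGIOMA)
SPLITS = ("train", "test")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class BrainImage:
    """A 2-D 8-bit grayscale slice.

    ``pixels`` is a uint8 array of shape (height, width); ``source_id`` is a
    free-form provenance tag (file stem, phantom seed, ...).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise ValidationError("zero-area image")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError(f"pixels must be integer, got dtype {px.dtype}")
        if px.min() < 0 or px.max() > 255:
            raise ValidationError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    label: str
    mask_path: Optional[str] = None
    split: str = "train"


@dataclass(frozen=True)
class DatasetManifest:
    """Dataset description: one record per image, two classes, two splits."""

    records: tuple[ManifestRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for i, rec in enumerate(self.records):
            if rec.label not in LABELS:
                raise ValidationError(
                    f"record {i}: unknown label {rec.label!r}; allowed: {LABELS}"
                )
            if rec.split not in SPLITS:
                raise ValidationError(
                    f"record {i}: unknown split {rec.split!r}; allowed: {SPLITS}"
                )
            prev = seen.get(rec.image_path)
            if prev is not None and prev != rec.split:
                raise ValidationError(
                    f"image path {rec.image_path!r} appears in both splits"
                )
            seen[rec.image_path] = rec.split

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(tuple(r for r in self.records if r.split == split))

    def __len__(self) -> int:
        return len(self.records)


def _rescale_to_uint8(data: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255] and round half-up.

    Data already integral and within [0, 255] is passed through unchanged,
    so 8-bit sources round-trip exactly.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValidationError("image contains non-finite values")
    if np.allclose(data, np.rint(data)) and data.min() >= 0 and data.max() <= 255:
        return np.rint(data).astype(np.uint8)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros(data.shape, dtype=np.uint8)
    scaled = (data - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up


def load_image(path: str, slice_index: int = 0) -> BrainImage:
    """Read a PNG or NIfTI file as a :class:`BrainImage`.

    3-D NIfTI volumes are reduced to a single 2-D slice along the first axis
    (``slice_index``, default 0). Non-8-bit data is min-max rescaled to
    [0, 255] with round-half-up.
    """
    if not os.path.exists(path):
        raise IOError(f"cannot read image: no such file {path!r}")
    source_id = os.path.splitext(os.path.basename(path))[0]
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asarray(nib.load(path).get_fdata())
        if vol.ndim == 3:
            if not 0 <= slice_index < vol.shape[0]:
                raise ValidationError(
                    f"slice_index {slice_index} out of range for volume {vol.shape}"
                )
            vol = vol[slice_index]
        if vol.ndim != 2:
            raise ValidationError(f"unsupported NIfTI dimensionality: {vol.ndim}")
        data = vol
    else:
        try:
            with PILImage.open(path) as im:
                if im.mode not in ("L", "I", "I;16", "F"):
                    im = im.convert("L")
                data = np.asarray(im)
        except Exception as exc:  # noqa: BLE001 - re-raise with the path
            raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-area image: {path!r}")
    return BrainImage(_rescale_to_uint8(data), source_id=source_id)


def save_image(image: BrainImage, path: str) -> None:
    """Write an 8-bit grayscale PNG; inverse of :func:`load_image` on pixels."""
    PILImage.fromarray(image.pixels, mode="L").save(path, format="PNG")


def save_mask(mask, path: str) -> None:
    """Write a binary mask as a 0/255 grayscale PNG.

    Round-trips losslessly through :func:`load_mask` / :func:`load_image`.
    """
    arr = np.asarray(getattr(mask, "mask", mask))
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"mask must be non-empty 2-D, got shape {arr.shape}")
    png = np.where(arr.astype(bool), 255, 0).astype(np.uint8)
    try:
        PILImage.fromarray(png, mode="L").save(path, format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write mask to {path!r}: {exc}") from exc


def load_mask(path: str) -> np.ndarray:
    """Read a 0/255 PNG mask back as a boolean array."""
    return load_image(path).pixels > 127


def load_manifest(path: str) -> DatasetManifest:
    """Parse a manifest CSV with header image_path,label,mask_path,split.

    Relative image/mask paths are resolved against the CSV's own directory.
    """
    import pandas as pd

    if not os.path.exists(path):
        raise IOError(f"no such manifest: {path!r}")
    df = pd.read_csv(path, dtype=str)
    required = {"image_path", "label", "mask_path", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p: Optional[str]) -> Optional[str]:
        if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
            return None
        return p if os.path.isabs(p) else os.path.join(base, p)

    records = []
    for idx, row in df.iterrows():
        label = row["label"]
        if label not in LABELS:
            raise ValidationError(f"manifest row {idx}: unknown label {label!r}")
        records.append(
            ManifestRecord(
                image_path=_resolve(row["image_path"]),
                label=label,
                mask_path=_resolve(row.get("mask_path")),
                split=row["split"],
            )
        )
    return DatasetManifest(tuple(records))


def write_manifest(manifest: DatasetManifest, path: str, relative_to: Optional[str] = None) -> None:
    """Write a manifest CSV; paths can be stored relative to a base directory."""
    import pandas as pd

    def _rel(p: Optional[str]) -> str:
        if p is None:
            return ""
        return os.path.relpath(p, relative_to) if relative_to else p

    df = pd.DataFrame(
        {
            "image_path": [_rel(r.image_path) for r in manifest.records],
            "label": [r.label for r in manifest.records],
            "mask_path": [_rel(r.mask_path) for r in manifest.records],
            "split": [r.split for r in manifest.records],
        }
    )
    df.to_csv(path, index=False)
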