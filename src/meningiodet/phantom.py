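"""Synthetic brain-slice phantoms with exact ground truth.

Each phantom is a 2-D 8-bit slice with the structure the detection method
assumes: black air background, a bright smooth skull/cortex annulus, noisy
brain parenchyma, and — for the meningioma class — one compact tumor blob of
markedly LOWER intensity than the surrounding parenchyma. Region transitions
are smooth ramps a few pixels wide, mimicking the partial-volume smoothing of
real MRI rather than artificial step edges.

The generator is the package's stand-in for clinical datasets; it makes no
claim of radiological realism, only of reproducing the intensity structure
(dark compact tumor, textured parenchyma, bright rim) that the classifier and
segmenter rely on. Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .image_io import (
    BrainImage,
    DatasetManifest,
    ManifestRecord,
    MENINGIOMA,
    NON_MENINGIOMA,
    ValidationError,
    save_image,
    save_mask,
    write_manifest,
)
from .segmentation import SegmentationMask

# radial layout of the slice, in units of the brain ellipse radius. Region
# transitions are smooth ramps several pixels wide (partial-volume blur);
# the skull annulus is a flat plateau wider than typical structuring
# elements, so grayscale opening/closing leave it untouched.
_R_NOISE_FADE = 0.66  # parenchyma texture starts fading
_R_PARENCHYMA = 0.74  # parenchyma plateau ends
_R_SKULL_IN = 0.86  # inner edge of the skull plateau (ramp in between)
_R_SKULL_OUT = 0.97  # outer edge of the skull plateau
_R_EDGE = 1.18  # slice fades to background
_TEXTURE_CORR = 1.5  # Gaussian correlation length (px) of parenchyma texture


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity bands of the synthetic slice.

    ``tumor_band`` must sit below the parenchyma mean: meningiomas are
    emulated as low-intensity blobs.
    """

    size: int = 128
    skull_band: tuple = (200, 255)
    parenchyma_mean: float = 120.0
    parenchyma_sd: float = 10.0
    tumor_radius: tuple = (8, 20)
    tumor_band: tuple = (60, 95)
    irregular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValidationError("phantom size must be >= 32 pixels")
        if self.tumor_band[1] >= self.parenchyma_mean:
            raise ValidationError(
                "tumor intensity band must lie below the parenchyma mean"
            )
        if self.tumor_radius[0] < 1 or self.tumor_radius[1] < self.tumor_radius[0]:
            raise ValidationError("invalid tumor radius range")
        if self.tumor_radius[1] > self.size // 4:
            raise ValidationError("tumor radius range too large for the image")


@dataclass(frozen=True)
class LabeledPhantom:
    image: BrainImage
    label: str
    mask: SegmentationMask

    def __post_init__(self) -> None:
        nonempty = self.mask.area > 0
        if nonempty != (self.label == MENINGIOMA):
            raise ValidationError("mask must be nonempty iff label is meningioma")


def _radial(spec: PhantomSpec):
    size = spec.size
    cy = cx = (size - 1) / 2.0
    # head fits fully inside the frame, fade ring included (ay * _R_EDGE < size/2)
    ay, ax = 0.40 * size, 0.34 * size
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    rho = np.sqrt(((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2)
    return rho, (cy, cx), (ay, ax)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


def _base_profile(rho: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Noise-free radial intensity profile of the slice.

    Parenchyma plateau, smooth ramp up to a flat skull annulus at the middle
    of the skull intensity band, smooth fade down to black air.
    """
    skull_value = float(round(0.5 * (spec.skull_band[0] + spec.skull_band[1])))
    base = np.zeros_like(rho)
    base += spec.parenchyma_mean * (rho < _R_PARENCHYMA)
    ramp = (rho >= _R_PARENCHYMA) & (rho < _R_SKULL_IN)
    t = (rho - _R_PARENCHYMA) / (_R_SKULL_IN - _R_PARENCHYMA)
    base += ramp * (
        spec.parenchyma_mean + (skull_value - spec.parenchyma_mean) * _smoothstep(t)
    )
    base += skull_value * ((rho >= _R_SKULL_IN) & (rho < _R_SKULL_OUT))
    fade = (rho >= _R_SKULL_OUT) & (rho < _R_EDGE)
    tf = (rho - _R_SKULL_OUT) / (_R_EDGE - _R_SKULL_OUT)
    base += fade * (skull_value * (1.0 - _smoothstep(tf)))
    return base


def _parenchyma_texture(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Spatially correlated zero-mean texture field with empirical sd = sd.

    Healthy parenchyma texture varies smoothly at the millimetre scale, so
    white pixel noise would be sensor noise, not tissue texture; a
    Gaussian-correlated field is used instead.
    """
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.normal(size=shape), _TEXTURE_CORR, mode="wrap")
    field -= field.mean()
    return field / field.std() * sd


def _tumor_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Draw a tumor centre and radius fully inside the parenchyma plateau."""
    size = spec.size
    _, (cy, cx), (ay, ax) = _radial(spec)
    radius = int(rng.integers(spec.tumor_radius[0], spec.tumor_radius[1] + 1))
    # margin keeps the (possibly perturbed) boundary inside the plateau
    slack = 1.3 if spec.irregular else 1.0
    max_rho = _R_PARENCHYMA - (slack * radius + 2) / min(ay, ax)
    if max_rho <= 0:
        raise ValidationError(
            f"tumor of radius {radius} cannot fit inside the brain of size {size}"
        )
    while True:
        r0 = cy + rng.uniform(-1, 1) * max_rho * ay
        c0 = cx + rng.uniform(-1, 1) * max_rho * ax
        rho0 = np.sqrt(((r0 - cy) / ay) ** 2 + ((c0 - cx) / ax) ** 2)
        if rho0 <= max_rho:
            return (r0, c0), radius


def _tumor_mask(spec: PhantomSpec, center, radius, rng) -> np.ndarray:
    size = spec.size
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    dy, dx = rows - center[0], cols - center[1]
    if not spec.irregular:
        return dy**2 + dx**2 <= radius**2
    theta = np.arctan2(dy, dx)
    r_theta = np.full_like(theta, float(radius))
    for harmonic in (2, 3, 5):
        amp = rng.uniform(0.0, 0.12) * radius
        phase = rng.uniform(0, 2 * np.pi)
        r_theta = r_theta + amp * np.sin(harmonic * theta + phase)
    return dy**2 + dx**2 <= r_theta**2


def generate_phantom(spec: PhantomSpec, with_tumor: bool) -> LabeledPhantom:
    """Render one phantom slice (and its exact mask when a tumor is placed).

    The tumor blob is filled with the base intensity drawn from the tumor
    band plus an uncorrelated zero-mean texture of the same sd as the
    parenchyma (tumor tissue is heterogeneous at the pixel scale). Both
    texture fields are empirically zero-mean, so the blob's mean intensity
    equals its base and the plateau's mean equals the parenchyma mean.
    """
    rng = np.random.default_rng(spec.seed)
    rho, _, _ = _radial(spec)
    base = _base_profile(rho, spec)

    # correlated parenchyma texture, faded out before the skull ramp begins;
    # recentred over the plateau so the parenchyma mean is the configured mean
    noise = _parenchyma_texture(rng, base.shape, spec.parenchyma_sd)
    plateau = rho < _R_PARENCHYMA
    noise -= noise[plateau].mean()
    fade = np.clip((_R_PARENCHYMA - rho) / (_R_PARENCHYMA - _R_NOISE_FADE), 0.0, 1.0)
    img = base + noise * fade * plateau

    mask = np.zeros(base.shape, dtype=bool)
    if with_tumor:
        center, radius = _tumor_geometry(spec, rng)
        mask = _tumor_mask(spec, center, radius, rng)
        lo, hi = spec.tumor_band
        tumor_base = float(rng.integers(lo, hi))  # half-open band, stays < hi
        tumor_noise = rng.normal(0.0, spec.parenchyma_sd, size=base.shape)
        tumor_noise -= tumor_noise[mask].mean()
        img = np.where(mask, tumor_base + tumor_noise, img)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    label = MENINGIOMA if with_tumor else NON_MENINGIOMA
    return LabeledPhantom(
        image=BrainImage(pixels, source_id=f"phantom_seed{spec.seed}_{label}"),
        label=label,
        mask=SegmentationMask(mask),
    )


def _derived_seed(master: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n_per_class: int, spec: PhantomSpec, out_dir: str
) -> DatasetManifest:
    """Write a balanced phantom dataset (PNGs + masks + manifest CSV).

    The split is 50/50 train/test, stratified by class; per-image seeds are
    derived deterministically from the master seed, so regenerating with the
    same spec reproduces identical files.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir!r}: {exc}") from exc

    records = []
    for class_idx, (label, with_tumor) in enumerate(
        [(MENINGIOMA, True), (NON_MENINGIOMA, False)]
    ):
        for i in range(n_per_class):
            sub = replace(spec, seed=_derived_seed(spec.seed, class_idx, i))
            ph = generate_phantom(sub, with_tumor=with_tumor)
            stem = f"{label}_{i:04d}"
            image_path = os.path.join(out_dir, f"{stem}.png")
            save_image(ph.image, image_path)
            mask_path = None
            if with_tumor:
                mask_path = os.path.join(out_dir, f"{stem}_mask.png")
                save_mask(ph.mask, mask_path)
            split = "train" if i < (n_per_class + 1) // 2 else "test"
            records.append(
                ManifestRecord(
                    image_path=image_path, label=label, mask_path=mask_path, split=split
                )
            )
    manifest = DatasetManifest(tuple(records))
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"), relative_to=out_dir)
    return manifest
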