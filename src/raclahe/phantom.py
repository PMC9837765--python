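"""Synthetic prostate-like T2 MRI phantoms with WG/TZ/PZ masks.

Each synthetic patient is a stack of 256 x 256 slices containing an
elliptical whole gland (WG) whose peripheral shell (PZ) is brighter than
its transitional core (TZ) — the bright-rim appearance of T2-weighted
prostate MRI.  The mask algebra follows the dataset convention
TZ inside WG, PZ = WG minus TZ.  Slices share a patient-level geometry
with small per-slice axis jitter.  Intensities are region means plus
Gaussian texture, corrupted by a smooth multiplicative bias field (a
single low-frequency Gaussian bump, enough to defeat any global
histogram remap) and Rician noise (the modulus of a complex Gaussian
perturbation, the noise law of magnitude MR images), then clipped and
rounded onto the 8-bit gray-level grid.

A classical threshold-based segmenter (:func:`baseline_segment`) serves
as a deterministic stand-in for a trained segmentation model, so the
effect of enhancement on downstream segmentation is measurable without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .pipeline import RaclaheParams, RegionBox, apply_raclahe, propose_region_from_mask
from .seg_metrics import overlap_metrics, confusion_counts
from .volio import Frame, MaskStack


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic patient cohort.

    Geometry is in pixels, intensities in gray levels of the quantized
    [0, levels-1] domain.  ``noise_sigma`` is the scale of the complex
    Gaussian perturbation whose modulus gives Rician noise;
    ``bias_amplitude`` is the peak relative deviation of the
    multiplicative bias field (0.3 = up to +30% brightness on one side).
    """

    frame_shape: tuple[int, int] = (256, 256)
    slices_per_patient: int = 15
    wg_semiaxis_range: tuple[float, float] = (42.0, 62.0)
    wg_center_jitter: float = 10.0
    slice_axis_jitter: float = 0.05
    tz_fraction: float = 0.55
    background_mean: float = 80.0
    tz_mean: float = 100.0
    pz_mean: float = 110.0
    texture_sd: float = 4.0
    noise_sigma: float = 8.0
    bias_amplitude: float = 0.4
    bias_sigma: float = 90.0
    levels: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.tz_fraction < 1:
            raise ValueError("tz_fraction must lie in (0, 1)")
        if self.texture_sd < 0 or self.noise_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        for m in (self.background_mean, self.tz_mean, self.pz_mean):
            if not 0 <= m <= self.levels - 1:
                raise ValueError("intensity means must lie in the quantization range")
        rows, cols = self.frame_shape
        if 2 * self.wg_semiaxis_range[1] + 2 * self.wg_center_jitter >= min(rows, cols):
            raise ValueError("gland geometry exceeds the frame")


def low_contrast_spec(**overrides) -> PhantomSpec:
    """The hard preset: TZ/PZ mean gap of 10 gray levels, Rician noise
    sigma 8, modest gland/background contrast, and a bias field strong
    and narrow enough (peak +60%, length scale 40 px) to vary across the
    gland region, so a single threshold inside the region misclassifies."""
    return replace(PhantomSpec(
        background_mean=80.0, tz_mean=100.0, pz_mean=110.0,
        noise_sigma=8.0, bias_amplitude=0.6, bias_sigma=40.0,
    ), **overrides)


def high_contrast_spec(**overrides) -> PhantomSpec:
    """The easy preset: bright gland on a dark background, mild noise and bias."""
    return replace(PhantomSpec(
        background_mean=30.0, tz_mean=150.0, pz_mean=180.0,
        noise_sigma=4.0, bias_amplitude=0.1,
    ), **overrides)


PRESETS = {"low-contrast": low_contrast_spec, "high-contrast": high_contrast_spec}


@dataclass
class SyntheticPatient:
    patient_id: str
    frames: list[Frame]
    masks: dict[str, MaskStack]  # keys WG, TZ, PZ
    spec: PhantomSpec


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             semiaxes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = semiaxes
    return (((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2) <= 1.0


def generate_patient(spec: PhantomSpec, patient_seed: int, patient_id: str = "P000") -> SyntheticPatient:
    """Deterministically generate one patient from (spec, patient_seed)."""
    rng = np.random.default_rng(patient_seed)
    rows, cols = spec.frame_shape
    center = (
        rows / 2 + rng.uniform(-spec.wg_center_jitter, spec.wg_center_jitter),
        cols / 2 + rng.uniform(-spec.wg_center_jitter, spec.wg_center_jitter),
    )
    base_axes = rng.uniform(*spec.wg_semiaxis_range, size=2)
    bias_center = (rows / 2 + rng.uniform(-rows / 4, rows / 4),
                   cols / 2 + rng.uniform(-cols / 4, cols / 4))
    rr, cc = np.ogrid[:rows, :cols]
    d2 = (rr - bias_center[0]) ** 2 + (cc - bias_center[1]) ** 2
    bias = 1.0 + spec.bias_amplitude * np.exp(-d2 / (2 * spec.bias_sigma ** 2))

    frames: list[Frame] = []
    wg_masks, tz_masks, pz_masks = [], [], []
    for _ in range(spec.slices_per_patient):
        scale = 1.0 + rng.uniform(-spec.slice_axis_jitter, spec.slice_axis_jitter, size=2)
        axes = np.clip(base_axes * scale, 4.0, None)
        wg = _ellipse(spec.frame_shape, center, tuple(axes))
        tz = _ellipse(spec.frame_shape, center, tuple(axes * spec.tz_fraction))
        tz &= wg
        pz = wg & ~tz

        img = np.full(spec.frame_shape, spec.background_mean, dtype=float)
        img[tz] = spec.tz_mean
        img[pz] = spec.pz_mean
        if spec.texture_sd > 0:
            img += rng.normal(0.0, spec.texture_sd, size=spec.frame_shape)
        img *= bias
        if spec.noise_sigma > 0:
            g1 = rng.normal(0.0, spec.noise_sigma, size=spec.frame_shape)
            g2 = rng.normal(0.0, spec.noise_sigma, size=spec.frame_shape)
            img = np.sqrt((img + g1) ** 2 + g2 ** 2)
        px = np.clip(np.round(img), 0, spec.levels - 1).astype(np.int64)
        frames.append(Frame(px, spec.levels))
        wg_masks.append(wg.astype(np.uint8))
        tz_masks.append(tz.astype(np.uint8))
        pz_masks.append(pz.astype(np.uint8))

    masks = {
        "WG": MaskStack(wg_masks, "WG"),
        "TZ": MaskStack(tz_masks, "TZ"),
        "PZ": MaskStack(pz_masks, "PZ"),
    }
    return SyntheticPatient(patient_id=patient_id, frames=frames, masks=masks, spec=spec)


def generate_cohort(spec: PhantomSpec, n_patients: int, seed: int) -> list[SyntheticPatient]:
    """Reproducible cohort; patient seeds derive from the master seed."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    patient_seeds = rng.integers(0, 2**31 - 1, size=n_patients)
    return [
        generate_patient(spec, int(s), patient_id=f"P{i:03d}")
        for i, s in enumerate(patient_seeds)
    ]


def baseline_segment(frame: Frame, roi: RegionBox) -> np.ndarray:
    """Otsu threshold inside the ROI, 3x3 opening, largest connected component.

    Pixels outside the ROI are background; a constant ROI yields an empty
    mask.
    """
    if roi.frame_shape != frame.shape:
        raise ValueError("roi frame_shape does not match frame")
    crop = frame.pixels[roi.slices]
    out = np.zeros(frame.shape, dtype=np.uint8)
    if crop.min() == crop.max():
        return out
    fg = crop > threshold_otsu(crop)
    fg = ndimage.binary_opening(fg, structure=np.ones((3, 3), dtype=bool))
    labels, n = ndimage.label(fg)
    if n == 0:
        return out
    largest = 1 + np.argmax(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1)))
    out[roi.slices] = (labels == largest).astype(np.uint8)
    return out


def enhancement_demo(
    spec: PhantomSpec | None = None,
    n_slices: int = 50,
    seed: int = 42,
    params: RaclaheParams | None = None,
    margin: int = 20,
) -> dict:
    """Measure baseline-segmenter Dice on raw vs RACLAHE-enhanced frames.

    Generates enough low-contrast patients to cover ``n_slices`` slices,
    proposes the gland region from the WG mask, segments each slice with
    the classical baseline before and after enhancement, and reports the
    mean whole-gland Dice of both conditions.

    The default enhancement uses the standard (clipped, interpolated)
    CLAHE mode with 64-px tiles: tiles must sit between the noise
    correlation scale and the bias-field length scale for a *threshold*
    segmenter to benefit.  The literal per-8-px-patch mode targets local
    texture contrast for CNN feature extraction and is actively harmful
    to a global in-region threshold.
    """
    spec = spec or low_contrast_spec()
    params = params or RaclaheParams(clahe_mode="standard", clip_limit=0.02, patch_size=64)
    n_patients = -(-n_slices // spec.slices_per_patient)
    cohort = generate_cohort(spec, n_patients, seed)
    ds_raw, ds_enh = [], []
    for patient in cohort:
        for frame, wg in zip(patient.frames, patient.masks["WG"].frames):
            if len(ds_raw) >= n_slices:
                break
            region = propose_region_from_mask(wg, params, margin=margin)
            pred_raw = baseline_segment(frame, region)
            enhanced = apply_raclahe(frame, region, params)
            pred_enh = baseline_segment(enhanced, region)
            ds_raw.append(overlap_metrics(confusion_counts(pred_raw, wg))["DS"])
            ds_enh.append(overlap_metrics(confusion_counts(pred_enh, wg))["DS"])
    return {
        "n_slices": len(ds_raw),
        "mean_ds_raw": float(np.mean(ds_raw)),
        "mean_ds_enhanced": float(np.mean(ds_enh)),
    }
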