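"""Histogram-based frame enhancers: HE, CLAHE, AGCWD, AGCCPF, RLBHE.

The core primitive is per-patch histogram equalization: within a patch of
``TotNum`` pixels the probability of each level is ``P(i) = Num(i)/TotNum``,
its cumulative distribution ``CDF(i)``, and the equalized level
``round((L-1) * CDF(i))``.  Everything else in this module is a different
way of building a per-level lookup table from a histogram:

* ``global_he``   — the whole frame as one patch.
* ``clahe``       — per-tile equalization; the *literal* mode equalizes
  every tile independently and pastes the results, the *standard* mode is
  classic contrast-limited CLAHE (histogram clipping with uniform excess
  redistribution, bilinear blending of neighboring tile mappings).
* ``agcwd``       — adaptive gamma correction: a per-level gamma
  ``1 - cdf_w(l)`` from a weighting-distribution-transformed pdf.
* ``agccpf``      — blends the input histogram with a uniform one before
  the AGCWD gamma stage (the color-restoration stage of the original
  method is the identity on grayscale).
* ``rlbhe``       — bi-histogram equalization split at the Otsu threshold,
  with the two output ranges chosen to preserve mean brightness.

All enhancers map a :class:`~raclahe.volio.Frame` to a Frame of identical
shape and level count, and every per-level mapping is monotone
non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rounding import round_levels
from .volio import Frame

logger = logging.getLogger(__name__)


@dataclass
class PatchHistogram:
    """Occurrence counts per intensity level within one patch."""

    num: np.ndarray  # counts per level, length = levels
    tot_num: int
    levels: int

    def __post_init__(self) -> None:
        self.num = np.asarray(self.num, dtype=np.int64)
        if self.num.ndim != 1 or len(self.num) != self.levels:
            raise ValueError("num must be 1D of length `levels`")
        if (self.num < 0).any() or int(self.num.sum()) != self.tot_num:
            raise ValueError("counts must be >= 0 and sum to tot_num")

    @classmethod
    def from_patch(cls, patch: np.ndarray, levels: int) -> "PatchHistogram":
        patch = np.asarray(patch)
        _validate_levels(patch, levels)
        num = np.bincount(patch.ravel().astype(np.int64), minlength=levels)
        return cls(num=num, tot_num=patch.size, levels=levels)

    @property
    def pdf(self) -> np.ndarray:
        return self.num / self.tot_num

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.num) / self.tot_num


@dataclass
class IntensityMapping:
    """A monotone level -> level lookup table."""

    lut: np.ndarray
    domain_levels: int

    def __post_init__(self) -> None:
        self.lut = np.asarray(self.lut, dtype=np.int64)
        if len(self.lut) != self.domain_levels:
            raise ValueError("lut length must equal domain_levels")
        if (np.diff(self.lut) < 0).any():
            raise ValueError("lut must be monotone non-decreasing")
        if self.lut.min() < 0 or self.lut.max() > self.domain_levels - 1:
            raise ValueError("lut outputs must lie in [0, domain_levels-1]")

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return self.lut[pixels]


def _validate_levels(patch: np.ndarray, levels: int) -> None:
    if patch.size == 0:
        raise ValueError("patch must be non-empty")
    if not np.issubdtype(np.asarray(patch).dtype, np.integer):
        raise ValueError("patch must be integer-valued")
    if patch.min() < 0 or patch.max() >= levels:
        raise ValueError(f"patch values must lie in [0, {levels - 1}]")


# ---------------------------------------------------------------------------
# Histogram equalization core


def equalization_lut(hist: PatchHistogram, rounding: str = "half-up") -> IntensityMapping:
    """LUT mapping level i to round((L-1) * CDF(i)).

    (L-1) * CDF(i) is the rational (L-1) * cum(i) / TotNum; the rounding
    is done in exact integer arithmetic so ties at .5 are never subject
    to floating-point association.
    """
    num = (hist.levels - 1) * np.cumsum(hist.num)  # exact int64
    total = hist.tot_num
    if rounding == "half-up":
        lut = (2 * num + total) // (2 * total)
    elif rounding == "half-even":
        q, r = np.divmod(num, total)
        up = (2 * r > total) | ((2 * r == total) & (q % 2 == 1))
        lut = q + up
    else:
        round_levels(0.0, rounding)  # raise the standard error
    return IntensityMapping(lut=lut, domain_levels=hist.levels)


def equalize_patch(
    patch: np.ndarray,
    levels: int,
    rounding: str = "half-up",
    preserve_constant: bool = False,
) -> np.ndarray:
    """Histogram-equalize one patch onto [0, levels-1].

    A constant patch maps to ``levels - 1`` everywhere (the CDF of the sole
    occupied level is 1); pass ``preserve_constant=True`` to leave constant
    patches unchanged instead.
    """
    patch = np.asarray(patch)
    hist = PatchHistogram.from_patch(patch, levels)
    if preserve_constant and np.count_nonzero(hist.num) == 1:
        return patch.astype(np.int64).copy()
    return equalization_lut(hist, rounding)(patch.astype(np.int64))


def global_he(frame: Frame, rounding: str = "half-up") -> Frame:
    """Frame-wise histogram equalization (the whole frame as one patch)."""
    return Frame(equalize_patch(frame.pixels, frame.levels, rounding), frame.levels)


# ---------------------------------------------------------------------------
# CLAHE


def _tile_edges(extent: int, patch_size: int) -> list[tuple[int, int]]:
    """Half-open tile intervals covering [0, extent); the last may be partial."""
    return [(s, min(s + patch_size, extent)) for s in range(0, extent, patch_size)]


def _clipped_cdf(counts: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clip histogram bins at clip_limit * total, redistribute excess uniformly."""
    total = counts.sum()
    ceiling = max(clip_limit * total, 1.0)
    clipped = np.minimum(counts, ceiling)
    excess = total - clipped.sum()
    clipped = clipped + excess / len(counts)
    return np.cumsum(clipped) / total


def clahe(
    frame: Frame,
    patch_size: int = 8,
    clip_limit: float = 0.01,
    mode: str = "literal",
    rounding: str = "half-up",
) -> Frame:
    """Patch-wise adaptive histogram equalization.

    ``literal`` mode tiles the frame into ``patch_size`` x ``patch_size``
    blocks (partial blocks at the edges keep their own histograms) and
    equalizes each block independently; the output is the aggregation of
    the equalized patches.  ``standard`` mode is classic contrast-limited
    CLAHE: per-tile histograms are clipped at ``clip_limit`` x tile pixel
    count with the excess redistributed uniformly, and each pixel's output
    is the bilinear blend of the mappings of its (up to) four nearest tile
    centers.  ``clip_limit`` is ignored in literal mode.

    A patch size exceeding the frame degrades to global equalization with
    a logged warning.
    """
    if patch_size < 2:
        raise ValueError("patch_size must be >= 2")
    if mode not in ("literal", "standard"):
        raise ValueError("mode must be 'literal' or 'standard'")
    if mode == "standard" and not (0 < clip_limit <= 1):
        raise ValueError("clip_limit must lie in (0, 1]")
    rows, cols = frame.shape
    if patch_size > max(rows, cols):
        logger.warning(
            "patch_size %d exceeds frame side %d; degrading to global HE",
            patch_size, max(rows, cols),
        )
        return global_he(frame, rounding)

    px = frame.pixels.astype(np.int64)
    L = frame.levels
    row_tiles = _tile_edges(rows, patch_size)
    col_tiles = _tile_edges(cols, patch_size)

    if mode == "literal":
        out = np.empty_like(px)
        for r0, r1 in row_tiles:
            for c0, c1 in col_tiles:
                out[r0:r1, c0:c1] = equalize_patch(px[r0:r1, c0:c1], L, rounding)
        return Frame(out, L)

    # standard mode: clipped per-tile LUTs, bilinear interpolation between
    # tile centers; outside the outer centers the nearest tile is used.
    n_tr, n_tc = len(row_tiles), len(col_tiles)
    luts = np.empty((n_tr, n_tc, L), dtype=float)
    for i, (r0, r1) in enumerate(row_tiles):
        for j, (c0, c1) in enumerate(col_tiles):
            counts = np.bincount(px[r0:r1, c0:c1].ravel(), minlength=L)
            luts[i, j] = (L - 1) * _clipped_cdf(counts, clip_limit)

    r_centers = np.array([(r0 + r1 - 1) / 2.0 for r0, r1 in row_tiles])
    c_centers = np.array([(c0 + c1 - 1) / 2.0 for c0, c1 in col_tiles])

    rr = np.arange(rows, dtype=float)
    cc = np.arange(cols, dtype=float)
    i1 = np.clip(np.searchsorted(r_centers, rr), 0, n_tr - 1)
    i0 = np.clip(i1 - 1, 0, n_tr - 1)
    j1 = np.clip(np.searchsorted(c_centers, cc), 0, n_tc - 1)
    j0 = np.clip(j1 - 1, 0, n_tc - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        wr = np.where(i1 > i0, (rr - r_centers[i0]) / (r_centers[i1] - r_centers[i0]), 0.0)
        wc = np.where(j1 > j0, (cc - c_centers[j0]) / (c_centers[j1] - c_centers[j0]), 0.0)
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    I0 = np.broadcast_to(i0[:, None], (rows, cols))
    I1 = np.broadcast_to(i1[:, None], (rows, cols))
    J0 = np.broadcast_to(j0[None, :], (rows, cols))
    J1 = np.broadcast_to(j1[None, :], (rows, cols))
    v00 = luts[I0, J0, px]
    v01 = luts[I0, J1, px]
    v10 = luts[I1, J0, px]
    v11 = luts[I1, J1, px]
    blended = ((1 - wr) * ((1 - wc) * v00 + wc * v01)
               + wr * ((1 - wc) * v10 + wc * v11))
    return Frame(np.clip(round_levels(blended, rounding), 0, L - 1), L)


# ---------------------------------------------------------------------------
# Adaptive gamma correction (AGCWD / AGCCPF)


def _gamma_lut(pdf: np.ndarray, levels: int, alpha: float, rounding: str) -> IntensityMapping:
    """Per-level gamma LUT from a pdf via the weighting-distribution transform.

    pdf_w(l) = pdf_max * ((pdf(l) - pdf_min) / (pdf_max - pdf_min))^alpha,
    cdf_w from the normalized pdf_w, gamma(l) = 1 - cdf_w(l), and
    T(l) = round((L-1) * (l/(L-1))^gamma(l)).
    """
    pdf = np.asarray(pdf, dtype=float)
    p_min, p_max = pdf.min(), pdf.max()
    if p_max == p_min:
        pdf_w = pdf.copy()  # flat pdf: weighting transform is degenerate
    else:
        pdf_w = p_max * ((pdf - p_min) / (p_max - p_min)) ** alpha
    cdf_w = np.cumsum(pdf_w) / pdf_w.sum()
    gamma = 1.0 - cdf_w
    base = np.arange(levels) / (levels - 1)
    with np.errstate(divide="ignore"):
        t = (levels - 1) * np.power(base, gamma)
    t[0] = 0.0  # 0^gamma, gamma > 0
    lut = np.clip(round_levels(t, rounding), 0, levels - 1)
    lut = np.maximum.accumulate(lut)  # guard against fp non-monotonicity
    return IntensityMapping(lut=lut, domain_levels=levels)


def agcwd(frame: Frame, alpha: float = 1.0, rounding: str = "half-up") -> Frame:
    """Adaptive gamma correction with weighting distribution.

    With the default ``alpha = 1`` the per-level gamma ``1 - cdf_w(l)`` is
    at most 1, so low intensities are brightened (T(l) >= l) while level 0
    and level L-1 are fixed points.  Constant frames are returned
    unchanged (the weighting distribution is undefined).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    hist = PatchHistogram.from_patch(frame.pixels, frame.levels)
    if np.count_nonzero(hist.num) < 2:
        return frame.copy()
    lut = _gamma_lut(hist.pdf, frame.levels, alpha, rounding)
    return Frame(lut(frame.pixels.astype(np.int64)), frame.levels)


def agccpf(frame: Frame, blend: float = 0.5, rounding: str = "half-up") -> Frame:
    """Adaptive gamma correction with a histogram-modification front end.

    The input histogram is blended with the uniform (flat) histogram of
    equal total mass — ``h' = blend * h_uniform + (1 - blend) * h_input`` —
    before the AGCWD gamma stage (alpha = 1) is applied to h'.  ``blend=0``
    reduces exactly to :func:`agcwd`.  The color-restoration stage of the
    original method is the identity for grayscale input.
    """
    if not 0 <= blend <= 1:
        raise ValueError("blend must lie in [0, 1]")
    L = frame.levels
    hist = PatchHistogram.from_patch(frame.pixels, L)
    h_mod = blend * (hist.tot_num / L) * np.ones(L) + (1 - blend) * hist.num
    if np.count_nonzero(h_mod) < 2:  # only possible at blend=0 on a constant frame
        return frame.copy()
    lut = _gamma_lut(h_mod / h_mod.sum(), L, alpha=1.0, rounding=rounding)
    return Frame(lut(frame.pixels.astype(np.int64)), L)


# ---------------------------------------------------------------------------
# RLBHE


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied levels."""


def otsu_threshold(hist: PatchHistogram) -> int:
    """Level t maximizing between-class variance of [0, t] vs (t, L-1].

    Ties are broken toward the smallest t.  Requires at least two occupied
    levels.
    """
    counts = hist.num.astype(float)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("otsu_threshold needs >= 2 occupied levels")
    p = counts / counts.sum()
    levels = np.arange(hist.levels, dtype=float)
    w0 = np.cumsum(p)[:-1]           # weight of class [0, t], t = 0..L-2
    m0 = np.cumsum(p * levels)[:-1]  # unnormalized class-0 mean
    mu = float((p * levels).sum())
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.full(hist.levels - 1, -np.inf)
    var_between[valid] = (mu * w0[valid] - m0[valid]) ** 2 / (w0[valid] * w1[valid])
    return int(np.argmax(var_between))  # argmax returns the first (smallest) maximizer


def rlbhe(frame: Frame, rounding: str = "half-up") -> Frame:
    """Range-limited bi-histogram equalization with brightness preservation.

    The histogram is split at the Otsu threshold t; the lower and upper
    sub-histograms are equalized independently into the disjoint output
    ranges [X0, t] and (t, XL].  X0 and XL are chosen by exact search over
    all integer pairs to minimize |mean(output) - mean(input)| (ties go to
    the smallest (X0, XL)).  Constant frames are returned unchanged.
    """
    L = frame.levels
    hist = PatchHistogram.from_patch(frame.pixels, L)
    if np.count_nonzero(hist.num) < 2:
        return frame.copy()
    t = otsu_threshold(hist)

    p = hist.pdf
    p_lo, p_hi = p[: t + 1], p[t + 1:]
    w_lo, w_hi = p_lo.sum(), p_hi.sum()
    cdf_lo = np.cumsum(p_lo) / w_lo
    cdf_hi = np.cumsum(p_hi) / w_hi

    # Output mean decomposes as A(X0) + B(XL); search both ranges exactly.
    x0s = np.arange(0, t + 1)
    a_vals = np.array([
        float(np.dot(p_lo, x0 + round_levels((t - x0) * cdf_lo, rounding)))
        for x0 in x0s
    ])
    xls = np.arange(t + 1, L)
    b_vals = np.array([
        float(np.dot(p_hi, (t + 1) + round_levels((xl - t - 1) * cdf_hi, rounding)))
        for xl in xls
    ])
    target = float(frame.pixels.mean())
    dev = np.abs(a_vals[:, None] + b_vals[None, :] - target)
    i, j = np.unravel_index(np.argmin(dev), dev.shape)  # row-major: smallest (X0, XL)
    x0, xl = int(x0s[i]), int(xls[j])

    lut = np.empty(L, dtype=np.int64)
    lut[: t + 1] = x0 + round_levels((t - x0) * cdf_lo, rounding)
    lut[t + 1:] = (t + 1) + round_levels((xl - t - 1) * cdf_hi, rounding)
    return Frame(lut[frame.pixels.astype(np.int64)], L)


# ---------------------------------------------------------------------------
# dispatch table used by the CLI and the benchmark harness

METHODS = ("he", "clahe", "agcwd", "agccpf", "rlbhe")


def enhance_frame(frame: Frame, method: str, **kwargs) -> Frame:
    """Apply one of the named frame-level enhancers ('he', 'clahe', 'agcwd',
    'agccpf', 'rlbhe')."""
    dispatch = {
        "he": global_he,
        "clahe": clahe,
        "agcwd": agcwd,
        "agccpf": agccpf,
        "rlbhe": rlbhe,
    }
    if method not in dispatch:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return dispatch[method](frame, **kwargs)
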