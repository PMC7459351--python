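"""Parafoveal flow-void quantification for en-face OCTA angiograms.

The algorithm extracts the vascular network by repeated global histogram
equalization and fixed-threshold binarization, thins it to one-pixel
centerlines (Zhang–Suen), blurs the centerline field with a normalized
Gaussian kernel into a *perfusion map*, and reads capillary-nonperfusion
("flow void") regions and the foveal avascular zone (FAZ) off that map as
connected low-perfusion components.  Areas are reported in mm² using the
image's physical scale.

Histogram equalization maps intensity ``v`` to

    h(v) = round(255 * cdf(v) / MN)

where ``cdf(v)`` counts pixels with intensity <= v and ``MN`` is the number
of pixels being equalized.  Repeating equalization on the *residual* (not
yet classified) pixels re-stretches the remaining dynamic range, so each
pass reveals progressively fainter vessels; the final vessel mask is the
union over passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from skimage import measure

from .image import AngiogramImage, RegionSpec

__all__ = [
    "EqualizationMap",
    "GaussianKernel",
    "PerfusionMap",
    "FlowVoidResult",
    "QuantConfig",
    "QuantResult",
    "RejectedImageError",
    "equalize_histogram",
    "binarize",
    "extract_vessels",
    "skeletonize",
    "gaussian_kernel",
    "perfusion_map",
    "detect_flow_voids",
    "measure_faz",
    "vessel_density",
    "quantify_image",
]


class RejectedImageError(ValueError):
    """Raised when an image fails the quality guard (analogue of a low
    device signal-strength index or a gross artifact)."""


@dataclass(frozen=True)
class EqualizationMap:
    """Lookup table and cumulative histogram of one equalization pass."""

    lut: np.ndarray  # shape (256,), uint8: v -> h(v)
    cdf: np.ndarray  # shape (256,), cumulative pixel counts
    n_pixels: int  # MN: number of pixels equalized


def _equalize_values(px: np.ndarray, select: np.ndarray | None = None):
    """Equalize the selected pixels of an intensity array.

    Returns the equalized full-size array (unselected pixels unchanged)
    plus the EqualizationMap.  ``select=None`` equalizes every pixel.
    """
    px = np.asarray(px, dtype=np.uint8)
    values = px if select is None else px[select]
    if values.size == 0:
        raise ValueError("cannot equalize an empty set of pixels")
    counts = np.bincount(values.ravel(), minlength=256)
    cdf = np.cumsum(counts)
    mn = int(cdf[-1])
    lut = np.rint(255.0 * cdf / mn).astype(np.uint8)
    out = px.copy()
    if select is None:
        out = lut[px]
    else:
        out[select] = lut[values]
    return out, EqualizationMap(lut=lut, cdf=cdf, n_pixels=mn)


def equalize_histogram(img: AngiogramImage) -> tuple[AngiogramImage, EqualizationMap]:
    """Global histogram equalization of an angiogram (h(v) = round(255·cdf(v)/MN)).

    The output is monotone in the input: equal intensities map to equal
    intensities and the brightest present intensity maps to 255.
    """
    out, eq = _equalize_values(img.pixels)
    return img.with_pixels(out), eq


def binarize(img: AngiogramImage | np.ndarray, threshold: int = 185) -> np.ndarray:
    """Threshold an (equalized) angiogram into a boolean vessel mask.

    Vessels carry high flow signal, so the mask is ``intensity >= threshold``.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    px = img.pixels if isinstance(img, AngiogramImage) else np.asarray(img)
    return px >= threshold


def extract_vessels(
    img: AngiogramImage, passes: int = 3, threshold: int = 185
) -> np.ndarray:
    """Multi-pass vessel extraction: equalize → binarize, on residual pixels.

    Pass 1 equalizes the whole image and thresholds it; pass k re-equalizes
    only the pixels not yet classified as vessel and thresholds again.  The
    returned mask is the union over passes, so it is non-decreasing in
    ``passes``; bright trunk vessels appear in early passes and faint
    capillaries in later ones.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    px = img.pixels
    vessel = np.zeros(px.shape, dtype=bool)
    for _ in range(passes):
        residual = ~vessel
        if not residual.any():
            break
        eq, _ = _equalize_values(px, select=residual)
        vessel |= residual & (eq >= threshold)
    return vessel


def _zhang_suen_pass(img: np.ndarray, step: int) -> np.ndarray:
    """One Zhang–Suen sub-iteration; returns the deletion mask.

    Neighbors P1..P8 run clockwise from the pixel above.  A pixel is
    deletable when it has 2–6 set neighbors, exactly one 0→1 transition
    around the ring, and the step-specific corner products vanish.
    """
    p = np.pad(img, 1)
    # P1..P8: N, NE, E, SE, S, SW, W, NW of every interior pixel
    n = [
        p[:-2, 1:-1], p[:-2, 2:], p[1:-1, 2:], p[2:, 2:],
        p[2:, 1:-1], p[2:, :-2], p[1:-1, :-2], p[:-2, :-2],
    ]
    b = sum(x.astype(np.uint8) for x in n)
    a = sum(
        ((n[i] == 0) & (n[(i + 1) % 8] == 1)).astype(np.uint8) for i in range(8)
    )
    if step == 0:
        corners = (~(n[0] & n[2] & n[4])) & (~(n[2] & n[4] & n[6]))
    else:
        corners = (~(n[0] & n[2] & n[6])) & (~(n[0] & n[4] & n[6]))
    return img & (b >= 2) & (b <= 6) & (a == 1) & corners


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a vessel mask to one-pixel-wide centerlines (Zhang–Suen).

    Alternating sub-iterations delete south-east then north-west boundary
    pixels until no pixel changes.  The result is a subset of the input,
    one pixel wide, idempotent, and preserves 8-connectivity.
    """
    img = np.asarray(mask, dtype=bool).copy()
    while True:
        changed = False
        for step in (0, 1):
            delete = _zhang_suen_pass(img, step)
            if delete.any():
                img &= ~delete
                changed = True
        if not changed:
            return img


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized L x L Gaussian blur kernel.

    ``sigma`` follows the block-size rule sigma = 0.3*((L-1)*0.5 - 1) + 0.8
    and ``alpha`` scales the weights to sum to exactly 1.
    """

    L: int
    sigma: float
    alpha: float
    weights: np.ndarray
    profile: np.ndarray = field(repr=False, default=None)  # 1-D separable factor


def gaussian_kernel(L: int = 35) -> GaussianKernel:
    """Build the normalized Gaussian kernel for a given odd block size."""
    if L < 1 or L % 2 == 0:
        raise ValueError("block size L must be a positive odd integer")
    sigma = 0.3 * ((L - 1) * 0.5 - 1) + 0.8
    c = (L - 1) / 2.0
    d = np.arange(L) - c
    profile = np.exp(-(d**2) / (2.0 * sigma**2))
    raw = np.outer(profile, profile)
    alpha = 1.0 / raw.sum()
    return GaussianKernel(L=L, sigma=sigma, alpha=alpha, weights=alpha * raw, profile=profile)


@dataclass(frozen=True)
class PerfusionMap:
    """Blurred skeleton-density field; high where capillaries are dense."""

    values: np.ndarray
    normalization: float  # map maximum, the reference for void thresholds

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def perfusion_map(skel: np.ndarray, kernel: GaussianKernel) -> PerfusionMap:
    """Convolve the binary skeleton with the Gaussian kernel (zero-padded).

    The kernel sums to 1, so total map mass equals the skeleton pixel count
    up to border losses.
    """
    f = np.asarray(skel, dtype=float)
    tmp = convolve1d(f, kernel.profile, axis=0, mode="constant", cval=0.0)
    out = convolve1d(tmp, kernel.profile, axis=1, mode="constant", cval=0.0)
    out *= kernel.alpha
    np.clip(out, 0.0, None, out=out)
    return PerfusionMap(values=out, normalization=float(out.max()))


@dataclass(frozen=True)
class FlowVoidResult:
    """Detected non-perfused regions and their areas.

    ``parafoveal_void_area_mm2`` sums void pixels inside the parafoveal
    annulus over all surviving components *except* the one containing the
    region center, which is the physiologically avascular FAZ and is
    reported separately as ``faz_area_mm2``.
    """

    contours: list[np.ndarray]
    component_areas_mm2: list[float]
    parafoveal_void_area_mm2: float
    faz_area_mm2: float
    void_mask: np.ndarray = field(repr=False, default=None)
    faz_mask: np.ndarray = field(repr=False, default=None)


# fraction of the robust perfused level at which a void boundary is placed;
# the half-height level localizes a Gaussian-blurred step at the true edge
BOUNDARY_LEVEL = 0.5


def _void_components(
    pmap: PerfusionMap,
    region: RegionSpec,
    scale_mm_per_px: float,
    void_threshold_frac: float,
    min_component_px: int,
):
    """Label candidate void components by seeded hysteresis thresholding.

    Pixels below ``void_threshold_frac × max`` seed a void; each void is
    grown (4-connectivity) through pixels below half the robust perfused
    plateau, which places the boundary where the blurred perfusion profile
    has fallen to half its surround — the unbiased edge location for a
    Gaussian-smoothed step.
    """
    if not 0 < void_threshold_frac < 1:
        raise ValueError("void_threshold_frac must lie strictly between 0 and 1")
    v = pmap.values
    vmax = pmap.normalization
    if vmax <= 0:
        weak = np.ones_like(v, dtype=bool)
        seeds = weak
    else:
        disc = (
            region.radius_map_mm(v.shape, scale_mm_per_px)
            <= region.parafovea_outer_radius_mm
        )
        perfused = disc & (v >= 0.5 * vmax)
        plateau = float(np.median(v[perfused])) if perfused.any() else vmax
        seeds = v < void_threshold_frac * vmax
        weak = (v < BOUNDARY_LEVEL * plateau) | seeds
    labels = measure.label(weak, connectivity=1)
    keep = np.unique(labels[seeds & (labels > 0)])
    sizes = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    keep = [int(k) for k in keep if sizes[k] >= min_component_px]
    return labels, keep


def detect_flow_voids(
    pmap: PerfusionMap,
    region: RegionSpec,
    scale_mm_per_px: float,
    void_threshold_frac: float = 0.10,
    min_component_px: int = 10,
) -> FlowVoidResult:
    """Find non-perfused regions on the perfusion map and measure their areas.

    Components smaller than ``min_component_px`` are discarded as noise.
    The component containing the region center is reported as the FAZ and
    excluded from the parafoveal flow-void total.  Component areas are
    pixel counts times ``scale_mm_per_px**2``.
    """
    if not region.contains(pmap.shape, scale_mm_per_px):
        raise ValueError("analysis region does not fit inside the image")
    labels, keep = _void_components(
        pmap, region, scale_mm_per_px, void_threshold_frac, min_component_px
    )
    annulus = region.annulus_mask(pmap.shape, scale_mm_per_px)
    cy, cx = int(round(region.center[0])), int(round(region.center[1]))
    center_label = int(labels[cy, cx])
    px_area = scale_mm_per_px**2

    contours: list[np.ndarray] = []
    component_areas: list[float] = []
    void_total_px = 0
    faz_px = 0
    faz_mask = np.zeros(pmap.shape, dtype=bool)
    void_mask = np.zeros(pmap.shape, dtype=bool)
    for lab in keep:
        comp = labels == lab
        area = float(comp.sum()) * px_area
        component_areas.append(area)
        contours.extend(measure.find_contours(comp.astype(float), 0.5))
        if lab == center_label:
            faz_px = int(comp.sum())
            faz_mask |= comp
        else:
            void_total_px += int((comp & annulus).sum())
            void_mask |= comp
    return FlowVoidResult(
        contours=contours,
        component_areas_mm2=component_areas,
        parafoveal_void_area_mm2=void_total_px * px_area,
        faz_area_mm2=faz_px * px_area,
        void_mask=void_mask,
        faz_mask=faz_mask,
    )


def measure_faz(
    pmap: PerfusionMap,
    region: RegionSpec,
    scale_mm_per_px: float,
    void_threshold_frac: float = 0.10,
    min_component_px: int = 10,
) -> float:
    """Area (mm²) of the avascular component containing the region center.

    Returns 0 when the center pixel is perfused.
    """
    res = detect_flow_voids(
        pmap, region, scale_mm_per_px, void_threshold_frac, min_component_px
    )
    return res.faz_area_mm2


def vessel_density(
    mask: np.ndarray,
    region: RegionSpec,
    scale_mm_per_px: float,
    which: str = "parafovea",
) -> float:
    """Percentage of a region's pixels occupied by the vessel mask."""
    mask = np.asarray(mask, dtype=bool)
    if which == "fovea":
        sel = region.fovea_mask(mask.shape, scale_mm_per_px)
    elif which == "parafovea":
        sel = region.annulus_mask(mask.shape, scale_mm_per_px)
    else:
        raise ValueError("which must be 'fovea' or 'parafovea'")
    total = int(sel.sum())
    if total == 0:
        raise ValueError(f"region '{which}' contains no pixels at this scale")
    return 100.0 * float(mask[sel].sum()) / total


@dataclass(frozen=True)
class QuantConfig:
    """Tunable parameters of the quantification pipeline."""

    threshold: int = 185  # binarization cut on equalized intensities
    passes: int = 3  # equalize/binarize repetitions
    block_size: int = 35  # Gaussian kernel side L
    void_threshold_frac: float = 0.10  # seed threshold, fraction of map max
    min_component_px: int = 10  # smallest surviving void component
    fovea_radius_mm: float = 0.5
    parafovea_outer_radius_mm: float = 1.5
    min_vessel_fraction: float = 0.05  # quality-guard bounds on pass-1 mask
    max_vessel_fraction: float = 0.95


@dataclass(frozen=True)
class QuantResult:
    """Per-image outputs of the full quantification pipeline."""

    parafoveal_vessel_density_pct: float
    parafoveal_flow_void_area_mm2: float
    faz_area_mm2: float
    fovea_vessel_density_pct: float
    vessel_fraction_pass1: float
    qc_flag: str = "ok"
    flow_voids: FlowVoidResult = field(repr=False, default=None)


def quantify_image(img: AngiogramImage, config: QuantConfig = QuantConfig()) -> QuantResult:
    """Run the full pipeline on one angiogram.

    extract_vessels → skeletonize → perfusion_map → flow-void / FAZ /
    vessel-density measurement over the fovea-centered regions.  Images
    failing the quality guard (constant intensity, or a pass-1 vessel
    fraction outside the plausible range) are rejected, mirroring the
    exclusion of low-signal or artifacted scans.
    """
    px = img.pixels
    if px.max() == px.min():
        raise RejectedImageError("constant image: no vascular signal")
    eq1, _ = equalize_histogram(img)
    pass1 = binarize(eq1, config.threshold)
    frac1 = float(pass1.mean())
    if not config.min_vessel_fraction <= frac1 <= config.max_vessel_fraction:
        raise RejectedImageError(
            f"pass-1 vessel fraction {frac1:.3f} outside "
            f"[{config.min_vessel_fraction}, {config.max_vessel_fraction}]"
        )
    region = RegionSpec(
        center=img.center,
        fovea_radius_mm=config.fovea_radius_mm,
        parafovea_outer_radius_mm=config.parafovea_outer_radius_mm,
    )
    mask = extract_vessels(img, passes=config.passes, threshold=config.threshold)
    skel = skeletonize(mask)
    pmap = perfusion_map(skel, gaussian_kernel(config.block_size))
    voids = detect_flow_voids(
        pmap,
        region,
        img.scale_mm_per_px,
        void_threshold_frac=config.void_threshold_frac,
        min_component_px=config.min_component_px,
    )
    return QuantResult(
        parafoveal_vessel_density_pct=vessel_density(
            mask, region, img.scale_mm_per_px, "parafovea"
        ),
        parafoveal_flow_void_area_mm2=voids.parafoveal_void_area_mm2,
        faz_area_mm2=voids.faz_area_mm2,
        fovea_vessel_density_pct=vessel_density(
            mask, region, img.scale_mm_per_px, "fovea"
        ),
        vessel_fraction_pass1=frac1,
        flow_voids=voids,
    )
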