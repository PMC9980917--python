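"""Pixel-classification segmentation of registered multiplexed cores.

The compartment chain mirrors classical TMA pipelines: tissue is thresholded
from the (normalized, log-compressed) sum of all channels; epithelium is an
adaptive-Otsu threshold of the PanEpi channel inside tissue, converted to
gland objects; stroma is tissue minus epithelium; gland lumens are the
enclosed holes of the epithelial mask (fill-and-subtract); nuclei come from
adaptive-Otsu thresholding of DAPI with watershed declumping; stromal marker
positivity is an Otsu cut of the marker intensities restricted to stroma.

The Otsu primitive is implemented on exact integer histograms so that the
threshold maximizes between-class variance over the sample's own discrete
values (shift-equivariant for integer data); ``adaptive`` means per-block
thresholds interpolated bilinearly, with a global fallback for near-constant
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import watershed
from skimage.transform import resize

from stromascope.datatypes import CompartmentMasks, MultiplexCoreImage
from stromascope.errors import DegenerateInputError, ParameterError


@dataclass
class SegmentationParams:
    """Tunable segmentation scales (pixels at 0.25 um/px)."""

    adaptive_block_px: int = 128
    min_gland_area_px: int = 500
    min_lumen_area_px: int = 100
    nuclei_size_range_px: tuple[float, float] = (5.0, 30.0)  # equiv. diameter
    smoothing_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.adaptive_block_px < 32:
            raise ParameterError("adaptive_block_px must be >= 32")
        if self.min_gland_area_px < 1 or self.min_lumen_area_px < 1:
            raise ParameterError("minimum areas must be >= 1")
        lo, hi = self.nuclei_size_range_px
        if not lo < hi:
            raise ParameterError("nuclei size range must satisfy min < max")

    @classmethod
    def for_image_size(cls, size: int, base: int = 1024) -> "SegmentationParams":
        """Defaults rescaled for a core rendered at ``size`` instead of 1024.

        Area thresholds scale with (size/base)^2 and the adaptive block with
        size/base (floored at 32 px); the nucleus size range is absolute and
        stays fixed.
        """
        s = size / base
        return cls(
            adaptive_block_px=max(32, int(round(128 * s))),
            min_gland_area_px=max(1, int(round(500 * s * s))),
            min_lumen_area_px=max(1, int(round(100 * s * s))),
        )


# ---------------------------------------------------------------------------
# Otsu primitive
# ---------------------------------------------------------------------------


def otsu_threshold(values: np.ndarray) -> float:
    """Between-class-variance-maximizing threshold of an intensity sample.

    Works on the sample's exact discrete values (integer data keeps integer
    spacing; float data is binned to 256 levels).  The returned cut ``t``
    splits the sample into ``x <= t`` / ``x > t``; it is placed midway
    between the optimal level and the next distinct level, so for integer
    samples adding a constant shifts the threshold by exactly that constant.

    Raises :class:`DegenerateInputError` for samples with < 2 distinct values.
    """
    v = np.asarray(values).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DegenerateInputError("empty sample")
    levels, counts = np.unique(v, return_counts=True)
    if levels.size < 2:
        raise DegenerateInputError("constant sample, Otsu undefined")
    if levels.size > 256 and not np.issubdtype(v.dtype, np.integer):
        # bin continuous data; represent each bin by its center
        hist, edges = np.histogram(v, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        levels, counts = centers[keep], hist[keep]
    return _otsu_from_histogram(levels.astype(np.float64), counts.astype(np.float64))


def _otsu_from_histogram(levels: np.ndarray, counts: np.ndarray) -> float:
    """Vectorized cumulative-moment Otsu over (level, count) pairs."""
    w = np.cumsum(counts)
    m = np.cumsum(counts * levels)
    total_w, total_m = w[-1], m[-1]
    # candidate cuts after each level except the last
    w0, m0 = w[:-1], m[:-1]
    w1 = total_w - w0
    mu0 = m0 / w0
    mu1 = (total_m - m0) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(sigma_b))  # ties -> lowest cut
    return float(0.5 * (levels[best] + levels[best + 1]))


def _otsu_effectiveness(vals: np.ndarray, thr: float) -> float:
    """Between-class / total variance ratio of the split at ``thr``.

    Near 1 for well-separated bimodal samples; ~0.6-0.75 when Otsu merely
    splits a unimodal distribution in half.
    """
    total = vals.var()
    if total == 0:
        return 0.0
    lo = vals[vals <= thr]
    hi = vals[vals > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0 = lo.size / vals.size
    return float(w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2 / total)


def adaptive_otsu(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    block_px: int = 128,
    min_block_pixels: int = 64,
    min_effectiveness: float = 0.8,
    clamp: tuple[float, float] = (0.7, 1.5),
) -> np.ndarray:
    """Per-block Otsu thresholds bilinearly interpolated to a threshold map.

    A block threshold is used only when the block is genuinely bimodal
    (between-class variance ratio >= ``min_effectiveness``); near-constant or
    unimodal blocks — e.g. fully inside one bright compartment, where a local
    Otsu would split the signal itself — fall back to the global Otsu of the
    masked image.  Accepted block thresholds are clamped to
    ``clamp * global`` so a block whose two modes are both below the signal
    (glass vs unstained tissue) cannot drag the map under the background.
    """
    img = np.asarray(image, dtype=np.float64)
    sel = np.ones(img.shape, bool) if mask is None else mask.astype(bool)
    sample = img[sel]
    if sample.size == 0 or np.unique(sample).size < 2:
        raise DegenerateInputError("no contrast under mask")
    global_thr = otsu_threshold(sample)

    h, w = img.shape
    nby = max(1, round(h / block_px))
    nbx = max(1, round(w / block_px))
    grid = np.full((nby, nbx), global_thr)
    ys = np.linspace(0, h, nby + 1).astype(int)
    xs = np.linspace(0, w, nbx + 1).astype(int)
    for i in range(nby):
        for j in range(nbx):
            blk = img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            bsel = sel[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            vals = blk[bsel]
            if vals.size < min_block_pixels or np.unique(vals).size < 2:
                continue
            thr = otsu_threshold(vals)
            if _otsu_effectiveness(vals, thr) < min_effectiveness:
                continue  # unimodal block -> global fallback
            grid[i, j] = min(max(thr, clamp[0] * global_thr),
                             clamp[1] * global_thr)
    if grid.size == 1:
        return np.full(img.shape, float(grid[0, 0]))
    return resize(grid, img.shape, order=1, mode="edge", anti_aliasing=False)


# ---------------------------------------------------------------------------
# compartments
# ---------------------------------------------------------------------------


def segment_tissue(
    image: MultiplexCoreImage, params: SegmentationParams | None = None
) -> tuple[np.ndarray, bool]:
    """Tissue mask from the sum of all channels.

    Channels are scaled by their 99.9th percentile, summed, log-compressed
    (so the dominant histogram gap is tissue-vs-glass rather than
    bright-stain-vs-everything), smoothed and Otsu-thresholded.  Holes
    smaller than ``min_lumen_area_px`` are filled; larger holes (gland
    lumens) are retained.  Returns ``(mask, low_tissue_flag)``.
    """
    params = params or SegmentationParams()
    total = np.zeros(image.shape, dtype=np.float64)
    for ch in image.channels.values():
        chf = ch.astype(np.float64)
        p = np.percentile(chf, 99.9)
        if p > 0:
            total += np.clip(chf / p, 0.0, 1.0)
    compressed = np.log1p(5.0 * total)
    smoothed = ndi.gaussian_filter(compressed, params.smoothing_sigma_px)
    try:
        thr = otsu_threshold(smoothed)
    except DegenerateInputError:
        return np.zeros(image.shape, bool), True
    mask = smoothed > thr
    mask = remove_small_objects(mask, max_size=params.min_gland_area_px - 1)
    mask = remove_small_holes(mask, max_size=params.min_lumen_area_px - 1)
    low = mask.mean() < 0.05
    return mask, low


def segment_epithelium(
    panepi: np.ndarray, tissue: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Labelled epithelial gland objects inside tissue.

    Adaptive Otsu of the PanEpi channel restricted to tissue; connected
    components below ``min_gland_area_px`` are discarded.  Returns an int
    label image (0 background); no PanEpi contrast yields zero objects.
    """
    params = params or SegmentationParams()
    if not tissue.any():
        return np.zeros(tissue.shape, dtype=np.int32)
    try:
        thr_map = adaptive_otsu(panepi, mask=tissue, block_px=params.adaptive_block_px)
    except DegenerateInputError:
        return np.zeros(tissue.shape, dtype=np.int32)
    mask = (np.asarray(panepi, float) > thr_map) & tissue
    mask = remove_small_objects(mask, max_size=params.min_gland_area_px - 1)
    labels, _ = ndi.label(mask)
    return labels.astype(np.int32)


def segment_stroma(tissue: np.ndarray, epithelium_objects: np.ndarray) -> np.ndarray:
    """Stroma = tissue minus epithelium (disjointness by construction)."""
    if tissue.shape != epithelium_objects.shape:
        raise ParameterError("tissue and epithelium masks differ in shape")
    return tissue & ~(epithelium_objects > 0)


def segment_lumen(
    epithelium_objects: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Gland lumens: enclosed holes of the epithelial mask (fill - subtract)."""
    params = params or SegmentationParams()
    epi = epithelium_objects > 0
    filled = ndi.binary_fill_holes(epi)
    lumen = filled & ~epi
    lumen = remove_small_objects(lumen, max_size=params.min_lumen_area_px - 1)
    labels, _ = ndi.label(lumen)
    return labels.astype(np.int32)


def segment_nuclei(
    dapi: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Labelled nuclei from DAPI: adaptive Otsu + distance-transform watershed.

    Touching nuclei are split at distance-transform peaks; objects outside
    the equivalent-diameter range are discarded.
    """
    params = params or SegmentationParams()
    img = np.asarray(dapi, dtype=np.float64)
    if np.unique(img).size < 2:
        raise DegenerateInputError("constant DAPI image")
    # no-signal guard: if the best global split barely beats a unimodal
    # noise split, there are no stained nuclei to find
    if _otsu_effectiveness(img.ravel(), otsu_threshold(img)) < 0.75:
        return np.zeros(img.shape, dtype=np.int32)
    thr_map = adaptive_otsu(img, block_px=params.adaptive_block_px)
    mask = img > thr_map
    lo, hi = params.nuclei_size_range_px
    min_area = int(np.pi * (lo / 2) ** 2)
    max_area = int(np.pi * (hi / 2) ** 2)
    mask = remove_small_objects(mask, max_size=max(0, min_area - 1))
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    smooth_dist = ndi.gaussian_filter(distance, 1.0)
    peaks = peak_local_max(
        smooth_dist, min_distance=max(2, int(lo)), labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth_dist, markers, mask=mask)
    # size filter on equivalent diameter
    out = np.zeros_like(labels)
    next_id = 1
    for lbl, area in zip(*np.unique(labels[labels > 0], return_counts=True)):
        if min_area <= area <= max_area:
            out[labels == lbl] = next_id
            next_id += 1
    return out


def marker_positivity(
    marker: np.ndarray,
    stroma: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray | None:
    """Binary marker-positive mask inside stroma, or ``None`` when missing.

    The Otsu cut is computed from the stroma-restricted intensities of this
    core.  A floor of ``p25 + 4*(p25 - p5)`` of the stromal intensities (a
    robust upper bound on background spread, assuming at least a quarter of
    the stroma is unstained) prevents an Otsu split of pure background noise
    from being read as positivity.
    """
    if not stroma.any():
        return None
    vals = np.asarray(marker, dtype=np.float64)[stroma]
    if np.unique(vals).size < 2:
        return np.zeros(stroma.shape, dtype=bool)
    thr = otsu_threshold(vals)
    p5, p25 = np.percentile(vals, [5, 25])
    floor = p25 + 4.0 * (p25 - p5)
    thr = max(thr, floor)
    return (np.asarray(marker, float) > thr) & stroma


def segment_core(
    registered: MultiplexCoreImage,
    round2_aligned: MultiplexCoreImage | None = None,
    params: SegmentationParams | None = None,
) -> tuple[CompartmentMasks, bool]:
    """Full compartment segmentation of a registered core.

    ``registered`` must carry the round-1 channels; ``round2_aligned``
    supplies SMA in the round-1 frame (omitted -> no SMA mask).  Returns
    ``(masks, low_tissue_flag)``.
    """
    params = params or SegmentationParams()
    channels = dict(registered.channels)
    if round2_aligned is not None:
        channels = {**channels, "SMA": round2_aligned["SMA"]}
    stack = MultiplexCoreImage(
        core_id=registered.core_id, channels=channels,
        pixel_size_um=registered.pixel_size_um,
    )
    tissue, low = segment_tissue(stack, params)
    epi = segment_epithelium(registered["PanEpi"], tissue, params)
    stroma = segment_stroma(tissue, epi)
    lumen = segment_lumen(epi, params)
    try:
        nuclei = segment_nuclei(registered["DAPI"], params)
    except DegenerateInputError:
        nuclei = np.zeros(tissue.shape, dtype=np.int32)
    marker_masks: dict[str, np.ndarray | None] = {}
    for m in ("CD8", "FAP", "CD163"):
        marker_masks[m] = marker_positivity(registered[m], stroma, params)
    if round2_aligned is not None:
        marker_masks["SMA"] = marker_positivity(
            round2_aligned["SMA"], stroma, params
        )
    else:
        marker_masks["SMA"] = None
    masks = CompartmentMasks(
        tissue=tissue, epithelium_objects=epi, stroma=stroma,
        lumen_objects=lumen, nuclei_objects=nuclei, marker_masks=marker_masks,
    )
    return masks, low
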