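"""Two-round alignment via DAPI phase correlation (translation-only).

Restained slides from the same scanner differ by a small planar translation;
the shared DAPI channel is the landmark.  The estimate is spectral
cross-correlation with subpixel refinement; its quality score is the
normalized cross-correlation after alignment, and a core whose score falls
below ``min_score`` is flagged so its round-2 (SMA) measurement can be
recorded as missing downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from stromascope.datatypes import MultiplexCoreImage, RegistrationResult
from stromascope.errors import DegenerateInputError, ParameterError

DEFAULT_MIN_SCORE = 0.5


def estimate_shift(
    dapi_r1: np.ndarray,
    dapi_r2: np.ndarray,
    min_score: float = DEFAULT_MIN_SCORE,
    upsample_factor: int = 20,
) -> RegistrationResult:
    """Estimate the (dx, dy) displacement of round 2 relative to round 1.

    Convention: ``round2 ≈ translate(round1, (dx, dy))`` — content sits
    ``dx`` columns right and ``dy`` rows down of its round-1 position.
    """
    a = np.asarray(dapi_r1, dtype=np.float64)
    b = np.asarray(dapi_r2, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant DAPI image, cannot register")
    # phase_cross_correlation returns the (row, col) shift that maps the
    # moving image (b) onto the reference (a), i.e. minus our displacement
    # unnormalized cross-correlation: the spectral-whitening variant is
    # unreliable on smooth, low-texture images
    reg, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    dy, dx = -reg[0], -reg[1]
    score = _ncc_at_shift(a, b, (dx, dy))
    return RegistrationResult(
        shift=(float(dx), float(dy)), score=float(score),
        ok=bool(score >= min_score),
    )


def _ncc_at_shift(a: np.ndarray, b: np.ndarray, shift) -> float:
    """Pearson correlation between a and b aligned back by ``shift``."""
    dx, dy = shift
    aligned = ndi.shift(b, (-dy, -dx), order=1, cval=np.nan)
    valid = np.isfinite(aligned)
    if valid.sum() < 16:
        return 0.0
    x, y = a[valid], aligned[valid]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return max(-1.0, min(1.0, r))


def apply_shift(
    image: MultiplexCoreImage, shift: tuple[float, float]
) -> MultiplexCoreImage:
    """Translate all channels by ``-shift``, mapping round 2 into round 1.

    Out-of-view pixels are filled with the channel median and flagged False
    in the returned image's validity mask.
    """
    dx, dy = float(shift[0]), float(shift[1])
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ParameterError("shift must be finite")
    channels = {}
    valid = None
    for name, ch in image.channels.items():
        fill = float(np.median(ch))
        moved = ndi.shift(ch.astype(np.float64), (-dy, -dx), order=1, cval=np.nan)
        v = np.isfinite(moved)
        moved[~v] = fill
        if np.issubdtype(ch.dtype, np.integer):
            moved = np.clip(np.rint(moved), np.iinfo(ch.dtype).min,
                            np.iinfo(ch.dtype).max)
        channels[name] = moved.astype(ch.dtype)
        valid = v if valid is None else (valid & v)
    return MultiplexCoreImage(
        core_id=image.core_id, channels=channels,
        pixel_size_um=image.pixel_size_um,
        staining_round=image.staining_round, valid=valid,
    )


def register_rounds(
    round1: MultiplexCoreImage,
    round2: MultiplexCoreImage,
    min_score: float = DEFAULT_MIN_SCORE,
) -> tuple[MultiplexCoreImage, RegistrationResult]:
    """Estimate the round-2 shift from DAPI and align round 2 onto round 1."""
    result = estimate_shift(round1["DAPI"], round2["DAPI"], min_score=min_score)
    aligned = apply_shift(round2, result.shift)
    return aligned, result
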