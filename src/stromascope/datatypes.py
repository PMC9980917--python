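"""Shared in-memory containers for images, masks and per-core measurements.

Conventions
-----------
* Images are 2-D ``numpy`` arrays indexed ``[row, col]``; a planar shift is
  expressed as ``(dx, dy)`` = (column displacement, row displacement), i.e.
  the vector that moves round-1 content onto its round-2 position.
* Area fractions of compartments are relative to total tissue area; marker
  fractions are relative to total stroma area.  Missing measurements are
  ``None`` (scalar) / ``NaN`` (tabular), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stromascope.errors import ParameterError

#: Lesion classes of a TMA core: benign glandular tissue, MRI false-negative
#: cancer and MRI true-positive cancer.
LESION_CLASSES = ("benign", "mri_neg", "mri_pos")

#: First-round fluorescence channels and the second-round channels.
ROUND1_CHANNELS = ("DAPI", "CD8", "FAP", "CD163", "PanEpi")
ROUND2_CHANNELS = ("DAPI", "SMA")

#: Stromal markers quantified as fractions of stroma area.
MARKERS = ("CD8", "FAP", "CD163", "SMA")


@dataclass
class MultiplexCoreImage:
    """Named-channel raster stack for one TMA core and one staining round."""

    core_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.25
    staining_round: int = 1
    #: pixels whose value is real data (False where a shift moved content
    #: out of view and a fill value was substituted)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ParameterError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class CompartmentMasks:
    """Binary / labelled compartment masks of one core, all in one frame.

    Invariants (checked by :meth:`validate`): stroma and epithelium are
    disjoint and together exactly tile the tissue mask; lumen never overlaps
    epithelium; every marker mask lies inside stroma.
    """

    tissue: np.ndarray
    epithelium_objects: np.ndarray  # int labels, 0 = background
    stroma: np.ndarray
    lumen_objects: np.ndarray
    nuclei_objects: np.ndarray
    marker_masks: dict[str, np.ndarray | None] = field(default_factory=dict)

    @property
    def epithelium(self) -> np.ndarray:
        return self.epithelium_objects > 0

    @property
    def lumen(self) -> np.ndarray:
        return self.lumen_objects > 0

    @property
    def nuclei(self) -> np.ndarray:
        return self.nuclei_objects > 0

    def validate(self) -> None:
        epi = self.epithelium
        if np.any(self.stroma & epi):
            raise ParameterError("stroma and epithelium overlap")
        if np.any((self.stroma | epi) & ~self.tissue):
            raise ParameterError("stroma/epithelium outside tissue")
        if np.any(self.lumen & epi):
            raise ParameterError("lumen overlaps epithelium")
        for name, mask in self.marker_masks.items():
            if mask is not None and np.any(mask & ~self.stroma):
                raise ParameterError(f"marker {name} mask outside stroma")


@dataclass
class CoreQuant:
    """Per-core measurements: compartment fractions and marker fractions.

    ``gland_count`` / ``lumen_count`` are raw object counts;
    ``glands_per_mm2`` / ``lumens_per_mm2`` are normalized per tissue area.
    """

    core_id: str
    lesion_class: str | None = None
    epithelium_fraction: float | None = None
    stroma_fraction: float | None = None
    nuclei_fraction: float | None = None
    lumen_fraction: float | None = None
    gland_count: int | None = None
    lumen_count: int | None = None
    nuclei_count: int | None = None
    glands_per_mm2: float | None = None
    lumens_per_mm2: float | None = None
    marker_fractions: dict[str, float | None] = field(default_factory=dict)
    qc_flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "core_id": self.core_id,
            "lesion_class": self.lesion_class,
            "epithelium_fraction": _nan(self.epithelium_fraction),
            "stroma_fraction": _nan(self.stroma_fraction),
            "nuclei_fraction": _nan(self.nuclei_fraction),
            "lumen_fraction": _nan(self.lumen_fraction),
            "gland_count": _nan(self.gland_count),
            "lumen_count": _nan(self.lumen_count),
            "nuclei_count": _nan(self.nuclei_count),
            "glands_per_mm2": _nan(self.glands_per_mm2),
            "lumens_per_mm2": _nan(self.lumens_per_mm2),
            "qc_flags": ";".join(self.qc_flags),
        }
        for m in MARKERS:
            row[f"{m}_fraction"] = _nan(self.marker_fractions.get(m))
        return row


def _nan(x):
    return np.nan if x is None else x


@dataclass
class RegistrationResult:
    """Translation estimate between staining rounds (round-2 minus round-1)."""

    shift: tuple[float, float]  # (dx, dy)
    score: float  # normalized cross-correlation at the estimate
    ok: bool

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ParameterError(f"correlation score out of range: {self.score}")
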