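"""Supervised 4-class pixel classification of chromogenic FAP/SMA stains.

Emulates an interactive pixel-classification workflow for double-antibody
brightfield IHC: FAP develops brown (DAB), SMA red (permanent red), nuclei /
background tissue blue (hematoxylin), and bare glass stays white.  Every
pixel is assigned to exactly one of four classes — ``empty``, ``FAP_pos``,
``SMA_pos``, ``other_tissue`` — by a random forest over per-pixel color and
texture features (raw RGB, stain-deconvolved channels, multi-scale Gaussian
and gradient features).  FAP- and SMA-positive pixel counts are normalized
by total tissue pixels (everything not ``empty``); there is no
epithelium/stroma split in this modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
from scipy import ndimage as ndi, stats
from skimage.color import rgb2hed
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from stromascope.errors import InsufficientDataError, ParameterError

#: fixed class order; class maps store the index into this tuple
CLASSES = ("empty", "FAP_pos", "SMA_pos", "other_tissue")

#: nominal RGB of each class used by the synthetic brightfield renderer
CLASS_COLORS = {
    "empty": (242, 242, 242),
    "FAP_pos": (130, 85, 40),  # DAB brown
    "SMA_pos": (205, 70, 85),  # permanent red
    "other_tissue": (150, 140, 200),  # hematoxylin blue-purple
}

_FEATURE_SIGMAS = (1.0, 2.0, 4.0)


@dataclass
class ScribbleSet:
    """Sparse per-class training annotations on one or more images.

    ``entries`` is a list of ``(image_index, rows, cols, class_index)``
    blocks.  Training requires at least one annotated pixel per class.
    """

    entries: list[tuple[int, np.ndarray, np.ndarray, int]] = field(
        default_factory=list
    )

    def add(self, image_index: int, rows, cols, class_name: str) -> None:
        self.entries.append(
            (image_index, np.asarray(rows), np.asarray(cols),
             CLASSES.index(class_name))
        )

    def covered_classes(self) -> set[int]:
        return {c for _, r, _, c in self.entries if len(r) > 0}


@dataclass
class BrightfieldQuant:
    """Tissue-normalized FAP/SMA pixel fractions of one brightfield core."""

    fap_fraction: float | None
    sma_fraction: float | None
    tissue_pixels: int


def pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: RGB + stain deconvolution + multi-scale.

    Returns ``(h, w, f)`` float array: raw RGB, hematoxylin/eosin-red/DAB
    optical-density channels, and Gaussian-smoothed intensity plus gradient
    magnitude at three scales.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError("brightfield image must be RGB (h, w, 3)")
    feats = [img / 255.0]
    hed = rgb2hed(img / 255.0)
    feats.append(hed)
    gray = img.mean(axis=2) / 255.0
    for s in _FEATURE_SIGMAS:
        sm = ndi.gaussian_filter(gray, s)
        gy, gx = np.gradient(sm)
        feats.append(sm[..., None])
        feats.append(np.hypot(gx, gy)[..., None])
    return np.concatenate(feats, axis=2)


class PixelClassifier:
    """Random-forest pixel classifier over the fixed 4-class scheme.

    sklearn-style estimator: ``fit(images, scribbles)`` trains from sparse
    annotations, ``predict(image)`` returns a class-index map.  Fitted
    attributes carry the trailing underscore (``model_``,
    ``holdout_accuracy_``).
    """

    def __init__(self, n_estimators: int = 60, seed: int = 0,
                 holdout_fraction: float = 0.25):
        self.n_estimators = n_estimators
        self.seed = seed
        self.holdout_fraction = holdout_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "seed": self.seed,
            "holdout_fraction": self.holdout_fraction,
        }

    def set_params(self, **params) -> "PixelClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ParameterError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, images: list[np.ndarray], scribbles: ScribbleSet
            ) -> "PixelClassifier":
        missing = set(range(len(CLASSES))) - scribbles.covered_classes()
        if missing:
            names = ", ".join(CLASSES[i] for i in sorted(missing))
            raise ParameterError(f"scribbles missing class(es): {names}")
        feats = {i: pixel_features(img) for i, img in enumerate(images)}
        xs, ys = [], []
        for idx, rows, cols, cls in scribbles.entries:
            if len(rows) == 0:
                continue
            xs.append(feats[idx][rows, cols])
            ys.append(np.full(len(rows), cls))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        xtr, xte, ytr, yte = train_test_split(
            x, y, test_size=self.holdout_fraction, random_state=self.seed,
            stratify=y,
        )
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1,
        )
        self.model_.fit(xtr, ytr)
        self.holdout_accuracy_ = float(self.model_.score(xte, yte))
        return self

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Class-index map (uint8, indices into :data:`CLASSES`)."""
        if not hasattr(self, "model_"):
            raise ParameterError("classifier is not fitted")
        f = pixel_features(image)
        h, w, nf = f.shape
        pred = self.model_.predict(f.reshape(-1, nf))
        return pred.reshape(h, w).astype(np.uint8)


def train_pixel_classifier(
    images: list[np.ndarray], scribbles: ScribbleSet, seed: int = 0
) -> PixelClassifier:
    """Convenience wrapper: fit a :class:`PixelClassifier` on scribbles."""
    return PixelClassifier(seed=seed).fit(images, scribbles)


def classify_and_quantify(
    model: PixelClassifier, image: np.ndarray
) -> tuple[BrightfieldQuant, np.ndarray]:
    """Per-pixel argmax classes and tissue-normalized FAP/SMA fractions.

    ``tissue_pixels`` counts everything not classified ``empty``; fractions
    are missing (None) when no tissue is detected.
    """
    class_map = model.predict(image)
    tissue = int((class_map != CLASSES.index("empty")).sum())
    if tissue == 0:
        return BrightfieldQuant(None, None, 0), class_map
    fap = int((class_map == CLASSES.index("FAP_pos")).sum())
    sma = int((class_map == CLASSES.index("SMA_pos")).sum())
    return BrightfieldQuant(fap / tissue, sma / tissue, tissue), class_map


def fluorescence_concordance(
    fluor_fap: np.ndarray, brightfield_fap: np.ndarray
) -> float | None:
    """Pearson correlation of FAP fractions across paired cores.

    ``fluor_fap`` are stroma-normalized fluorescence fractions,
    ``brightfield_fap`` tissue-normalized chromogenic fractions of the same
    cores.  Returns None (with a warning) if either vector is constant.
    """
    a = np.asarray(fluor_fap, float)
    b = np.asarray(brightfield_fap, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise InsufficientDataError("need >= 3 paired cores")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warn("constant fraction vector, concordance undefined")
        return None
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# synthetic brightfield rendering
# ---------------------------------------------------------------------------


def render_class_map(
    class_map: np.ndarray, rng: np.random.Generator, noise_sd: float = 6.0
) -> np.ndarray:
    """RGB image from a class-index map: class color + lognormal shading + noise."""
    h, w = class_map.shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    for idx, name in enumerate(CLASSES):
        sel = class_map == idx
        n = int(sel.sum())
        if not n:
            continue
        shade = np.exp(rng.normal(0.0, 0.06, n))
        for c in range(3):
            img[sel, c] = CLASS_COLORS[name][c] * shade
    img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def class_map_from_masks(
    tissue: np.ndarray, fap_mask: np.ndarray, sma_mask: np.ndarray
) -> np.ndarray:
    """Ground-truth class map from compartment masks (FAP wins overlaps)."""
    cm = np.zeros(tissue.shape, dtype=np.uint8)  # empty
    cm[tissue] = CLASSES.index("other_tissue")
    cm[tissue & sma_mask] = CLASSES.index("SMA_pos")
    cm[tissue & fap_mask] = CLASSES.index("FAP_pos")
    return cm


def render_brightfield_core(truth_masks, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Chromogenic rendition of a fluorescence core's ground truth.

    Returns ``(rgb_image, true_class_map)``; the stain-positive pixels are
    the same FAP/SMA ground-truth masks used for the fluorescence rounds, so
    paired-modality concordance can be assessed on identical cores.
    """
    cm = class_map_from_masks(
        truth_masks.tissue | truth_masks.lumen,  # lumen renders as tissue bg
        truth_masks.marker_masks["FAP"],
        truth_masks.marker_masks["SMA"],
    )
    cm[truth_masks.lumen] = CLASSES.index("empty")  # lumens are unstained
    return render_class_map(cm, rng), cm


def sample_scribbles(
    class_maps: list[np.ndarray],
    n_per_class: int = 300,
    seed: int = 0,
) -> ScribbleSet:
    """Random sparse annotations drawn from ground-truth class maps."""
    rng = np.random.default_rng(seed)
    sc = ScribbleSet()
    for idx, cls in enumerate(CLASSES):
        pool = []
        for i, cm in enumerate(class_maps):
            r, c = np.nonzero(cm == idx)
            pool.append((i, r, c))
        total = sum(len(r) for _, r, _ in pool)
        if total == 0:
            continue
        for i, r, c in pool:
            if len(r) == 0:
                continue
            k = max(1, int(round(n_per_class * len(r) / total)))
            take = rng.choice(len(r), size=min(k, len(r)), replace=False)
            sc.entries.append((i, r[take], c[take], idx))
    return sc
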