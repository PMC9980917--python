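"""Segmentation: Otsu primitive, compartments, markers, conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stromascope.datatypes import MultiplexCoreImage
from stromascope.errors import DegenerateInputError
from stromascope.segment import (
    SegmentationParams,
    adaptive_otsu,
    marker_positivity,
    otsu_threshold,
    segment_epithelium,
    segment_lumen,
    segment_nuclei,
    segment_stroma,
    segment_tissue,
)
from stromascope.synthcore import CoreSpec, generate_core, render_gland_annuli


def otsu_bruteforce(values):
    """Oracle: explicit loop over every candidate cut maximizing the
    between-class variance; independent of the cumulative-moment path."""
    v = np.sort(np.asarray(values, float).ravel())
    levels = np.unique(v)
    best_t, best_s = None, -1.0
    for i in range(len(levels) - 1):
        lo = v[v <= levels[i]]
        hi = v[v > levels[i]]
        w0, w1 = len(lo) / len(v), len(hi) / len(v)
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-12:
            best_s, best_t = s, 0.5 * (levels[i] + levels[i + 1])
    return best_t


class TestOtsu:
    def test_perfect_bimodal_separates_classes(self):
        sample = np.array([0] * 100 + [255] * 100)
        t = otsu_threshold(sample)
        assert 0 < t < 255
        assert ((sample > t) == (sample == 255)).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sample = rng.integers(0, 256, size=500).astype(np.uint8)
        assert otsu_threshold(sample) == pytest.approx(otsu_bruteforce(sample))

    @given(st.integers(min_value=-100, max_value=100))
    def test_shift_equivariance_on_integers(self, c):
        rng = np.random.default_rng(42)
        sample = np.concatenate([
            rng.integers(0, 60, 200), rng.integers(150, 250, 80)
        ])
        t0 = otsu_threshold(sample)
        t1 = otsu_threshold(sample + c)
        assert t1 == pytest.approx(t0 + c)

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(100, 7))

    def test_adaptive_map_matches_global_on_uniform_image(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((128, 128)) < 0.3, 200, 20).astype(float)
        thr_map = adaptive_otsu(img, block_px=64)
        g = otsu_threshold(img)
        assert np.all(np.abs(thr_map - g) < 40)
        assert ((img > thr_map) == (img > g)).mean() > 0.999


class TestTissue:
    def test_blank_image_empty_mask_with_flag(self):
        img = MultiplexCoreImage(core_id="b", channels={
            "DAPI": np.zeros((128, 128), np.uint8),
            "PanEpi": np.zeros((128, 128), np.uint8),
        })
        mask, low = segment_tissue(img)
        assert not mask.any()
        assert low

    def test_synthetic_core_jaccard_and_area(self, mri_pos_core, params_small):
        _, r1, _, truth = mri_pos_core
        mask, low = segment_tissue(r1, params_small)
        t = truth.masks.tissue
        jacc = (mask & t).sum() / (mask | t).sum()
        assert jacc >= 0.95
        assert not low
        assert mask.mean() == pytest.approx(t.mean(), abs=0.02)


class TestEpithelium:
    def test_no_panepi_signal_zero_objects(self, params_small):
        tissue = np.ones((128, 128), bool)
        panepi = np.full((128, 128), 30, np.uint8)
        labels = segment_epithelium(panepi, tissue, params_small)
        assert labels.max() == 0

    def test_twelve_annular_glands_recovered(self):
        panepi, tissue, epi_true, lumen_true = render_gland_annuli(
            size=256, n_glands=12)
        params = SegmentationParams.for_image_size(256)
        labels = segment_epithelium(panepi, tissue, params)
        assert abs(int(labels.max()) - 12) <= 1
        lumen = segment_lumen(labels, params)
        assert int(lumen.max()) == 12
        # each recovered lumen coincides with a true enclosed hole
        assert ((lumen > 0) & ~lumen_true).sum() < 0.02 * lumen_true.sum()

    def test_area_fraction_recovery(self, mri_pos_core, segmented_core):
        _, _, _, truth = mri_pos_core
        masks, quant, _, _ = segmented_core
        assert quant.epithelium_fraction == pytest.approx(
            truth.true_fractions.epithelium_fraction, abs=0.02)


class TestStromaLumen:
    def test_stroma_complement_and_conservation(self, segmented_core):
        masks, _, _, _ = segmented_core
        assert not (masks.stroma & masks.epithelium).any()
        assert masks.tissue.sum() == masks.stroma.sum() + masks.epithelium.sum()

    def test_stroma_edge_cases(self):
        tissue = np.zeros((64, 64), bool)
        tissue[8:56, 8:56] = True
        epi = np.zeros((64, 64), np.int32)
        # empty epithelium -> stroma == tissue
        np.testing.assert_array_equal(segment_stroma(tissue, epi), tissue)
        # epithelium == tissue -> empty stroma
        epi[tissue] = 1
        assert not segment_stroma(tissue, epi).any()

    def test_solid_glands_have_no_lumen(self):
        epi = np.zeros((64, 64), np.int32)
        epi[10:30, 10:30] = 1
        assert segment_lumen(epi).max() == 0

    def test_annulus_lumen_equals_enclosed_hole(self):
        yy, xx = np.mgrid[:64, :64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        epi = ((d2 <= 400) & (d2 > 100)).astype(np.int32)
        params = SegmentationParams(min_lumen_area_px=10)
        lumen = segment_lumen(epi, params)
        assert lumen.max() == 1
        np.testing.assert_array_equal(lumen > 0, d2 <= 100)

    def test_benign_lumen_fraction_recovery(self):
        from tests.conftest import segment_one
        spec, truth, masks, quant, _ = segment_one("benign", seed=21)
        assert quant.lumen_fraction == pytest.approx(
            truth.true_fractions.lumen_fraction, abs=0.02)
        assert truth.true_fractions.lumen_fraction == pytest.approx(0.097, abs=0.02)


class TestNuclei:
    def test_blank_dapi_no_nuclei(self, params_small):
        rng = np.random.default_rng(0)
        dapi = rng.normal(20, 2, (128, 128)).clip(0, 255).astype(np.uint8)
        labels = segment_nuclei(dapi, params_small)
        assert labels.max() == 0

    def test_constant_dapi_degenerate(self, params_small):
        with pytest.raises(DegenerateInputError):
            segment_nuclei(np.full((64, 64), 10, np.uint8), params_small)

    def test_nucleus_count_recovered_within_two_percent(self):
        spec = CoreSpec.for_class(
            "benign", seed=31, size=512,
            target_epithelium_fraction=0.30, target_lumen_fraction=0.05,
            target_nuclei_fraction=0.11,
        )
        r1, _, truth = generate_core(spec)
        n_true = truth.true_fractions.nuclei_count
        assert n_true > 300  # several hundred non-touching disks
        labels = segment_nuclei(r1["DAPI"], SegmentationParams.for_image_size(512))
        assert labels.max() == pytest.approx(n_true, rel=0.02)

    def test_nuclei_area_fraction_recovery(self, mri_pos_core, segmented_core):
        _, _, _, truth = mri_pos_core
        _, quant, _, _ = segmented_core
        assert quant.nuclei_fraction == pytest.approx(
            truth.true_fractions.nuclei_fraction, abs=0.02)


class TestMarkers:
    def test_background_only_fraction_below_half_percent(self, params_small):
        rng = np.random.default_rng(1)
        stroma = np.zeros((256, 256), bool)
        stroma[20:236, 20:236] = True
        marker = rng.normal(30, 5, (256, 256)).clip(0, 255).astype(np.uint8)
        mask = marker_positivity(marker, stroma, params_small)
        assert mask.sum() / stroma.sum() < 0.005

    def test_empty_stroma_returns_missing(self, params_small):
        marker = np.zeros((64, 64), np.uint8)
        assert marker_positivity(marker, np.zeros((64, 64), bool),
                                 params_small) is None

    def test_mask_confined_to_stroma(self, segmented_core):
        masks, _, _, _ = segmented_core
        for name, mask in masks.marker_masks.items():
            assert mask is not None
            assert not (mask & masks.epithelium).any()
            assert not (mask & ~masks.stroma).any()

    def test_low_fap_recovered_within_30_percent_relative(self, mri_pos_core,
                                                          segmented_core):
        _, _, _, truth = mri_pos_core
        _, quant, _, _ = segmented_core
        true_fap = truth.true_fractions.marker_fractions["FAP"]
        assert true_fap == pytest.approx(0.031, abs=0.003)
        assert quant.marker_fractions["FAP"] == pytest.approx(true_fap, rel=0.30)
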