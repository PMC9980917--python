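"""Generator contracts: exact ground truth, determinism, class structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromascope.datatypes import MARKERS
from stromascope.errors import ParameterError
from stromascope.synthcore import (
    CLASS_DEFAULTS,
    CohortSpec,
    CoreSpec,
    generate_cohort,
    generate_core,
)


class TestGenerateCore:
    def test_truth_fractions_equal_independent_recount(self, mri_pos_core):
        """Stored fractions must equal a brute-force pixel recount, exactly."""
        spec, r1, r2, truth = mri_pos_core
        m = truth.masks
        t = int(np.count_nonzero(m.tissue))
        q = truth.true_fractions
        assert q.epithelium_fraction == np.count_nonzero(m.epithelium) / t
        assert q.stroma_fraction == np.count_nonzero(m.stroma) / t
        assert q.lumen_fraction == np.count_nonzero(m.lumen) / t
        assert q.nuclei_fraction == np.count_nonzero(m.nuclei & m.tissue) / t
        s = int(np.count_nonzero(m.stroma))
        for mk in MARKERS:
            assert q.marker_fractions[mk] == np.count_nonzero(m.marker_masks[mk]) / s

    def test_rendered_fractions_hit_targets(self):
        spec = CoreSpec(
            core_id="c", lesion_class="mri_pos",
            target_epithelium_fraction=0.40, target_lumen_fraction=0.08,
            target_nuclei_fraction=0.15,
            marker_fractions={"CD8": 0.01, "FAP": 0.031, "CD163": 0.03, "SMA": 0.45},
            seed=11, size=256,
        )
        _, _, truth = generate_core(spec)
        q = truth.true_fractions
        assert q.epithelium_fraction == pytest.approx(0.40, abs=0.02)
        assert q.lumen_fraction == pytest.approx(0.08, abs=0.02)
        assert q.nuclei_fraction == pytest.approx(0.15, abs=0.02)
        assert q.marker_fractions["FAP"] == pytest.approx(0.031, abs=0.005)

    def test_mask_invariants_hold(self, mri_pos_core):
        _, _, _, truth = mri_pos_core
        truth.masks.validate()  # raises on violation
        m = truth.masks
        # conservation: tissue exactly tiled by epithelium + stroma
        assert (m.epithelium.sum() + m.stroma.sum()) == m.tissue.sum()

    def test_zero_epithelium_gives_background_panepi(self):
        spec = CoreSpec.for_class(
            "benign", seed=5, size=128,
            target_epithelium_fraction=0.0, target_lumen_fraction=0.0,
        )
        r1, _, truth = generate_core(spec)
        assert truth.true_fractions.epithelium_fraction == 0.0
        assert r1["PanEpi"].max() < 80  # background + noise only, no stain

    def test_same_seed_bit_identical(self):
        spec = CoreSpec.for_class("mri_neg", seed=7, size=128)
        a1, a2, _ = generate_core(spec)
        b1, b2, _ = generate_core(spec)
        for ch in a1.channels:
            np.testing.assert_array_equal(a1[ch], b1[ch])
        for ch in a2.channels:
            np.testing.assert_array_equal(a2[ch], b2[ch])

    def test_infeasible_geometry_rejected(self):
        spec = CoreSpec.for_class("benign", target_epithelium_fraction=0.95,
                                  target_lumen_fraction=0.2)
        with pytest.raises(ParameterError):
            generate_core(spec)

    def test_fap_pixel_count_monotone_in_target(self):
        counts = []
        for f in (0.01, 0.05, 0.10, 0.20):
            spec = CoreSpec.for_class(
                "mri_pos", seed=9, size=128,
                marker_fractions={"CD8": 0.01, "FAP": f, "CD163": 0.03, "SMA": 0.4},
            )
            _, _, truth = generate_core(spec)
            counts.append(int(truth.masks.marker_masks["FAP"].sum()))
        assert counts == sorted(counts)

    def test_class_default_ordering_matches_biology(self):
        fap = [CLASS_DEFAULTS[c]["markers"]["FAP"]
               for c in ("benign", "mri_neg", "mri_pos")]
        sma = [CLASS_DEFAULTS[c]["markers"]["SMA"]
               for c in ("benign", "mri_neg", "mri_pos")]
        assert fap == sorted(fap) and len(set(fap)) == 3
        assert sma == sorted(sma, reverse=True) and len(set(sma)) == 3


class TestGenerateCohort:
    def test_class_ordering_on_simulated_cohort(self):
        """FAP rises and SMA falls from benign to MRI-positive (rank test)."""
        df = generate_cohort(CohortSpec(n_patients=200, seed=2))
        for a, b, col in [
            ("benign", "mri_pos", "FAP"),
            ("benign", "mri_neg", "FAP"),
        ]:
            u = stats.mannwhitneyu(df[f"{a}_{col}_fraction"],
                                   df[f"{b}_{col}_fraction"],
                                   alternative="less")
            assert u.pvalue < 0.01
        u = stats.mannwhitneyu(df["benign_SMA_fraction"],
                               df["mri_pos_SMA_fraction"],
                               alternative="greater")
        assert u.pvalue < 0.01

    def test_rank_correlations_recovered(self):
        cspec = CohortSpec(n_patients=400, seed=4)
        df = generate_cohort(cspec)
        for (a, b), target in cspec.marker_correlation.items():
            rho = stats.spearmanr(df[f"mri_pos_{a}_fraction"],
                                  df[f"mri_pos_{b}_fraction"]).statistic
            assert rho == pytest.approx(target, abs=0.1)

    def test_extreme_censoring_censors_everyone(self):
        df = generate_cohort(CohortSpec(n_patients=50, censoring_rate=1e6, seed=1))
        assert df["event"].sum() == 0
        assert df["time_months"].max() < 0.01

    def test_seed_determinism(self):
        a = generate_cohort(CohortSpec(n_patients=30, seed=8))
        b = generate_cohort(CohortSpec(n_patients=30, seed=8))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(CohortSpec(n_patients=1))

    def test_null_effect_cox_calibration(self):
        """With zero log-hazards, the Cox estimate stays within 2 SE of 0."""
        from stromascope.cohortstats import cox_fit

        hits = 0
        reps = 40
        for s in range(reps):
            df = generate_cohort(CohortSpec(
                n_patients=500, log_hazard_fap=0.0, log_hazard_sma=0.0,
                baseline_hazard=0.006, seed=1000 + s,
            ))
            fit = cox_fit(df["time_months"], df["event"],
                          df[["mri_pos_FAP_fraction"]])
            row = fit.coefs.iloc[0]
            se = (np.log(row.ci_high) - np.log(row.ci_low)) / (2 * 1.959964)
            if abs(row.beta) < 2 * se:
                hits += 1
        assert hits / reps >= 0.90
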