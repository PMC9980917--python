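"""Calibration and validation experiments for the whole pipeline.

Each function here re-runs a slice of the package on synthetic data with
known truth and returns the measured quantities: segmentation recovery on a
multi-class core sweep, registration accuracy, marker-level recovery,
survival-engine operating characteristics (CI coverage, log-rank power,
family-wise error of the Bonferroni screen, Schoenfeld and DeLong type-I
error), brightfield recovery and cross-modality concordance, and full-run
determinism.  The published association table (counts printed for the
PTEN / ERG / BCR cross-tabulations) is reproduced from its printed counts.

Both the test suite and ``scripts/acceptance.py`` call these functions, so
every reported number is recomputed from scratch at run time.
"""

from __future__ import annotations

import filecmp
import math
import tempfile
import time as _time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from stromascope import cohortstats as cs
from stromascope.brightfield import (
    CLASSES,
    classify_and_quantify,
    fluorescence_concordance,
    render_brightfield_core,
    render_class_map,
    sample_scribbles,
    train_pixel_classifier,
)
from stromascope.quantify import quantify_core
from stromascope.register import estimate_shift, register_rounds
from stromascope.segment import SegmentationParams, otsu_threshold, segment_core
from stromascope.synthcore import CohortSpec, CoreSpec, generate_cohort, generate_core

# ---------------------------------------------------------------------------
# published association table (printed counts are the input data)
# ---------------------------------------------------------------------------

#: FAP-low / FAP-high counts per clinical stratum as printed for the
#: MRI-visible-lesion cohort (rows: variable level, cols: low/high).
TABLE1_FAP_COUNTS = {
    "PTEN": {"Neg": (11, 36), "Pos": (140, 115)},
    "ERG": {"Neg": (107, 103), "Pos": (44, 48)},
    "BCR": {"No": (133, 115), "Yes": (9, 23)},
}

#: row percentages as printed (integers)
TABLE1_FAP_PRINTED_PERCENT = {
    "PTEN": {"Neg": (23, 77), "Pos": (55, 45)},
    "ERG": {"Neg": (51, 49), "Pos": (48, 52)},
    "BCR": {"No": (54, 46), "Yes": (28, 72)},
}


def table1_reproduction() -> dict:
    """Row percentages and tests recomputed from the printed counts."""
    out: dict = {"rows": {}}
    for var, rows in TABLE1_FAP_COUNTS.items():
        counts = np.array([rows[k] for k in rows])
        ct = cs.crosstab_from_counts(counts, force_fisher=True)
        for i, level in enumerate(rows):
            out["rows"][f"{var}_{level}"] = tuple(
                int(round(p)) for p in ct.row_percent[i]
            )
        out[f"{var}_p"] = ct.p
        out[f"{var}_test"] = ct.test_used
    neg = TABLE1_FAP_COUNTS["PTEN"]["Neg"]
    out["fap_high_share_pten_neg_percent"] = 100.0 * neg[1] / sum(neg)
    return out


# ---------------------------------------------------------------------------
# segmentation + registration + marker recovery sweep
# ---------------------------------------------------------------------------


def segmentation_sweep(n_cores: int = 50, size: int = 256, seed: int = 0
                       ) -> pd.DataFrame:
    """Generate, register, segment and quantify ``n_cores`` cores across the
    three lesion classes; one row per core with truth and measured values."""
    rng = np.random.default_rng(seed)
    params = SegmentationParams.for_image_size(size)
    classes = ("benign", "mri_neg", "mri_pos")
    rows = []
    for i in range(n_cores):
        lc = classes[i % 3]
        shift = tuple(np.round(rng.uniform(-12.0, 12.0, 2), 1))
        spec = CoreSpec.for_class(
            lc, core_id=f"sweep{i:03d}", seed=int(rng.integers(2**31 - 1)),
            size=size, round2_shift=shift,
        )
        r1, r2, truth = generate_core(spec)
        aligned, reg = register_rounds(r1, r2)
        masks, _ = segment_core(r1, aligned, params)
        q = quantify_core(masks, pixel_size_um=spec.pixel_size_um,
                          core_id=spec.core_id, lesion_class=lc,
                          registration_ok=reg.ok)
        t = truth.true_fractions
        row = {
            "lesion_class": lc,
            "shift_err": math.hypot(reg.shift[0] - shift[0],
                                    reg.shift[1] - shift[1]),
            "conserved": (masks.epithelium.sum() + masks.stroma.sum()
                          == masks.tissue.sum()),
            "marker_in_stroma": all(
                m is None or not (m & ~masks.stroma).any()
                for m in masks.marker_masks.values()
            ),
        }
        for f in ("epithelium", "stroma", "nuclei", "lumen"):
            row[f"{f}_true"] = getattr(t, f"{f}_fraction")
            row[f"{f}_meas"] = getattr(q, f"{f}_fraction")
            row[f"{f}_err"] = row[f"{f}_meas"] - row[f"{f}_true"]
        for m in ("CD8", "FAP", "CD163", "SMA"):
            row[f"{m}_true"] = t.marker_fractions[m]
            row[f"{m}_meas"] = q.marker_fractions[m]
        rows.append(row)
    return pd.DataFrame(rows)


def otsu_oracle_max_deviation(n_samples: int = 25, seed: int = 0) -> float:
    """Max |implementation - exhaustive-search oracle| over random 8-bit
    samples (the oracle is an explicit loop over every cut point)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        kind = rng.integers(3)
        if kind == 0:
            sample = rng.integers(0, 256, 400)
        elif kind == 1:
            sample = np.r_[rng.integers(0, 80, 300), rng.integers(150, 256, 100)]
        else:
            sample = np.clip(rng.normal(100, 40, 400).astype(int), 0, 255)
        if np.unique(sample).size < 2:
            continue
        worst = max(worst, abs(otsu_threshold(sample)
                               - _otsu_bruteforce(sample)))
    return worst


def _otsu_bruteforce(values) -> float:
    v = np.asarray(values, float).ravel()
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


def registration_shift_errors(max_shift: int = 20, seed: int = 0,
                              size: int = 192) -> list[float]:
    """Recovery error for a grid of known shifts up to ±``max_shift`` px."""
    spec = CoreSpec.for_class("mri_neg", seed=seed, size=size)
    r1, _, _ = generate_core(spec)
    dapi = r1["DAPI"]
    errors = []
    from scipy import ndimage as ndi
    for dx, dy in [(max_shift, max_shift), (-max_shift, max_shift),
                   (7, -13), (-4, 2), (0, -max_shift), (11, 0)]:
        moved = ndi.shift(dapi.astype(float), (dy, dx), order=1, cval=4.0)
        res = estimate_shift(dapi, moved)
        errors.append(math.hypot(res.shift[0] - dx, res.shift[1] - dy))
    return errors


def marker_recovery(levels=(0.003, 0.01, 0.031, 0.10, 0.20), size: int = 256,
                    seed: int = 0) -> pd.DataFrame:
    """Stromal FAP recovery across plausible levels; one row per level."""
    params = SegmentationParams.for_image_size(size)
    rows = []
    for i, level in enumerate(levels):
        spec = CoreSpec.for_class(
            "mri_pos", seed=seed + 7 * i, size=size,
            marker_fractions={"CD8": 0.015, "FAP": level, "CD163": 0.031,
                              "SMA": 0.413},
        )
        r1, r2, truth = generate_core(spec)
        aligned, reg = register_rounds(r1, r2)
        masks, _ = segment_core(r1, aligned, params)
        q = quantify_core(masks, core_id=spec.core_id, registration_ok=reg.ok)
        true = truth.true_fractions.marker_fractions["FAP"]
        rows.append({
            "target": level, "true": true, "measured": q.marker_fractions["FAP"],
            "rel_err": (q.marker_fractions["FAP"] - true) / true,
            "in_stroma": not (masks.marker_masks["FAP"] & ~masks.stroma).any(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival-engine operating characteristics
# ---------------------------------------------------------------------------

#: event-process defaults for the calibration experiments: constant baseline
#: hazard giving roughly a quarter of patients an event over the five-year
#: follow-up window, with light independent censoring.
_CAL_BASELINE = 0.006
_CAL_CENSOR = 0.004


def cox_ci_coverage(true_hr: float = 2.75, n: int = 300, reps: int = 200,
                    seed: int = 0) -> dict:
    """Wald-CI coverage of a median-dichotomized marker effect.

    Cohorts are generated with the hazard acting on the median split of the
    FAP fraction; each replicate re-derives the split with
    :func:`stromascope.cohortstats.dichotomize` and fits the Cox model.
    """
    covered = 0
    hrs = []
    used = 0
    for s in range(reps):
        df = generate_cohort(CohortSpec(
            n_patients=n, log_hazard_fap=math.log(true_hr), log_hazard_sma=0.0,
            baseline_hazard=_CAL_BASELINE, censoring_rate=_CAL_CENSOR,
            hazard_form="median", seed=seed * reps + s,
        ))
        labels, _ = cs.dichotomize(df["mri_pos_FAP_fraction"].to_numpy(),
                                   "median")
        fit = cs.cox_fit(df["time_months"], df["event"],
                         pd.DataFrame({"fap_high": labels.astype(float)}))
        if not fit.converged:
            continue
        row = fit.coefs.loc["fap_high"]
        used += 1
        hrs.append(row.HR)
        if row.ci_low <= true_hr <= row.ci_high:
            covered += 1
    return {"coverage": covered / used, "mean_hr": float(np.mean(hrs)),
            "reps_used": used}


def logrank_power(true_hr: float = 4.48, n: int = 280, reps: int = 200,
                  seed: int = 0, alpha: float = 0.05) -> float:
    """Log-rank rejection rate for a top-decile (10% prevalence) marker."""
    rejected = 0
    for s in range(reps):
        df = generate_cohort(CohortSpec(
            n_patients=n, log_hazard_fap=math.log(true_hr), log_hazard_sma=0.0,
            baseline_hazard=_CAL_BASELINE, censoring_rate=_CAL_CENSOR,
            hazard_form="top_decile", seed=seed * reps + s,
        ))
        labels, _ = cs.dichotomize(df["mri_pos_FAP_fraction"].to_numpy(),
                                   "top_decile")
        fit, _ = cs.km_logrank(df["time_months"].to_numpy(),
                               df["event"].to_numpy(), labels)
        if fit.logrank_p is not None and fit.logrank_p < alpha:
            rejected += 1
    return rejected / reps


def screen_fwer(n_vars: int = 53, n: int = 120, reps: int = 200,
                seed: int = 0, alpha: float = 0.05) -> float:
    """Family-wise error of the Bonferroni-corrected univariable screen
    under the global null (no covariate affects the hazard)."""
    rng = np.random.default_rng(seed)
    any_hit = 0
    cols = [f"v{i}" for i in range(n_vars)]
    for _ in range(reps):
        tm = rng.exponential(1.0 / _CAL_BASELINE, n)
        cm = np.minimum(rng.exponential(1.0 / _CAL_CENSOR, n), 60.0)
        df = pd.DataFrame(rng.standard_normal((n, n_vars)), columns=cols)
        df["time_months"] = np.minimum(tm, cm)
        df["event"] = (tm <= cm).astype(int)
        results = cs.univariable_screen(df, cols, family_size=n_vars)
        if any(r.p_corrected is not None and r.p_corrected <= alpha
               for r in results):
            any_hit += 1
    return any_hit / reps


def schoenfeld_type1(reps: int = 500, n: int = 150, seed: int = 0,
                     alpha: float = 0.05) -> float:
    """Rejection rate of the Schoenfeld PH test on PH-consistent cohorts."""
    rej = used = 0
    for s in range(reps):
        df = generate_cohort(CohortSpec(
            n_patients=n, baseline_hazard=_CAL_BASELINE,
            censoring_rate=_CAL_CENSOR, seed=seed * reps + s,
        ))
        fit = cs.cox_fit(df["time_months"], df["event"],
                         df[["mri_pos_FAP_fraction"]])
        if not fit.converged:
            continue
        p = cs.ph_check(fit)["mri_pos_FAP_fraction"]
        used += 1
        rej += p < alpha
    return rej / used


def delong_type1(reps: int = 500, n: int = 200, seed: int = 0,
                 alpha: float = 0.05) -> float:
    """Type-I error of the DeLong comparison for equal-AUC correlated scores
    sharing a latent risk variable."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        latent = rng.standard_normal(n)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-latent))).astype(int)
        if y.min() == y.max():
            continue
        a = latent + rng.standard_normal(n)
        b = latent + rng.standard_normal(n)
        rej += cs.delong_compare(y, a, b).p_raw < alpha
    return rej / reps


# ---------------------------------------------------------------------------
# brightfield
# ---------------------------------------------------------------------------


def brightfield_composition_recovery(seed: int = 0) -> dict:
    """Train on one mosaic, recover known 10% FAP / 30% SMA composition."""
    rng = np.random.default_rng(seed)
    h = w = 160
    cm = np.zeros((h, w), dtype=np.uint8)
    inner = np.zeros((h - 20, w - 20), dtype=np.uint8)
    npix = inner.size
    order = rng.permutation(npix)
    inner.flat[order[: int(0.1 * npix)]] = CLASSES.index("FAP_pos")
    inner.flat[order[int(0.1 * npix): int(0.4 * npix)]] = CLASSES.index("SMA_pos")
    inner.flat[order[int(0.4 * npix):]] = CLASSES.index("other_tissue")
    cm[10:-10, 10:-10] = inner
    img = render_class_map(cm, rng)
    model = train_pixel_classifier(
        [img], sample_scribbles([cm], 400, seed=seed + 1), seed=seed + 2)
    q, _ = classify_and_quantify(model, img)
    return {
        "fap_fraction": q.fap_fraction, "sma_fraction": q.sma_fraction,
        "holdout_accuracy": model.holdout_accuracy_,
        "model": model,
    }


def modality_concordance(n_pairs: int = 50, size: int = 192, seed: int = 0,
                         model=None) -> float:
    """Pearson r between fluorescence (stroma-normalized) and chromogenic
    (tissue-normalized) FAP fractions on paired renditions of the same
    cores, spanning FAP 0-0.25."""
    if model is None:
        model = brightfield_composition_recovery(seed)["model"]
    rng = np.random.default_rng(seed + 3)
    fluor, bright = [], []
    for i in range(n_pairs):
        fap = 0.25 * (i + 1) / n_pairs
        spec = CoreSpec.for_class(
            "mri_pos", seed=int(rng.integers(2**31 - 1)), size=size,
            marker_fractions={"CD8": 0.015, "FAP": fap, "CD163": 0.031,
                              "SMA": 0.413},
        )
        _, _, truth = generate_core(spec)
        img, _ = render_brightfield_core(truth.masks, rng)
        q, _ = classify_and_quantify(model, img)
        fluor.append(truth.true_fractions.marker_fractions["FAP"])
        bright.append(q.fap_fraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fluorescence_concordance(fluor, bright)


# ---------------------------------------------------------------------------
# determinism / runtime of the demo pipeline
# ---------------------------------------------------------------------------


def pipeline_determinism(seed: int = 0, n_patients: int = 20,
                         image_size: int = 192) -> dict:
    """Run the demo pipeline twice with one seed; compare outputs byte-wise."""
    from stromascope.pipeline import RunConfig, run_pipeline

    with tempfile.TemporaryDirectory() as tmp:
        t0 = _time.perf_counter()
        cfg_a = RunConfig(out_dir=str(Path(tmp) / "a"), seed=seed,
                          n_patients=n_patients, image_size=image_size)
        run_pipeline(cfg_a)
        runtime = _time.perf_counter() - t0
        cfg_b = RunConfig(out_dir=str(Path(tmp) / "b"), seed=seed,
                          n_patients=n_patients, image_size=image_size)
        run_pipeline(cfg_b)
        identical = all(
            filecmp.cmp(Path(tmp) / "a" / f, Path(tmp) / "b" / f,
                        shallow=False)
            for f in ("cores.csv", "patients.csv", "screen.csv",
                      "km_curves.csv", "model_summary.json")
        )
    return {"identical": identical, "runtime_s": runtime}
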