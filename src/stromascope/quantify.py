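"""Per-core quantification and patient-level aggregation.

Compartment areas and object counts are normalized to total tissue
area/count; marker-positive areas are normalized to total stroma area.
Patients are analyzed case-based: replicate cores of the same lesion class
are averaged (unweighted mean of fractions over non-missing cores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stromascope.datatypes import LESION_CLASSES, MARKERS, CompartmentMasks, CoreQuant
from stromascope.errors import ParameterError

#: follow-up below this (3 weeks, in months) excludes a patient from outcome
#: analyses.
MIN_FOLLOWUP_MONTHS = 21 / 30.4375


def quantify_core(
    masks: CompartmentMasks,
    pixel_size_um: float = 0.25,
    core_id: str = "",
    lesion_class: str | None = None,
    registration_ok: bool = True,
) -> CoreQuant:
    """Exact pixel-count fractions and counts from compartment masks.

    Marker fractions are missing when stroma is empty; the SMA fraction is
    additionally missing when ``registration_ok`` is False (failed round-2
    alignment).  An empty tissue mask yields all-missing with a QC flag.
    """
    q = CoreQuant(core_id=core_id, lesion_class=lesion_class)
    t = int(masks.tissue.sum())
    if t == 0:
        q.qc_flags.append("empty_tissue")
        q.marker_fractions = {m: None for m in MARKERS}
        return q

    epi = int(masks.epithelium.sum())
    stroma = int(masks.stroma.sum())
    q.epithelium_fraction = epi / t
    q.stroma_fraction = stroma / t
    q.lumen_fraction = int(masks.lumen.sum()) / t
    q.nuclei_fraction = int((masks.nuclei & masks.tissue).sum()) / t
    q.gland_count = int(masks.epithelium_objects.max())
    q.lumen_count = int(masks.lumen_objects.max())
    q.nuclei_count = int(masks.nuclei_objects.max())
    area_mm2 = t * (pixel_size_um**2) / 1e6
    q.glands_per_mm2 = q.gland_count / area_mm2
    q.lumens_per_mm2 = q.lumen_count / area_mm2

    for m in MARKERS:
        mask = masks.marker_masks.get(m)
        if stroma == 0 or mask is None or (m == "SMA" and not registration_ok):
            q.marker_fractions[m] = None
            if stroma == 0:
                q.qc_flags.append("empty_stroma")
            elif m == "SMA" and not registration_ok:
                q.qc_flags.append("registration_failed")
        else:
            q.marker_fractions[m] = int(mask.sum()) / stroma
    return q


# ---------------------------------------------------------------------------
# patient aggregation
# ---------------------------------------------------------------------------

_FRACTION_COLS = [
    "epithelium_fraction",
    "stroma_fraction",
    "nuclei_fraction",
    "lumen_fraction",
    "glands_per_mm2",
    "lumens_per_mm2",
] + [f"{m}_fraction" for m in MARKERS]


@dataclass
class ExclusionLog:
    """REMARK-style accounting of patients entering / leaving the analysis."""

    loaded: int = 0
    analyzed: int = 0
    excluded: dict[str, int] = field(default_factory=dict)

    def exclude(self, reason: str) -> None:
        self.excluded[reason] = self.excluded.get(reason, 0) + 1

    def check(self) -> None:
        if self.loaded != self.analyzed + sum(self.excluded.values()):
            raise ParameterError("exclusion accounting does not balance")


def aggregate_patient(cores: list[CoreQuant], meta: dict) -> dict:
    """Average one patient's replicate cores per lesion class.

    ``meta`` carries patient_id, covariates and outcome (``event``,
    ``time_months``; NaN/None outcome marks it missing).  Returns a flat
    record with ``{lesion_class}_{measure}`` columns; classes with zero
    usable cores stay missing.  Exclusion reasons (``no_usable_cores``,
    ``missing_outcome``, ``short_followup``) are listed under ``"exclude"``.
    """
    rec = dict(meta)
    rec.setdefault("patient_id", "unknown")
    any_usable = False
    for lc in LESION_CLASSES:
        sub = [c.to_row() for c in cores if c.lesion_class == lc]
        for col in _FRACTION_COLS:
            vals = [r[col] for r in sub if np.isfinite(r[col])]
            rec[f"{lc}_{col}"] = float(np.mean(vals)) if vals else np.nan
            if vals:
                any_usable = True
    reasons = []
    if not any_usable:
        reasons.append("no_usable_cores")
    ev, tm = rec.get("event"), rec.get("time_months")
    if ev is None or (isinstance(ev, float) and np.isnan(ev)):
        reasons.append("missing_outcome")
    elif tm is None or (isinstance(tm, float) and np.isnan(tm)):
        reasons.append("missing_outcome")
    elif tm < MIN_FOLLOWUP_MONTHS:
        reasons.append("short_followup")
    rec["exclude"] = ";".join(reasons)
    return rec


def aggregate_patients(
    core_df: pd.DataFrame, meta_df: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Aggregate a per-core table to the per-patient analysis table.

    ``core_df`` needs ``patient_id``, ``lesion_class`` and the measurement
    columns; ``meta_df`` one row per patient.  Patients flagged for exclusion
    are dropped from the returned table but counted in the log
    (loaded = analyzed + excluded).
    """
    log = ExclusionLog(loaded=len(meta_df))
    records = []
    cores_by_pid = dict(tuple(core_df.groupby("patient_id", sort=False)))
    for _, meta in meta_df.iterrows():
        pid = meta["patient_id"]
        sub = cores_by_pid.get(pid, pd.DataFrame(columns=core_df.columns))
        quants = []
        for _, row in sub.iterrows():
            q = CoreQuant(core_id=row.get("core_id", ""), lesion_class=row["lesion_class"])
            q.epithelium_fraction = _get(row, "epithelium_fraction")
            q.stroma_fraction = _get(row, "stroma_fraction")
            q.nuclei_fraction = _get(row, "nuclei_fraction")
            q.lumen_fraction = _get(row, "lumen_fraction")
            q.glands_per_mm2 = _get(row, "glands_per_mm2")
            q.lumens_per_mm2 = _get(row, "lumens_per_mm2")
            for m in MARKERS:
                q.marker_fractions[m] = _get(row, f"{m}_fraction")
            quants.append(q)
        rec = aggregate_patient(quants, meta.to_dict())
        if rec["exclude"]:
            for reason in rec["exclude"].split(";"):
                log.exclude(reason)
                break  # first reason counts, one exclusion per patient
        else:
            records.append(rec)
    log.analyzed = len(records)
    log.check()
    out = pd.DataFrame(records)
    if "exclude" in out.columns:
        out = out.drop(columns=["exclude"])
    return out, log


def _get(row, col):
    v = row.get(col, np.nan)
    return None if (v is None or (isinstance(v, float) and np.isnan(v))) else float(v)
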