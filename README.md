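# stromascope

Quantification of stromal composition in prostate tissue microarray (TMA)
cores from two-round multiplexed fluorescence immunohistochemistry (mfIHC),
with the statistics layer needed to relate stromal phenotypes to MRI lesion
visibility and patient outcome.

## The problem

MRI misses a nontrivial fraction of clinically significant prostate cancers,
and the tumor microenvironment is a suspected driver of that visibility.
Quantifying it from multiplexed imaging requires a full computational chain:

1. **Registration** — round 2 (SMA) is acquired after bleaching and restaining,
   so its channels must be aligned onto round 1 via the shared DAPI channel
   (translation-only phase correlation with subpixel refinement).
2. **Segmentation** — pixel classification of each core into tissue (Otsu
   threshold on the channel sum), epithelial gland objects (adaptive Otsu of
   the PanEpi channel inside tissue), stroma (tissue minus epithelium),
   gland lumens (fill-and-subtract of the epithelial mask), and nuclei
   (adaptive Otsu of DAPI with watershed declumping).
3. **Quantification** — compartment areas and object counts normalized to
   total tissue area (A_epi/A_tissue, …); marker-positive areas for CD8, FAP,
   CD163 and SMA normalized to total stroma area (A_marker/A_stroma), with
   replicate cores of a patient averaged per lesion class
   (benign / MRI false-negative / MRI true-positive).
4. **Brightfield path** — a supervised 4-class pixel classifier
   (empty / FAP⁺ / SMA⁺ / other tissue) for chromogenic FAP(brown)/SMA(red)/
   hematoxylin double stains, reporting FAP and SMA fractions of total tissue.
5. **Statistics** — KS-normality-gated t / Mann–Whitney contrasts,
   Pearson/Spearman correlations, Fisher/χ² cross-tabulations, biomarker
   dichotomization (median / fixed / decile cutoffs), a Bonferroni-corrected
   univariable Cox screen, Kaplan–Meier with log-rank, multivariable Cox
   (Efron ties, Wald inference), Schoenfeld proportional-hazards diagnostics,
   and the DeLong test for correlated AUCs.

Because the cohort images are not public, the package ships a first-class
synthetic-data module: two-round core images with exact pixel-level ground
truth (class-conditional compartment and marker fractions, inter-round
misregistration, correlated marker levels, proportional-hazards outcomes),
so every stage is testable end to end.

## Worked example

```python
from stromascope.synthcore import CoreSpec, generate_core
from stromascope.register import register_rounds
from stromascope.segment import SegmentationParams, segment_core
from stromascope.quantify import quantify_core

spec = CoreSpec.for_class("mri_pos", seed=3, size=256, round2_shift=(5.0, -3.0))
r1, r2, truth = generate_core(spec)

aligned, reg = register_rounds(r1, r2)
print(f"estimated shift: ({reg.shift[0]:.2f}, {reg.shift[1]:.2f}), score {reg.score:.3f}")

masks, _ = segment_core(r1, aligned, SegmentationParams.for_image_size(256))
q = quantify_core(masks, core_id=spec.core_id, registration_ok=reg.ok)

t = truth.true_fractions
print(f"epithelium {q.epithelium_fraction:.3f} (truth {t.epithelium_fraction:.3f})")
print(f"stroma     {q.stroma_fraction:.3f} (truth {t.stroma_fraction:.3f})")
print(f"lumen      {q.lumen_fraction:.3f} (truth {t.lumen_fraction:.3f})")
print(f"FAP        {q.marker_fractions['FAP']:.4f} (truth {t.marker_fractions['FAP']:.4f})")
print(f"SMA        {q.marker_fractions['SMA']:.3f} (truth {t.marker_fractions['SMA']:.3f})")
```

prints

```
estimated shift: (5.00, -3.00), score 0.959
epithelium 0.476 (truth 0.480)
stroma     0.524 (truth 0.520)
lumen      0.076 (truth 0.076)
FAP        0.0306 (truth 0.0310)
SMA        0.407 (truth 0.413)
```

The true inter-round shift of (5, −3) px is recovered exactly; compartment
fractions land within half a percentage point of the rendered ground truth,
and the stroma-normalized FAP fraction (here a typical MRI-positive-lesion
level of ~3%) within a few percent relative.

The full pipeline — simulate a cohort, register, segment, quantify,
aggregate to patients, run the statistics — is one command:

```bash
stromascope run --out demo_run --seed 1
```

which writes `cores.csv`, `patients.csv`, `screen.csv`, `km_curves.csv`,
`crosstabs.csv`, `model_summary.json` and a `manifest.json` that accounts
for every simulated core and patient (loaded = analyzed + excluded, with
per-reason exclusion counts).

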