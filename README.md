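# truet

Quantification of T-cell infiltration in colorectal-cancer immunohistochemistry
(IHC) and its conversion into a prognostic label. The pipeline has three
stages, one model per marker (CD3 = all T-cells, CD4 = helper, CD8 =
cytotoxic):

1. **Segmentation** — a U-Net with a four-stage residual encoder (7×7
   stride-2 stem with 64 feature maps, /32 bottleneck with 1024 maps at
   default width, transpose-convolution decoder with skip connections)
   predicts DAB-positive cell masks from RGB patches; probabilities are
   thresholded at 0.5. Training: Adam (lr 1e-4), batch 16, weighted
   cross-entropy, rotation ≤ 30° and flips at p = 0.5, patient-wise
   70/16/14 split.
2. **Quantification** — cells are counted as 4-connected components and
   converted to density

   `density = ToC · 10⁶ / (p² · h · w · n_patches)  [cells/mm²]`

   where ToC is the total component count, `h × w` the patch size in pixels
   and `p` the pixel pitch in µm (0.25 by default, so one 512×512 patch
   covers 0.016384 mm²).
3. **Survival stratification** — a patient is **Low** when at least two
   marker densities fall strictly below per-marker cutoffs (defaults
   500 / 300 / 700 cells/mm²; cutoffs can be derived by ROC analysis of
   five-year mortality via Youden's J). Groups are compared with
   Kaplan–Meier curves and the log-rank test; a Cox model of the Low
   indicator plus age, stage, MSI and chemotherapy returns five-year
   survival probabilities `S(t|x) = S0(t)^exp(βᵀx)`.

Because clinical cohorts are not redistributable, the package ships a
synthetic generator producing IHC-like patches with *exact* ground-truth
masks (anti-aliased ellipse cells, per-institution stain shifts) and
survival cohorts with a latent immune-hot/cold state of known hazard ratio.
The neural-network engine is pure NumPy (convolutions, batch norm,
transpose convolutions, Adam, hand-derived backprop, finite-difference
checked), so everything runs offline on one CPU; see `docs/methods.md`.

## Worked example

```sh
truet simulate --out patches --n-patients 6 --patches-per-patient 2 --seed 3
truet quantify --masks patches --um-per-px 0.25 --out densities.csv
```

writes one density record per patient × marker, e.g.

```
patient_id,marker,total_cells,n_patches,density_per_mm2
P000,CD3,93,2,2838.134765625
```

(93 cells over two 512×512 patches at 0.25 µm/px → 93·10⁶/(0.0625·512·512·2)
= 2838.13 cells/mm²). Stratifying a simulated 200-patient cohort:

```sh
truet stratify --cohort cohort.csv --thresholds 500,300,700 --out strat.json
# log-rank p = 0.0013437457122035335
```

with a cold-state hazard ratio of 3 the majority-vote High/Low split
separates the survival curves decisively. Five-year prediction for one
patient:

```sh
truet predict-survival --cohort cohort.csv --patient P005
# P005: 5-year survival 85.2% [True-T High]
```

The full pipeline (`truet run --config run.yaml`) chains
simulate → train → predict → quantify → evaluate → stratify and writes a
manifest with checksums of every artifact.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs
the complete pipeline end to end on a small synthetic cohort (8 patients ×
3 markers, reduced-capacity model, ~1 min on one CPU): it trains the three
segmentation models, predicts and evaluates masks (pooled Dice ≈ 0.78–0.79,
object-level precision ≈ 0.88–0.95 per marker on the configured world),
quantifies densities and stratifies the simulated cohort, then writes the
JSON report to `--out`. All artifacts land in `scratch/acceptance_run/`.
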