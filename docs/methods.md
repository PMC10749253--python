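# Methods

## Scope and model

`truet` quantifies T-cell infiltration in colorectal-cancer IHC and converts
it into a prognostic label. The pipeline has three stages:

1. **Segmentation.** One binary segmentation model per marker (CD3, CD4,
   CD8) maps an RGB patch to a positive-cell probability map. The network is
   a U-Net whose encoder is a four-stage residual CNN: a 7×7 stride-2
   convolution producing 64 feature maps (at default width), a 2×2 max-pool,
   four stages of basic residual blocks doubling channels while halving
   resolution, and a 3×3 bottleneck at 1/32 resolution with 1024 feature
   maps (8×8 spatial for a 256×256 input). The decoder mirrors the encoder
   with 2×2 transpose convolutions and concatenating skip connections from
   every encoder stage, ending in a 1×1 convolution and sigmoid. Masks are
   produced by thresholding the probability map at 0.5.
2. **Quantification.** Predicted masks are labeled with 4-connected
   components (von Neumann neighborhood); each component counts as one cell.
   Density is `ToC · 10⁶ / (p² · h · w · n_patches)` cells/mm², with `p` the
   pixel pitch in µm (default 0.25, i.e. 40× scanning), `h × w` the patch
   geometry, and ToC the total count over a patient's patches. A minimum
   component area of 4 px (≈ sub-micron debris at 0.25 µm/px) is applied by
   default; 0 disables it.
3. **Stratification.** Each patient's three densities are compared against
   per-marker cutoffs (defaults 500 / 300 / 700 cells/mm² for CD3/CD4/CD8).
   A patient is **Low** when at least two available markers lie strictly
   below their cutoffs, else **High**; equality votes High. Cutoffs can
   instead be derived per marker by ROC analysis against five-year
   mortality, maximizing Youden's J over the observed densities (ties →
   lowest cutoff). Group survival is summarized with Kaplan–Meier curves and
   compared with the two-sample log-rank test. A Cox proportional-hazards
   model of the Low indicator plus age, stage (III/IV dummies vs II), MSI
   and chemotherapy yields per-patient five-year survival probabilities
   `S(t|x) = S0(t)^exp(βᵀx)`.

## Training recipe and defaults

Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e-4, batch 16, 100 epochs,
images scaled to [0, 1], weighted cross-entropy with probabilities clipped
at 1e-7, augmentation by rotation up to ±30° and independent
horizontal/vertical flips at p = 0.5, and a patient-wise 70/16/14
train/val/test split. Class weights are inverse pixel frequencies
normalized to mean one, `w_c = N/(2 N_c)`, computed once over the training
split and capped at 100 when a class is (nearly) absent. Model selection
keeps the epoch state with the best validation Dice. Rotation uses bilinear
interpolation with reflect fill for images and nearest-neighbor with
constant-0 fill for masks, so masks stay binary.

Because no deep-learning framework is assumed, the engine (`truet.nn`) is
pure NumPy with hand-derived backpropagation; all layers are checked against
central finite differences in the test suite. Consequences: training is
CPU-bound, so tests and the worked examples use a narrow channel plan
(8–16× fewer channels) and smaller inputs than the default 256×256/64-ch
recipe. The architecture, loss, optimizer and augmentation are identical at
any width. Encoder weights can be loaded from a local `.npz` via
`encoder_pretrained`/`pretrained_weights_path`; no download is attempted.

Divisibility: the forward pass requires sides divisible by 32; prediction
reflect-pads and crops automatically, and can resize to the training
resolution (`input_size`) before inference. The network is fully
convolutional, so a model trained at 256 can predict at native 512.

## Synthetic data: what it does and does not emulate

Patches: DAB-brown positive cells and hematoxylin-blue negative nuclei are
anti-aliased filled ellipses (random orientation, eccentricity ≤ 0.6) on a
pale noisy background; per-cell color jitter and per-institution mean-color
shifts emulate multi-site stain variability. The binary mask is thresholded
(≥ 50 % subpixel coverage) from the same geometry that is painted, so
ground truth is exact, and with non-overlap enforced (rejection sampling,
1000 retries, shortfalls recorded in `n_cells`) the 4-connected component
count equals the rendered cell count. Not modeled: chromatin texture,
stromal architecture, folds/bubbles, out-of-focus blur, or physically
based stain mixing. A green segmentation test therefore establishes that
the optimization and architecture work, not clinical-grade accuracy.

Cohorts: a latent immune-hot/cold state (p_hot = 0.5) drives per-marker
Gamma-distributed densities whose hot means (900/550/1100) sit above and
cold means (250/140/350) below the working cutoffs, and multiplies an
exponential baseline hazard of 0.045/yr (≈ 80 % five-year survival when
hot) by a hazard ratio of 3 when cold. Censoring is exponential (0.03/yr)
with an administrative cap at 5 years. Covariates (age ~ N(68, 10), stage
II/III/IV at 45/40/15 %, MSI 15 %, chemo 50 %) are drawn independently of
the latent state, so recovered Cox effects for them are null checks.

## Numerical choices and edge cases

- Counting uses 4-connectivity throughout, including object-level
  evaluation; "diagonal-only" contacts are distinct cells.
- AJI follows the greedy aggregated-Jaccard formulation: ground-truth
  objects in ascending label order, each matched to the unused intersecting
  prediction of highest IoU (ties → lower prediction label); unmatched
  prediction areas enter the union sum.
- Object precision/recall: one-to-one matching, candidates need ≥ 1 px of
  overlap, matched greedily by descending overlap; an optional IoU floor is
  exposed (default 0).
- Ratio metrics with empty denominators: 1 when both masks are empty,
  0 when only one side is empty. Averaging over a split pools confusion
  counts (micro); macro is available by averaging per-patch rows.
- ROC cutoffs use the death-within-5-years endpoint; patients censored
  alive before 5 years are excluded from cutoff derivation (a documented
  simplification). Log-rank with no events in either group is flagged
  rather than reported as 0/1.
- Cox ties use Efron's method, the baseline cumulative hazard the Breslow
  estimator (lifelines). `predict_survival_5yr` rescales the mean-centered
  lifelines baseline to the at-zero baseline so the closed form above holds
  exactly; horizons beyond follow-up carry the last value forward and are
  flagged as extrapolation.
- All randomness flows from explicit seeds; per-patient generator streams
  are derived via `SeedSequence([seed, patient_index])` so a patient's
  patches are invariant to cohort size.

## Known limitations

Touching positive cells merge into one component (no watershed splitting),
biasing counts low in dense infiltrates; overlap-allowed simulations
exercise this. The NumPy engine makes full-width 100-epoch training
impractical on one CPU; the package is faithful in structure and verified
at reduced capacity. Thresholds 500/300/700 are treated as cells/mm² and
are cancer-type specific; they are defaults, not constants.
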