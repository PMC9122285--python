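# Methods

## The model

`convsdm` studies a multi-species classification formulation of species
distribution modeling. Each occurrence *i* of species *y_i* at location
*(x, y)* is paired with an environmental tensor **x** — a C × H × W patch of
co-registered raster channels centered on the occurrence. A convolutional
feature extractor maps the patch to a feature vector **z** = φ(**x**), and a
linear head ψ gives per-species logits, normalized by the softmax:

    P(Y = k | X = x) = exp(ψ_k(z)) / Σ_j exp(ψ_j(z))

Training minimizes the multinomial cross-entropy. The species' logit serves
downstream as a relative habitat-suitability index; the probabilities are
*relative* probabilities of observing each species at the location, not
probabilities of presence (the data are presence-only).

The reference comparison is a point-environment model: a random forest
(100 trees, maximum depth 10, other parameters at library defaults) on the
vector of environment-raster values at the occurrence point. The scientific
contrast is informational: the forest sees point values only, the
convolutional model sees the spatial neighborhood.

### Backbone

The feature extractor is a stack of stride-2 3 × 3 convolutions with ReLU,
ending in global average pooling; default widths (24, 48, 64) give a 64-d
feature space for 32 × 32 patches. The same φ/ψ decomposition scales to a
full-size image backbone (an Inception-class network with a 2,048-d feature
space on 256 × 256 patches); the architecture is entirely configuration-
driven (`ModelConfig`) so that scale is a choice, not a code change. The
implementation is plain numpy — im2col convolutions with explicit
forward/backward passes and an Adam optimizer — which keeps the desk-scale
model dependency-free and bit-reproducible given the seed.

Input handling: the categorical land-cover channel is one-hot expanded at
model input (stored tensors keep the integer code) to avoid imposing a fake
ordering on classes; continuous channels are standardized with per-channel
mean/std computed on the training split only and stored with the model
(leakage hygiene). Training defaults: Adam, learning rate 2e-3, batch 64,
30 epochs, seeded shuffling and initialization.

## Tensor assembly

Rasters are north-up grids of square pixels in a planar (projected, meters)
CRS. Pixel extents are half-open — the containing pixel of a point is found
by flooring — which makes every geometric rule unambiguous:

- **Resampling.** Continuous layers are interpolated bilinearly (smooth,
  avoids sharp artificial edges a convolution would latch onto); categorical
  layers only by nearest neighbor, the one method that cannot invent
  classes. Bilinear on a categorical layer is an error, not a warning.
- **Patches.** For an even patch size P the occurrence pixel sits at index
  (P/2, P/2) and the patch spans source indices [c − P/2, c − P/2 + P) on
  each axis. There is no padding: a patch that would cross a layer border
  raises an error, and the synthetic generator excludes a half-patch margin
  at sampling time so the situation never arises. Real-data ingestion would
  need to filter border occurrences explicitly.
- **Point vectors.** The environment vector takes the value of the
  containing cell per raster; missing cells yield NaN (never silently 0),
  and a point outside all rasters is a coverage error.

Raster I/O is TIFF with the georeferencing (origin, resolution, kind,
nodata) embedded as JSON in the image description tag.

## Evaluation protocol

With r_i the rank of the true species in the descending score list:

- A_k = (1/n) Σ_i 1[r_i ≤ k] — top-k accuracy over occurrences;
- SA_{k,s} — the same indicator averaged over the j occurrences of species
  s; MSA_k — the unweighted mean of SA_{k,s} over species present in the
  test set, so frequent species do not dominate;
- ties in r_i are resolved pessimistically (true species placed last among
  equal scores), so a constant predictor gets rank S rather than rank 1.
  The default k is 30 at full scale; the desk-scale studies use k = 5 with
  20 species so that random ranking sits at 0.25.

**Spatial block holdout.** The domain is gridded into square quadrats
anchored at the lower-left corner of the occurrence bounding box (5 × 5 km
at full scale; 200 m in the desk-scale world). Quadrats are drawn uniformly
at random and wholly assigned to test until the test fraction first reaches
its target (2.5% at full scale; ~11% desk-scale so the test set keeps
≈500 occurrences); a random 0.5% of the remaining occurrences becomes a
validation set. No quadrat ever contains both train and test occurrences.

**Pseudo-absence AUC.** Presence-only data have no absences, so the AUC for
a species uses surrogate absences drawn from other species' test
occurrences in two stages: first a species, uniformly among species other
than the target with ≥1 test occurrence; then one of its test occurrences,
uniformly. This species-balanced draw avoids over-representing the habitats
of abundant species. Per species we draw 100 pseudo-absences, or as many as
the presences when the species has more than 100 test occurrences. Draws
are independent (with replacement across draws). The AUC is the rank
(Mann–Whitney) statistic with midrank tie handling; the convolutional model
is scored by its logits, the baseline by its probabilities. MeanAUC is the
unweighted mean over species, optionally recomputed within regions
(restricting both presences and pseudo-absences to the region's test set).

## Feature-space interpretation

2,000+ feature vectors are reduced to 2D by PCA to 50 components followed
by t-SNE (perplexity 30, PCA initialization, fixed seed; sklearn
implementation). The 3D variant for dense habitat maps skips the PCA. On
the 2D embedding:

- an n × n **mosaic** over the bounding box assigns to each cell the
  occurrence *inside that cell* nearest the cell center (a local search,
  not a global nearest neighbor — the distinction matters at cell borders);
- a **bilinear color gradient** (four fixed, maximally distinct corner
  colors — blue/red/green/yellow — configurable) colors each occurrence by
  its embedding position; a territory grid then takes each point's color
  from its geographically nearest embedded occurrence (1-NN, planar
  Euclidean), which reveals the ecoregion structure the model learned;
- per-axis **OLS regressions** on species traits or environment variables
  quantify whether the learned features relate to ecology. Predictors that
  are an exact difference of two others (the temperature-annual-range
  pattern, range = max − min) are perfectly collinear and excluded
  automatically, dropping from the end of the predictor table until no
  exact-difference relation remains. Rows with missing predictors are
  dropped and counted. These are deliberately plain linear models on a
  nonlinear embedding — a conservative check for signal, not a full
  spatial-statistical treatment (no autocorrelation correction, raw
  p-values).

## Suitability maps

A regular lattice (anchored at the area's lower-left corner, bounds
inclusive when the step divides the extent) is scored by extracting a patch
at every lattice point with exactly the training-data rules; points whose
patch would cross a border are marked failed, never silently dropped. Per
species, logits over the area are scaled to [0, 1] by a sigmoid whose
threshold is the mean logit of that species over the (successful) lattice
points, followed by min-max; the sigmoid slope is fixed at 1 in logit units
(any positive slope preserves order; 1 is the canonical choice). Baseline
probabilities get only the min-max step. Both scalings are strictly
increasing, so rank statistics — in particular the pseudo-absence AUC — are
exactly invariant; this is verified, not assumed. Constant scores over an
area make the rescaling undefined and raise a degenerate-map error.
Rendering composites the map over an RGB background with linear alpha from
transparent (0) to bright red (1).

## The synthetic study system

The generator emulates the structure of a very-high-resolution SDM dataset
at desk scale. Defaults — which are the study conditions for all end-to-end
tests — are a 2 × 2 km world at 2 m/px with 20 species, 4,500 occurrences
and 32 × 32 px patches:

- **Latent fields**, each min-max scaled to [0, 1]: a deterministic
  *temperature* gradient (monotone along x with a smooth sinusoidal
  cross-term); *moisture*, white noise smoothed with a 50 m Gaussian
  kernel; *elevation*, a two-scale surface — 120 m-kernel macro-relief plus
  8 m-kernel fine texture whose amplitude is modulated by an independent
  60 m-kernel *ruggedness* field. Real terrain is rough where there are
  mountains and smooth on plains; the two-scale construction makes local
  elevation variability a genuine landscape property. Its 60 m correlation
  length is shorter than the 200 m holdout quadrat, so a point-value model
  cannot recover it by spatial interpolation from neighboring training
  blocks, while a 64 m patch sees it directly — this is precisely the
  information asymmetry the convolutional model is meant to exploit.
- **Channels**: land cover = quantile band (5 classes) of a
  temperature/moisture mixture; pseudo-RGB = fixed per-class base colors
  modulated by the fields plus 2% sensor noise; near-IR = affine mix of
  moisture and per-class reflectance; elevation passes through unchanged.
- **Species niches**: product-Gaussian responses. Point-niche species have
  optima uniform in [0.15, 0.85] and breadths in [0.08, 0.18] on
  temperature, moisture and elevation. The 8 *context species* replace the
  elevation dimension by terrain ruggedness (local std of elevation in an
  8-px ≈ 16 m radius window; optima within the 10–90% quantile range,
  breadths 0.12–0.22 of that range) and are climate generalists (breadths
  0.2–0.35 on temperature/moisture): habitat-structure specialists whose
  discriminating axis is invisible to point values.
- **Sampling**: species drawn with probability ∝ prevalence (log-normal,
  σ = 0.6, mimicking right-skewed opportunistic recording); locations drawn
  ∝ suitability × effort; coordinates snapped to pixel centers; a
  half-patch margin excluded at the borders. The effort field is uniform by
  default with an optional roadside-stripe variant for bias experiments —
  the sampling-bias model is an assumption, flagged as such, since the bias
  of real opportunistic data is not characterized.
- **Environment rasters** for the baseline: the latent fields re-exported
  at 50 m/px. Real climate/soil rasters are 1–3 orders of magnitude coarser
  than the imagery; 25× is a conservative emulation of that gap.

What passing tests on this system do and do not show: they demonstrate that
the pipeline's mechanics are correct (exact oracle agreement for every
metric), that the convolutional model extracts neighborhood information a
point model cannot (the context-species contrast), and that its feature
space organizes along the generating environment (t-SNE regressions, map
correlations). They do not show that the desk-scale backbone matches a
full-size model on real imagery — real data add registration error,
seasonal/sensor variation, richer land-cover semantics and far more
species, none of which the generator emulates.

## Numerical choices and degenerate inputs

- Ranks use the pessimistic tie rule (documented above) so oracles match
  bit-for-bit.
- The AUC uses midranks; all-equal scores give exactly 0.5.
- Softmax and cross-entropy are max-shifted for stability; probabilities
  sum to 1 within 1e-6 (checked per forward pass in tests).
- Channel standardization floors the std at 1e-6; one-hot channels are not
  standardized. Channel statistics are stored in float64 so that a saved
  and reloaded model reproduces predictions exactly.
- Empty test sets, single-species training data, constant map scores,
  zero-extent embedding axes, rank-deficient regression designs and
  patches crossing borders all raise typed errors rather than returning
  silently wrong values.
- Sub-seeds for fields, channels, species and sampling derive from one
  world seed via `SeedSequence.spawn`, so every artifact is reproducible
  from a single integer and components can be varied independently.

## Desk-scale problem sizes

End-to-end runs use the default world above (≈4,000 train / ≈500 test
occurrences), 30 training epochs (≈2 minutes on one CPU), 2,000-point
t-SNE embeddings, and 20 m inference lattices over 1 × 1 km sub-areas
(≈2,600 points). These sizes were chosen so a complete study — generation,
training, evaluation, interpretation, mapping — runs in a few minutes while
keeping per-species test counts (~25) large enough for stable species-wise
accuracies.

## Known limitations

- Presence-only evaluation: the pseudo-absence AUC depends on the extent
  and composition of the test pool; MSA_k avoids that choice and is the
  preferred headline metric here.
- The OLS interpretation layer ignores spatial autocorrelation and
  collinearity beyond exact differences.
- The generator has no temporal dynamics, species interactions or
  dispersal, and uses a local planar CRS (no reprojection support).
- The desk backbone underfits relative to a full-scale model; its absolute
  accuracies are not comparable to published full-dataset numbers, only
  the *contrasts* (conv vs point baseline, context vs point-niche species)
  are meaningful.
- Desk-scale contrasts vary across world seeds: with only 8 context species
  and ~25 test occurrences each, the per-group accuracy difference has
  substantial sampling noise, and on some world realizations the
  context-species contrast can shrink or invert even when the overall
  species-weighted advantage persists. Conclusions should be read per fixed
  study configuration, or averaged over seeds for a population-level claim.
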