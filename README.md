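# convsdm

Convolutional species distribution modeling with an interpretable feature
space, exercisable end to end on synthetic landscapes with known ground
truth.

## The problem

Species distribution models (SDMs) predict where species occur from
environmental predictors at occurrence locations. Classical SDMs (MaxEnt,
random forests, boosted trees) consume the *point value* of each
environmental variable — annual mean temperature, soil pH, elevation — at
the occurrence. A convolutional SDM instead consumes a spatial
*environmental tensor*: a multi-channel patch (imagery bands, land cover,
elevation) centered on the occurrence. The convolution layers can extract
spatial patterns — habitat structure, landscape context, terrain
heterogeneity — that no point value carries.

`convsdm` is a tested, reusable pipeline for this kind of analysis, written
for ecologists and methodologists who want to study *why* and *when* the
convolutional approach wins, on data where the truth is known:

- **`convsdm.synthetic`** — landscapes with smooth environmental fields,
  derived raster channels (pseudo-RGB, near-IR, categorical land cover,
  two-scale elevation), species with parameterized Gaussian niches (the
  niche optima double as a species trait table), and biased presence-only
  sampling. A configurable subset of *context species* have niches on a
  neighborhood statistic (terrain ruggedness = local standard deviation of
  elevation) that is visible in a patch but not in any point value.
- **`convsdm.rasters`** — raster layers, bilinear/nearest resampling
  (nearest-only for categorical layers), patch tensor extraction with a
  strict no-padding border policy, and point environment vectors.
- **`convsdm.model`** — the multi-species classifier: a feature extractor
  `z = φ(x)` (strided conv blocks + global average pooling, in plain numpy
  with explicit backprop and Adam) and a linear head `ψ`, trained by
  cross-entropy on

  `P(Y = k | X = x) = exp(ψ_k(z)) / Σ_j exp(ψ_j(z))`.

- **`convsdm.baseline`** — the point-environment comparison model: a random
  forest (100 trees, max depth 10) on per-occurrence environment vectors.
- **`convsdm.metrics`** — evaluation for presence-only data: the rank
  `r_i` of the true species, top-k accuracy `A_k`, species-wise `SA_{k,s}`,
  the unweighted mean `MSA_k` over species, a spatial block holdout
  (whole quadrats withheld; no train/test quadrat sharing), and a
  species-balanced pseudo-absence AUC (absences drawn species-uniformly
  from other species' test occurrences; Mann–Whitney AUC with midranks;
  conv model scored by logits, baseline by probabilities).
- **`convsdm.embedding`** — feature-space interpretation: PCA(50) + t-SNE
  to 2D/3D, occupancy mosaics, bilinear color gradients projected onto
  geographic space by 1-nearest-neighbor, 3D-embedding → RGB habitat maps,
  and per-axis OLS regressions on traits or environment (with automatic
  exclusion of derived range variables such as annual range = max − min).
- **`convsdm.suitability`** — dense lattice inference and map scaling:
  per-species logits → sigmoid centered on the area-mean activation →
  min-max to [0, 1]; baseline probabilities → min-max; rendering as a
  transparent-to-red overlay.
- **`convsdm.pipeline`** — one-call orchestration of the whole comparison.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

trains the convolutional SDM on a 1 × 1 km world (10 species, 1,500
occurrences) and prints:

```
train 1307 / test 186 occurrences (realized test fraction 12.4%)
training loss: 1.799 -> 1.368

                           A_5   MSA_5  MeanAUC
convolutional SDM        0.903   0.773    0.733
point-env baseline       0.866   0.772    0.757

context species (niche on terrain ruggedness, invisible to point values):
  mean SA_5 conv 0.821 vs baseline 0.774
```

`A_5` is the fraction of held-out occurrences whose true species ranks in
the model's top 5; `MSA_5` averages that per species first, so rare species
count as much as common ones; `MeanAUC` is the pseudo-absence AUC averaged
over species. The last two lines isolate the species whose habitat depends
on terrain ruggedness — a neighborhood property no point value contains —
where the convolutional model's advantage is concentrated.

The other examples generate a world and inspect its exported ground truth
(`01`), embed and regress the learned feature space (`03`), and produce
dense suitability maps compared against the generating truth (`04`).

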