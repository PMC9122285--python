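"""Feature-space interpretation: dimension reduction, mosaics, maps, regressions.

The trained classifier's feature space z = φ(x) concentrates what the model
learned about landscapes and habitats. To interpret it we reduce z to 2 or 3
dimensions with t-SNE (optionally preceded by PCA to 50 components, the usual
preamble for high-dimensional inputs), then:

* tile the 2D embedding into an n x n mosaic, each cell showing the
  occurrence closest to its center (RGB patch, trait value or environment
  value);
* paint the 2D embedding with a bilinear color gradient and project those
  colors onto geographic space by 1-nearest-neighbor, revealing the
  ecoregion structure the model learned;
* rescale a 3D embedding to RGB for dense fine-scale habitat maps;
* regress each embedding axis on species traits or environmental variables
  with ordinary least squares to test, statistically, whether the learned
  features relate to species ecology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingResult",
    "MosaicGrid",
    "AxisRegressionReport",
    "reduce_features",
    "build_mosaic",
    "mosaic_payload",
    "bilinear_embedding_colors",
    "geographic_projection",
    "embedding3_to_rgb",
    "axis_linear_models",
    "DEFAULT_CORNER_COLORS",
]

# four maximally distinct fixed corner colors for the bilinear gradient:
# (u=0,v=0) blue, (1,0) red, (0,1) green, (1,1) yellow
DEFAULT_CORNER_COLORS = np.array(
    [[0, 0, 255], [255, 0, 0], [0, 255, 0], [255, 255, 0]], dtype=float
)


@dataclass
class EmbeddingResult:
    """Low-dimensional t-SNE coordinates of a (sub)sample of occurrences."""

    coords: np.ndarray  # (n, 2 or 3)
    indices: np.ndarray  # positions of the embedded rows in the input
    out_dim: int
    used_pca: bool


@dataclass
class MosaicGrid:
    """n x n grid over the embedding bounding box; per-cell occupant index.

    ``occupant[i, j]`` is the index (into the embedded sample) of the
    occurrence closest to the center of cell (i, j), or -1 for empty cells.
    Row i indexes the second embedding axis, column j the first.
    """

    occupant: np.ndarray
    n: int
    bbox: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.bbox
        w, h = (xmax - xmin) / self.n, (ymax - ymin) / self.n
        return (xmin + (j + 0.5) * w, ymin + (i + 0.5) * h)


@dataclass
class AxisRegressionReport:
    """Per-axis OLS summaries of embedding coordinates on predictors."""

    tables: dict[int, pd.DataFrame]  # axis -> coefficient table
    r_squared: dict[int, float]
    adj_r_squared: dict[int, float]
    f_pvalue: dict[int, float]
    predictor_set: str
    n_used: int
    n_dropped: int
    excluded: list[str]


def reduce_features(
    feature_vectors: np.ndarray,
    out_dim: int = 2,
    use_pca_preamble: bool = True,
    pca_dim: int = 50,
    sample_size: int | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
) -> EmbeddingResult:
    """Seeded subsample → optional PCA(50) → t-SNE to 2 or 3 dimensions.

    The PCA preamble preserves global structure and speeds up t-SNE on
    high-dimensional features; for 3D habitat-map embeddings it is typically
    skipped. Deterministic given the seed and t-SNE settings.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    if out_dim not in (2, 3):
        raise ValueError(f"embedding dimension must be 2 or 3, got {out_dim}")
    x = np.asarray(feature_vectors, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    if sample_size is not None and sample_size < n:
        indices = np.sort(rng.choice(n, size=sample_size, replace=False))
    else:
        indices = np.arange(n)
    xs = x[indices]

    used_pca = False
    if use_pca_preamble and xs.shape[1] > pca_dim:
        xs = PCA(n_components=pca_dim, random_state=seed).fit_transform(xs)
        used_pca = True

    perp = min(perplexity, max(2.0, (len(xs) - 1) / 3.0))
    tsne = TSNE(
        n_components=out_dim,
        perplexity=perp,
        random_state=seed,
        init="pca",
        n_jobs=1,
    )
    coords = tsne.fit_transform(xs)
    return EmbeddingResult(np.asarray(coords, float), indices, out_dim, used_pca)


def build_mosaic(embedding: np.ndarray, n: int) -> MosaicGrid:
    """Assign to each grid cell the in-cell occurrence nearest its center.

    The grid spans the embedding bounding box. The search is local: only
    occurrences falling inside a cell compete for it; cells with no
    occurrence stay empty (rendered blank downstream).
    """
    z = np.asarray(embedding, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("mosaic requires a 2D embedding")
    if len(z) == 0:
        raise ValueError("cannot build a mosaic from an empty embedding")
    if n < 1:
        raise ValueError("grid size must be >= 1")
    xmin, ymin = z.min(axis=0)
    xmax, ymax = z.max(axis=0)
    w = (xmax - xmin) or 1.0
    h = (ymax - ymin) or 1.0
    jj = np.clip(((z[:, 0] - xmin) / w * n).astype(int), 0, n - 1)
    ii = np.clip(((z[:, 1] - ymin) / h * n).astype(int), 0, n - 1)

    grid = MosaicGrid(np.full((n, n), -1, dtype=int), n, (xmin, ymin, xmax, ymax))
    best = np.full((n, n), np.inf)
    cw, ch = w / n, h / n
    cx = xmin + (jj + 0.5) * cw
    cy = ymin + (ii + 0.5) * ch
    d2 = (z[:, 0] - cx) ** 2 + (z[:, 1] - cy) ** 2
    for idx in range(len(z)):
        i, j = ii[idx], jj[idx]
        if d2[idx] < best[i, j]:
            best[i, j] = d2[idx]
            grid.occupant[i, j] = idx
    return grid


def mosaic_payload(grid: MosaicGrid, values) -> np.ndarray:
    """Per-cell payload for an occupied mosaic: values[occupant], NaN if empty.

    ``values`` is indexed like the embedded sample and may be per-occurrence
    scalars (a trait or environment value) or arrays (e.g. RGB patches);
    empty cells get NaN payloads of the same shape.
    """
    values = np.asarray(values, dtype=float)
    cell_shape = values.shape[1:]
    out = np.full((grid.n, grid.n, *cell_shape), np.nan)
    occ = grid.occupant
    filled = occ >= 0
    out[filled] = values[occ[filled]]
    return out


def bilinear_embedding_colors(
    embedding: np.ndarray, corner_colors: np.ndarray | None = None
) -> np.ndarray:
    """Color every 2D embedding point by a bilinear gradient of 4 corner colors.

    The embedding is normalized to the unit square via its bounding box;
    ``corner_colors`` rows are the colors at (0,0), (1,0), (0,1), (1,1).
    Returns (n, 3) float RGB, continuous in the embedding coordinates.
    """
    z = np.asarray(embedding, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("bilinear gradient requires a 2D embedding")
    c = DEFAULT_CORNER_COLORS if corner_colors is None else np.asarray(corner_colors, float)
    lo, hi = z.min(axis=0), z.max(axis=0)
    if np.any(hi == lo):
        raise ValueError("degenerate embedding: an axis has zero extent")
    uv = (z - lo) / (hi - lo)
    u, v = uv[:, 0:1], uv[:, 1:2]
    return (1 - u) * (1 - v) * c[0] + u * (1 - v) * c[1] + (1 - u) * v * c[2] + u * v * c[3]


def geographic_projection(
    geo_coords: np.ndarray,
    colors: np.ndarray,
    grid_step: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Project occurrence colors onto a regular geographic grid by 1-NN.

    Each grid point takes the color of its geographically nearest embedded
    occurrence (planar Euclidean distance). Returns the (rows, cols, 3) color
    raster — row 0 northmost — and a georeferencing dict.
    """
    pts = np.asarray(geo_coords, dtype=float)
    if len(pts) == 0:
        raise ValueError("cannot project an empty occurrence set")
    col = np.asarray(colors, dtype=float)
    if bounds is None:
        bounds = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, xmax + grid_step / 2, grid_step)
    ys = np.arange(ymax, ymin - grid_step / 2, -grid_step)  # north to south
    gx, gy = np.meshgrid(xs, ys)
    tree = cKDTree(pts)
    _, nn = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), k=1)
    raster = col[nn].reshape(len(ys), len(xs), col.shape[1])
    georef = {"origin": (float(xs[0]), float(ys[0])), "step": float(grid_step)}
    return raster, georef


def embedding3_to_rgb(embedding: np.ndarray) -> np.ndarray:
    """Min-max rescale each 3D embedding axis to 0–255; axes map to (R, G, B)."""
    z = np.asarray(embedding, dtype=float)
    if z.ndim != 2 or z.shape[1] != 3:
        raise ValueError("RGB mapping requires a 3D embedding")
    lo, hi = z.min(axis=0), z.max(axis=0)
    if np.any(hi == lo):
        bad = [i for i in range(3) if hi[i] == lo[i]]
        raise ValueError(f"constant embedding axis {bad}: RGB rescale undefined")
    return (z - lo) / (hi - lo) * 255.0


def _find_difference_columns(x: pd.DataFrame, tol: float = 1e-9) -> list[str]:
    """Columns that are an exact difference of two other columns (bio_7-like)."""
    cols = list(x.columns)
    out = []
    arr = {c: x[c].to_numpy(float) for c in cols}
    for c in cols:
        found = False
        for a in cols:
            if found or a == c:
                continue
            for b in cols:
                if b in (a, c):
                    continue
                if np.allclose(arr[c], arr[a] - arr[b], atol=tol, rtol=0):
                    out.append(c)
                    found = True
                    break
    return out


def axis_linear_models(
    embedding: np.ndarray,
    predictor_table: pd.DataFrame,
    predictor_set: str = "traits",
) -> AxisRegressionReport:
    """OLS of each embedding axis on a predictor table (traits or environment).

    Rows with missing predictors are dropped and counted. For the
    ``environment`` predictor set, any predictor that is an exact difference
    of two others (the temperature-annual-range pattern: range = max - min)
    is excluded automatically, since it is perfectly collinear with them.
    Reports estimates, standard errors, two-sided p-values, R² and adjusted
    R² per axis, plus the model F-test p-value.
    """
    import statsmodels.api as sm

    z = np.asarray(embedding, dtype=float)
    x = predictor_table.copy()
    if len(x) != len(z):
        raise ValueError("predictor table must align with the embedding rows")

    excluded: list[str] = []
    if predictor_set == "environment":
        # a derived range variable (e.g. annual range = max - min) makes the
        # whole triple mutually expressible; drop greedily from the end of the
        # table (derived variables are conventionally appended) until no
        # exact-difference relation remains
        while True:
            diff_cols = _find_difference_columns(x)
            if not diff_cols:
                break
            drop = [c for c in x.columns if c in diff_cols][-1]
            excluded.append(drop)
            x = x.drop(columns=[drop])

    keep = ~x.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    x = x.loc[keep.to_numpy()]
    zk = z[keep.to_numpy()]

    design = sm.add_constant(x.to_numpy(float))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(x.to_numpy(float).T)
        pairs = [
            (x.columns[i], x.columns[j])
            for i in range(len(x.columns))
            for j in range(i + 1, len(x.columns))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or list(x.columns)}")

    tables, r2, ar2, fp = {}, {}, {}, {}
    for axis in range(zk.shape[1]):
        fit = sm.OLS(zk[:, axis], design).fit()
        tables[axis] = pd.DataFrame(
            {
                "estimate": fit.params,
                "std_error": fit.bse,
                "p_value": fit.pvalues,
            },
            index=["intercept", *x.columns],
        )
        r2[axis] = float(fit.rsquared)
        ar2[axis] = float(fit.rsquared_adj)
        fp[axis] = float(fit.f_pvalue)
    return AxisRegressionReport(
        tables, r2, ar2, fp, predictor_set, n_used=len(x), n_dropped=n_dropped,
        excluded=excluded,
    )
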