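"""Dense-grid inference and habitat suitability map scaling.

The per-species logit of the convolutional model serves as an index of
habitat suitability. To map it over an area the model is activated on a
regular lattice of points (a patch is extracted at each point exactly as for
training occurrences), and the species' logits are rescaled to a comparable
[0, 1] map: first a sigmoid whose threshold is the mean logit of that species
over the area (centering the scores on the area's typical activation), then a
min-max scaler so the local maximum is exactly 1 and the local minimum 0.
Point-value baseline probabilities are already in [0, 1] and get only the
min-max step. Both scalings are strictly increasing, so rank-based metrics
(AUC) computed from scaled scores equal those computed from raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConvSDM, softmax_probabilities
from .rasters import BoundaryError, CoverageError, NodataError, RasterLayer, extract_patch

__all__ = [
    "InferenceGrid",
    "SuitabilityMap",
    "DegenerateMapError",
    "lattice_points",
    "dense_inference",
    "scale_cnn_logits",
    "scale_baseline_probabilities",
    "render_map",
]


class DegenerateMapError(ValueError):
    """Constant scores over the area: the [0, 1] rescaling is undefined."""


@dataclass
class InferenceGrid:
    """Model activations on a regular lattice over an area.

    ``logits``/``probabilities`` are (n_points, S); ``ok`` flags lattice
    points whose patch could be extracted (others are explicit failures, not
    silently dropped points).
    """

    points: np.ndarray  # (n_points, 2) x,y
    shape: tuple[int, int]  # rows, cols of the lattice (row 0 northmost)
    step: float
    logits: np.ndarray
    probabilities: np.ndarray
    features: np.ndarray
    ok: np.ndarray


@dataclass
class SuitabilityMap:
    species_id: int
    values: np.ndarray  # flat, aligned with InferenceGrid.points; NaN where failed
    shape: tuple[int, int]
    provenance: dict = field(default_factory=dict)

    def grid(self) -> np.ndarray:
        return self.values.reshape(self.shape)


def lattice_points(
    bounds: tuple[float, float, float, float], step: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Regular lattice anchored at the lower-left bound, both bounds inclusive
    when the step divides the extent; degenerate axes get a single centered
    point. Points are ordered row-major with row 0 northmost."""
    if step <= 0:
        raise ValueError("lattice step must be positive")
    xmin, ymin, xmax, ymax = bounds

    def axis(lo: float, hi: float) -> np.ndarray:
        if step > hi - lo:
            return np.array([(lo + hi) / 2.0])
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    xs = axis(xmin, xmax)
    ys = axis(ymin, ymax)[::-1]  # north first
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()]), (len(ys), len(xs))


def dense_inference(
    model: ConvSDM,
    layers: list[RasterLayer],
    bounds: tuple[float, float, float, float],
    step: float,
    batch_size: int = 256,
) -> InferenceGrid:
    """Activate the model on every lattice point of an area.

    A patch is extracted at each point with the same rules as for training
    data; points whose patch crosses a layer border or hits nodata are marked
    failed (``ok = False``) with NaN scores rather than silently skipped.
    Deterministic for a frozen model.
    """
    points, shape = lattice_points(bounds, step)
    n = len(points)
    s = model.config.n_species
    d = model.config.feature_dim
    logits = np.full((n, s), np.nan)
    feats = np.full((n, d), np.nan)
    ok = np.zeros(n, dtype=bool)

    patches, idx = [], []
    for i, (x, y) in enumerate(points):
        try:
            t = extract_patch(layers, (float(x), float(y)), model.config.patch_px)
        except (BoundaryError, NodataError, CoverageError):
            continue
        patches.append(t.channels)
        idx.append(i)
        if len(patches) == batch_size:
            _flush(model, patches, idx, logits, feats, ok)
            patches, idx = [], []
    if patches:
        _flush(model, patches, idx, logits, feats, ok)

    probs = np.full_like(logits, np.nan)
    if ok.any():
        probs[ok] = softmax_probabilities(logits[ok])
    return InferenceGrid(points, shape, step, logits, probs, feats, ok)


def _flush(model, patches, idx, logits, feats, ok):
    z, lg, _ = model.forward_batch(np.stack(patches))
    logits[idx] = lg
    feats[idx] = z
    ok[idx] = True


def scale_cnn_logits(
    logit_values: np.ndarray, species_id: int = -1, provenance: dict | None = None,
    shape: tuple[int, int] | None = None,
) -> SuitabilityMap:
    """Sigmoid (threshold = area mean of the species' logits) then min-max.

    The mean is computed over successful lattice points only; NaNs mark failed
    points and are carried through. The composition is strictly increasing,
    so score order — and hence any rank statistic — is preserved. Constant
    logits raise :class:`DegenerateMapError`.
    """
    v = np.asarray(logit_values, dtype=float)
    valid = ~np.isnan(v)
    vv = v[valid]
    if vv.size < 2 or np.all(vv == vv[0]):
        raise DegenerateMapError(
            "constant (or near-empty) logits over the area: map scaling undefined"
        )
    m = vv.mean()
    sig = 1.0 / (1.0 + np.exp(-(v - m)))
    out = _minmax_map(sig, valid)
    prov = {"scaling": "sigmoid+minmax", "threshold": float(m)}
    prov.update(provenance or {})
    return SuitabilityMap(species_id, out, shape or (1, v.size), prov)


def scale_baseline_probabilities(
    probability_values: np.ndarray, species_id: int = -1,
    provenance: dict | None = None, shape: tuple[int, int] | None = None,
) -> SuitabilityMap:
    """Plain min-max rescale of already-[0, 1] baseline probabilities."""
    v = np.asarray(probability_values, dtype=float)
    valid = ~np.isnan(v)
    vv = v[valid]
    if vv.size < 2 or np.all(vv == vv[0]):
        raise DegenerateMapError(
            "constant (or near-empty) probabilities over the area: map scaling undefined"
        )
    out = _minmax_map(v, valid)
    prov = {"scaling": "minmax"}
    prov.update(provenance or {})
    return SuitabilityMap(species_id, out, shape or (1, v.size), prov)


def _minmax_map(v: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.full_like(v, np.nan, dtype=float)
    lo, hi = v[valid].min(), v[valid].max()
    out[valid] = (v[valid] - lo) / (hi - lo)
    return out


def render_map(
    suitability: SuitabilityMap,
    background_rgb: np.ndarray,
    overlay_color: tuple[float, float, float] = (255.0, 0.0, 0.0),
) -> np.ndarray:
    """Alpha-composite the suitability over a background image.

    Value 0 is fully transparent (background shows through), value 1 is the
    opaque overlay color (bright red by default), with linear alpha between.
    Failed (NaN) cells render as background. Returns a uint8 (H, W, 3) image.
    """
    bg = np.asarray(background_rgb, dtype=float)
    vals = suitability.grid()
    if bg.shape[:2] != vals.shape:
        raise ValueError(
            f"extent mismatch: background {bg.shape[:2]} vs map {vals.shape}"
        )
    alpha = np.nan_to_num(vals, nan=0.0)[..., None]
    color = np.asarray(overlay_color, dtype=float)
    out = (1.0 - alpha) * bg + alpha * color
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
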