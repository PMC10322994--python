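"""Effect of max pooling on size-invariance of population SF responses.

For each bandpass probe (center SF × expression × individual) the population
response of a layer is compared between the two stimulus sizes with the
dissimilarity index

    D(x, y) = ‖x − y‖ / (N · M)

where x and y are the flattened unit responses to the large and small
stimulus, N is the number of units, and M normalizes by the maximum raw
Euclidean distance over the whole evaluation family (all center SFs ×
expressions × individuals for one model and layer), so D ranges over (0, 1]
at the family maximum.  Comparing D before pooling (first convolution layer,
after ReLU) and after pooling (first max-pooling layer, before LRN) shows
how much pooling equalizes responses across sizes — the mechanism by which
wide spatial pooling builds size-invariant, object-based SF coding at low
SFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .architectures import Model
from .stimuli import CANVAS, bandpass_stimulus_batch, center_sf_grid

#: Analysis layer name -> internal record name.  "conv1" is the first
#: convolution after its ReLU; "pool1" is after max pooling, before LRN.
LAYER_RECORDS = {"conv1": "relu1", "pool1": "pool1"}


def dissimilarity_index(x: np.ndarray, y: np.ndarray, M: float) -> float:
    """Euclidean distance between two population responses, normalized by N·M."""
    x = np.asarray(x, np.float64).ravel()
    y = np.asarray(y, np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if M <= 0:
        raise ValueError("normalizing maximum M must be positive")
    return float(np.linalg.norm(x - y) / (x.size * M))


@dataclass
class DissimilarityCurve:
    """Per-center-SF dissimilarity of one layer between the two sizes."""

    layer: str
    center_sfs: np.ndarray
    raw_distances: np.ndarray  # (61, n_expressions, n_individuals) ‖x−y‖
    n_units: int
    M: float  # normalizing maximum (raw distance)
    config_tag: str = ""

    @property
    def D(self) -> np.ndarray:
        """Normalized dissimilarity indices, same shape as raw_distances."""
        return self.raw_distances / (self.n_units * self.M)

    @property
    def mean(self) -> np.ndarray:
        return self.D.reshape(len(self.center_sfs), -1).mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.D.reshape(len(self.center_sfs), -1).std(axis=1)

    @property
    def n_evaluations(self) -> int:
        return int(np.prod(self.raw_distances.shape))


def _layer_responses(
    model: Model, stims: np.ndarray, record_names: Sequence[str]
) -> dict[str, np.ndarray]:
    """Flattened per-stimulus responses of the requested layers."""
    x = model._check_batch(stims)
    out = {}
    remaining = set(record_names)
    for lyr in model.layers:
        x = lyr.forward(x)
        if lyr.name in remaining:
            out[lyr.name] = x.reshape(len(x), -1).astype(np.float64)
            remaining.discard(lyr.name)
            if not remaining:
                break
    return out


def population_distances(
    model: Model,
    faces_by_expression: dict[str, Sequence[np.ndarray]],
    layers: Sequence[str] = ("conv1", "pool1"),
    sizes: tuple[int, int] = (CANVAS, CANVAS // 2),
    grid: Optional[np.ndarray] = None,
) -> dict[str, np.ndarray]:
    """Raw large-vs-small distances per layer, shape (61, n_expr, n_indiv).

    Both analysis layers are captured from the same forward passes, so the
    conv1/pool1 comparison costs one sweep over the stimuli.
    """
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    unknown = set(layers) - set(LAYER_RECORDS)
    if unknown:
        raise ValueError(f"unknown analysis layers {unknown}; choose from {set(LAYER_RECORDS)}")
    record_names = [LAYER_RECORDS[l] for l in layers]
    large, small = max(sizes), min(sizes)
    expressions = list(faces_by_expression)
    n_ind = {len(v) for v in faces_by_expression.values()}
    if len(n_ind) != 1:
        raise ValueError("every expression needs the same number of individuals")
    n_ind = n_ind.pop()
    dists = {
        l: np.zeros((len(grid), len(expressions), n_ind)) for l in layers
    }
    for e, expression in enumerate(expressions):
        for i, face in enumerate(faces_by_expression[expression]):
            resp_large = _layer_responses(
                model, bandpass_stimulus_batch(face, grid, large), record_names
            )
            resp_small = _layer_responses(
                model, bandpass_stimulus_batch(face, grid, small), record_names
            )
            for layer, rec in zip(layers, record_names):
                diff = resp_large[rec] - resp_small[rec]
                dists[layer][:, e, i] = np.linalg.norm(diff, axis=1)
    return dists


def dissimilarity_curves(
    model: Model,
    faces_by_expression: dict[str, Sequence[np.ndarray]],
    layers: Sequence[str] = ("conv1", "pool1"),
    sizes: tuple[int, int] = (CANVAS, CANVAS // 2),
    grid: Optional[np.ndarray] = None,
    normalization: str = "per-family",
    config_tag: str = "",
) -> dict[str, DissimilarityCurve]:
    """Dissimilarity curves for the requested layers.

    ``normalization="per-family"`` computes M separately per (model, layer)
    evaluation family; ``"shared"`` uses one M across the layers computed in
    this call (for cross-layer comparability on a common scale).
    """
    if normalization not in ("per-family", "shared"):
        raise ValueError("normalization must be 'per-family' or 'shared'")
    grid = center_sf_grid() if grid is None else np.asarray(grid)
    dists = population_distances(model, faces_by_expression, layers, sizes, grid)
    shapes = model.shapes
    layer_units = {"conv1": shapes.units("conv1"), "pool1": shapes.units("pool1")}
    shared_M = max(d.max() for d in dists.values())
    curves = {}
    for layer in layers:
        M = shared_M if normalization == "shared" else dists[layer].max()
        if M <= 0:
            raise ValueError(f"all responses identical across sizes in layer {layer}")
        curves[layer] = DissimilarityCurve(
            layer=layer,
            center_sfs=grid,
            raw_distances=dists[layer],
            n_units=layer_units[layer],
            M=float(M),
            config_tag=config_tag,
        )
    return curves


def dissimilarity_curve(
    model: Model,
    layer: str,
    faces_by_expression: dict[str, Sequence[np.ndarray]],
    sizes: tuple[int, int] = (CANVAS, CANVAS // 2),
    grid: Optional[np.ndarray] = None,
) -> DissimilarityCurve:
    """Single-layer convenience wrapper around :func:`dissimilarity_curves`."""
    return dissimilarity_curves(model, faces_by_expression, (layer,), sizes, grid)[layer]


def pooling_ratio(
    before: DissimilarityCurve, after: DissimilarityCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SF mean and SD of the after/before dissimilarity ratio.

    Ratios are taken evaluation-wise (same center SF, expression and
    individual); evaluations with a zero before-pooling index are undefined
    and excluded (NaN-aware means).  A mean ratio < 1 at a given SF means
    pooling made the population response more similar across stimulus sizes.
    """
    if before.raw_distances.shape != after.raw_distances.shape:
        raise ValueError("curves must come from the same stimuli")
    b = before.D
    a = after.D
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, a / b, np.nan)
    flat = ratio.reshape(len(before.center_sfs), -1)
    return np.nanmean(flat, axis=1), np.nanstd(flat, axis=1)
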