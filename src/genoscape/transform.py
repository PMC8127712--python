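"""Adaptive-landscape mapping.

Environmental raster stacks are pushed through the fitted cumulative
importance functions so every cell is expressed in common genomic
turnover units, reduced to principal components (fitted once on the
pooled current+future cells so the two time points share one rotation),
and rendered as an RGB map in which colour differences are proportional
to differences in modelled genomic composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .gea import GradientForestModel
from .grids import EnvStack, GridSpec

__all__ = ["PcRgbRaster", "transform_env_stack", "pca_reduce", "rgb_map"]


def transform_env_stack(model: GradientForestModel, env_stack: EnvStack) -> EnvStack:
    """Replace each cell value x of predictor p by F_p(x).

    Extrapolation outside the training range is clamped to endpoint
    values; geometry and nodata mask are carried through unchanged.
    """
    missing = [p for p in model.predictor_names if p not in env_stack.layer_names]
    if missing:
        raise KeyError(f"env stack lacks predictor layer(s): {', '.join(missing)}")
    out = np.empty((len(model.predictor_names), env_stack.grid.rows, env_stack.grid.cols))
    for i, p in enumerate(model.predictor_names):
        out[i] = model.cif[p](env_stack.layer(p))
        out[i][~env_stack.mask] = np.nan
    return EnvStack(env_stack.grid, list(model.predictor_names), out, env_stack.mask.copy())


@dataclass
class PcRgbRaster:
    """Principal-component scores (and optional RGB rendering) on a grid."""

    grid: GridSpec
    scores: np.ndarray  # (n_components, rows, cols), NaN on nodata
    mask: np.ndarray
    loadings: np.ndarray  # (n_components, n_layers) rotation rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    rgb: np.ndarray | None = None  # (3, rows, cols) uint8
    scaling_record: dict = field(default_factory=dict)


def pca_reduce(
    transformed_current: EnvStack,
    transformed_future: EnvStack,
    n_components: int = 2,
) -> tuple[PcRgbRaster, PcRgbRaster]:
    """Reduce the transformed stacks to principal components.

    The PCA is fitted once on the pooled (current ∪ future) unmasked
    cells, centred but not variance-scaled (the layers already share
    cumulative-importance units); both time points are projected with
    the same rotation so their scores are directly comparable.  Each
    component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    if not transformed_current.grid.matches(transformed_future.grid):
        raise ValueError("current and future stacks must share geometry")
    if transformed_current.layer_names != transformed_future.layer_names:
        raise ValueError("current and future stacks must share layer names")
    mask = transformed_current.mask & transformed_future.mask
    cur = transformed_current.data[:, mask].T  # (cells, layers)
    fut = transformed_future.data[:, mask].T
    pooled = np.vstack([cur, fut])
    informative = np.ptp(pooled, axis=0) > 0
    if informative.sum() < n_components:
        raise ValueError(
            f"only {int(informative.sum())} informative layer(s) for {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(pooled)
    comps = pca.components_.copy()
    for k in range(n_components):  # deterministic sign convention
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    mean = pca.mean_

    def project(flat: np.ndarray) -> np.ndarray:
        scores = np.full((n_components, *transformed_current.grid.shape), np.nan)
        scores[:, mask] = ((flat - mean) @ comps.T).T
        return scores

    common = dict(
        grid=transformed_current.grid,
        mask=mask,
        loadings=comps,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
    return (
        PcRgbRaster(scores=project(cur), **common),
        PcRgbRaster(scores=project(fut), **common),
    )


def rgb_map(
    pc_raster_pair: tuple[PcRgbRaster, PcRgbRaster], mode: str = "2pc"
) -> tuple[PcRgbRaster, PcRgbRaster]:
    """Render PC scores to RGB, filling ``rgb`` on each raster in place.

    Channel scaling uses the joint min/max over both time points, so a
    cell with identical scores at both times gets identical colour in
    both maps.  Mode ``"2pc"`` maps PC1→R, PC2→G with blue fixed at 128;
    ``"3pc"`` maps PC1..3→R,G,B.  A constant (degenerate) component maps
    to 128 with a warning.  The per-channel min/max is kept in
    ``scaling_record``.
    """
    cur, fut = pc_raster_pair
    n_needed = {"2pc": 2, "3pc": 3}.get(mode)
    if n_needed is None:
        raise ValueError(f"unknown mode {mode!r}; use '2pc' or '3pc'")
    if cur.scores.shape[0] < n_needed:
        raise ValueError(f"mode {mode!r} needs {n_needed} components")
    record: dict[str, tuple[float, float]] = {}
    channels = ("R", "G", "B")
    for raster in (cur, fut):
        raster.rgb = np.full((3, *raster.grid.shape), 128, dtype=np.uint8)
        raster.rgb[:, ~raster.mask] = 0
    for ch in range(3):
        if mode == "2pc" and ch == 2:
            record["B"] = (np.nan, np.nan)  # fixed channel
            continue
        pooled = np.concatenate(
            [cur.scores[ch][cur.mask].ravel(), fut.scores[ch][fut.mask].ravel()]
        )
        lo, hi = float(np.min(pooled)), float(np.max(pooled))
        record[channels[ch]] = (lo, hi)
        if hi - lo <= 1e-12 * max(abs(lo), abs(hi), 1.0):
            warnings.warn(f"component {ch + 1} is constant; channel {channels[ch]} set to 128")
            continue
        for raster in (cur, fut):
            scaled = (raster.scores[ch] - lo) / (hi - lo) * 255.0
            vals = np.clip(np.round(scaled), 0, 255)
            raster.rgb[ch][raster.mask] = vals[raster.mask].astype(np.uint8)
    for raster in (cur, fut):
        raster.scaling_record = {"mode": mode, "channels": record}
    return cur, fut
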