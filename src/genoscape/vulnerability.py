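"""Adaptive turnover and genomic vulnerability.

*Adaptive turnover* is a focal-window range statistic on the mapped
composition surface: how much the genome–environment relationship
changes in a cell's neighbourhood.  *Genomic vulnerability* is the
per-cell offset between the transformed current and future
environments — the adaptive change a resident population would need to
track climate.  The per-SNP *allele shift* makes that offset concrete:
each SNP's forest predicts its frequency under current and future
conditions and the relative change is summarized per cell and
categorized (low/medium/high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gea import GradientForestModel
from .grids import EnvStack, GridSpec
from .transform import transform_env_stack

__all__ = [
    "TurnoverRaster",
    "VulnerabilityRaster",
    "focal_range",
    "genomic_vulnerability",
    "predict_allele_shift",
    "classify_vulnerability",
]

CLASS_LABELS = {0: "low", 1: "medium", 2: "high", 255: "nodata"}


@dataclass
class TurnoverRaster:
    grid: GridSpec
    values: np.ndarray  # (rows, cols), NaN on nodata
    window_radius: int
    mask: np.ndarray


@dataclass
class VulnerabilityRaster:
    grid: GridSpec
    offset: np.ndarray  # (rows, cols) >= 0, NaN on nodata
    metric: str
    mask: np.ndarray
    class_raster: np.ndarray | None = None  # uint8 with CLASS_LABELS codes
    class_breaks: tuple[float, ...] | None = None


def _band_focal_range(band: np.ndarray, valid: np.ndarray, size: int) -> np.ndarray:
    hi = np.where(valid, band, -np.inf)
    lo = np.where(valid, band, np.inf)
    mx = ndimage.maximum_filter(hi, size=size, mode="constant", cval=-np.inf)
    mn = ndimage.minimum_filter(lo, size=size, mode="constant", cval=np.inf)
    out = mx - mn
    out[~np.isfinite(mx) | ~np.isfinite(mn)] = np.nan  # all-nodata window
    return out


def focal_range(raster, radius: int = 1, mask: np.ndarray | None = None) -> TurnoverRaster:
    """Per-cell range (max − min) over a (2r+1)×(2r+1) moving window.

    Accepts a 2-D array, a (bands, rows, cols) array, an
    :class:`EnvStack` or a PC/RGB raster object with ``rgb`` filled.
    Multi-band input is composited as the mean of per-band ranges.
    Windows are intersected with valid cells; edge cells use the
    truncated window; an all-nodata window yields nodata.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grid = None
    if isinstance(raster, EnvStack):
        grid, data, valid = raster.grid, raster.data, raster.mask
    elif hasattr(raster, "rgb") and raster.rgb is not None:
        grid, data, valid = raster.grid, raster.rgb.astype(float), raster.mask
    else:
        data = np.asarray(raster, dtype=float)
        if data.ndim == 2:
            data = data[None]
        valid = mask if mask is not None else np.all(np.isfinite(data), axis=0)
    if data.ndim != 3:
        raise ValueError("raster must be 2-D or (bands, rows, cols)")
    if mask is not None:
        valid = valid & mask
    size = 2 * radius + 1
    ranges = np.stack([_band_focal_range(b, valid, size) for b in data])
    values = ranges.mean(axis=0)
    values[~valid] = np.nan
    if grid is None:
        grid = GridSpec(rows=data.shape[1], cols=data.shape[2], x_origin=0.0, y_origin=float(data.shape[1]), cell_size=1.0)
    return TurnoverRaster(grid=grid, values=values, window_radius=radius, mask=valid)


def genomic_vulnerability(
    model: GradientForestModel,
    env_current: EnvStack,
    env_future: EnvStack,
    metric: str = "euclidean",
) -> VulnerabilityRaster:
    """Per-cell offset between transformed current and future environments.

    metric "euclidean": sqrt(Σ_p ΔF_p²); "manhattan": Σ_p |ΔF_p|.  The
    two coincide when a single predictor changes.
    """
    if not env_current.grid.matches(env_future.grid):
        raise ValueError(
            "geometry mismatch between current "
            f"({env_current.grid}) and future ({env_future.grid})"
        )
    if metric not in ("euclidean", "manhattan"):
        raise ValueError(f"unknown metric {metric!r}")
    t_cur = transform_env_stack(model, env_current)
    t_fut = transform_env_stack(model, env_future)
    mask = t_cur.mask & t_fut.mask
    diff = np.abs(t_fut.data - t_cur.data)
    if metric == "euclidean":
        offset = np.sqrt(np.sum(diff**2, axis=0))
    else:
        offset = np.sum(diff, axis=0)
    offset[~mask] = np.nan
    return VulnerabilityRaster(
        grid=env_current.grid, offset=offset, metric=metric, mask=mask
    )


def predict_allele_shift(
    model: GradientForestModel,
    env_current: EnvStack,
    env_future: EnvStack,
    snp_set: set[str] | None = None,
    summary: str = "mean",
    eps: float = 0.01,
) -> np.ndarray:
    """Relative allele-frequency change each SNP needs per cell.

    For every cell and SNP the retained forest predicts the frequency
    under the current and the future predictor vector; the relative
    shift is ``|p_fut − p_cur| / max(p_cur, eps)``.  Cells are
    summarized over the SNP set by the mean (default) or max.  Returns
    a (rows, cols) array with NaN on nodata.
    """
    if model.forests is None or not model.forests:
        raise ValueError(
            "model was fitted without retained forests; refit with "
            "GradientForestParams(retain_forests=True)"
        )
    if not env_current.grid.matches(env_future.grid):
        raise ValueError("geometry mismatch between current and future stacks")
    if snp_set is None:
        snp_set = model.significant_snps if model.significant_snps is not None else set(model.forests)
    unknown = [s for s in snp_set if s not in model.forests]
    if unknown:
        raise KeyError(f"no retained forest for SNP(s): {', '.join(sorted(unknown)[:5])}")
    if summary not in ("mean", "max"):
        raise ValueError(f"unknown summary {summary!r}")
    mask = env_current.mask & env_future.mask
    order = model.predictor_names
    Xc = np.stack([env_current.layer(p)[mask] for p in order], axis=1)
    Xf = np.stack([env_future.layer(p)[mask] for p in order], axis=1)
    n_cells = Xc.shape[0]
    acc = np.zeros(n_cells)
    for sid in sorted(snp_set):
        f = model.forests[sid]
        p_cur = np.clip(f.predict(Xc), 0.0, 1.0)
        p_fut = np.clip(f.predict(Xf), 0.0, 1.0)
        shift = np.abs(p_fut - p_cur) / np.maximum(p_cur, eps)
        acc = acc + shift if summary == "mean" else np.maximum(acc, shift)
    if summary == "mean":
        acc = acc / max(len(snp_set), 1)
    out = np.full(env_current.grid.shape, np.nan)
    out[mask] = acc
    return out


def classify_vulnerability(
    shift_raster: np.ndarray, breaks: tuple[float, ...] = (0.25, 0.50)
) -> np.ndarray:
    """Categorize per-cell shifts into low/medium/high classes.

    With the default breaks: low ≤ 0.25 < medium ≤ 0.50 < high (upper
    boundaries inclusive in the lower class).  Returns a uint8 raster
    coded by :data:`CLASS_LABELS` with 255 for nodata.
    """
    breaks = tuple(float(b) for b in breaks)
    if any(b <= 0 for b in breaks) or any(
        b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])
    ):
        raise ValueError(f"breaks must be strictly increasing and positive, got {breaks}")
    shift = np.asarray(shift_raster, dtype=float)
    out = np.full(shift.shape, 255, dtype=np.uint8)
    valid = np.isfinite(shift)
    cls = np.zeros(shift.shape, dtype=np.uint8)
    for b in breaks:
        cls = cls + (shift > b).astype(np.uint8)
    out[valid] = cls[valid]
    return out
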