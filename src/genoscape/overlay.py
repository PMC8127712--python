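"""Socio-economic threat, richness/endemism and protected-area overlays.

Polygon layers (mining/logging/agriculture concessions, protected areas,
species ranges) are rasterized onto the analysis grid by cell-centre
containment, summarized zonally against the turnover and vulnerability
surfaces, compared with pooled two-sample t tests, and combined into a
single weight-explicit composite priority map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import shape as shapely_shape

from .grids import GridSpec

__all__ = [
    "PolygonFeature",
    "ComparisonResult",
    "read_geojson_layer",
    "rasterize_layer",
    "species_richness",
    "zonal_stats",
    "two_sample_t",
    "composite_priority",
]

_CATEGORIES = {"mining", "logging", "agriculture", "protected", "species_range"}


@dataclass
class PolygonFeature:
    geometry: shapely.Geometry
    category: str
    name: str = ""
    species_id: str | None = None
    endemic: bool = False

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            self.geometry = shapely.make_valid(self.geometry)


def read_geojson_layer(path) -> list[PolygonFeature]:
    """Read a GeoJSON FeatureCollection into polygon features."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = []
    for f in gj.get("features", []):
        props = f.get("properties") or {}
        feats.append(
            PolygonFeature(
                geometry=shapely_shape(f["geometry"]),
                category=props.get("category", ""),
                name=props.get("name", ""),
                species_id=props.get("species_id"),
                endemic=bool(props.get("endemic", False)),
            )
        )
    return feats


def _centers(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    lon, lat = grid.cell_centers()
    return lon.ravel(), lat.ravel()


def _mask_from_geoms(geoms, grid: GridSpec) -> np.ndarray:
    if not geoms:
        return np.zeros(grid.shape, dtype=bool)
    union = shapely.union_all(list(geoms))
    x, y = _centers(grid)
    hit = shapely.intersects_xy(union, x, y)  # boundary-inclusive containment
    return hit.reshape(grid.shape)


def rasterize_layer(
    polygons: list[PolygonFeature], grid_spec: GridSpec, category: str | None = None
) -> np.ndarray:
    """Boolean mask: cell marked iff its centre falls inside any polygon
    (of ``category``, if given).  Overlapping polygons mark a cell once;
    the result is invariant to feature order.
    """
    if category is not None:
        polygons = [p for p in polygons if p.category == category]
    return _mask_from_geoms([p.geometry for p in polygons], grid_spec)


def species_richness(
    range_layers: list[PolygonFeature], grid_spec: GridSpec, endemic_only: bool = False
) -> np.ndarray:
    """Per-cell count of distinct species whose range covers the cell centre."""
    feats = [f for f in range_layers if f.category == "species_range" or f.species_id]
    missing = [f.name or "<unnamed>" for f in feats if not f.species_id]
    if missing:
        raise ValueError(f"features without species_id: {', '.join(missing)}")
    if endemic_only:
        feats = [f for f in feats if f.endemic]
    by_species: dict[str, list] = {}
    for f in feats:
        by_species.setdefault(f.species_id, []).append(f.geometry)
    richness = np.zeros(grid_spec.shape, dtype=np.int32)
    for geoms in by_species.values():  # duplicates of one species count once
        richness += _mask_from_geoms(geoms, grid_spec)
    return richness


def zonal_stats(
    value_raster: np.ndarray,
    mask: np.ndarray,
    threshold: float | None = None,
) -> dict:
    """Summary statistics of a raster inside a zone and range-wide.

    Nodata (NaN) cells are excluded.  Returns dicts ``zone`` and
    ``rangewide`` with mean, median, ``prop_ge`` (proportion >=
    ``threshold``; range-wide median when threshold is None) and n.
    """
    values = np.asarray(value_raster, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("value raster and mask must share geometry")
    valid = np.isfinite(values)
    if threshold is None:
        threshold = float(np.median(values[valid])) if valid.any() else np.nan

    def summarize(sel: np.ndarray) -> dict:
        v = values[sel & valid]
        if v.size == 0:
            return {"mean": None, "median": None, "prop_ge": None, "n": 0}
        return {
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "prop_ge": float(np.mean(v >= threshold)),
            "n": int(v.size),
        }

    return {
        "threshold": threshold,
        "zone": summarize(mask),
        "rangewide": summarize(np.ones_like(mask)),
    }


@dataclass
class ComparisonResult:
    t_stat: float
    df: int
    p_value: float
    tails: str
    cohen_d: float
    group_sizes: tuple[int, int]


def two_sample_t(group_a, group_b, tails: str = "one") -> ComparisonResult:
    """Pooled-variance Student t test of mean(a) − mean(b).

    One-tailed (default) tests H1: mean(a) > mean(b) with
    p = P(T_df >= t); two-tailed doubles the symmetric tail.  Cohen's d
    is the mean difference over the pooled standard deviation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: groups are constant")
    sp = np.sqrt(sp2)
    t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
    if tails == "one":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2 * stats.t.sf(abs(t), df))
    d = (a.mean() - b.mean()) / sp
    return ComparisonResult(
        t_stat=float(t), df=df, p_value=p, tails=tails, cohen_d=float(d), group_sizes=(n1, n2)
    )


def _percentile_rank(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-cell percentile score in [0, 1] over valid cells (average ranks)."""
    out = np.full(values.shape, np.nan)
    v = values[valid]
    if v.size == 0:
        return out
    if v.size == 1:
        out[valid] = 0.5
        return out
    ranks = stats.rankdata(v, method="average")
    out[valid] = (ranks - 1) / (v.size - 1)
    return out


def composite_priority(
    vulnerability: np.ndarray,
    turnover: np.ndarray,
    threat_masks: list[np.ndarray],
    protected_mask: np.ndarray | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict:
    """Weight-explicit composite conservation priority.

    priority = w1·rank(low vulnerability) + w2·rank(high turnover)
    − w3·(any threat present), with ranks as per-cell percentile scores
    in [0, 1].  Protected cells are flagged separately, not scored into
    the surface.  Returns the priority raster plus the metadata needed
    to reproduce it.
    """
    w1, w2, w3 = (float(w) for w in weights)
    if min(w1, w2, w3) < 0:
        raise ValueError("weights must be non-negative")
    vul = np.asarray(vulnerability, dtype=float)
    turn = np.asarray(turnover, dtype=float)
    if vul.shape != turn.shape:
        raise ValueError("vulnerability and turnover must share geometry")
    valid = np.isfinite(vul) & np.isfinite(turn)
    if not valid.any():
        raise ValueError("all cells are nodata")
    threat = np.zeros(vul.shape, dtype=bool)
    for m in threat_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != vul.shape:
            raise ValueError("threat mask geometry mismatch")
        threat |= m
    priority = (
        w1 * _percentile_rank(-vul, valid)
        + w2 * _percentile_rank(turn, valid)
        - w3 * threat.astype(float)
    )
    priority[~valid] = np.nan
    return {
        "priority": priority,
        "protected": None if protected_mask is None else np.asarray(protected_mask, dtype=bool),
        "metadata": {
            "formula": "w1*rank(low vulnerability) + w2*rank(high turnover) - w3*threat",
            "weights": [w1, w2, w3],
        },
    }
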