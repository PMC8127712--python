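"""Gradient-forest genotype–environment association modelling.

The model relates population allele frequencies to environmental
predictors at the sampling sites.  One regression forest is fitted per
SNP; each split's impurity improvement is attributed to the (predictor,
threshold) pair at which it occurred.  Improvements are weighted by the
SNP's out-of-bag R² (negative-R² SNPs contribute nothing), pooled across
SNPs, density-standardized along each predictor's gradient, and
accumulated into a monotone *cumulative importance* ("turnover")
function :math:`F_p` per predictor.  :math:`F_p` transforms raw
environmental values into common units of compositional genomic
turnover; its total rise is the predictor's overall importance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import SmallForest, fit_forest

__all__ = [
    "AlleleFreqTable",
    "SnpFitRecord",
    "CumulativeImportanceFunction",
    "GradientForestModel",
    "GradientForestParams",
    "filter_snps_by_maf",
    "fit_gradient_forest",
    "select_significant_snps",
    "cumulative_importance",
    "overall_importance",
]

logger = logging.getLogger(__name__)


@dataclass
class AlleleFreqTable:
    """Sites × SNPs matrix of population allele frequencies.

    ``frequencies`` is (n_sites, n_snps) with values in [0, 1]; missing
    SNP–site cells are NaN.  ``coordinates`` is (n_sites, 2) lon/lat.
    """

    site_ids: list[str]
    coordinates: np.ndarray
    snp_ids: list[str]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        n_sites, n_snps = len(self.site_ids), len(self.snp_ids)
        if n_sites < 2:
            raise ValueError("need at least 2 sites")
        # n_snps == 0 is tolerated so a filter may legitimately empty the
        # panel (with a warning); model fitting requires >= 1
        if self.coordinates.shape != (n_sites, 2):
            raise ValueError("coordinates must be (n_sites, 2)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("site coordinates must not be missing")
        if self.frequencies.shape != (n_sites, n_snps):
            raise ValueError(
                f"frequencies shape {self.frequencies.shape} != ({n_sites}, {n_snps})"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.frequencies < 0) | (self.frequencies > 1)
        if np.any(bad):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def mean_frequencies(self) -> np.ndarray:
        """Per-SNP mean frequency across sites, ignoring missing cells."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.frequencies, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, index=self.site_ids, columns=self.snp_ids)
        df.insert(0, "lat", self.coordinates[:, 1])
        df.insert(0, "lon", self.coordinates[:, 0])
        df.index.name = "site_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFreqTable":
        coords = df[["lon", "lat"]].to_numpy()
        snps = [c for c in df.columns if c not in ("lon", "lat")]
        return cls(
            site_ids=[str(s) for s in df.index],
            coordinates=coords,
            snp_ids=[str(c) for c in snps],
            frequencies=df[snps].to_numpy(dtype=float),
        )

    def subset_snps(self, keep: np.ndarray) -> "AlleleFreqTable":
        keep = np.asarray(keep)
        return AlleleFreqTable(
            site_ids=list(self.site_ids),
            coordinates=self.coordinates.copy(),
            snp_ids=[self.snp_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.snp_ids[i] for i in keep],
            frequencies=self.frequencies[:, keep],
        )


def filter_snps_by_maf(table: AlleleFreqTable, threshold: float = 0.02) -> AlleleFreqTable:
    """Retain SNPs whose minor allele frequency exceeds ``threshold``.

    The MAF of SNP *j* is ``min(p̄_j, 1 − p̄_j)`` where ``p̄_j`` is the
    unweighted mean frequency across sites.  Column order is preserved.
    """
    if not 0 < threshold < 0.5:
        raise ValueError(f"threshold must be in (0, 0.5), got {threshold}")
    pbar = table.mean_frequencies()
    maf = np.minimum(pbar, 1.0 - pbar)
    keep = maf > threshold
    if not np.any(keep):
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return table.subset_snps(keep)


@dataclass
class SnpFitRecord:
    snp_id: str
    oob_r2: float
    # predictor name -> (k, 2) array of (threshold, improvement) pairs,
    # improvements >= 0, thresholds within the predictor's observed range
    per_predictor_importance: dict[str, np.ndarray]


@dataclass
class CumulativeImportanceFunction:
    """Monotone step function F_p: predictor value -> cumulative importance.

    ``breakpoints`` are strictly increasing; ``cumulative`` is
    non-decreasing and starts at 0.  Evaluation uses step interpolation:
    F(x) equals the cumulative value at the largest breakpoint <= x,
    clamped to the endpoint values outside the training range.
    """

    predictor: str
    breakpoints: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.breakpoints.shape != self.cumulative.shape or self.breakpoints.ndim != 1:
            raise ValueError("breakpoints and cumulative must be 1-D and congruent")
        if len(self.breakpoints) == 0:
            self.breakpoints = np.array([0.0])
            self.cumulative = np.array([0.0])
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if abs(self.cumulative[0]) > 1e-12:
            raise ValueError("cumulative must start at 0")
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ValueError("cumulative must be non-decreasing")

    @property
    def total_rise(self) -> float:
        return float(self.cumulative[-1])

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.breakpoints, x, side="right") - 1
        idx = np.clip(idx, 0, len(self.breakpoints) - 1)
        out = self.cumulative[idx]
        return out

    @classmethod
    def from_splits(
        cls,
        predictor: str,
        splits: list[tuple[float, float]],
        start: float | None = None,
    ) -> "CumulativeImportanceFunction":
        """Build F directly from pooled (threshold, mass) pairs.

        ``start`` anchors F(start) = 0; defaults to just below the first
        threshold.
        """
        if not splits:
            return cls(predictor, np.array([0.0]), np.array([0.0]))
        arr = np.asarray(sorted(splits), dtype=float)
        thr, mass = arr[:, 0], arr[:, 1]
        if np.any(mass < 0):
            raise ValueError("split masses must be non-negative")
        # merge duplicate thresholds
        uthr, inv = np.unique(thr, return_inverse=True)
        umass = np.zeros(len(uthr))
        np.add.at(umass, inv, mass)
        if start is None:
            span = uthr[-1] - uthr[0]
            start = uthr[0] - max(span, 1.0) * 1e-6
        if start >= uthr[0]:
            raise ValueError("start must precede the first threshold")
        bp = np.concatenate([[start], uthr])
        cum = np.concatenate([[0.0], np.cumsum(umass)])
        return cls(predictor, bp, cum)


@dataclass
class GradientForestParams:
    """Forest and aggregation settings (configurable; see methods note)."""

    n_trees: int = 500
    mtry: int | None = None  # default ceil(p / 3)
    min_leaf: int = 2
    n_bins: int = 50
    density_standardize: bool = True
    retain_forests: bool = True
    min_informative_sites: int = 5
    significance: str = "empirical_null"  # or "permutation_fdr" / "r2_positive"
    fdr_q: float = 0.05
    n_null: int = 499


@dataclass
class GradientForestModel:
    predictor_names: list[str]
    fits: list[SnpFitRecord]
    cif: dict[str, CumulativeImportanceFunction]
    overall: dict[str, float]
    params: GradientForestParams
    seed: int
    env_at_sites: pd.DataFrame
    significant_snps: set[str] | None = None
    forests: dict[str, SmallForest] | None = None
    snp_site_mask: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return [f.snp_id for f in self.fits]

    def oob_r2(self) -> pd.Series:
        return pd.Series({f.snp_id: f.oob_r2 for f in self.fits})


def _snp_seed(seed: int, j: int) -> int:
    return (int(seed) * 1000003 + 7919 * (j + 1)) % (2**63 - 1)


def _pool_importances(
    fits: list[SnpFitRecord], predictor_names: list[str]
) -> dict[str, np.ndarray]:
    """R²-weighted pooling of per-SNP split improvements.

    Each SNP's improvements are normalized to sum to 1 and weighted by
    max(oob_r2, 0), so a SNP distributes exactly its explainable
    variance across its splits and non-informative SNPs contribute
    nothing.  The pool is divided by the number of SNPs so totals are
    mean-R² decompositions, invariant to panel size.  Returns per
    predictor an (k, 2) array of (threshold, pooled mass).
    """
    parts: dict[str, list[np.ndarray]] = {p: [] for p in predictor_names}
    n = len(fits)
    for rec in fits:
        w = max(rec.oob_r2, 0.0)
        if w == 0.0:
            continue
        tot = sum(float(a[:, 1].sum()) for a in rec.per_predictor_importance.values() if a.size)
        if tot <= 0:
            continue
        scale = w / (tot * n)
        for p, a in rec.per_predictor_importance.items():
            if a.size:
                parts[p].append(np.column_stack([a[:, 0], a[:, 1] * scale]))
    return {
        p: (np.vstack(v) if v else np.empty((0, 2))) for p, v in parts.items()
    }


def _build_cif(
    predictor: str,
    pooled: np.ndarray,
    env_values: np.ndarray,
    n_bins: int,
    density_standardize: bool,
) -> CumulativeImportanceFunction:
    """Bin pooled split mass along the predictor and accumulate.

    Bins are ``n_bins`` equal-width intervals over the predictor's
    observed range at the sites.  Under density standardization the bin
    masses are divided by the local density of split *opportunities*
    (midpoints of adjacent distinct observed values), then rescaled to
    preserve the predictor's total importance — standardization reshapes
    F along the gradient without changing its total rise.
    """
    lo = float(np.min(env_values))
    hi = float(np.max(env_values))
    if pooled.size == 0 or hi <= lo:
        return CumulativeImportanceFunction(predictor, np.array([lo]), np.array([0.0]))
    thr = pooled[:, 0]
    mass = pooled[:, 1]
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, thr, side="right") - 1, 0, n_bins - 1)
    bin_mass = np.zeros(n_bins)
    np.add.at(bin_mass, which, mass)
    total = bin_mass.sum()
    if density_standardize and total > 0:
        uvals = np.unique(env_values)
        mids = 0.5 * (uvals[1:] + uvals[:-1])
        if len(mids) > 0:
            mwhich = np.clip(np.searchsorted(edges, mids, side="right") - 1, 0, n_bins - 1)
            dens = np.zeros(n_bins)
            np.add.at(dens, mwhich, 1.0)
            dens /= dens[dens > 0].mean()
            floor = dens[dens > 0].min()
            std = bin_mass / np.maximum(dens, floor)
            if std.sum() > 0:
                bin_mass = std * (total / std.sum())
    bp = edges  # breakpoint k is the upper edge of bin k-1; bp[0] anchors F=0
    cum = np.concatenate([[0.0], np.cumsum(bin_mass)])
    # guard tiny negative drift
    cum = np.maximum.accumulate(cum)
    return CumulativeImportanceFunction(predictor, bp, cum)


def fit_gradient_forest(
    table: AlleleFreqTable,
    env_at_sites: pd.DataFrame,
    params: GradientForestParams | None = None,
    seed: int = 0,
) -> GradientForestModel:
    """Fit the gradient-forest model of allele frequencies on predictors.

    Parameters
    ----------
    table : allele-frequency table (sites × SNPs).
    env_at_sites : DataFrame (sites × predictors), rows aligned with
        ``table.site_ids``.
    params : forest/aggregation settings.
    seed : master seed; per-SNP forest seeds are derived from it.
    """
    params = params or GradientForestParams()
    if table.n_snps < 1:
        raise ValueError("need at least 1 SNP to fit the model")
    if table.n_sites < 5:
        raise ValueError("need at least 5 sites to fit the model")
    if env_at_sites.shape[1] < 1:
        raise ValueError("need at least one predictor")
    if env_at_sites.shape[0] != table.n_sites:
        raise ValueError("env_at_sites rows must align with table sites")
    X_full = env_at_sites.to_numpy(dtype=float)
    if not np.all(np.isfinite(X_full)):
        raise ValueError("predictor values must be finite")
    predictor_names = [str(c) for c in env_at_sites.columns]

    const = [p for p, v in zip(predictor_names, X_full.T) if np.ptp(v) == 0]
    for p in const:
        warnings.warn(f"predictor {p!r} is constant across sites; it gets a zero function")

    mtry = params.mtry if params.mtry is not None else int(np.ceil(len(predictor_names) / 3))

    fits: list[SnpFitRecord] = []
    forests: dict[str, SmallForest] = {}
    masks: dict[str, np.ndarray] = {}
    n_skipped = 0
    for j, snp in enumerate(table.snp_ids):
        y_full = table.frequencies[:, j]
        ok = np.isfinite(y_full)
        if ok.sum() < params.min_informative_sites:
            n_skipped += 1
            continue
        X = X_full[ok]
        y = y_full[ok]
        if np.ptp(y) == 0:
            fits.append(
                SnpFitRecord(snp, 0.0, {p: np.empty((0, 2)) for p in predictor_names})
            )
            masks[snp] = ok
            continue
        f = fit_forest(
            X,
            y,
            n_trees=params.n_trees,
            mtry=mtry,
            min_leaf=params.min_leaf,
            seed=_snp_seed(seed, j),
        )
        per = {
            p: np.column_stack(
                [f.split_threshold[f.split_feature == i], f.split_improvement[f.split_feature == i]]
            )
            for i, p in enumerate(predictor_names)
        }
        fits.append(SnpFitRecord(snp, float(f.oob_r2), per))
        masks[snp] = ok
        if params.retain_forests:
            forests[snp] = f
    if n_skipped:
        logger.info("skipped %d SNPs with < %d informative sites", n_skipped, params.min_informative_sites)

    pooled = _pool_importances(fits, predictor_names)
    cif = {
        p: _build_cif(p, pooled[p], X_full[:, i], params.n_bins, params.density_standardize)
        for i, p in enumerate(predictor_names)
    }
    overall = {p: cif[p].total_rise for p in predictor_names}
    return GradientForestModel(
        predictor_names=predictor_names,
        fits=fits,
        cif=cif,
        overall=overall,
        params=params,
        seed=seed,
        env_at_sites=env_at_sites.copy(),
        forests=forests if params.retain_forests else None,
        snp_site_mask=masks,
    )


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level q."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    below = pvals[order] <= q * (np.arange(1, m + 1) / m)
    k = np.max(np.flatnonzero(below)) + 1 if np.any(below) else 0
    out = np.zeros(m, dtype=bool)
    out[order[:k]] = True
    return out


def _permutation_null_r2(model: GradientForestModel, freqs: np.ndarray, n_null: int) -> np.ndarray:
    """Null distribution of OOB R²: forests on permuted responses."""
    rng = np.random.default_rng((model.seed * 69069 + 12345) % 2**31)
    X = model.env_at_sites.to_numpy(dtype=float)
    mtry = model.params.mtry or int(np.ceil(X.shape[1] / 3))
    n_snps = freqs.shape[1]
    out = np.empty(n_null)
    for k in range(n_null):
        y = ok = None
        for _ in range(20):  # redraw if the sampled SNP is degenerate
            j = int(rng.integers(n_snps))
            y_full = freqs[:, j]
            ok = np.isfinite(y_full)
            y = y_full[ok]
            if len(y) >= 5 and np.ptp(y) > 0:
                break
        else:
            out[k] = 0.0
            continue
        f = fit_forest(
            X[ok],
            rng.permutation(y),
            n_trees=model.params.n_trees,
            mtry=mtry,
            min_leaf=model.params.min_leaf,
            seed=int(rng.integers(2**31)),
        )
        out[k] = f.oob_r2
    return out


def select_significant_snps(
    model: GradientForestModel,
    criterion: str | None = None,
    table: AlleleFreqTable | None = None,
) -> set[str]:
    """Select SNPs significantly associated with the environment.

    Criteria:

    ``"r2_positive"``
        out-of-bag R² > 0 (the simple gradient-forest convention).
    ``"empirical_null"`` (default)
        Efron-style empirical-null calibration: the null location and
        scale of OOB R² are estimated robustly (median, MAD) from the
        bulk of the observed per-SNP distribution — under a sparse
        adaptive architecture the bulk is neutral — then z-scores
        against that null are converted to one-sided normal p-values
        and controlled with Benjamini–Hochberg at ``params.fdr_q``,
        intersected with R² > 0.
    ``"permutation_fdr"``
        empirical p-values of OOB R² against a permutation null
        (responses permuted across sites), BH at ``params.fdr_q``,
        intersected with R² > 0.  Requires ``table`` to rebuild null
        responses.

    The selected set is stored on ``model.significant_snps``.
    """
    from scipy import stats as _stats

    criterion = criterion or model.params.significance
    r2 = np.array([f.oob_r2 for f in model.fits])
    ids = np.array([f.snp_id for f in model.fits])
    if criterion == "r2_positive":
        sel = set(ids[r2 > 0])
    elif criterion == "empirical_null":
        med = np.median(r2)
        mad = np.median(np.abs(r2 - med))
        scale = 1.4826 * mad
        if scale <= 0:
            sel = set()
        else:
            z = (r2 - med) / scale
            pvals = _stats.norm.sf(z)
            sel = set(ids[_bh_reject(pvals, model.params.fdr_q) & (r2 > 0)])
    elif criterion == "permutation_fdr":
        if table is None:
            raise ValueError("permutation_fdr selection needs the allele-frequency table")
        null = _permutation_null_r2(model, table.frequencies, model.params.n_null)
        # empirical upper-tail p-value with add-one correction
        pvals = (1.0 + np.sum(null[None, :] >= r2[:, None], axis=1)) / (1.0 + len(null))
        sel = set(ids[_bh_reject(pvals, model.params.fdr_q) & (r2 > 0)])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    model.significant_snps = sel
    return sel


def cumulative_importance(model: GradientForestModel, predictor: str) -> CumulativeImportanceFunction:
    """The fitted turnover function F_p for one predictor."""
    try:
        return model.cif[predictor]
    except KeyError:
        raise KeyError(
            f"unknown predictor {predictor!r}; known: {', '.join(model.predictor_names)}"
        ) from None


def overall_importance(model: GradientForestModel) -> list[tuple[str, float]]:
    """Predictors ranked by total turnover, descending; ties lexicographic."""
    return sorted(model.overall.items(), key=lambda kv: (-kv[1], kv[0]))
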