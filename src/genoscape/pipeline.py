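"""End-to-end pipeline: filter → fit → transform → PCA/RGB → turnover →
vulnerability → allele shift/classes → overlays → report.

Every run writes a manifest recording the seed, a config hash and the
SHA-256 checksum of each artifact; a rerun with an identical config
reproduces identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import overlay as ov
from .gea import (
    GradientForestParams,
    filter_snps_by_maf,
    fit_gradient_forest,
    overall_importance,
    select_significant_snps,
)
from .grids import write_geotiff
from .io import read_freq_csv, read_pop_map, read_vcf_to_freq_table
from .synthetic import SyntheticBundle, SyntheticConfig, generate_bundle, read_bundle
from .transform import pca_reduce, rgb_map, transform_env_stack
from .vulnerability import (
    classify_vulnerability,
    focal_range,
    genomic_vulnerability,
    predict_allele_shift,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; precedence: flags > config file > defaults."""

    output_dir: str = "results/pipeline"
    seed: int = 0
    synthetic: SyntheticConfig | None = None  # generate inputs when set
    bundle_dir: str | None = None  # ... or load a written bundle
    vcf_path: str | None = None
    pop_map_path: str | None = None
    freq_csv_path: str | None = None
    maf_threshold: float = 0.02
    gf_params: GradientForestParams = field(default_factory=GradientForestParams)
    metric: str = "euclidean"
    rgb_mode: str = "2pc"
    turnover_radius: int = 1
    class_breaks: tuple[float, float] = (0.25, 0.50)
    shift_summary: str = "mean"
    threat_geojson: str | None = None
    protected_geojson: str | None = None
    species_geojson: str | None = None
    priority_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig) -> SyntheticBundle:
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        if syn.seed != cfg.seed:
            syn = dataclasses.replace(syn, seed=cfg.seed)
        return generate_bundle(syn)
    if cfg.bundle_dir is not None:
        return read_bundle(cfg.bundle_dir)
    raise ValueError(
        "pipeline needs either a synthetic config or a bundle directory "
        "(external raster+VCF runs assemble a bundle first)"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and persist artifacts + manifest.

    Returns a dict with artifact paths and headline numbers.  A stage
    failure raises with the stage name; artifacts completed before the
    failure remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    t_all = time.perf_counter()
    try:
        t0 = time.perf_counter()
        bundle = _load_inputs(config)
        grid = bundle.env_current.grid
        timings[stage] = time.perf_counter() - t0

        stage = "filter"
        t0 = time.perf_counter()
        table = bundle.freqs
        if config.vcf_path:
            table = read_vcf_to_freq_table(config.vcf_path, read_pop_map(config.pop_map_path))
        elif config.freq_csv_path:
            table = read_freq_csv(config.freq_csv_path)
        filtered = filter_snps_by_maf(table, config.maf_threshold)
        timings[stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        env_sites = bundle.env_at_sites("current")
        model = fit_gradient_forest(filtered, env_sites, config.gf_params, seed=config.seed)
        selected = select_significant_snps(model, table=filtered)
        ranking = overall_importance(model)
        imp = pd.DataFrame(ranking, columns=["predictor", "importance"])
        imp.to_csv(out / "predictor_importance.csv", index=False)
        artifacts["predictor_importance"] = "predictor_importance.csv"
        timings[stage] = time.perf_counter() - t0

        stage = "transform"
        t0 = time.perf_counter()
        t_cur = transform_env_stack(model, bundle.env_current)
        t_fut = transform_env_stack(model, bundle.env_future)
        for label, st in (("current", t_cur), ("future", t_fut)):
            fn = f"transformed_{label}.tif"
            write_geotiff(out / fn, st.data, grid, description=",".join(st.layer_names))
            artifacts[f"transformed_{label}"] = fn
        timings[stage] = time.perf_counter() - t0

        stage = "pca-rgb"
        t0 = time.perf_counter()
        pc_cur, pc_fut = pca_reduce(t_cur, t_fut, n_components=2)
        rgb_map((pc_cur, pc_fut), mode=config.rgb_mode)
        for label, pc in (("current", pc_cur), ("future", pc_fut)):
            fn = f"adaptive_landscape_{label}_rgb.tif"
            write_geotiff(out / fn, pc.rgb, grid, description=f"RGB {config.rgb_mode}")
            artifacts[f"rgb_{label}"] = fn
        sidecar = {
            "loadings": pc_cur.loadings.tolist(),
            "explained_variance": pc_cur.explained_variance.tolist(),
            "explained_variance_ratio": pc_cur.explained_variance_ratio.tolist(),
            "scaling_record": pc_cur.scaling_record,
        }
        (out / "pca.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        artifacts["pca_sidecar"] = "pca.json"
        timings[stage] = time.perf_counter() - t0

        stage = "turnover"
        t0 = time.perf_counter()
        turnover = focal_range(pc_cur, radius=config.turnover_radius)
        write_geotiff(
            out / "adaptive_turnover.tif",
            turnover.values,
            grid,
            description=f"focal range, radius={config.turnover_radius}",
        )
        artifacts["turnover"] = "adaptive_turnover.tif"
        timings[stage] = time.perf_counter() - t0

        stage = "vulnerability"
        t0 = time.perf_counter()
        vuln = genomic_vulnerability(model, bundle.env_current, bundle.env_future, config.metric)
        write_geotiff(out / "genomic_vulnerability.tif", vuln.offset, grid, description=config.metric)
        artifacts["vulnerability"] = "genomic_vulnerability.tif"
        timings[stage] = time.perf_counter() - t0

        stage = "allele-shift"
        t0 = time.perf_counter()
        shift = predict_allele_shift(
            model,
            bundle.env_current,
            bundle.env_future,
            snp_set=selected or None,
            summary=config.shift_summary,
        )
        classes = classify_vulnerability(shift, config.class_breaks)
        write_geotiff(out / "allele_shift.tif", shift, grid, description=config.shift_summary)
        write_geotiff(
            out / "vulnerability_classes.tif",
            classes,
            grid,
            description="0=low,1=medium,2=high,255=nodata; breaks=" + ",".join(map(str, config.class_breaks)),
        )
        artifacts["allele_shift"] = "allele_shift.tif"
        artifacts["classes"] = "vulnerability_classes.tif"
        timings[stage] = time.perf_counter() - t0

        stage = "overlays"
        t0 = time.perf_counter()
        threat_masks = []
        protected_mask = None
        report: dict = {}
        if config.threat_geojson:
            feats = ov.read_geojson_layer(config.threat_geojson)
            for cat in ("mining", "logging", "agriculture"):
                m = ov.rasterize_layer(feats, grid, cat)
                if m.any():
                    threat_masks.append(m)
        if config.protected_geojson:
            feats = ov.read_geojson_layer(config.protected_geojson)
            protected_mask = ov.rasterize_layer(feats, grid, "protected")
            report["protected_turnover"] = ov.zonal_stats(turnover.values, protected_mask)
        if config.species_geojson:
            feats = ov.read_geojson_layer(config.species_geojson)
            richness = ov.species_richness(feats, grid)
            write_geotiff(out / "species_richness.tif", richness.astype(np.float64), grid)
            artifacts["richness"] = "species_richness.tif"
        prio = ov.composite_priority(
            vuln.offset,
            turnover.values,
            threat_masks,
            protected_mask,
            config.priority_weights,
        )
        write_geotiff(out / "composite_priority.tif", prio["priority"], grid)
        artifacts["priority"] = "composite_priority.tif"
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        valid = np.isfinite(vuln.offset)
        cls_valid = classes[classes != 255]
        report.update(
            {
                "n_snps_input": table.n_snps,
                "n_snps_after_maf": filtered.n_snps,
                "n_significant_snps": len(selected),
                "predictor_ranking": ranking,
                "offset_quantiles": {
                    q: float(np.quantile(vuln.offset[valid], q)) for q in (0.05, 0.5, 0.95)
                },
                "class_counts": {
                    label: int((cls_valid == code).sum())
                    for code, label in ((0, "low"), (1, "medium"), (2, "high"))
                },
                "priority_metadata": prio["metadata"],
            }
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["report"] = "report.json"
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # timings go to the log, not the manifest, so identical configs
    # reproduce byte-identical manifests
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": {k: {"file": v, "sha256": _sha256(out / v)} for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for name, secs in timings.items():
        logger.info("stage %-14s %.3f s", name, secs)
    logger.info(
        "pipeline done in %.1fs; seed=%d config=%s",
        time.perf_counter() - t_all,
        config.seed,
        manifest["config_hash"][:12],
    )
    return {"output_dir": str(out), "artifacts": artifacts, "report": report, "manifest": manifest}
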