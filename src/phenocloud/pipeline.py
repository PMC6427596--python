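"""The full processing chain: simplify -> denoise -> traits.

`run_pipeline` is the library-level entry point the CLI wraps. It records
every stage's parameters and summary numbers in one JSON-serializable
report so a run is reproducible from its output alone.
"""

from __future__ import annotations

import logging

import numpy as np

from . import denoise as dn
from .config import PipelineConfig
from .core import PointCloud, build_knn
from .geometry import estimate_field
from .simplify import simplify as simplify_cloud
from .traits import compute_traits

__all__ = ["run_pipeline"]

log = logging.getLogger("phenocloud")


def run_pipeline(cloud: PointCloud, config: PipelineConfig | None = None
                 ) -> dict:
    """Process one plant cloud and return the aggregated stage report."""
    config = config or PipelineConfig()
    report: dict = {"config": config.model_dump(mode="json"), "stages": {}}
    work = cloud
    report["stages"]["input"] = {"n_points": len(work)}

    k = min(config.knn, max(1, len(work) - 1))
    graph = build_knn(work, k)
    field = estimate_field(work, graph)

    if not config.skip_simplify:
        log.info("simplify: %d points, gamma=%g", len(work), config.gamma)
        simp = simplify_cloud(work, field, config.gamma,
                              config.beta_detail, config.beta_nondetail)
        report["stages"]["simplify"] = {
            "n_raw": len(work),
            "n_kept": len(simp.cloud),
            "rate_percent": round(simp.rate_percent, 1),
            "n_detail_cells": simp.n_detail_cells,
            "n_nondetail_cells": simp.n_nondetail_cells,
        }
        work = simp.cloud
        k = min(config.knn, max(1, len(work) - 1))
        graph = build_knn(work, k)
        field = estimate_field(work, graph)

    if not config.skip_denoise and config.denoise_method != "none":
        log.info("denoise: %s on %d points", config.denoise_method, len(work))
        if config.denoise_method == "bilateral":
            labels = dn.region_division(field)
            params = dn.BilateralParams(k=k,
                                        iterations=config.denoise_iterations)
            work, rep = dn.bilateral_filter(work, field, labels, params)
            extra = {"n_rich": int(labels.rich.sum()),
                     "n_single": int(labels.single.sum())}
        else:
            work, rep = dn.laplace_filter(work, graph, config.laplace_lambda,
                                          config.denoise_iterations)
            extra = {}
        report["stages"]["denoise"] = {
            "method": config.denoise_method,
            "max_error_mm": rep.max_error,
            "avg_error_mm": rep.avg_error,
            "n_moved": rep.n_moved,
            **extra,
        }

    traits = compute_traits(
        work, vertical_axis=config.vertical_axis,
        breadth_axis=config.breadth_axis, stem_window=config.stem_window,
        apex_quantile=config.apex_quantile,
        search_radius=config.base_search_radius,
        height_tolerance=config.height_tolerance,
        r_gate_factor=config.r_gate_factor)
    report["traits"] = traits.as_dict()
    report["stages"]["output"] = {"n_points": len(work)}
    report["_cloud"] = work  # stripped before serialization
    return report


def serializable_report(report: dict) -> dict:
    """Drop in-memory objects and round floats for stable JSON output."""

    def conv(obj):
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items() if k != "_cloud"}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.ndarray):
            return conv(obj.tolist())
        return obj

    return conv(report)
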