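"""End-to-end pipeline runs: hemodynamics and imaging chains.

``run_hemodynamics`` simulates a WSS field for the configured windows,
computes the per-node metrics, summarizes regions in the per-location
min/max/mean table format and classifies every node, writing CSV
artifacts.  ``run_imaging`` generates one monolayer per regime, runs
segmentation, profiling (factor analysis + LDA) and junction analysis,
and writes per-cell, factor, LDA and junction-ratio tables.  Both are
deterministic for a fixed config (seeds included).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bfio
from .config import RunConfig
from .fields import make_wall_mesh
from .junctions import classify_segments, faj_ratio, trace_junctions
from .metrics import classify_regimes, compute_all, summarize_regions
from .morphometry import (extract_profile, segment_cells, segment_nuclei,
                          summarize_groups)
from .profiling import biplot_attribution, factor_reduce, lda_fit, \
    zscore_normalize
from .synthimage import generate_monolayer, write_monolayer
from .synthwss import generate_field

log = logging.getLogger("bypassflow")


def run_hemodynamics(config: RunConfig, outdir: str | Path | None = None
                     ) -> dict[str, pd.DataFrame]:
    """simulate -> metrics -> summarize -> classify; returns the tables.

    Writes ``metrics.csv``, ``region_summary.csv`` and the simulated field
    (CSV pair + VTK) when ``outdir`` is given.
    """
    mesh = make_wall_mesh(config.windows, config.mesh.nodes_per_mm,
                          config.mesh.n_circ, config.geometry)
    field = generate_field(
        mesh, config.windows, config.regimes,
        n_steps=config.field_cfg.n_steps, period=config.field_cfg.period,
        transition_halfwidth=config.field_cfg.transition_halfwidth)
    metrics = compute_all(field, mesh)
    metrics["regime"] = classify_regimes(metrics, config.thresholds)
    summary = summarize_regions(metrics, config.windows)
    log.info("hemodynamics: %d nodes, regime recovery %.3f",
             mesh.n_nodes, (metrics["regime"] == mesh.region).mean())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bfio.write_csv(outdir / "field", mesh, field)
        bfio.write_vtk(outdir / "field.vtk", mesh, field)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        summary.to_csv(outdir / "region_summary.csv", index=False)
        config.to_yaml(outdir / "config.yaml")
    return {"metrics": metrics, "region_summary": summary}


def run_imaging(config: RunConfig, outdir: str | Path | None = None,
                variance_target: float = 0.80) -> dict[str, object]:
    """Per-regime monolayers -> morphometry -> profiling -> junctions.

    Returns per-cell profiles (with regime labels), group summaries, the
    factor model, the LDA result, biplot attribution and per-regime FAJ
    ratios.
    """
    profiles = []
    ratios = {}
    for regime, spec in config.monolayers.items():
        image, truth = generate_monolayer(spec)
        nuclei = segment_nuclei(image[0], spec.pixel_size)
        cells = segment_cells(nuclei, image[1])
        prof = extract_profile(cells, image, spec.pixel_size,
                               flow_direction=spec.flow_direction)
        prof.insert(0, "group", regime)
        profiles.append(prof)
        segs = trace_junctions(image[1], spec.pixel_size)
        segs = classify_segments(segs, image[2], image[1], spec.pixel_size)
        try:
            ratios[regime] = faj_ratio(segs)
        except ValueError:
            ratios[regime] = float("nan")
        if outdir is not None:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            write_monolayer(out / f"monolayer_{regime}", image, truth)
        log.info("imaging %s: %d cells, FAJ ratio %.3f",
                 regime, len(prof), ratios[regime])
    allprof = pd.concat(profiles, ignore_index=True)
    feature_cols = [c for c in allprof.columns
                    if c not in ("group", "cell_id", "on_border")]
    normalized, dropped = zscore_normalize(allprof[feature_cols])
    if dropped:
        log.info("dropped %d constant feature columns", len(dropped))
    fmodel = factor_reduce(normalized, variance_target)
    scores = fmodel.transform(normalized)
    lda = lda_fit(scores, allprof["group"].to_numpy(), seed=config.seed)
    attribution = biplot_attribution(lda) if lda.n_axes >= 2 else None
    summary = summarize_groups(
        allprof[["group", "shape_alignment_deg", "shape_eccentricity",
                 "shape_axis_ratio"]], "group")
    ratio_df = pd.DataFrame({"regime": list(ratios), "faj_ratio":
                             [ratios[r] for r in ratios]})
    if outdir is not None:
        out = Path(outdir)
        allprof.to_csv(out / "cell_profiles.csv", index=False)
        pd.DataFrame(fmodel.loadings_,
                     index=normalized.columns).to_csv(out / "loadings.csv")
        pd.DataFrame(scores).to_csv(out / "factor_scores.csv", index=False)
        pd.DataFrame(lda.scores).to_csv(out / "lda_scores.csv", index=False)
        if attribution is not None:
            attribution.to_csv(out / "attribution.csv", index=False)
        summary.to_csv(out / "group_summary.csv", index=False)
        ratio_df.to_csv(out / "faj_ratios.csv", index=False)
    return {"profiles": allprof, "factor_model": fmodel, "lda": lda,
            "attribution": attribution, "group_summary": summary,
            "faj_ratios": ratio_df}
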