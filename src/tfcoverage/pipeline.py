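"""End-to-end orchestration of the coverage audit.

Stages, in dependency order: expression thresholding -> cell-line name
matching -> coverage inventory -> inequality metrics -> cover-ratio series
-> acquisition-order simulation -> prioritization.  Every stage logs row
counts in/out (the analysis is a filter cascade; attrition must be
auditable), writes a tidy TSV stamped with the run ID, and the whole run is
byte-identical when repeated with the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .coverage import gwas_series, reg_tf_series
from .inventory import (attention_correlations, build_inventory,
                        counterfactual_gini, experiment_counts, gini,
                        lorenz_curve, measured_pairs, unmeasured_fraction)
from .name_matching import accepted_pairs, match_cell_lines
from .prioritize import compare_deg_groups, hidden_gems
from .simulation import run_order_simulation, simulation_summary
from .stepminer import aggregate_to_class, call_expression, expressed_pairs
from .synthetic_data import SyntheticWorld, WorldConfig, generate_world

log = logging.getLogger("tfcoverage")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Run configuration: either a synthetic world or a set of input paths.

    ``paths`` names the input files (keys: metadata, expression, tss, snps,
    deg, markers, class_map, publications, peaks_dir, tfs); ``markers``,
    ``deg``, ``publications`` and ``tfs`` are optional — dependent stages are
    skipped with a warning when they are absent.
    """

    world: WorldConfig | None = None
    paths: dict = field(default_factory=dict)
    level: str = "class"
    flank: int = 500
    top_fraction: float = 0.25
    deg_threshold: int = 1000
    match_threshold: float = 0.9
    n_order_reps: int = 25
    n_reg_tf_lines: int = 3
    order_entity: str | None = None   # default: most-measured class
    split_year: int | None = None     # default: midpoint of the date range
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.world is not None:
            d["world"] = self.world.to_dict()
        return d


def _load_inputs(config: PipelineConfig):
    if config.world is not None:
        world = generate_world(config.world)
        return world
    p = config.paths
    for key in ("metadata", "expression", "tss", "snps", "class_map",
                "peaks_dir"):
        if key not in p:
            raise ValueError(f"pipeline config is missing input path {key!r}")
    metadata, meta_report = io_formats.read_experiment_table(p["metadata"])
    log.info("metadata: %d rows kept, %d dropped", meta_report.n_kept,
             meta_report.n_dropped)
    expression = io_formats.read_expression_matrix(p["expression"])
    tss = io_formats.read_bed(p["tss"]).rename(columns={"name": "gene"})
    snps, _ = io_formats.read_snp_table(p["snps"])
    cmap = io_formats.read_class_map(p["class_map"])
    deg = io_formats.read_deg_table(p["deg"]) if "deg" in p else None
    markers = (io_formats.read_marker_table(p["markers"])
               if "markers" in p else None)
    pubs = (pd.read_csv(p["publications"], sep="\t")
            if "publications" in p else None)
    tfs = (Path(p["tfs"]).read_text().split()
           if "tfs" in p else sorted(expression.index))
    peaks = {f.stem: io_formats.read_bed(f)
             for f in sorted(Path(p["peaks_dir"]).glob("*.bed"))}
    return SyntheticWorld(config=None, metadata=metadata,
                          expression=expression, tss=tss, snps=snps,
                          deg=deg, markers=markers, class_map=cmap,
                          publications=pubs, peaks=peaks, truth=None), tfs


def _write(df: pd.DataFrame, path: Path, run_id: str) -> str:
    out = df.copy()
    out.insert(0, "run_id", run_id)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
               lineterminator="\n")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    run_id = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    manifest: dict = {"run_id": run_id, "config": config.to_dict(),
                      "stages": {}, "outputs": {}}

    if config.world is not None:
        world = _load_inputs(config)
        tf_list = world.tfs
    else:
        world, tf_list = _load_inputs(config)
    hashes = manifest["outputs"]

    # stage 1: expression thresholding (TF rows of the expression matrix)
    tf_rows = [t for t in tf_list if t in world.expression.index]
    calls_res = call_expression(world.expression.loc[tf_rows])
    manifest["stages"]["threshold"] = {
        "n_tfs_fit": len(calls_res.fits), "n_skipped": len(calls_res.skipped)}
    hashes["fits.tsv"] = _write(calls_res.fits, outdir / "fits.tsv", run_id)
    calls_out = (calls_res.calls.astype("object")
                 .mask(calls_res.calls.isna(), "NA").reset_index())
    calls_out = calls_out.rename(columns={"index": "tf", "gene": "tf"})
    hashes["calls.tsv"] = _write(calls_out, outdir / "calls.tsv", run_id)

    # stage 2: cell-line name matching (expression columns vs metadata)
    meta_cells = sorted(set(world.metadata["cell_type"]))
    matches = match_cell_lines(sorted(world.expression.columns), meta_cells,
                               threshold=config.match_threshold)
    mapping_ab = accepted_pairs(matches)
    manifest["stages"]["match"] = {
        "n_candidates": len(matches), "n_accepted": len(mapping_ab)}
    hashes["matches.tsv"] = _write(matches, outdir / "matches.tsv", run_id)
    calls = calls_res.calls.rename(columns=mapping_ab)

    # stage 3: inventory (cell-type and class level)
    cline_pairs = expressed_pairs(calls)
    known = [c for c in calls.columns if c in world.class_map.index]
    class_pairs = aggregate_to_class(calls[known], world.class_map)
    inventories = {}
    for level in ("cell_type", "class"):
        meas, counts = measured_pairs(
            world.metadata, level=level,
            mapping=world.class_map if level == "class" else None)
        exp_pairs = cline_pairs if level == "cell_type" else class_pairs
        sample_universe = (sorted(world.class_map.index) if level == "cell_type"
                           else sorted(set(world.class_map)))
        inv = build_inventory(exp_pairs, meas, level=level,
                              tf_universe=tf_rows,
                              sample_universe=sample_universe)
        inventories[level] = inv
        manifest["stages"][f"inventory_{level}"] = \
            {k: int(v) for k, v in inv.status_counts().items()}
        hashes[f"inventory_{level}.tsv"] = _write(
            inv.table, outdir / f"inventory_{level}.tsv", run_id)
    frac = unmeasured_fraction(inventories["class"], by="sample")
    hashes["unmeasured_fraction.tsv"] = _write(
        frac, outdir / "unmeasured_fraction.tsv", run_id)

    # stage 4: inequality
    tf_counts = experiment_counts(world.metadata, by="tf", universe=tf_rows)
    ct_counts = experiment_counts(world.metadata, by="cell_type",
                                  universe=world.class_map.index)
    ineq = pd.DataFrame({
        "metric": ["gini_tf", "gini_cell_type", "counterfactual_gini_tf"],
        "value": [gini(tf_counts), gini(ct_counts),
                  counterfactual_gini(cline_pairs)],
    })
    hashes["inequality.tsv"] = _write(ineq, outdir / "inequality.tsv", run_id)
    for label, counts in (("tf", tf_counts), ("cell_type", ct_counts)):
        pts = lorenz_curve(counts)
        hashes[f"lorenz_{label}.tsv"] = _write(
            pd.DataFrame(pts, columns=["cum_entities", "cum_experiments"]),
            outdir / f"lorenz_{label}.tsv", run_id)
    manifest["stages"]["inequality"] = {
        m: float(v) for m, v in zip(ineq["metric"], ineq["value"])}
    if world.publications is not None:
        pubs = pd.Series(world.publications["n_publications"].to_numpy(),
                         index=world.publications["tf"].to_numpy())
        years = pd.to_datetime(world.metadata["deposit_date"]).dt.year
        split = config.split_year or int((years.min() + years.max()) // 2)
        rho_pub, rho_time = attention_correlations(world.metadata, pubs, split)
        att = pd.DataFrame({"metric": ["rho_publications",
                                       "rho_rich_get_richer"],
                            "split_year": split,
                            "value": [rho_pub, rho_time]})
        hashes["attention.tsv"] = _write(att, outdir / "attention.tsv", run_id)
        manifest["stages"]["attention"] = {"rho_publications": rho_pub,
                                           "rho_rich_get_richer": rho_time}
    else:
        log.warning("publications table absent: attention stage skipped")

    # stage 5: cover-ratio series
    years = pd.to_datetime(world.metadata["deposit_date"]).dt.year
    year_grid = list(range(int(years.min()), int(years.max()) + 1))
    top_lines = (world.metadata.groupby("cell_type").size()
                 .sort_values(ascending=False)
                 .index[:config.n_reg_tf_lines])
    reg_frames = []
    for line in top_lines:
        if line not in world.expression.columns:
            continue
        reg_frames.append(reg_tf_series(
            world.expression, world.tss, world.peaks, world.metadata, line,
            year_grid, flank=config.flank,
            top_fraction=config.top_fraction).to_frame())
    if reg_frames:
        hashes["reg_tf_series.tsv"] = _write(
            pd.concat(reg_frames, ignore_index=True),
            outdir / "reg_tf_series.tsv", run_id)
    gwas_frames = [gwas_series(world.snps, world.peaks, world.metadata, cls,
                               year_grid, level="class",
                               mapping=world.class_map).to_frame()
                   for cls in sorted(set(world.class_map))]
    hashes["gwas_series.tsv"] = _write(
        pd.concat(gwas_frames, ignore_index=True),
        outdir / "gwas_series.tsv", run_id)
    manifest["stages"]["cover_ratio"] = {
        "n_reg_tf_lines": len(reg_frames), "n_classes": len(gwas_frames)}

    # stage 6: acquisition-order simulation (most-measured class by default)
    entity = config.order_entity or (world.metadata["cell_type_class"]
                                     .value_counts().index[0])
    results = run_order_simulation(world.metadata, world.snps, world.peaks,
                                   entity, level="class",
                                   mapping=world.class_map,
                                   n_reps=config.n_order_reps,
                                   seed=config.seed)
    summary = simulation_summary(results)
    summary.insert(1, "entity", entity)
    hashes["order_simulation.tsv"] = _write(
        summary, outdir / "order_simulation.tsv", run_id)
    traj = pd.concat([r.series.to_frame().assign(provenance=r.provenance)
                      for r in results], ignore_index=True)
    hashes["order_trajectories.tsv"] = _write(
        traj, outdir / "order_trajectories.tsv", run_id)
    manifest["stages"]["order_simulation"] = {
        "entity": entity, "n_orders": len(results),
        "real_auc": float(summary.loc[summary["provenance"] == "real",
                                      "auc"].iloc[0])}

    # stage 7: prioritization
    if world.deg is None or world.markers is None:
        log.warning("DEG or marker table absent: prioritization skipped")
        manifest["stages"]["prioritization"] = "skipped"
    else:
        marker_set = set(world.markers["tf"])
        gems, audit = hidden_gems(inventories["class"], world.deg, marker_set,
                                  deg_threshold=config.deg_threshold)
        hashes["gems.tsv"] = _write(gems, outdir / "gems.tsv", run_id)
        hashes["gems_audit.tsv"] = _write(audit, outdir / "gems_audit.tsv",
                                          run_id)
        comp_rows = []
        for grouping in ("marker_vs_nonmarker", "measured_vs_unmeasured"):
            try:
                c = compare_deg_groups(world.deg, grouping,
                                       inventory=inventories["class"],
                                       marker_tfs=marker_set)
            except ValueError as err:
                log.warning("DEG comparison %s skipped: %s", grouping, err)
                continue
            comp_rows.append((grouping, *c.group_names, *c.sizes, *c.medians,
                              c.test.statistic, c.test.p_value, c.test.method))
        comp = pd.DataFrame(comp_rows, columns=[
            "grouping", "group_a", "group_b", "n_a", "n_b", "median_a",
            "median_b", "u_statistic", "p_value", "method"])
        hashes["deg_comparison.tsv"] = _write(
            comp, outdir / "deg_comparison.tsv", run_id)
        manifest["stages"]["prioritization"] = {"n_gems": len(gems),
                                                "n_audit": len(audit)}

    io_formats.dump_config(manifest, outdir / "manifest.yaml")
    return manifest
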