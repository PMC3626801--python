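"""End-to-end orchestration: preprocess -> network -> module stats ->
enrichment -> (optional) cross-disease comparison.

Every output is a CSV/TSV/JSON file under the configured output directory and
is deterministic given the config (a single seed drives all stochastic
steps).  Input files are never mutated.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cross_disease as xd
from . import enrichment as enr
from . import io as cio
from . import module_stats as ms
from . import network as net
from . import preprocess as pre
from .config import PipelineConfig, config_to_dict
from .genesets import read_gmt
from .study import ExpressionStudy, hiv_positive_mask

STAGES = ("preprocess", "network", "stats", "enrich", "crossdisease")

logger = logging.getLogger("coexnet")


def run_pipeline(config: PipelineConfig, stages=STAGES) -> Path:
    """Run the requested stages in order; returns the output directory.

    Later stages depend on earlier ones, so requesting e.g. only "stats"
    still computes (but does not have to re-request) its prerequisites.
    """
    _validate_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("coexnet %s starting; stages=%s", __version__, list(stages))
    for key, value in sorted(config_to_dict(config).items()):
        logger.info("config %s = %r", key, value)

    study = _load_study(config)
    ctx: dict = {"study": study}

    _stage_preprocess(config, ctx, out)
    if _wants(stages, "network"):
        _stage_network(config, ctx, out)
    if _wants(stages, "stats"):
        _stage_stats(config, ctx, out)
    if _wants(stages, "enrich"):
        _stage_enrich(config, ctx, out)
    if _wants(stages, "crossdisease") and config.ad_expression:
        _stage_crossdisease(config, ctx, out)

    manifest = {
        "version": __version__,
        "stages": list(stages),
        "config": config_to_dict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("done")
    return out


def _wants(stages, stage: str) -> bool:
    order = {s: i for i, s in enumerate(STAGES)}
    wanted = max(order[s] for s in stages)
    return order[stage] <= wanted


def _validate_inputs(config: PipelineConfig) -> None:
    if not config.expression:
        raise ValueError("config is missing the expression input path")
    if not config.phenotypes:
        raise ValueError("config is missing the phenotypes input path")
    for name in ("expression", "phenotypes", "presence", "probe_map",
                 "gene_sets", "marker_sets", "ad_expression", "ad_phenotypes",
                 "second_region_expression", "second_region_phenotypes"):
        value = getattr(config, name)
        if value and not Path(value).exists():
            raise FileNotFoundError(f"{name} input not found: {value}")


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)


def _load_study(config: PipelineConfig) -> ExpressionStudy:
    expression = cio.read_expression_tsv(config.expression)
    phenotypes = cio.read_phenotypes_csv(config.phenotypes)
    presence = cio.read_presence_tsv(config.presence) if config.presence else None
    probe_map = cio.read_probe_map_tsv(config.probe_map) if config.probe_map else None
    return ExpressionStudy(
        expression=expression, phenotypes=phenotypes,
        presence=presence, probe_to_gene=probe_map,
    )


def _stage_preprocess(config: PipelineConfig, ctx: dict, out: Path) -> None:
    study: ExpressionStudy = ctx["study"]
    report = pre.detect_outlier_arrays(study.expression, config.sd_multiplier)
    report.to_frame().to_csv(out / "outlier_report.csv", index_label="sample_id")
    logger.info("outlier detection: flagged %s", report.flagged_samples or "none")
    kept = [s for s in study.samples if s not in report.flagged_samples]
    study = study.subset_samples(kept)

    normalized = pre.quantile_normalize(study.expression)

    if study.presence is not None:
        de_expr = pre.filter_absent(normalized, study.presence,
                                    config.max_absent_fraction)
        net_expr = pre.filter_min_present(normalized, study.presence,
                                          config.min_present_samples)
        logger.info(
            "absent filter kept %d/%d rows; min-present filter kept %d",
            len(de_expr), len(normalized), len(net_expr),
        )
    else:
        de_expr = net_expr = normalized

    if study.probe_to_gene is not None:
        de_expr, _ = pre.collapse_probes(de_expr, study.probe_to_gene)
        net_expr, collapse = pre.collapse_probes(net_expr, study.probe_to_gene)
        logger.info("collapsed to %d genes (network matrix)", len(net_expr))

    cio.write_expression_tsv(de_expr, out / "processed_expression.tsv")
    ctx.update(
        phenotypes=study.phenotypes, de_expr=de_expr, net_expr=net_expr,
        presence=study.presence,
    )


def _stage_network(config: PipelineConfig, ctx: dict, out: Path) -> None:
    net_expr: pd.DataFrame = ctx["net_expr"]
    variable = net_expr.index[net_expr.std(axis=1) > 0]
    if len(variable) < len(net_expr):
        logger.warning("dropping %d zero-variance gene(s) before adjacency",
                       len(net_expr) - len(variable))
        net_expr = net_expr.loc[variable]
    adjacency = net.signed_adjacency(net_expr, beta=config.beta)
    tom = net.topological_overlap(adjacency)
    assignment = net.cluster_and_cut(
        tom, min_module_size=config.min_module_size,
        cut_height=config.cut_height, deep_split=config.deep_split,
    )
    net.write_assignment_tsv(assignment, out / "modules.tsv")
    pd.DataFrame(assignment.linkage,
                 columns=["left", "right", "height", "count"]).to_csv(
        out / "dendrogram_heights.csv", index=False)
    logger.info("modules: %s", assignment.module_sizes().to_dict())
    ctx.update(net_expr=net_expr, adjacency=adjacency, tom=tom,
               assignment=assignment)


def _stage_stats(config: PipelineConfig, ctx: dict, out: Path) -> None:
    assignment: net.ModuleAssignment = ctx["assignment"]
    net_expr: pd.DataFrame = ctx["net_expr"]
    phenotypes: pd.DataFrame = ctx["phenotypes"]
    if not assignment.module_sizes().size:
        logger.warning("no modules found; skipping module statistics")
        return
    mes = ms.module_eigengenes(net_expr, assignment)
    mes.eigengenes.to_csv(out / "eigengenes.csv", index_label="sample_id")

    results = []
    hiv_mask = hiv_positive_mask(phenotypes)
    for trait, mask in (("GCR", hiv_mask), ("CPE", hiv_mask), ("MMSE", None)):
        if trait not in phenotypes.columns:
            continue
        usable = pd.to_numeric(phenotypes[trait], errors="coerce")
        if mask is not None:
            usable = usable.where(mask)
        if usable.dropna().nunique() < 2 or usable.notna().sum() < 4:
            logger.warning("trait %s unusable; skipped", trait)
            continue
        results.append(
            ms.module_trait_correlation(mes, phenotypes, trait, sample_filter=mask)
        )
    if results:
        pd.concat(results, ignore_index=True).to_csv(
            out / "module_trait.csv", index=False)

    if "group" in phenotypes.columns:
        counts = phenotypes["group"].value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            ms.module_group_test(mes, phenotypes).to_csv(
                out / "module_groups.csv", index=False)

    conn = ms.scaled_intramodular_connectivity(
        ctx["adjacency"], assignment, expression=net_expr)
    conn.to_csv(out / "connectivity.csv", index_label="gene")
    ctx.update(eigengenes=mes, connectivity=conn)


def _stage_enrich(config: PipelineConfig, ctx: dict, out: Path) -> None:
    de_expr: pd.DataFrame = ctx["de_expr"]
    phenotypes: pd.DataFrame = ctx["phenotypes"]
    sets = read_gmt(config.gene_sets) if config.gene_sets else None
    universe = list(de_expr.index)
    hiv_mask = hiv_positive_mask(phenotypes)
    for trait, mask in (("GCR", hiv_mask), ("CPE", hiv_mask), ("MMSE", None)):
        if trait not in phenotypes.columns:
            continue
        usable = pd.to_numeric(phenotypes[trait], errors="coerce")
        if mask is not None:
            usable = usable.where(mask)
        if usable.dropna().nunique() < 2 or usable.notna().sum() < 4:
            continue
        table = enr.gene_trait_correlations(
            de_expr, phenotypes, trait, sample_filter=mask, region=config.region)
        table.to_csv(out / f"gene_trait_{trait}.csv")
        enr.top_gene_table(table, config.r_top).to_csv(
            out / f"top_genes_{trait}.csv")
        if sets is not None:
            up, down = enr.significant_gene_lists(table, config.de_alpha)
            for direction, genes in (("up", up), ("down", down)):
                if genes:
                    enr.ease_enrichment(genes, universe, sets).to_csv(
                        out / f"enrichment_{trait}_{direction}.csv", index=False)
    if config.marker_sets and "assignment" in ctx:
        markers = read_gmt(config.marker_sets, source="celltype")
        enr.user_list_enrichment(ctx["assignment"], markers, universe).to_csv(
            out / "marker_enrichment.csv", index=False)


def _stage_crossdisease(config: PipelineConfig, ctx: dict, out: Path) -> None:
    xout = out / "crossdisease"
    xout.mkdir(exist_ok=True)
    ad_study = ExpressionStudy(
        expression=cio.read_expression_tsv(config.ad_expression),
        phenotypes=cio.read_phenotypes_csv(config.ad_phenotypes),
    )
    fc_study = ExpressionStudy(
        expression=ctx["de_expr"], phenotypes=ctx["phenotypes"])
    if config.second_region_expression:
        bg_study = ExpressionStudy(
            expression=cio.read_expression_tsv(config.second_region_expression),
            phenotypes=cio.read_phenotypes_csv(config.second_region_phenotypes),
        )
    else:
        bg_study = None
        logger.warning("no second HIV region provided; classification uses "
                       "the single HIV region twice")

    common, fc_sub, ad_sub = xd.align_common_genes(fc_study, ad_study)
    logger.info("common genes: %d", len(common))
    r_fc = xd.impairment_correlations(fc_sub, "GCR")
    r_ad = xd.impairment_correlations(ad_sub, "MMSE")
    if bg_study is not None:
        common2, bg_sub, _ = xd.align_common_genes(bg_study, ad_sub)
        r_bg = xd.impairment_correlations(bg_sub, "GCR").reindex(common)
    else:
        r_bg = r_fc
    paired = xd.paired_correlation_table(
        r_ad, r_fc, r_bg, threshold=config.impair_threshold)
    paired.to_csv(xout / "paired_correlations.csv", index_label="gene")
    up, down = xd.classify_impairment_genes(paired, config.impair_threshold)
    pd.DataFrame(
        {"gene": sorted(up) + sorted(down),
         "direction": ["up"] * len(up) + ["down"] * len(down)}
    ).to_csv(xout / "impairment_genes.csv", index=False)
    logger.info("impairment genes: %d up, %d down", len(up), len(down))

    if config.gene_sets:
        sets = read_gmt(config.gene_sets)
        tables = xd.common_impairment_enrichment(up, down, common, sets)
        for direction, table in tables.items():
            if len(table):
                table.to_csv(xout / f"enrichment_{direction}.csv", index=False)

    if "assignment" in ctx:
        ad_up = set(paired.index[paired["R_ad"] > config.impair_threshold])
        ad_down = set(paired.index[paired["R_ad"] < -config.impair_threshold])
        xd.module_ad_enrichment(
            ctx["assignment"], ad_up, ad_down, common,
            alpha=config.module_ad_alpha,
        ).to_csv(xout / "module_ad_flags.csv", index=False)

    if "connectivity" in ctx:
        conn_fc = ctx["connectivity"]
        conn_ad = _connectivity_for(ad_sub.expression, config)
        conn_bg = (_connectivity_for(bg_sub.expression, config)
                   if bg_study is not None else conn_fc)
        directions = {g: "up" for g in up}
        directions.update({g: "down" for g in down})
        xd.common_hub_table(
            conn_ad, conn_fc, conn_bg, directions,
            threshold=config.hub_threshold,
        ).to_csv(xout / "common_hubs.csv", index=False)


def _connectivity_for(expression: pd.DataFrame, config: PipelineConfig):
    variable = expression.index[expression.std(axis=1) > 0]
    expression = expression.loc[variable]
    adjacency = net.signed_adjacency(expression, beta=config.beta)
    tom = net.topological_overlap(adjacency)
    assignment = net.cluster_and_cut(
        tom, min_module_size=config.min_module_size,
        cut_height=config.cut_height, deep_split=config.deep_split)
    return ms.scaled_intramodular_connectivity(adjacency, assignment)
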