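"""Cross-disease comparison of impairment-correlated transcription.

Disease 1 (HIV) impairment is the GCR score (higher = more impaired) on
seropositive cases; disease 2 (AD) impairment is the sign-flipped MMSE
correlation (lower MMSE = more impaired), so a positive impairment
correlation always means "up with impairment" in both diseases.

An impairment gene is one whose impairment correlation exceeds the threshold
(default 0.25) in the AD study and in both HIV regions simultaneously
(strictly greater / strictly less than minus the threshold).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ease_enrichment, gene_trait_correlations
from .genesets import GeneSetCollection, canonical_symbol
from .network import ModuleAssignment
from .study import ExpressionStudy, hiv_positive_mask

IMPAIR_THRESHOLD = 0.25
HUB_THRESHOLD = 0.70
MODULE_AD_ALPHA = 2e-5


def align_common_genes(
    study1: ExpressionStudy, study2: ExpressionStudy
) -> tuple[list[str], ExpressionStudy, ExpressionStudy]:
    """Restrict both gene-collapsed studies to their common gene symbols.

    Symbols are canonicalized (upper-case, stripped); the common list is
    sorted so row alignment is deterministic.
    """
    map1 = {canonical_symbol(g): g for g in study1.expression.index}
    map2 = {canonical_symbol(g): g for g in study2.expression.index}
    common = sorted(set(map1) & set(map2))
    if not common:
        raise ValueError("no genes in common between the two studies")
    sub1 = study1.subset_genes([map1[g] for g in common])
    sub2 = study2.subset_genes([map2[g] for g in common])
    sub1.expression.index = common
    sub2.expression.index = common
    if sub1.presence is not None:
        sub1.presence.index = common
    if sub2.presence is not None:
        sub2.presence.index = common
    return common, sub1, sub2


def impairment_correlations(study: ExpressionStudy, trait: str) -> pd.Series:
    """Per-gene impairment correlation vector.

    ``trait="GCR"``: Pearson R with GCR on HIV+ samples (higher GCR = more
    impaired).  ``trait="MMSE"``: sign-flipped Pearson R with MMSE over all
    samples with a score (lower MMSE = more impaired).  Positive output
    always means expression rises with impairment.
    """
    if trait == "GCR":
        table = gene_trait_correlations(
            study.expression, study.phenotypes, "GCR",
            sample_filter=hiv_positive_mask(study.phenotypes),
        )
        return table["R"].rename("impairment_R")
    if trait == "MMSE":
        table = gene_trait_correlations(study.expression, study.phenotypes, "MMSE")
        return (-table["R"]).rename("impairment_R")
    raise ValueError("trait must be 'GCR' or 'MMSE'")


def paired_correlation_table(
    r_ad: pd.Series,
    r_fc: pd.Series,
    r_bg: pd.Series | None = None,
    threshold: float = IMPAIR_THRESHOLD,
) -> pd.DataFrame:
    """Join per-gene impairment correlations and classify each gene.

    class "up" requires every provided correlation strictly above the
    threshold; "down" requires every one strictly below its negative;
    everything else (including boundary values) is "none".
    """
    data = {"R_ad": r_ad, "R_fc": r_fc}
    if r_bg is not None:
        data["R_bg"] = r_bg
    table = pd.DataFrame(data).dropna()
    cols = table.columns
    up = (table[cols] > threshold).all(axis=1)
    down = (table[cols] < -threshold).all(axis=1)
    table["class"] = np.where(up, "up", np.where(down, "down", "none"))
    return table


def classify_impairment_genes(
    paired: pd.DataFrame, threshold: float = IMPAIR_THRESHOLD
) -> tuple[set, set]:
    """(up set, down set) from a paired correlation table (reclassified at
    ``threshold``)."""
    cols = [c for c in paired.columns if c.startswith("R_")]
    up = (paired[cols] > threshold).all(axis=1)
    down = (paired[cols] < -threshold).all(axis=1)
    return set(paired.index[up]), set(paired.index[down])


def common_impairment_enrichment(
    up: Iterable[str],
    down: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
) -> dict[str, pd.DataFrame]:
    """EASE enrichment run separately on the up and down impairment sets."""
    out = {}
    for direction, genes in (("up", set(up)), ("down", set(down))):
        if not genes:
            warnings.warn(f"{direction} impairment set is empty; no enrichment")
            out[direction] = pd.DataFrame()
            continue
        out[direction] = ease_enrichment(genes, universe, sets)
    return out


def module_ad_enrichment(
    assignment: ModuleAssignment,
    ad_impair_up: Iterable[str],
    ad_impair_down: Iterable[str],
    universe: Iterable[str],
    alpha: float = MODULE_AD_ALPHA,
) -> pd.DataFrame:
    """Flag modules enriched for AD impairment genes (hypergeometric).

    Per module, a one-tailed hypergeometric p-value against the up- and
    down-direction sets; a module is flagged when p < alpha (default 2e-5).
    """
    universe_set = {canonical_symbol(g) for g in universe}
    up = {canonical_symbol(g) for g in ad_impair_up} & universe_set
    down = {canonical_symbol(g) for g in ad_impair_down} & universe_set
    rows = []
    for label, members in assignment.modules().items():
        module_genes = {canonical_symbol(g) for g in members} & universe_set
        row = {"module": label, "module_size": len(module_genes)}
        for direction, target in (("up", up), ("down", down)):
            if not target or not module_genes:
                row[f"p_{direction}"] = np.nan
                continue
            overlap = len(module_genes & target)
            row[f"overlap_{direction}"] = overlap
            row[f"p_{direction}"] = float(
                stats.hypergeom.sf(
                    overlap - 1, len(universe_set), len(target), len(module_genes)
                )
            )
        p_up = row.get("p_up", np.nan)
        p_down = row.get("p_down", np.nan)
        if not np.isnan(p_up) and p_up < alpha:
            row["flag"] = "up"
        elif not np.isnan(p_down) and p_down < alpha:
            row["flag"] = "down"
        else:
            row["flag"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def common_hub_table(
    connectivity_ad: pd.DataFrame,
    connectivity_fc: pd.DataFrame,
    connectivity_bg: pd.DataFrame,
    directions: Mapping[str, str],
    threshold: float = HUB_THRESHOLD,
    require_all_regions: bool = False,
    functions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Common-hub table: genes with scaled intramodular connectivity strictly
    above the threshold in AD and in at least one HIV region (or all regions
    when ``require_all_regions``), grouped by impairment direction.

    ``directions`` maps gene -> "up"/"down"; genes not in it are skipped.
    Connectivity values missing in a region render as "--".  ``functions``
    is optional free-text annotation passed through to the output.
    """
    def scaled(conn: pd.DataFrame) -> pd.Series:
        return conn["scaled_kIN"]

    s_ad, s_fc, s_bg = (scaled(c) for c in (connectivity_ad, connectivity_fc,
                                            connectivity_bg))
    rows = []
    for gene, direction in directions.items():
        if direction not in ("up", "down"):
            raise ValueError(f"direction for {gene!r} must be 'up' or 'down'")
        v_ad = s_ad.get(gene, np.nan)
        v_fc = s_fc.get(gene, np.nan)
        v_bg = s_bg.get(gene, np.nan)
        hub_ad = (not pd.isna(v_ad)) and v_ad > threshold
        hiv_hits = [(not pd.isna(v)) and v > threshold for v in (v_fc, v_bg)]
        hub_hiv = all(hiv_hits) if require_all_regions else any(hiv_hits)
        if hub_ad and hub_hiv:
            rows.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "function": (functions or {}).get(gene, ""),
                    "kin_ad": _fmt(v_ad),
                    "kin_fc": _fmt(v_fc if hiv_hits[0] else np.nan),
                    "kin_bg": _fmt(v_bg if hiv_hits[1] else np.nan),
                }
            )
    out = pd.DataFrame(
        rows, columns=["gene", "direction", "function", "kin_ad", "kin_fc", "kin_bg"]
    )
    if len(out):
        out = out.sort_values(
            ["direction", "kin_ad"], ascending=[False, False]
        ).reset_index(drop=True)
    return out


def _fmt(value: float) -> str:
    return "--" if pd.isna(value) else f"{value:.2f}"
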