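"""Gene-level trait correlations and EASE-style gene-set enrichment.

The EASE score is a conservative ("jackknifed") one-tailed Fisher exact
probability: one gene is removed from the category's list hits before the
tail probability is evaluated, i.e.

    EASE(LH, LT, PH, PT) = P[X >= LH - 1],
    X ~ Hypergeometric(population PT, successes PH, draws LT - 1)

so a category hit by a single list gene scores 1.  This construction
reproduces published EASE outputs to 3 significant figures.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection, canonical_symbol
from .network import ModuleAssignment

#: column order for enrichment tables
ENRICHMENT_COLUMNS = (
    "category", "list_hits", "list_total", "pop_hits", "pop_total",
    "ease_score", "bonferroni",
)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson correlation of each row of ``x`` with vector ``y``
    plus two-sided p-values from the t-distribution."""
    n = len(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / den
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return r, p


def gene_trait_correlations(
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
    sample_filter: pd.Series | None = None,
    region: str | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation with a numeric trait.

    Missing trait values are dropped pairwise, p-values are two-sided from
    the t-distribution and no multiple-testing adjustment is applied.  Genes
    with fewer than 4 paired observations (or zero variance) get NaN with a
    warning.
    """
    if trait not in phenotypes.columns:
        raise ValueError(f"trait {trait!r} not in phenotypes")
    values = pd.to_numeric(phenotypes[trait], errors="coerce")
    if sample_filter is not None:
        values = values.where(sample_filter.reindex(values.index, fill_value=False))
    values = values.dropna()
    if values.nunique() <= 1:
        raise ValueError(f"trait {trait!r} is constant on the selected samples")
    if len(values) < 4:
        raise ValueError(f"trait {trait!r}: fewer than 4 usable samples")
    sub = expression[values.index]
    x = sub.to_numpy(dtype=float)
    r, p = pearson_with_p(x, values.to_numpy(dtype=float))
    bad = np.isnan(r)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} gene(s) with undefined correlation (NaN)")
    out = pd.DataFrame(
        {"gene": sub.index, "R": r, "p": p, "n": len(values), "trait": trait}
    ).set_index("gene")
    if region is not None:
        out["region"] = region
    return out


def top_gene_table(table: pd.DataFrame, r_threshold: float = 0.75) -> pd.DataFrame:
    """Rows with |R| >= threshold, sorted by descending |R|."""
    out = table[table["R"].abs() >= r_threshold].copy()
    return out.sort_values("R", key=lambda s: s.abs(), ascending=False)


def significant_gene_lists(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[set, set]:
    """Split genes at p < alpha into (up, down) lists by correlation sign."""
    sig = table[table["p"] < alpha]
    up = {canonical_symbol(g) for g in sig.index[sig["R"] > 0]}
    down = {canonical_symbol(g) for g in sig.index[sig["R"] < 0]}
    return up, down


def ease_score(list_hits: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """Jackknifed one-tailed Fisher exact probability (see module docstring)."""
    if not (0 <= list_hits <= list_total <= pop_total):
        raise ValueError("invalid contingency counts")
    if not (list_hits <= pop_hits <= pop_total):
        raise ValueError("invalid contingency counts")
    if list_hits <= 1:
        return 1.0
    return float(
        stats.hypergeom.sf(list_hits - 2, pop_total, pop_hits, list_total - 1)
    )


def fisher_score(list_hits: int, list_total: int, pop_hits: int, pop_total: int) -> float:
    """Plain one-tailed Fisher exact probability on the same margins (no
    jackknife); used for comparison and property checks."""
    return float(
        stats.hypergeom.sf(list_hits - 1, pop_total, pop_hits, list_total)
    )


def ease_enrichment(
    list_genes: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    population: str = "source",
) -> pd.DataFrame:
    """EASE enrichment of a gene list against every category.

    Population totals are source-specific by default (``population="source"``:
    the universe is intersected with the union of all genes annotated by the
    category's source, so different annotation sources have different PT).
    ``population="universe"`` uses the full universe for every category.
    Categories with zero list hits are omitted; the Bonferroni factor is the
    number of tested (LH >= 1) categories within the same source.
    """
    list_set = {canonical_symbol(g) for g in list_genes}
    universe_set = {canonical_symbol(g) for g in universe}
    if not list_set:
        raise ValueError("empty gene list")
    if not universe_set:
        raise ValueError("empty universe")
    if not list_set <= universe_set:
        raise ValueError("gene list must be a subset of the universe")

    rows = []
    for source, names in sets.by_source().items():
        if population == "source":
            pop = universe_set & set(sets.source_universe(source))
        else:
            pop = universe_set
        lt = len(list_set & pop)
        tested = []
        for name in names:
            genes = sets.categories[name] & pop
            lh = len(genes & list_set)
            if lh == 0:
                continue
            tested.append(
                {
                    "category": name,
                    "source": source,
                    "list_hits": lh,
                    "list_total": lt,
                    "pop_hits": len(genes),
                    "pop_total": len(pop),
                    "ease_score": ease_score(lh, lt, len(genes), len(pop)),
                }
            )
        for row in tested:
            row["bonferroni"] = min(1.0, row["ease_score"] * len(tested))
        rows.extend(tested)
    out = pd.DataFrame(
        rows,
        columns=["category", "source", "list_hits", "list_total", "pop_hits",
                 "pop_total", "ease_score", "bonferroni"],
    )
    return out.sort_values("ease_score").reset_index(drop=True)


def user_list_enrichment(
    assignment: ModuleAssignment,
    marker_sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-tailed hypergeometric enrichment of every module against every
    marker set, Bonferroni-corrected over all (module, set) pairs."""
    universe_set = {canonical_symbol(g) for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    rows = []
    for label, members in assignment.modules().items():
        module_genes = {canonical_symbol(g) for g in members} & universe_set
        if not module_genes:
            warnings.warn(f"module {label!r} empty after universe intersection")
            continue
        for name, genes in marker_sets.categories.items():
            cat = genes & universe_set
            if not cat:
                continue
            overlap = len(module_genes & cat)
            p = float(
                stats.hypergeom.sf(
                    overlap - 1, len(universe_set), len(cat), len(module_genes)
                )
            )
            rows.append(
                {"module": label, "category": name, "overlap": overlap,
                 "module_size": len(module_genes), "category_size": len(cat),
                 "pop_total": len(universe_set), "p": p}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["bonferroni"] = np.minimum(1.0, out["p"] * len(out))
        out = out.sort_values("p").reset_index(drop=True)
    return out
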