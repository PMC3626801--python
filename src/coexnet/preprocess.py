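"""Array quality control and probe-to-gene reduction.

Stage order used by the pipeline: outlier detection on the un-normalized
matrix -> quantile normalization -> absent-call filter -> probe collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform


@dataclass
class OutlierReport:
    """Per-sample mean inter-array correlations and the samples flagged low.

    ``cluster_order`` is the leaf order of a single-linkage dendrogram on
    1 - IAC, emitted for manual inspection; flagging itself is purely the
    mean-IAC threshold rule.
    """

    mean_iac: pd.Series
    flagged_samples: list[str]
    threshold_used: float
    cluster_order: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_iac": self.mean_iac,
                "flagged": self.mean_iac.index.isin(self.flagged_samples),
            }
        )


@dataclass
class ProbeCollapseMap:
    """Chosen representative probe per gene plus the discarded probes."""

    gene_to_probe: pd.Series
    discarded_probes: list[str]


def detect_outlier_arrays(
    expression: pd.DataFrame, sd_multiplier: float = 2.0
) -> OutlierReport:
    """Flag arrays whose mean inter-array Pearson correlation is low.

    A sample is flagged when its mean correlation with all other arrays falls
    below (grand mean - sd_multiplier * SD) of the per-sample means.  Computed
    on the un-normalized matrix; the input is not mutated.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples for inter-array correlation")
    stds = expression.std(axis=0)
    dead = stds.index[stds == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance sample(s): {dead}")
    iac = np.corrcoef(expression.to_numpy().T)
    np.fill_diagonal(iac, np.nan)
    mean_iac = pd.Series(
        np.nanmean(iac, axis=1), index=expression.columns, name="mean_iac"
    )
    threshold = float(mean_iac.mean() - sd_multiplier * mean_iac.std())
    flagged = mean_iac.index[mean_iac < threshold].tolist()

    np.fill_diagonal(iac, 1.0)
    dist = squareform(1.0 - iac, checks=False)
    order = leaves_list(linkage(dist, method="single"))
    return OutlierReport(
        mean_iac=mean_iac,
        flagged_samples=flagged,
        threshold_used=threshold,
        cluster_order=[expression.columns[i] for i in order],
    )


def quantile_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the per-rank cross-column mean distribution."""
    if expression.isna().any().any():
        raise ValueError("quantile_normalize does not accept missing values")
    values = expression.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    cols = np.arange(values.shape[1])
    ranks[order, cols] = np.arange(values.shape[0])[:, None]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def filter_absent(
    expression: pd.DataFrame,
    presence: pd.DataFrame,
    max_absent_fraction: float = 0.90,
) -> pd.DataFrame:
    """Drop rows called absent in strictly more than ``max_absent_fraction``
    of samples (default: absent in >90%)."""
    if not presence.index.equals(expression.index) or not presence.columns.equals(
        expression.columns
    ):
        raise ValueError("presence matrix must align with expression")
    absent_fraction = 1.0 - presence.mean(axis=1)
    keep = absent_fraction <= max_absent_fraction
    return expression.loc[keep].copy()


def filter_min_present(
    expression: pd.DataFrame,
    presence: pd.DataFrame,
    min_present_samples: int = 6,
) -> pd.DataFrame:
    """Keep rows present in at least ``min_present_samples`` samples.

    Alternative detection filter used ahead of network construction; distinct
    from the >90%-absent exclusion rule and applied independently.
    """
    if not presence.index.equals(expression.index) or not presence.columns.equals(
        expression.columns
    ):
        raise ValueError("presence matrix must align with expression")
    keep = presence.sum(axis=1) >= min_present_samples
    return expression.loc[keep].copy()


def collapse_probes(
    expression: pd.DataFrame, probe_to_gene: pd.Series
) -> tuple[pd.DataFrame, ProbeCollapseMap]:
    """One row per gene symbol: the probe with maximal mean expression.

    Probes without a gene symbol are dropped.  Exact ties in mean expression
    are broken by the lexicographically smallest probe id (stable, documented).
    """
    if probe_to_gene is None or len(probe_to_gene) == 0:
        raise ValueError("probe_to_gene map is empty")
    mapped = probe_to_gene.dropna()
    mapped = mapped[mapped.index.isin(expression.index)]
    if len(mapped) == 0:
        raise ValueError("probe_to_gene map covers no rows of the matrix")

    means = expression.mean(axis=1)
    choice = (
        pd.DataFrame({"gene": mapped, "mean": means.loc[mapped.index]})
        .reset_index(names="probe")
        .sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    gene_to_probe = choice.set_index("gene")["probe"].sort_index()
    collapsed = expression.loc[gene_to_probe.to_numpy()].copy()
    collapsed.index = gene_to_probe.index
    discarded = sorted(set(mapped.index) - set(gene_to_probe))
    return collapsed, ProbeCollapseMap(
        gene_to_probe=gene_to_probe, discarded_probes=discarded
    )
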