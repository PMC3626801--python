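"""Core expression-study container shared by every pipeline stage.

An :class:`ExpressionStudy` bundles a (probes-or-genes x samples) log-intensity
matrix with per-sample phenotypes and two optional companions: a boolean
presence matrix aligned to the expression matrix, and a probe -> gene symbol
map.  All downstream stages consume and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Phenotype columns understood by the pipeline.  Missing columns are allowed;
#: missing values are NaN.
PHENOTYPE_COLUMNS = ("group", "GCR", "CPE", "MMSE")

GCR_RANGE = (1.0, 9.0)
MMSE_RANGE = (0.0, 30.0)


@dataclass
class ExpressionStudy:
    """Expression matrix plus sample phenotypes.

    Parameters
    ----------
    expression
        Rows are probe or gene identifiers, columns are sample identifiers,
        values are log-scale intensities.
    phenotypes
        One row per sample (index = sample id).  Recognised columns:
        ``group`` (categorical label, e.g. A-D or control/AD), ``GCR``
        (impairment score, 1-9, higher = more impaired), ``CPE``
        (regimen penetration score, >= 0) and ``MMSE`` (cognitive screen,
        0-30, lower = more impaired).  All optional.
    presence
        Optional boolean matrix with the same index/columns as ``expression``;
        True means the probe was detected ("present") in that sample.
    probe_to_gene
        Optional mapping from row identifier to gene symbol.  When absent the
        rows are taken to be gene-level already.
    """

    expression: pd.DataFrame
    phenotypes: pd.DataFrame
    presence: pd.DataFrame | None = None
    probe_to_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.expression, pd.DataFrame):
            raise TypeError("expression must be a pandas DataFrame")
        if not isinstance(self.phenotypes, pd.DataFrame):
            raise TypeError("phenotypes must be a pandas DataFrame")
        if list(self.expression.columns) != list(self.phenotypes.index):
            raise ValueError(
                "expression columns and phenotype rows must list the same "
                "samples in the same order"
            )
        if self.presence is not None:
            if not self.presence.index.equals(self.expression.index) or not (
                self.presence.columns.equals(self.expression.columns)
            ):
                raise ValueError("presence matrix must align with expression")
        if self.probe_to_gene is not None and not isinstance(
            self.probe_to_gene, pd.Series
        ):
            self.probe_to_gene = pd.Series(dict(self.probe_to_gene))
        _check_score_range(self.phenotypes, "GCR", *GCR_RANGE)
        _check_score_range(self.phenotypes, "MMSE", *MMSE_RANGE)

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    def subset_genes(self, genes) -> "ExpressionStudy":
        """Return a copy restricted (and reordered) to ``genes``."""
        genes = list(genes)
        return ExpressionStudy(
            expression=self.expression.loc[genes].copy(),
            phenotypes=self.phenotypes.copy(),
            presence=None if self.presence is None else self.presence.loc[genes].copy(),
            probe_to_gene=None
            if self.probe_to_gene is None
            else self.probe_to_gene.loc[self.probe_to_gene.index.intersection(genes)].copy(),
        )

    def subset_samples(self, samples) -> "ExpressionStudy":
        samples = list(samples)
        return ExpressionStudy(
            expression=self.expression[samples].copy(),
            phenotypes=self.phenotypes.loc[samples].copy(),
            presence=None if self.presence is None else self.presence[samples].copy(),
            probe_to_gene=None if self.probe_to_gene is None else self.probe_to_gene.copy(),
        )

    def equals(self, other: "ExpressionStudy") -> bool:
        """Strict equality on all components (used by round-trip tests)."""
        if not self.expression.equals(other.expression):
            return False
        if not self.phenotypes.equals(other.phenotypes):
            return False
        if (self.presence is None) != (other.presence is None):
            return False
        if self.presence is not None and not self.presence.equals(other.presence):
            return False
        if (self.probe_to_gene is None) != (other.probe_to_gene is None):
            return False
        if self.probe_to_gene is not None and not self.probe_to_gene.equals(
            other.probe_to_gene
        ):
            return False
        return True


def _check_score_range(phenotypes: pd.DataFrame, column: str, lo: float, hi: float) -> None:
    if column not in phenotypes.columns:
        return
    values = pd.to_numeric(phenotypes[column], errors="coerce").dropna()
    if len(values) and ((values < lo).any() or (values > hi).any()):
        raise ValueError(f"{column} values must lie within [{lo}, {hi}]")


def hiv_positive_mask(phenotypes: pd.DataFrame) -> pd.Series:
    """Boolean per-sample mask selecting HIV+ samples (group != 'A').

    Impairment-score analyses are restricted to seropositive cases; group A is
    the seronegative control group, so it is excluded whenever present.
    """
    if "group" not in phenotypes.columns:
        return pd.Series(True, index=phenotypes.index)
    return phenotypes["group"].astype(str) != "A"
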