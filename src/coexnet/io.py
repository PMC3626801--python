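"""Plain-text readers and writers for expression studies.

Formats:

* expression / presence: TSV, first column = probe/gene id, header = sample ids
* phenotypes: CSV with columns sample_id, group, GCR, CPE, MMSE (empty = missing)
* probe map: two-column TSV (probe, gene)

Floats are written with full ``repr`` precision so a write/read cycle is
lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .study import ExpressionStudy

EXPRESSION_FILE = "expression.tsv"
PHENOTYPES_FILE = "phenotypes.csv"
PRESENCE_FILE = "presence.tsv"
PROBE_MAP_FILE = "probe_map.tsv"


def write_expression_tsv(expression: pd.DataFrame, path) -> Path:
    path = Path(path)
    expression.to_csv(path, sep="\t", index_label="id", float_format="%.17g")
    return path


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def write_presence_tsv(presence: pd.DataFrame, path) -> Path:
    path = Path(path)
    presence.astype(int).to_csv(path, sep="\t", index_label="id")
    return path


def read_presence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df.astype(bool)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = phenotypes.copy()
    out.to_csv(path, index_label="sample_id", float_format="%.17g")
    return path


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    for col in df.columns:
        if col != "group":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "group" in df.columns:
        df["group"] = df["group"].astype(str).where(df["group"].notna())
    return df


def write_probe_map_tsv(probe_to_gene: pd.Series, path) -> Path:
    path = Path(path)
    probe_to_gene.rename("gene").to_csv(path, sep="\t", index_label="probe")
    return path


def read_probe_map_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="probe")
    series = df["gene"].astype(str)
    series.index = series.index.astype(str)
    series.index.name = None
    return series


def write_study(study: ExpressionStudy, directory) -> dict[str, Path]:
    """Write all study components under ``directory``; return the paths.

    The presence file and probe map are only emitted when the study carries
    them, and the reader tolerates their absence.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": write_expression_tsv(study.expression, directory / EXPRESSION_FILE),
        "phenotypes": write_phenotypes_csv(study.phenotypes, directory / PHENOTYPES_FILE),
    }
    if study.presence is not None:
        paths["presence"] = write_presence_tsv(study.presence, directory / PRESENCE_FILE)
    if study.probe_to_gene is not None:
        paths["probe_map"] = write_probe_map_tsv(
            study.probe_to_gene, directory / PROBE_MAP_FILE
        )
    return paths


def read_study(directory) -> ExpressionStudy:
    directory = Path(directory)
    expression = read_expression_tsv(directory / EXPRESSION_FILE)
    phenotypes = read_phenotypes_csv(directory / PHENOTYPES_FILE)
    presence = None
    if (directory / PRESENCE_FILE).exists():
        presence = read_presence_tsv(directory / PRESENCE_FILE)
    probe_to_gene = None
    if (directory / PROBE_MAP_FILE).exists():
        probe_to_gene = read_probe_map_tsv(directory / PROBE_MAP_FILE)
    return ExpressionStudy(
        expression=expression,
        phenotypes=phenotypes,
        presence=presence,
        probe_to_gene=probe_to_gene,
    )
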