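"""Module summaries (eigengenes, membership, connectivity) and their relation
to clinical traits and groups, plus permutation-based preservation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import DEFAULT_BETA, UNASSIGNED, AdjacencyMatrix, ModuleAssignment


@dataclass
class ModuleEigengenes:
    """Samples x modules matrix of first-principal-component summaries.

    Each eigengene is standardized to unit variance and sign-oriented so that
    the mean correlation of the module's genes with their eigengene is
    non-negative.
    """

    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    orientation: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mu) / sd


def module_eigengenes(
    expression: pd.DataFrame, assignment: ModuleAssignment
) -> ModuleEigengenes:
    """First principal component of each module's z-scored submatrix.

    Genes are z-scored first, so rescaling any gene profile by a positive
    constant leaves the eigengene unchanged.  "grey" is excluded.
    """
    mes = {}
    varexp = {}
    signs = {}
    for label, members in assignment.modules().items():
        sub = expression.loc[members]
        sds = sub.std(axis=1)
        variable = sub.index[sds > 0]
        if len(variable) == 0:
            raise ValueError(f"module {label!r} consists only of constant genes")
        if len(variable) < len(members):
            warnings.warn(
                f"module {label!r}: dropping {len(members) - len(variable)} "
                "constant gene(s) from eigengene computation"
            )
        x = _zscore_rows(sub.loc[variable].to_numpy(dtype=float))
        # right singular vector of the gene x sample matrix = PC1 scores
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        me = vt[0]
        me = (me - me.mean()) / me.std(ddof=1)
        # orient: mean correlation of member genes with the ME must be >= 0
        gene_cor = _cor_rows_with_vector(x, me)
        sign = 1.0 if gene_cor.mean() >= 0 else -1.0
        mes[label] = sign * me
        varexp[label] = float(s[0] ** 2 / (s**2).sum())
        signs[label] = sign
    eigengenes = pd.DataFrame(mes, index=expression.columns)
    return ModuleEigengenes(
        eigengenes=eigengenes,
        variance_explained=pd.Series(varexp, name="variance_explained"),
        orientation=pd.Series(signs, name="orientation"),
    )


def _cor_rows_with_vector(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    num = xc @ vc
    den = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    return num / den


def module_membership(
    expression: pd.DataFrame, eigengenes: ModuleEigengenes
) -> pd.DataFrame:
    """kME table: Pearson correlation of every gene with every eigengene."""
    if not eigengenes.eigengenes.index.equals(expression.columns):
        raise ValueError("eigengene samples must match expression columns")
    x = expression.to_numpy(dtype=float)
    sds = x.std(axis=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): kME undefined, set to NaN"
        )
    out = np.full((x.shape[0], len(eigengenes.modules)), np.nan)
    ok = ~constant
    for j, label in enumerate(eigengenes.modules):
        me = eigengenes.eigengenes[label].to_numpy()
        out[ok, j] = _cor_rows_with_vector(x[ok], me)
    return pd.DataFrame(out, index=expression.index, columns=eigengenes.modules)


def scaled_intramodular_connectivity(
    adjacency: AdjacencyMatrix,
    assignment: ModuleAssignment,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene kIN (sum of intramodular adjacencies, diagonal excluded) and
    kIN scaled by the module maximum; optionally kME against the own-module
    eigengene when ``expression`` is supplied.

    Genes outside any module ("grey") and singleton modules get NaN scaled
    connectivity.
    """
    missing = [g for g in adjacency.genes if g not in assignment.labels.index]
    if missing:
        raise ValueError(f"assignment does not cover genes: {missing[:5]}")
    a = adjacency.values
    rows = []
    kme_table = None
    if expression is not None:
        mes = module_eigengenes(expression, assignment)
        kme_table = module_membership(expression, mes)
    for label, members in assignment.modules(include_unassigned=True).items():
        members = [g for g in members if g in a.index]
        if label == UNASSIGNED:
            for g in members:
                rows.append({"gene": g, "module": label, "kIN": np.nan,
                             "scaled_kIN": np.nan, "kME": np.nan})
            continue
        sub = a.loc[members, members].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, 0.0)
        kin = sub.sum(axis=1)
        kin_max = kin.max() if len(kin) else np.nan
        for g, k in zip(members, kin):
            scaled = k / kin_max if len(members) > 1 and kin_max > 0 else np.nan
            kme = np.nan
            if kme_table is not None and label in kme_table.columns:
                kme = float(kme_table.at[g, label])
            rows.append(
                {"gene": g, "module": label, "kIN": float(k),
                 "scaled_kIN": scaled, "kME": kme}
            )
    return pd.DataFrame(rows).set_index("gene")


def module_trait_correlation(
    eigengenes: ModuleEigengenes,
    phenotypes: pd.DataFrame,
    trait: str,
    sample_filter: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with a numeric trait.

    Missing trait values are dropped pairwise; two-sided p-values come from
    the t-distribution; no multiple-testing adjustment is applied.
    ``sample_filter`` is an optional boolean mask over samples (e.g. restrict
    impairment-score analyses to seropositive cases).
    """
    if trait not in phenotypes.columns:
        raise ValueError(f"trait {trait!r} not in phenotypes")
    values = pd.to_numeric(phenotypes[trait], errors="coerce")
    if sample_filter is not None:
        values = values.where(sample_filter.reindex(values.index, fill_value=False))
    values = values.dropna()
    if len(values) < 4:
        raise ValueError(f"trait {trait!r}: fewer than 4 usable samples")
    if values.nunique() == 1:
        raise ValueError(f"trait {trait!r} is constant on the selected samples")
    rows = []
    for label in eigengenes.modules:
        me = eigengenes.eigengenes.loc[values.index, label]
        r, p = stats.pearsonr(me, values)
        rows.append(
            {"module": label, "trait": trait, "R": float(r), "p": float(p),
             "n": len(values), "test": "pearson", "statistic": float(r)}
        )
    return pd.DataFrame(rows)


def module_group_test(
    eigengenes: ModuleEigengenes,
    phenotypes: pd.DataFrame,
    group_column: str = "group",
) -> pd.DataFrame:
    """One-way ANOVA and Kruskal-Wallis of each eigengene across groups.

    Both tests are reported.  Degenerate input (identical values everywhere)
    yields H = 0, p = 1 rather than an error.
    """
    if group_column not in phenotypes.columns:
        raise ValueError(f"column {group_column!r} not in phenotypes")
    groups = phenotypes[group_column].dropna()
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    small = counts.index[counts < 2].tolist()
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    rows = []
    for label in eigengenes.modules:
        me = eigengenes.eigengenes[label]
        samples = [me.loc[groups.index[groups == g]].to_numpy() for g in counts.index]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            f, f_p, h, h_p = np.nan, np.nan, 0.0, 1.0
        else:
            f, f_p = stats.f_oneway(*samples)
            h, h_p = stats.kruskal(*samples)
        rows.append(
            {"module": label, "anova_F": float(f), "anova_p": float(f_p),
             "kruskal_H": float(h), "kruskal_p": float(h_p)}
        )
    return pd.DataFrame(rows)


@dataclass
class PreservationResult:
    """Permutation Z-scores of module density and connectivity preservation."""

    table: pd.DataFrame  # module, Z_density, Z_connectivity, Z_summary, ...
    n_permutations: int
    seed: int


def _signed_adjacency_array(x: np.ndarray, beta: float) -> np.ndarray:
    corr = np.corrcoef(x)
    a = np.clip((corr + 1.0) / 2.0, 0.0, 1.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def module_preservation(
    reference_expression: pd.DataFrame,
    assignment: ModuleAssignment,
    test_expression: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
    beta: float = DEFAULT_BETA,
) -> PreservationResult:
    """Reduced permutation composite of module preservation.

    For each module, two observed statistics are computed in the test data:
    density (mean intramodular adjacency) and connectivity (correlation of
    intramodular connectivity between reference and test over module genes).
    Each is compared with ``n_permutations`` random gene sets of equal size
    drawn from the common genes; Z = (obs - perm mean) / perm SD and
    Z_summary is the mean of the two Z-scores.  This is a desk-scale
    reduction of the full preservation-statistic suite.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    common = sorted(set(reference_expression.index) & set(test_expression.index))
    if not common:
        raise ValueError("no common genes between reference and test")
    rng = np.random.default_rng(seed)
    ref = reference_expression.loc[common]
    test = test_expression.loc[common]
    index = {g: i for i, g in enumerate(common)}

    ref_x = ref.to_numpy(dtype=float)
    test_x = test.to_numpy(dtype=float)

    def stats_for(idx: np.ndarray) -> tuple[float, float]:
        a_test = _signed_adjacency_array(test_x[idx], beta)
        a_ref = _signed_adjacency_array(ref_x[idx], beta)
        m = len(idx)
        density = a_test.sum() / (m * (m - 1))
        kin_ref = a_ref.sum(axis=1)
        kin_test = a_test.sum(axis=1)
        if np.std(kin_ref) == 0 or np.std(kin_test) == 0:
            conn = 0.0
        else:
            conn = float(np.corrcoef(kin_ref, kin_test)[0, 1])
        return float(density), conn

    rows = []
    for label, members in assignment.modules().items():
        idx = np.array([index[g] for g in members if g in index])
        if len(idx) < 3:
            rows.append(
                {"module": label, "n_genes": len(idx), "Z_density": np.nan,
                 "Z_connectivity": np.nan, "Z_summary": np.nan,
                 "density": np.nan, "connectivity": np.nan}
            )
            continue
        obs_density, obs_conn = stats_for(idx)
        perm = np.array(
            [
                stats_for(rng.choice(len(common), size=len(idx), replace=False))
                for _ in range(n_permutations)
            ]
        )
        mu, sd = perm.mean(axis=0), perm.std(axis=0, ddof=1)
        # degenerate permutation distribution (e.g. test == reference makes
        # every connectivity correlation exactly 1): Z defined as 0
        z_density = (obs_density - mu[0]) / sd[0] if sd[0] > 1e-9 else 0.0
        z_conn = (obs_conn - mu[1]) / sd[1] if sd[1] > 1e-9 else 0.0
        rows.append(
            {"module": label, "n_genes": len(idx),
             "Z_density": float(z_density), "Z_connectivity": float(z_conn),
             "Z_summary": float((z_density + z_conn) / 2.0),
             "density": obs_density, "connectivity": obs_conn}
        )
    return PreservationResult(
        table=pd.DataFrame(rows), n_permutations=n_permutations, seed=seed
    )
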