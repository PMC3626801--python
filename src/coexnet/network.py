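"""Signed weighted coexpression network, topological overlap and modules.

Adjacency is the signed transform a_ij = ((cor(x_i, x_j) + 1) / 2) ** beta
with soft-threshold power beta = 12 by default, so r = -1 maps to 0 and
r = +1 maps to 1.  Topological overlap uses the standard formula

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu

applied to the signed adjacency.  Genes are clustered by average linkage on
1 - TO and modules are branches of the dendrogram cut adaptively subject to a
minimum module size; unassigned genes are labeled "grey".  Module counts are
sensitive to the cut parameters (min_module_size, cut_height, deep_split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

DEFAULT_BETA = 12.0

#: fixed label palette assigned to modules by decreasing size
COLOR_ORDER = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

UNASSIGNED = "grey"


@dataclass
class AdjacencyMatrix:
    """Symmetric genes x genes signed adjacency in [0, 1].

    The diagonal is stored as 1 but is excluded from all connectivity sums.
    """

    values: pd.DataFrame
    beta: float = DEFAULT_BETA

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ModuleAssignment:
    """Per-gene module labels plus the dendrogram that produced them."""

    labels: pd.Series  # gene -> color label; "grey" = unassigned
    linkage: np.ndarray | None = None
    min_module_size: int = 30

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)

    def modules(self, include_unassigned: bool = False) -> dict[str, list[str]]:
        """Module label -> member genes, ordered by decreasing size."""
        out: dict[str, list[str]] = {}
        for label, members in self.labels.groupby(self.labels):
            if label == UNASSIGNED and not include_unassigned:
                continue
            out[label] = list(members.index)
        return dict(
            sorted(out.items(), key=lambda kv: (kv[0] == UNASSIGNED, -len(kv[1]), kv[0]))
        )

    def module_sizes(self) -> pd.Series:
        sizes = self.labels.value_counts()
        return sizes[sizes.index != UNASSIGNED]


def signed_adjacency(
    expression: pd.DataFrame, beta: float = DEFAULT_BETA
) -> AdjacencyMatrix:
    """Signed soft-threshold adjacency from Pearson correlations."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    stds = expression.std(axis=1)
    dead = stds.index[stds == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance gene(s): {dead[:10]}")
    corr = np.corrcoef(expression.to_numpy(dtype=float))
    corr = np.clip(corr, -1.0, 1.0)
    # snap 1-ulp rounding error so perfect (anti)correlation hits the exact
    # endpoints 0 and 1 of the transform
    corr[np.isclose(corr, 1.0, rtol=0.0, atol=1e-12)] = 1.0
    corr[np.isclose(corr, -1.0, rtol=0.0, atol=1e-12)] = -1.0
    adj = ((corr + 1.0) / 2.0) ** beta
    values = pd.DataFrame(adj, index=expression.index, columns=expression.index)
    return AdjacencyMatrix(values=values, beta=float(beta))


def topological_overlap(adjacency: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix of a signed adjacency; diagonal set to 1."""
    a = adjacency.values.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency matrix must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # with zero diagonal this is sum over u != i,j
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(
        tom, index=adjacency.values.index, columns=adjacency.values.columns
    )


def _branches(node, cut_height: float) -> list:
    """Maximal subtrees whose merge height is below the cut."""
    if node.is_leaf() or node.dist <= cut_height:
        return [node]
    return _branches(node.left, cut_height) + _branches(node.right, cut_height)


def _leaf_ids(node) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def _decompose(node, min_module_size: int) -> list[list[int]]:
    """Adaptive branch decomposition of a dendrogram subtree.

    Splits a branch whenever both children could stand as modules on their
    own; otherwise descends through the dominant child so that small side
    attachments (single genes joining an existing branch) do not mask deeper
    splits.  A subtree too small to hold two modules is a single candidate.
    """
    if node.count < 2 * min_module_size or node.is_leaf():
        return [_leaf_ids(node)]
    left, right = node.left, node.right
    if left.count >= min_module_size and right.count >= min_module_size:
        return _decompose(left, min_module_size) + _decompose(right, min_module_size)
    big = left if left.count >= right.count else right
    sub = _decompose(big, min_module_size)
    if len(sub) > 1:
        # genuine splits below; the small attachment stays unassigned
        return sub
    return [_leaf_ids(node)]


def _prune_members(
    candidate: list[int], tom_values: np.ndarray, prune_factor: float
) -> list[int]:
    """Drop weakly attached members: genes whose mean topological overlap
    with the rest of the candidate falls below ``prune_factor`` times the
    candidate median."""
    if len(candidate) < 3 or prune_factor <= 0:
        return candidate
    idx = np.asarray(candidate)
    sub = tom_values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    mean_to_rest = sub.sum(axis=1) / (len(idx) - 1)
    keep = mean_to_rest >= prune_factor * np.median(mean_to_rest)
    return [int(i) for i in idx[keep]]


def cluster_and_cut(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    deep_split: bool = True,
    prune_factor: float = 0.5,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TO with adaptive branch cutting.

    The dendrogram is first cut statically at ``cut_height * max_merge_height``;
    with ``deep_split`` (default) each resulting branch is decomposed
    adaptively: a branch splits wherever both sub-branches hold at least
    ``min_module_size`` genes, descending through dominant children past
    small side attachments.  Candidate modules are then pruned of weakly
    attached members (mean intramodular topological overlap below
    ``prune_factor`` x the candidate median) and kept when at least
    ``min_module_size`` genes remain; all other genes are "grey".  Labels are
    assigned by decreasing module size in a fixed color order.  Module counts
    are sensitive to these parameters.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = list(tom.index)
    tom_values = tom.to_numpy(dtype=float)
    dist = 1.0 - tom_values
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    root = to_tree(z)
    height = cut_height * z[:, 2].max()

    candidates: list[list[int]] = []
    for branch in _branches(root, height):
        if deep_split:
            candidates.extend(_decompose(branch, min_module_size))
        else:
            candidates.append(_leaf_ids(branch))

    member_lists = []
    for candidate in candidates:
        if len(candidate) < min_module_size:
            continue
        kept = _prune_members(candidate, tom_values, prune_factor)
        if len(kept) >= min_module_size:
            member_lists.append([genes[i] for i in kept])
    # decreasing size; ties broken by smallest member name for determinism
    member_lists.sort(key=lambda ms: (-len(ms), min(ms)))

    labels = pd.Series(UNASSIGNED, index=genes, name="module")
    for rank, members in enumerate(member_lists):
        labels.loc[members] = _label_for_rank(rank)
    return ModuleAssignment(labels=labels, linkage=z, min_module_size=min_module_size)


def _label_for_rank(rank: int) -> str:
    if rank < len(COLOR_ORDER):
        return COLOR_ORDER[rank]
    return f"module_{rank + 1}"


def match_labels(
    reference: ModuleAssignment,
    target: ModuleAssignment,
    alpha: float = 0.05,
) -> ModuleAssignment:
    """Relabel target modules to the best-overlapping reference module.

    For each non-grey target module, a one-tailed hypergeometric test of the
    overlap with every reference module is computed over the common gene
    universe.  The target module takes the reference label with the smallest
    p-value when that p-value survives Bonferroni correction over the number
    of reference modules; otherwise it receives a fresh label unused by the
    reference.  "grey" is never remapped.  When two target modules match the
    same reference label, the more significant one wins.
    """
    universe = sorted(set(reference.genes) & set(target.genes))
    if not universe:
        raise ValueError("reference and target share no genes")
    universe_set = set(universe)
    n_universe = len(universe)

    ref_modules = {
        label: set(members) & universe_set
        for label, members in reference.modules().items()
    }
    ref_modules = {k: v for k, v in ref_modules.items() if v}
    tgt_modules = {
        label: set(members) & universe_set
        for label, members in target.modules().items()
    }
    n_tests = max(len(ref_modules), 1)

    candidates = []  # (p, target_label, reference_label)
    for t_label, t_genes in tgt_modules.items():
        for r_label, r_genes in ref_modules.items():
            overlap = len(t_genes & r_genes)
            if overlap == 0:
                continue
            p = float(
                hypergeom.sf(overlap - 1, n_universe, len(r_genes), len(t_genes))
            )
            if p * n_tests < alpha:
                candidates.append((p, t_label, r_label))
    candidates.sort()

    mapping: dict[str, str] = {}
    used_refs: set[str] = set()
    for p, t_label, r_label in candidates:
        if t_label in mapping or r_label in used_refs:
            continue
        mapping[t_label] = r_label
        used_refs.add(r_label)

    taken = set(ref_modules) | set(mapping.values())
    fresh = (c for c in COLOR_ORDER if c not in taken)
    new_labels = target.labels.copy()
    for t_label in target.modules():
        if t_label in mapping:
            new = mapping[t_label]
        else:
            new = next(fresh, None) or f"unmatched_{t_label}"
            taken.add(new)
        new_labels[target.labels == t_label] = new
    return ModuleAssignment(
        labels=new_labels,
        linkage=target.linkage,
        min_module_size=target.min_module_size,
    )


def write_assignment_tsv(assignment: ModuleAssignment, path) -> None:
    assignment.labels.rename("module").to_csv(path, sep="\t", index_label="gene")


def read_assignment_tsv(path) -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    labels = df["module"].astype(str)
    labels.index = labels.index.astype(str)
    return ModuleAssignment(labels=labels)


def write_edge_list_tsv(
    tom: pd.DataFrame, path, threshold: float = 0.1
) -> None:
    """Thresholded upper-triangle edge list (gene_i, gene_j, tom)."""
    genes = list(tom.index)
    values = tom.to_numpy()
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\ttom\n")
        iu, ju = np.triu_indices(len(genes), k=1)
        keep = values[iu, ju] >= threshold
        for i, j in zip(iu[keep], ju[keep]):
            fh.write(f"{genes[i]}\t{genes[j]}\t{values[i, j]:.6g}\n")
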