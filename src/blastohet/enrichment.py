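"""Target-gene-set enrichment and co-expression clustering.

Target catalogs are merged with a support rule (a gene qualifies when it
appears in at least ``min_support`` of the source lists, emulating the
"two of three publications" construction for transcription-factor
targets) and intersected with the universe of genes expressed in the
data. Association between the target set and the highly variable genes
is then scored with a two-sided Fisher exact test over that universe.

Co-expression structure among a gene set is found from the matrix of
pairwise Spearman correlations: distance 1 − ρ (so anti-correlated genes
stay apart), complete-linkage agglomerative clustering, and a top-down
dynamic tree cut that recursively accepts well-separated branches with
at least ``min_cluster_size`` members, labeling everything else 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from .errors import ConfigurationError, InsufficientDataError


@dataclass
class TargetSet:
    genes: set
    source_sizes: list
    min_support: int
    universe: set


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows variable/not, cols target/not
    odds_ratio: float
    p_value: float
    universe_size: int


@dataclass
class ClusterAssignment:
    labels: pd.Series  # per gene; 0 = unassigned
    linkage_matrix: np.ndarray
    gene_order: list
    min_cluster_size: int
    correlation: pd.DataFrame
    excluded_constant: list

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels) != 0).sum())


def build_target_set(lists, min_support: int = 2, universe=None) -> TargetSet:
    """Genes present in >= min_support source lists, within the universe."""
    lists = [set(l) for l in lists]
    if not lists:
        raise ConfigurationError("at least one gene list required")
    if min_support > len(lists):
        raise ConfigurationError(
            f"min_support={min_support} exceeds number of lists ({len(lists)})"
        )
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")
    universe = set(universe) if universe is not None else None
    if universe is not None and len(universe) == 0:
        raise ConfigurationError("universe is empty")
    support: dict = {}
    for l in lists:
        for g in l:
            support[g] = support.get(g, 0) + 1
    genes = {g for g, c in support.items() if c >= min_support}
    if universe is not None:
        genes &= universe
    return TargetSet(
        genes=genes,
        source_sizes=[len(l) for l in lists],
        min_support=min_support,
        universe=universe if universe is not None else set(support),
    )


def enrichment_test(variable, target: TargetSet) -> EnrichmentResult:
    """Two-sided Fisher exact test of target membership among variable genes.

    The 2x2 table classifies every gene of the universe by variable /
    not-variable and target / not-target. The odds ratio is the sample
    cross-product (a·d)/(b·c), with the convention ∞ when b·c = 0 and
    a·d > 0.
    """
    universe = target.universe
    if not universe:
        raise ConfigurationError("universe is empty")
    variable = set(variable) & universe
    targ = target.genes & universe
    a = len(variable & targ)
    b = len(variable - targ)
    c = len(targ - variable)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else np.nan)
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        table=table, odds_ratio=float(odds), p_value=float(p), universe_size=len(universe)
    )


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    return np.corrcoef(ranks)


def _dynamic_tree_cut(Z: np.ndarray, n: int, min_cluster_size: int, min_gap: float):
    """Top-down variant: accept branches that split off distinctly.

    A merge node is a distinct split when the merge height exceeds both
    children's internal heights by at least ``min_gap``; each side of an
    accepted split becomes a cluster (if large enough) unless it splits
    distinctly again further down. Genes under no accepted branch stay
    unassigned (label 0) — with no real structure, no clusters form.
    """
    root = to_tree(Z)

    def height(node):
        return 0.0 if node.is_leaf() else node.dist

    def find(node):
        """Cluster-root nodes strictly below an accepted split under node."""
        if node.is_leaf() or node.get_count() < min_cluster_size:
            return []
        gap_l = node.dist - height(node.get_left())
        gap_r = node.dist - height(node.get_right())
        if gap_l >= min_gap and gap_r >= min_gap:
            return assign(node.get_left()) + assign(node.get_right())
        return find(node.get_left()) + find(node.get_right())

    def assign(child):
        sub = find(child)
        if sub:
            return sub
        if child.get_count() >= min_cluster_size:
            return [child]
        return []

    labels = np.zeros(n, dtype=int)
    for k, cluster_root in enumerate(find(root), start=1):
        labels[cluster_root.pre_order(lambda leaf: leaf.id)] = k
    return labels


def correlation_cluster(
    values: np.ndarray | pd.DataFrame,
    gene_ids=None,
    min_cluster_size: int = 20,
    min_gap: float = 0.15,
    method: str = "complete",
) -> ClusterAssignment:
    """Cluster genes by Spearman co-expression across cells.

    ``values`` is genes x cells. Constant genes (zero variance) are
    excluded with a warning since their correlation is undefined; they
    carry label 0 in the result.
    """
    if isinstance(values, pd.DataFrame):
        gene_ids = values.index
        values = values.to_numpy()
    values = np.asarray(values, float)
    if gene_ids is None:
        gene_ids = pd.Index([f"g{i}" for i in range(values.shape[0])])
    else:
        gene_ids = pd.Index(gene_ids)
    if values.shape[0] < 3 or values.shape[1] < 3:
        raise InsufficientDataError("clustering needs >= 3 genes and >= 3 cells")

    variable_rows = values.std(axis=1) > 0
    excluded = list(gene_ids[~variable_rows])
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant genes excluded from clustering", stacklevel=2
        )
    used_ids = gene_ids[variable_rows]
    used = values[variable_rows]
    labels = pd.Series(0, index=gene_ids, name="cluster")
    if used.shape[0] < 3:
        raise InsufficientDataError("fewer than 3 non-constant genes")

    rho = _spearman_matrix(used)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    condensed = np.maximum(condensed, 0.0)
    Z = linkage(condensed, method=method)
    lab = _dynamic_tree_cut(Z, used.shape[0], min_cluster_size, min_gap)
    labels.loc[used_ids] = lab

    from scipy.cluster.hierarchy import leaves_list

    order = [used_ids[i] for i in leaves_list(Z)]
    return ClusterAssignment(
        labels=labels,
        linkage_matrix=Z,
        gene_order=order,
        min_cluster_size=min_cluster_size,
        correlation=pd.DataFrame(rho, index=used_ids, columns=used_ids),
        excluded_constant=excluded,
    )


def dendrogram_newick(assignment: ClusterAssignment) -> str:
    """Serialize the gene dendrogram as a Newick string (branch lengths
    from merge heights)."""
    tree = to_tree(assignment.linkage_matrix)
    ids = list(assignment.correlation.index)

    def walk(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    return f"({walk(tree.get_left(), tree.dist)},{walk(tree.get_right(), tree.dist)});"
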