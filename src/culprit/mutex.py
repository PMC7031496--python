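"""Mutual exclusivity and co-occurrence among selected genes.

Within the CD8-Low (low signature tertile) samples, expression of each gene
is binarized against its within-group mean, groups are concatenated, and
every gene pair is tested by Fisher's exact test.  The log2 odds ratio of
the pair's 2x2 joint-state table is the association measure: negative
values mark mutual exclusion (the genes' high states avoid each other),
positive values co-occurrence.  A Haldane-Anscombe 0.5 is added to every
cell for the point estimate when any cell is zero; the exact test itself
uses the uncorrected table.

Genes involved in significant pairs are clustered (complete linkage on
1 - Spearman correlation, applicable to expression vectors or to rows of
the log2-OR matrix), yielding the mutually exclusive programs C1 and C2 as
the two children of the dendrogram root.  Synexpression groups are maximal
subtrees whose mean pairwise correlation clears a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionCohort, GeneSignature
from .errors import DegenerateInputError
from .signatures import SignatureScores, StratumLabels

logger = logging.getLogger(__name__)


@dataclass
class BinaryMatrix:
    """Genes x samples 0/1 matrix over the CD8-Low sample subset."""

    values: pd.DataFrame          # entries in {0, 1}
    group_of: pd.Series           # provenance: source tumor group per sample

    def __post_init__(self) -> None:
        if not self.values.isin([0, 1]).all().all():
            raise DegenerateInputError("binary matrix entries must be 0/1")


@dataclass
class MutexMatrix:
    """Symmetric all-pairs association matrices (diagonal NaN-masked)."""

    log2_or: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    degenerate: pd.Index          # genes with all-0 or all-1 binary state


@dataclass
class GeneClusterSet:
    """Dendrogram plus flat cluster labels (C1, C2, ... by descending size)."""

    linkage: np.ndarray
    genes: list
    labels: pd.Series             # gene -> cluster label
    leaf_order: list
    avg_corr: pd.Series           # cluster label -> mean pairwise Spearman rho


def binarize_within_group(cohort_low: ExpressionCohort) -> BinaryMatrix:
    """Binarize each gene against its within-group mean over CD8-Low samples.

    ``cohort_low`` must already be restricted to the low-tertile samples;
    the per-gene mean is computed over that subset only, per group, and an
    entry is 1 iff strictly above the mean.  Groups are then concatenated.
    """
    pieces = []
    for g in cohort_low.groups:
        ids = cohort_low.samples_in_group(g)
        if len(ids) < 2:
            raise DegenerateInputError(
                f"group {g!r} has < 2 CD8-Low samples; cannot binarize")
        block = cohort_low.values.loc[:, ids]
        pieces.append((block.gt(block.mean(axis=1), axis=0)).astype(np.int8))
    binary = pd.concat(pieces, axis=1).loc[:, cohort_low.sample_ids]
    return BinaryMatrix(binary, cohort_low.group_of.copy())


def restrict_to_low_tertile(cohort: ExpressionCohort,
                            tertiles: StratumLabels) -> ExpressionCohort:
    """Subset a cohort to its CD8-Low (low-tertile) samples."""
    low = tertiles.labels.index[tertiles.labels == "low"]
    return cohort.subset_samples([s for s in cohort.sample_ids if s in set(low)])


def _log2_or(n11, n10, n01, n00) -> float:
    cells = np.array([n11, n10, n01, n00], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5       # Haldane-Anscombe, point estimate only
    return float(np.log2(cells[0] * cells[3] / (cells[1] * cells[2])))


def pairwise_fisher(binary: BinaryMatrix,
                    genes: Sequence | None = None) -> MutexMatrix:
    """All-pairs Fisher exact tests on the concatenated binary states.

    Two-sided p by the minimum-likelihood convention (sum of hypergeometric
    probabilities of tables at least as extreme as observed, at fixed
    margins).  BH q across all non-degenerate pairs.  Genes whose binary
    state is constant (all 0 or all 1) are flagged and excluded from the q
    computation; their matrix entries are NaN.
    """
    values = binary.values if genes is None else binary.values.loc[list(genes)]
    ids = values.index
    if len(ids) < 2 or values.shape[1] < 4:
        raise DegenerateInputError("need >= 2 genes and >= 4 samples")
    X = values.to_numpy(dtype=np.int64)
    n = X.shape[1]
    margins = X.sum(axis=1)
    degenerate = ids[(margins == 0) | (margins == n)]
    n11 = X @ X.T
    n10 = margins[:, None] - n11
    n01 = margins[None, :] - n11
    n00 = n - n11 - n10 - n01

    k = len(ids)
    log2_or = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    cache: dict[tuple, float] = {}
    deg_pos = {ids.get_loc(g) for g in degenerate}
    pairs = []
    for i, j in combinations(range(k), 2):
        a, b, c, d = int(n11[i, j]), int(n10[i, j]), int(n01[i, j]), int(n00[i, j])
        log2_or[i, j] = log2_or[j, i] = _log2_or(a, b, c, d)
        if i in deg_pos or j in deg_pos:
            continue
        key = (a, b, c, d)
        if key not in cache:
            cache[key] = float(stats.fisher_exact([[a, b], [c, d]],
                                                  alternative="two-sided")[1])
        pmat[i, j] = pmat[j, i] = cache[key]
        pairs.append((i, j))
    qmat = np.full((k, k), np.nan)
    if pairs:
        pvals = np.array([pmat[i, j] for i, j in pairs])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (i, j), qv in zip(pairs, qvals):
            qmat[i, j] = qmat[j, i] = qv
    frame = lambda m: pd.DataFrame(m, index=ids, columns=ids)
    return MutexMatrix(frame(log2_or), frame(pmat), frame(qmat), degenerate)


def threshold_mutex_genes(mutex: MutexMatrix, or_cutoff: float, q_cutoff: float,
                          or_below: bool = True, q_below: bool = True) -> frozenset:
    """Genes participating in >= 1 pair passing the OR and q cutoffs.

    Defaults select mutual exclusion: log2 OR below ``or_cutoff`` and q
    below ``q_cutoff``.  The comparison directions are parameterised
    because published cutoffs appear in both orientations.
    """
    or_ok = (mutex.log2_or < or_cutoff) if or_below else (mutex.log2_or > or_cutoff)
    q_ok = (mutex.q < q_cutoff) if q_below else (mutex.q > q_cutoff)
    hit = (or_ok & q_ok).fillna(False)
    np.fill_diagonal(hit.values, False)
    return frozenset(hit.index[hit.any(axis=1)])


def _spearman_distance(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """1 - Spearman rho between gene rows; constant rows excluded."""
    const = features.index[features.nunique(axis=1) <= 1]
    if len(const):
        logger.warning("excluding %d constant gene vector(s) from clustering",
                       len(const))
    feats = features.drop(index=const)
    if len(feats) < 2:
        raise DegenerateInputError("need >= 2 non-constant gene vectors")
    ranks = feats.rank(axis=1)
    corr = np.corrcoef(ranks.to_numpy())
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(1.0 - corr, index=feats.index, columns=feats.index), const


def cluster_genes(features: pd.DataFrame, n_clusters: int = 2) -> GeneClusterSet:
    """Complete-linkage agglomerative clustering on 1 - Spearman rho.

    ``features`` holds one row per gene (expression vectors or rows of a
    log2-OR matrix; NaNs in the latter are treated as 0 = no association).
    Rows are sorted by gene id first so the dendrogram is deterministic.
    Flat labels come from the ``n_clusters``-cluster cut, named C1, C2, ...
    by descending size (ties by smallest member gene id).
    """
    feats = features.sort_index().fillna(0.0)
    dist, _ = _spearman_distance(feats)
    genes = list(dist.index)
    condensed = squareform(np.maximum(dist.to_numpy(), 0.0), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    leaf_order = [genes[i] for i in hierarchy.leaves_list(Z)]

    corr = 1.0 - dist
    sizes = {}
    for cid in np.unique(flat):
        members = [g for g, c in zip(genes, flat) if c == cid]
        sizes[cid] = (len(members), min(members))
    order = sorted(sizes, key=lambda c: (-sizes[c][0], sizes[c][1]))
    rename = {cid: f"C{i + 1}" for i, cid in enumerate(order)}
    labels = pd.Series([rename[c] for c in flat], index=pd.Index(genes, name="gene_id"))

    avg = {}
    for name in sorted(set(labels)):
        members = labels.index[labels == name]
        if len(members) > 1:
            sub = corr.loc[members, members].to_numpy()
            avg[name] = float(sub[np.triu_indices(len(members), 1)].mean())
        else:
            avg[name] = np.nan
    return GeneClusterSet(Z, genes, labels, leaf_order, pd.Series(avg))


def synexpression_groups(corr: pd.DataFrame, clusters: GeneClusterSet,
                         min_avg_corr: float = 0.15) -> list[list]:
    """Maximal dendrogram subtrees with mean pairwise correlation >= cutoff.

    The tree is scanned root to leaves; a qualifying subtree is reported
    and not descended further.  Singletons are never reported.
    """
    genes = clusters.genes
    cmat = corr.loc[genes, genes].to_numpy()
    tree = hierarchy.to_tree(clusters.linkage)
    out: list[list] = []

    def visit(node) -> None:
        if node.is_leaf():
            return
        leaves = node.pre_order(lambda leaf: leaf.id)
        sub = cmat[np.ix_(leaves, leaves)]
        mean_rho = float(sub[np.triu_indices(len(leaves), 1)].mean())
        if mean_rho >= min_avg_corr:
            out.append([genes[i] for i in sorted(leaves)])
            return
        visit(node.get_left())
        visit(node.get_right())

    visit(tree)
    return out


def cluster_signatures(clusters: GeneClusterSet,
                       prefix: str = "") -> list[GeneSignature]:
    """Wrap each flat cluster as a GeneSignature (for downstream scoring)."""
    return [GeneSignature(prefix + name,
                          frozenset(clusters.labels.index[clusters.labels == name]))
            for name in sorted(set(clusters.labels))]
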