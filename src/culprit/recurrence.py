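"""Cross-tumor recurrence analyses.

Once every tumor group has a rank table, three questions follow:

* Do the top-percentile gene sets of different groups overlap more than
  chance?  (Yates-corrected chi-square per unordered pair of groups, BH
  corrected across all pairs.)
* Which genes are *consistently* top-ranked?  **MPR selection**: median
  percentile rank across groups >= ``mpr_min`` by both the LFC and SC
  methods, with median BH q <= ``median_q_max`` by both.
* Which recurrence counts are *individually* significant?  **EBP
  selection**: a gene in the top-percentile set of k of T groups has exact
  binomial point probability ``C(T,k) f^k (1-f)^(T-k)``; Bonferroni
  multiplication by the G-gene universe gives the reported probability, and
  genes with k >= ``min_k`` are selected.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .data_model import AnalysisParams
from .errors import DegenerateInputError, InvalidConfigError


def pairwise_overlap_chi2(top_sets: Mapping[object, frozenset],
                          params: AnalysisParams) -> pd.DataFrame:
    """Chi-square (Yates continuity-corrected) overlap test for every pair.

    For groups A and B with top sets of sizes a and b overlapping in m
    genes, the 2x2 table over the G-gene universe is
    ``[[m, a-m], [b-m, G-a-b+m]]``.  Returns one row per unordered pair
    with columns (group_a, group_b, size_a, size_b, overlap, chi2, p, q);
    q is BH across all pairs.
    """
    groups = list(top_sets)
    if len(groups) < 2:
        raise DegenerateInputError("need >= 2 groups for pairwise overlap")
    G = params.universe_size
    for g, s in top_sets.items():
        if len(s) > G:
            raise InvalidConfigError(f"top set of {g!r} exceeds universe size")
    rows = []
    for a, b in combinations(groups, 2):
        sa, sb = top_sets[a], top_sets[b]
        m = len(sa & sb)
        table = np.array([[m, len(sa) - m],
                          [len(sb) - m, G - len(sa) - len(sb) + m]])
        if table.min() < 0:
            raise InvalidConfigError("overlap table has negative cell; check universe")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append((a, b, len(sa), len(sb), m, chi2, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "size_a", "size_b",
                                      "overlap", "chi2", "p"])
    out["q"] = multipletests(out["p"], method=params.fdr_method)[1]
    return out


def overlap_significance_fractions(results: pd.DataFrame,
                                   thresholds=(0.05, 0.01, 0.001)) -> pd.Series:
    """Fraction of group pairs whose overlap q falls below each threshold."""
    return pd.Series({t: float((results["q"] < t).mean()) for t in thresholds},
                     name="fraction_significant")


def median_percentile_table(rank_tables: Mapping[object, pd.DataFrame],
                            params: AnalysisParams | None = None) -> pd.DataFrame:
    """Per-gene medians of percentile ranks and q-values across groups.

    Genes missing from any group's table are dropped (with the count noted
    in the result's ``attrs``).  The ``selected`` flag applies the MPR
    rule: both-method median percentile rank >= ``mpr_min`` and both-method
    median q <= ``median_q_max`` (bounds inclusive).
    """
    params = params or AnalysisParams()
    tables = list(rank_tables.values())
    if not tables:
        raise DegenerateInputError("zero groups")
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    n_dropped = len(tables[0].index) - len(common)
    stack = {col: pd.concat([t.loc[common, col] for t in tables], axis=1)
             for col in ("pr_lfc", "pr_sc", "q_lfc", "q_sc")}
    out = pd.DataFrame({
        "mpr_lfc": stack["pr_lfc"].median(axis=1),
        "mpr_sc": stack["pr_sc"].median(axis=1),
        "med_q_lfc": stack["q_lfc"].median(axis=1),
        "med_q_sc": stack["q_sc"].median(axis=1),
    })
    out["selected"] = ((out["mpr_lfc"] >= params.mpr_min)
                       & (out["mpr_sc"] >= params.mpr_min)
                       & (out["med_q_lfc"] <= params.median_q_max)
                       & (out["med_q_sc"] <= params.median_q_max))
    out.attrs["n_dropped"] = n_dropped
    return out


def binomial_point_probability(k: int, n_groups: int, top_fraction: float) -> float:
    """P(X = k) for X ~ Binomial(T, f), evaluated in log space."""
    T, f = n_groups, top_fraction
    if not (0 <= k <= T):
        raise InvalidConfigError(f"k={k} out of range [0, {T}]")
    log_p = (gammaln(T + 1) - gammaln(k + 1) - gammaln(T - k + 1)
             + k * np.log(f) + (T - k) * np.log1p(-f))
    return float(np.exp(log_p))


def ebp(k: int, params: AnalysisParams | None = None, n_groups: int | None = None,
        tail: bool = False) -> float:
    """Bonferroni-corrected exact binomial probability of recurrence count k.

    ``min(1, G * C(T,k) f^k (1-f)^(T-k))`` — the binomial *point*
    probability at exactly k successes in T groups with per-group success
    probability f, multiplied by the universe size G.  Evaluated in log
    space.  ``tail=True`` substitutes the upper-tail probability
    P(X >= k) for the point mass.
    """
    params = params or AnalysisParams()
    T = n_groups if n_groups is not None else 23
    f, G = params.top_fraction, params.universe_size
    if tail:
        if not (0 <= k <= T):
            raise InvalidConfigError(f"k={k} out of range [0, {T}]")
        p = stats.binom.sf(k - 1, T, f)
    else:
        p = binomial_point_probability(k, T, f)
    return float(min(1.0, G * p))


def select_ebp_culprits(top_sets_lfc: Mapping[object, frozenset],
                        top_sets_sc: Mapping[object, frozenset],
                        params: AnalysisParams | None = None,
                        p_bonf_max: float | None = None) -> pd.DataFrame:
    """Count top-percentile recurrences per gene and apply the EBP rule.

    Returns one row per gene appearing in at least one top set, with
    columns (k_lfc, k_sc, p_bonf_lfc, p_bonf_sc, selected_lfc,
    selected_sc, selected), sorted by max(k) descending then gene id.
    Selection per method requires ``k >= params.min_k`` and, when
    ``p_bonf_max`` is given, additionally ``p_bonf <= p_bonf_max``.  The
    combined ``selected`` flag is the per-method disjunction (a gene
    qualifies by either ranking statistic).
    """
    params = params or AnalysisParams()
    if set(top_sets_lfc) != set(top_sets_sc):
        raise InvalidConfigError("LFC and SC top sets cover different groups")
    T = len(top_sets_lfc)
    counts: dict[object, list[int]] = {}
    for sets, j in ((top_sets_lfc, 0), (top_sets_sc, 1)):
        for s in sets.values():
            for g in s:
                counts.setdefault(g, [0, 0])[j] += 1
    genes = sorted(counts)
    out = pd.DataFrame(
        {"k_lfc": [counts[g][0] for g in genes],
         "k_sc": [counts[g][1] for g in genes]},
        index=pd.Index(genes, name="gene_id"))
    for m in ("lfc", "sc"):
        out[f"p_bonf_{m}"] = [ebp(k, params, n_groups=T) for k in out[f"k_{m}"]]
        sel = out[f"k_{m}"] >= params.min_k
        if p_bonf_max is not None:
            sel &= out[f"p_bonf_{m}"] <= p_bonf_max
        out[f"selected_{m}"] = sel
    out["selected"] = out["selected_lfc"] | out["selected_sc"]
    out["k_max"] = out[["k_lfc", "k_sc"]].max(axis=1)
    out = (out.sort_values(["k_max", "gene_id"], ascending=[False, True],
                           kind="stable").drop(columns="k_max"))
    return out
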