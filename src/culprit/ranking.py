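"""Per-group gene ranking for association with the CD8-Low state.

Two parallel statistics are computed for every gene within every tumor
group:

* **LFC method** — mean log2 expression difference between the high and the
  low signature tertile (``lfc = mean(high) - mean(low)``, so negative
  values mark genes overexpressed in CD8-Low tumors), with p-values from an
  empirical-Bayes moderated t statistic (per-gene pooled variances shrunk
  toward a scaled-inverse-chi-square prior fitted across genes by method of
  moments).
* **SC method** — tie-corrected Spearman correlation of the gene with the
  signature score over all samples of the group, irrespective of tertiles.

Genes are then ordered (most CD8-Low-associated first) and assigned
percentile ranks in (0, 100]: position 1 maps to 100, position G to 100/G.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import AnalysisParams, ExpressionCohort, GeneSignature
from .errors import DegenerateInputError
from .signatures import SignatureScores, StratumLabels, metagene_score, partition_tertiles

RANK_COLUMNS = ("lfc", "t_mod", "p_lfc", "q_lfc", "rho", "p_sc", "q_sc",
                "pr_lfc", "pr_sc")


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square prior.

    Under the hierarchical model the sample variances are marginally
    ``s0^2 * F(d, d0)``; matching the first two moments of the observed
    variances gives ``d0`` and ``s0^2``.  When the observed dispersion is
    no larger than the sampling dispersion of a chi-square with d degrees
    of freedom, the prior degrees of freedom are infinite (full shrinkage
    to the common variance).
    """
    m1 = float(np.mean(s2))
    m2 = float(np.mean(s2 ** 2))
    if m1 <= 0:
        return np.inf, max(m1, 1e-12)
    r = m2 / m1 ** 2
    c = (d + 2) / d
    if r <= c:
        return np.inf, m1
    d0 = (4 * r - 2 * c) / (r - c)
    s0_sq = m1 * (d0 - 2) / d0
    return d0, s0_sq


def differential_lfc(cohort: ExpressionCohort, tertiles: StratumLabels, group,
                     prior_df: float | None = None) -> pd.DataFrame:
    """Low-vs-high tertile differential expression within one group.

    Returns a DataFrame indexed by gene with columns (lfc, t_mod, p_lfc).
    ``prior_df`` overrides the fitted prior degrees of freedom; 0 recovers
    the ordinary pooled-variance two-sample t test.
    """
    low = tertiles.samples_in("low", group)
    high = tertiles.samples_in("high", group)
    if len(low) < 2 or len(high) < 2:
        raise DegenerateInputError(
            f"group {group!r}: need >= 2 samples in both low and high tertiles")
    x_low = cohort.values.loc[:, low].to_numpy(dtype=float)
    x_high = cohort.values.loc[:, high].to_numpy(dtype=float)
    n1, n2 = x_low.shape[1], x_high.shape[1]
    d = n1 + n2 - 2
    if d <= 0:
        raise DegenerateInputError("zero residual degrees of freedom")

    lfc = x_high.mean(axis=1) - x_low.mean(axis=1)
    ss = (x_low.var(axis=1, ddof=0) * n1 + x_high.var(axis=1, ddof=0) * n2)
    s2 = ss / d                       # pooled variance, d degrees of freedom

    d0, s0_sq = _fit_variance_prior(s2, d)
    if prior_df is not None:
        d0 = prior_df
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)
    return pd.DataFrame({"lfc": lfc, "t_mod": t_mod, "p_lfc": p},
                        index=cohort.gene_ids)


def spearman_assoc(cohort: ExpressionCohort, scores: SignatureScores,
                   group) -> pd.DataFrame:
    """Spearman correlation of every gene with the signature score in a group.

    Tie-corrected (Pearson on mid-ranks); two-sided p from the t
    approximation.  Constant genes get rho = 0, p = 1 and ``constant =
    True``.  A constant score within the group is an error.
    """
    ids = cohort.samples_in_group(group)
    if len(ids) < 4:
        raise DegenerateInputError(f"group {group!r}: need >= 4 samples")
    x = cohort.values.loc[:, ids].to_numpy(dtype=float)
    s = scores.scores[ids].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise DegenerateInputError(f"group {group!r}: constant signature score")
    n = len(ids)
    rx = stats.rankdata(x, axis=1)
    rs = stats.rankdata(s)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    rs_c = rs - rs.mean()
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (rs_c ** 2).sum())
    constant = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(constant, 0.0, (rx_c @ rs_c) / np.where(constant, 1.0, denom))
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(constant, 1.0, p)
    return pd.DataFrame({"rho": rho, "p_sc": p, "constant": constant},
                        index=cohort.gene_ids)


def percentile_ranks(statistic: pd.Series, tiebreak_q: pd.Series | None = None,
                     more_negative_is_top: bool = True,
                     flagged: pd.Series | None = None) -> pd.Series:
    """Percentile ranks in (0, 100]: the most CD8-Low-associated gene gets 100.

    Genes are ordered by the statistic (ascending when
    ``more_negative_is_top``), ties broken by smaller q then gene id;
    flagged genes are forced to the bottom.  ``pr = 100 (G - pos + 1) / G``.
    """
    if statistic.empty:
        raise DegenerateInputError("empty statistic vector")
    G = len(statistic)
    key = statistic if more_negative_is_top else -statistic
    frame = pd.DataFrame({"key": key})
    frame["q"] = tiebreak_q.reindex(statistic.index) if tiebreak_q is not None else 0.0
    frame["flag"] = (flagged.reindex(statistic.index).fillna(False).astype(bool)
                     if flagged is not None else False)
    # sort on (flag, key, q), remaining ties resolved by gene id
    frame = (frame.rename_axis("index").reset_index()
             .sort_values(["flag", "key", "q", "index"], kind="stable")
             .set_index("index"))
    pos = pd.Series(np.arange(1, G + 1), index=frame.index)
    pr = 100.0 * (G - pos + 1) / G
    return pr.reindex(statistic.index).rename("pr")


def rank_order(statistic: pd.Series, tiebreak_q: pd.Series | None = None,
               more_negative_is_top: bool = True,
               flagged: pd.Series | None = None) -> list:
    """Gene ids ordered most CD8-Low-associated first (same rules as
    :func:`percentile_ranks`)."""
    pr = percentile_ranks(statistic, tiebreak_q, more_negative_is_top, flagged)
    return list(pr.sort_values(ascending=False, kind="stable").index)


def top_percentile_set(ranked_genes: Sequence, params: AnalysisParams) -> frozenset:
    """The genes at positions 1..floor(f G) of the rank order (exactly)."""
    n_top = int(np.floor(params.top_fraction * len(ranked_genes)))
    if n_top < 1:
        raise DegenerateInputError(
            f"top_fraction {params.top_fraction} of {len(ranked_genes)} genes is < 1")
    return frozenset(ranked_genes[:n_top])


def build_rank_table(cohort: ExpressionCohort, scores: SignatureScores,
                     tertiles: StratumLabels, group,
                     params: AnalysisParams | None = None) -> pd.DataFrame:
    """Full per-gene rank table for one group (columns ``RANK_COLUMNS``).

    BH q-values are computed per method across all genes of the group.
    """
    params = params or AnalysisParams()
    de = differential_lfc(cohort, tertiles, group)
    sc = spearman_assoc(cohort, scores, group)
    tab = de.join(sc)
    tab["q_lfc"] = multipletests(tab["p_lfc"], method=params.fdr_method)[1]
    tab["q_sc"] = multipletests(tab["p_sc"], method=params.fdr_method)[1]
    tab["pr_lfc"] = percentile_ranks(tab["lfc"], tab["q_lfc"])
    tab["pr_sc"] = percentile_ranks(tab["rho"], tab["q_sc"],
                                    flagged=tab["constant"])
    return tab[list(RANK_COLUMNS)]


def rank_all_groups(cohort: ExpressionCohort, signature: GeneSignature,
                    params: AnalysisParams | None = None
                    ) -> dict[object, pd.DataFrame]:
    """Score the cohort, form tertiles per group, and rank every group.

    The one-call entry point for the ranking stage; returns
    ``{group: rank table}``.
    """
    params = params or AnalysisParams()
    scores = metagene_score(cohort, signature)
    tertiles = partition_tertiles(scores, cohort.group_of)
    return {g: build_rank_table(cohort, scores, tertiles, g, params)
            for g in cohort.groups}
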