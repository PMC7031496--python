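"""Metagene scoring and sample stratification.

A metagene score summarises a small gene set per sample as the geometric
mean of the log2-transformed expression values themselves.  Because the
geometric mean is taken on the log2 scale (not the linear scale), a single
zero among the member values zeroes the whole score — this is deliberate
and matches the pipeline's definition of the score; callers working with
sparse data should be aware of it.

Stratification into tertiles (CD8-Low / -Intermediate / -High) or quartiles
(Q1..Q4, Q1 = lowest) is rank-based and balanced: within each context the
samples are sorted by score (ties broken by sample id) and cut into blocks
whose sizes differ by at most one, extras going to the lowest strata first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionCohort, GeneSignature
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "mid", "high")
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class SignatureScores:
    """Per-sample metagene score for one signature (log2-unit scale)."""

    name: str
    scores: pd.Series

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DegenerateInputError("scores must be finite and >= 0")


@dataclass
class StratumLabels:
    """Per-sample stratum assignment computed within a grouping context."""

    scheme: str                 # "tertile" or "quartile"
    labels: pd.Series           # sample -> stratum label
    context_of: pd.Series       # sample -> context the split was computed in

    def samples_in(self, label, context=None) -> pd.Index:
        mask = self.labels == label
        if context is not None:
            mask &= self.context_of == context
        return self.labels.index[mask]


def metagene_score(cohort: ExpressionCohort, signature: GeneSignature) -> SignatureScores:
    """Geometric mean of the log2 expression values of the signature members.

    Members absent from the cohort are dropped with a warning; if none are
    present a :class:`DegenerateInputError` is raised.  Any zero member
    value makes the sample's score 0.
    """
    present = [g for g in sorted(signature.members) if g in cohort.gene_ids]
    absent = signature.members - set(present)
    if absent:
        logger.warning("signature %s: %d member(s) absent from cohort, dropped",
                       signature.name, len(absent))
    if not present:
        raise DegenerateInputError(
            f"no members of signature {signature.name!r} present in cohort")
    vals = cohort.values.loc[present].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(vals)
    score = np.where(np.any(vals == 0, axis=0), 0.0,
                     np.exp(np.mean(np.where(vals == 0, 0.0, logs), axis=0)))
    return SignatureScores(signature.name, pd.Series(score, index=cohort.sample_ids))


def _balanced_blocks(n: int, k: int) -> list[int]:
    """Block sizes summing to n, differing by <= 1, extras to the front."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _partition(scores: SignatureScores, context_of: pd.Series, k: int,
               labels: tuple, scheme: str) -> StratumLabels:
    context_of = context_of.reindex(scores.scores.index)
    out = pd.Series(index=scores.scores.index, dtype=object)
    for ctx in dict.fromkeys(context_of):
        ids = context_of.index[context_of == ctx]
        if len(ids) < k:
            raise DegenerateInputError(
                f"context {ctx!r} has {len(ids)} samples; need >= {k}")
        order = sorted(ids, key=lambda s: (scores.scores[s], s))
        sizes = _balanced_blocks(len(ids), k)
        pos = 0
        for label, size in zip(labels, sizes):
            out[order[pos:pos + size]] = label
            pos += size
    return StratumLabels(scheme, out, context_of)


def partition_tertiles(scores: SignatureScores, context_of: pd.Series) -> StratumLabels:
    """Split each context into low/mid/high score tertiles (balanced ranks)."""
    return _partition(scores, context_of, 3, TERTILE_LABELS, "tertile")


def partition_quartiles(scores: SignatureScores, context_of: pd.Series) -> StratumLabels:
    """Split each context into quartiles Q1 (lowest) .. Q4 (highest)."""
    return _partition(scores, context_of, 4, QUARTILE_LABELS, "quartile")


def score_annotation_correlation(scores: SignatureScores, annotation: pd.Series,
                                 context_of: pd.Series) -> pd.DataFrame:
    """Per-context Spearman correlation of the score with a numeric annotation.

    Returns a DataFrame indexed by context with columns (rho, p, n).
    Contexts where either vector is constant get NaN rho with a warning.
    """
    rows = {}
    for ctx in dict.fromkeys(context_of):
        ids = context_of.index[context_of == ctx]
        paired = pd.concat([scores.scores[ids], annotation.reindex(ids)],
                           axis=1, keys=["score", "ann"]).dropna()
        if len(paired) < 3:
            raise DegenerateInputError(
                f"context {ctx!r}: need >= 3 paired non-missing values")
        if paired["score"].nunique() == 1 or paired["ann"].nunique() == 1:
            logger.warning("context %r: constant vector, correlation undefined", ctx)
            rows[ctx] = (np.nan, np.nan, len(paired))
            continue
        rho, p = stats.spearmanr(paired["score"], paired["ann"])
        rows[ctx] = (rho, p, len(paired))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["rho", "p", "n"])
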