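"""Signature scores vs immunotherapy outcomes in a treatment cohort.

Derived signatures (the mutually exclusive programs C1/C2 and the CD8
identity metagene) are scored per biopsy, quartiles are formed within the
pre- and on-treatment strata independently, and quartile membership is
tested against RECIST response (Fisher's exact test, responders = CR/PR)
and overall survival (Kaplan-Meier curves compared by the log-rank test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .data_model import ClinicalTable, ExpressionCohort, GeneSignature
from .errors import DegenerateInputError
from .signatures import (SignatureScores, StratumLabels, metagene_score,
                         partition_quartiles)


@dataclass
class ResponseAssociation:
    """Fisher tests of responder status against score quartiles."""

    counts: pd.DataFrame          # responder/non-responder x Q1..Q4 counts
    p_q1_vs_q4: float
    p_q1_vs_mid: float            # Q1 vs pooled Q2+Q3
    responder_definition: str = "CR/PR (NE excluded)"


@dataclass
class SurvivalComparison:
    """Per-group KM curves plus the k-group log-rank test."""

    curves: dict                  # group -> DataFrame(time, at_risk, events, survival)
    statistic: float
    p: float
    df: int


def score_treatment_cohort(cohort: ExpressionCohort,
                           signatures: list[GeneSignature],
                           clinical: ClinicalTable
                           ) -> dict[str, tuple[SignatureScores, StratumLabels]]:
    """Score each signature and quartile the samples within timing strata.

    Quartiles are computed independently within the pre- and on-treatment
    sample sets, so Q1..Q4 are comparable across biopsy timing.
    """
    timing = clinical.table["timing"].reindex(cohort.sample_ids)
    if timing.isna().any():
        raise DegenerateInputError("every sample needs a timing label (pre/on)")
    out = {}
    for sig in signatures:
        scores = metagene_score(cohort, sig)
        quartiles = partition_quartiles(scores, timing)
        out[sig.name] = (scores, quartiles)
    return out


def response_quartile_test(strata: StratumLabels,
                           clinical: ClinicalTable) -> ResponseAssociation:
    """Fisher exact tests of response against quartile membership.

    Responders are CR/PR; SD/PD are non-responders; NE samples are
    excluded.  Two two-sided tests are reported: Q1 vs Q4, and Q1 vs the
    pooled interquartile strata Q2+Q3.
    """
    resp = clinical.responders()
    labels = strata.labels.reindex(resp.index).dropna()
    resp = resp[labels.index]
    if labels.empty:
        raise DegenerateInputError("no evaluable samples after NE exclusion")
    counts = pd.crosstab(resp.map({True: "responder", False: "non-responder"}),
                         labels).reindex(
        index=["responder", "non-responder"],
        columns=["Q1", "Q2", "Q3", "Q4"], fill_value=0)
    counts.index.name = "response"
    counts.columns.name = "quartile"
    for needed in ("Q1", "Q4"):
        if counts[needed].sum() == 0:
            raise DegenerateInputError(f"stratum {needed} empty after NE exclusion")
    q1 = counts["Q1"].to_numpy()
    q4 = counts["Q4"].to_numpy()
    mid = (counts["Q2"] + counts["Q3"]).to_numpy()
    if mid.sum() == 0:
        raise DegenerateInputError("strata Q2+Q3 empty after NE exclusion")
    _, p14 = stats.fisher_exact(np.column_stack([q1, q4]))
    _, p1m = stats.fisher_exact(np.column_stack([q1, mid]))
    return ResponseAssociation(counts, float(p14), float(p1m))


def km_logrank(clinical: ClinicalTable, groups: pd.Series) -> SurvivalComparison:
    """Kaplan-Meier curves per group and the standard k-group log-rank test."""
    groups = groups.reindex(clinical.sample_ids).dropna()
    tab = clinical.table.loc[groups.index]
    names = [g for g in dict.fromkeys(groups)]
    if len(names) < 2:
        raise DegenerateInputError("need >= 2 non-empty groups for log-rank")
    if (tab["os_time"] < 0).any():
        raise DegenerateInputError("negative survival times")

    curves = {}
    for name in names:
        ids = groups.index[groups == name]
        kmf = KaplanMeierFitter()
        kmf.fit(tab.loc[ids, "os_time"], tab.loc[ids, "os_event"])
        ev = kmf.event_table
        curves[name] = pd.DataFrame({
            "time": ev.index.to_numpy(),
            "at_risk": ev["at_risk"].to_numpy(),
            "events": ev["observed"].to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy(),
        })

    if tab["os_event"].sum() == 0:
        return SurvivalComparison(curves, 0.0, 1.0, len(names) - 1)
    res = multivariate_logrank_test(tab["os_time"], groups, tab["os_event"])
    return SurvivalComparison(curves, float(res.test_statistic),
                              float(res.p_value), len(names) - 1)


def signature_score_correlation(scores_a: SignatureScores,
                                scores_b: SignatureScores) -> tuple[float, float]:
    """Spearman correlation between two signatures' per-sample scores."""
    paired = pd.concat([scores_a.scores, scores_b.scores], axis=1).dropna()
    if len(paired) < 3:
        raise DegenerateInputError("need >= 3 paired scores")
    a, b = paired.iloc[:, 0], paired.iloc[:, 1]
    if a.nunique() == 1 or b.nunique() == 1:
        raise DegenerateInputError("constant score vector; correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def pool_quartiles(strata: StratumLabels, low: str = "Q1") -> pd.Series:
    """Collapse quartiles to a two-group labeling: ``low`` vs the rest."""
    return strata.labels.map(lambda q: q if q == low else "Q2-Q4")
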