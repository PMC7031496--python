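"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes in real pan-cancer data: each sample carries a latent CD8+ T-cell
infiltration factor ``z``; a small signature gene set loads positively on it
(so its metagene score tracks infiltration), planted "culprit" genes load
negatively in a configurable subset of tumor groups, and two planted
expression programs A and B activate mutually exclusively in
low-infiltration samples.  Everything else is baseline plus Gaussian noise,
clipped at 0 to respect the log2(count+1) floor.

Because every planted role is recorded in :class:`PlantedTruth`, each
downstream stage (ranking, recurrence selection, mutual-exclusivity
clustering, outcome association) has an exact recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ClinicalTable, ExpressionCohort, GeneSignature
from .errors import InvalidConfigError


@dataclass
class GeneratorConfig:
    """Parameters of the pan-tumor generator.

    Defaults mirror the desk-scale study conditions used throughout the test
    surface: 10 tumor groups of 120 samples, a 2,000-gene universe with a
    4-gene signature, 50 culprit genes active in 8 of the 10 groups at unit
    effect, and two 20-gene mutually exclusive programs.
    """

    n_groups: int = 10
    samples_per_group: int = 120
    n_genes: int = 2000
    baseline: float = 5.0        # alpha, log2 units
    noise_sd: float = 1.0        # sigma
    n_signature: int = 4
    signature_effect: float = 1.0   # beta > 0, loading on latent z
    n_culprits: int = 50
    culprit_effect: float = 1.0     # gamma >= 0, negative loading on z
    n_culprit_groups: int = 8       # groups carrying the culprit effect
    program_size_a: int = 20
    program_size_b: int = 20
    program_effect: float = 1.5     # delta, added when a program is active
    program_prob: float = 0.5       # pi, P(cold sample activates A rather than B)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_groups, self.samples_per_group, self.n_genes,
                  self.n_signature, self.n_culprits, self.program_size_a,
                  self.program_size_b)
        if any(c < 0 for c in counts) or self.n_groups < 1 or self.n_genes < 1:
            raise InvalidConfigError("counts must be >= 0 (groups/genes >= 1)")
        planted = self.n_signature + self.n_culprits + self.program_size_a + self.program_size_b
        if planted > self.n_genes:
            raise InvalidConfigError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if not (0 <= self.program_prob <= 1):
            raise InvalidConfigError("program_prob must lie in [0, 1]")
        if self.signature_effect <= 0 or self.culprit_effect < 0:
            raise InvalidConfigError("signature_effect > 0 and culprit_effect >= 0 required")
        if not (0 <= self.n_culprit_groups <= self.n_groups):
            raise InvalidConfigError("n_culprit_groups must lie in [0, n_groups]")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated cohort."""

    latent: pd.Series                 # per-sample infiltration factor z
    role_of: pd.Series                # gene -> signature/culprit/programA/programB/null
    program_of: pd.Series             # sample -> A/B/none
    effect_of: pd.Series              # gene -> planted effect size
    culprit_groups: tuple = ()

    def genes_with_role(self, role: str) -> pd.Index:
        return self.role_of.index[self.role_of == role]

    @property
    def signature(self) -> GeneSignature:
        return GeneSignature("SIG", frozenset(self.genes_with_role("signature")))


def _gene_roles(cfg: GeneratorConfig) -> pd.Series:
    names, roles = [], []
    for i in range(cfg.n_signature):
        names.append(f"SIG{i:03d}"); roles.append("signature")
    for i in range(cfg.n_culprits):
        names.append(f"CUL{i:03d}"); roles.append("culprit")
    for i in range(cfg.program_size_a):
        names.append(f"PGA{i:03d}"); roles.append("programA")
    for i in range(cfg.program_size_b):
        names.append(f"PGB{i:03d}"); roles.append("programB")
    n_null = cfg.n_genes - len(names)
    for i in range(n_null):
        names.append(f"NUL{i:04d}"); roles.append("null")
    return pd.Series(roles, index=pd.Index(names, name="gene_id"))


def generate_pan_tumor(cfg: GeneratorConfig) -> tuple[ExpressionCohort, PlantedTruth]:
    """Generate a grouped expression cohort with planted structure.

    Per sample ``s`` in group ``t``: ``z_s ~ N(mu_t, 1)`` with group means
    ``mu_t ~ N(0, 1)`` drawn once (emulating cross-tumor variation in
    infiltration).  Signature genes follow ``alpha + beta z_s + noise``;
    culprit genes ``alpha - gamma z_s + noise`` in culprit-carrying groups
    and pure noise elsewhere; program genes gain ``delta`` in the cold
    (lower z-tertile) samples assigned to their program; null genes are
    baseline noise.  Values are clipped at 0.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    roles = _gene_roles(cfg)
    genes = roles.index
    group_names = [f"G{t:02d}" for t in range(cfg.n_groups)]
    culprit_groups = tuple(group_names[: cfg.n_culprit_groups])

    sample_ids, group_labels = [], []
    for g in group_names:
        for i in range(cfg.samples_per_group):
            sample_ids.append(f"{g}_S{i:03d}")
            group_labels.append(g)
    samples = pd.Index(sample_ids, name="sample_id")
    group_of = pd.Series(group_labels, index=samples, name="group")

    mu = rng.normal(0.0, 1.0, size=cfg.n_groups)
    z = np.concatenate([
        rng.normal(mu[t], 1.0, size=cfg.samples_per_group)
        for t in range(cfg.n_groups)
    ])
    latent = pd.Series(z, index=samples, name="z")

    values = cfg.baseline + rng.normal(0.0, cfg.noise_sd,
                                       size=(cfg.n_genes, len(samples)))

    role_arr = roles.to_numpy()
    sig_rows = role_arr == "signature"
    cul_rows = role_arr == "culprit"
    pga_rows = role_arr == "programA"
    pgb_rows = role_arr == "programB"

    values[sig_rows] += cfg.signature_effect * z
    in_culprit_group = group_of.isin(culprit_groups).to_numpy()
    values[np.ix_(cul_rows, in_culprit_group)] -= (
        cfg.culprit_effect * z[in_culprit_group])

    # cold samples = lower z-tertile within each group; each activates A or B
    program_of = pd.Series("none", index=samples, name="program")
    for g in group_names:
        mask = (group_of == g).to_numpy()
        zg = latent[mask]
        n_cold = int(np.ceil(len(zg) / 3))
        cold = zg.sort_values(kind="stable").index[:n_cold]
        pick_a = rng.random(len(cold)) < cfg.program_prob
        program_of.loc[cold[pick_a]] = "A"
        program_of.loc[cold[~pick_a]] = "B"
    a_active = (program_of == "A").to_numpy()
    b_active = (program_of == "B").to_numpy()
    values[np.ix_(pga_rows, a_active)] += cfg.program_effect
    values[np.ix_(pgb_rows, b_active)] += cfg.program_effect

    np.clip(values, 0.0, None, out=values)

    effect = pd.Series(0.0, index=genes, name="effect")
    effect[sig_rows] = cfg.signature_effect
    effect[cul_rows] = -cfg.culprit_effect
    effect[pga_rows | pgb_rows] = cfg.program_effect

    cohort = ExpressionCohort(pd.DataFrame(values, index=genes, columns=samples),
                              group_of)
    truth = PlantedTruth(latent=latent, role_of=roles, program_of=program_of,
                         effect_of=effect, culprit_groups=culprit_groups)
    return cohort, truth


def generate_treatment_cohort(
    cfg: GeneratorConfig,
    signature: GeneSignature | None = None,
    response_slope: float = 0.0,
    hazard_slope: float = 0.0,
    n_samples: int = 96,
    response_intercept: float = -1.1,
    baseline_hazard: float = np.log(2) / 600.0,   # per day; median OS ~600 d
    censor_hazard: float = np.log(2) / 1200.0,
) -> tuple[ExpressionCohort, ClinicalTable, PlantedTruth]:
    """Generate a single-group treatment cohort with outcome-linked score.

    Expression follows the pan-tumor model with one group.  The probability
    of response is ``logistic(a - b * standardized score)`` where the score
    is the metagene score of ``signature`` (default: the planted signature
    genes), so a positive ``response_slope`` b concentrates responders in
    low-score samples.  Survival times are exponential with hazard
    ``lambda0 * exp(theta * standardized score)`` under independent
    exponential right-censoring.  Timing (pre/on) and cohort
    (Ipi-Naive/Ipi-Prog) labels are assigned round-robin.
    """
    if n_samples < 8:
        raise InvalidConfigError("n_samples must be >= 8 (quartiles undefined)")
    one_group = GeneratorConfig(**{
        **{f.name: getattr(cfg, f.name) for f in cfg.__dataclass_fields__.values()},
        "n_groups": 1, "samples_per_group": n_samples,
        "n_culprit_groups": min(cfg.n_culprit_groups, 1),
    })
    cohort, truth = generate_pan_tumor(one_group)
    if signature is None:
        signature = truth.signature
    missing = signature.members - set(cohort.gene_ids)
    if missing:
        raise InvalidConfigError(f"signature members absent from cohort: {sorted(missing)[:5]}")

    from .signatures import metagene_score  # local import avoids a cycle
    score = metagene_score(cohort, signature).scores
    zscore = (score - score.mean()) / score.std(ddof=0)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    p_resp = 1.0 / (1.0 + np.exp(-(response_intercept - response_slope * zscore)))
    responder = rng.random(n_samples) < p_resp

    # responders split CR:PR = 1:2, non-responders SD:PD = 1:2, deterministically
    response = np.empty(n_samples, dtype=object)
    response[responder] = [("CR" if i % 3 == 0 else "PR")
                           for i in range(int(responder.sum()))]
    response[~responder] = [("SD" if i % 3 == 0 else "PD")
                            for i in range(int((~responder).sum()))]

    rate = baseline_hazard * np.exp(hazard_slope * zscore)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / censor_hazard, size=n_samples)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    n = n_samples
    clinical = ClinicalTable(pd.DataFrame({
        "cohort": [("Ipi-Naive" if (i // 2) % 2 == 0 else "Ipi-Prog") for i in range(n)],
        "timing": [("pre" if i % 2 == 0 else "on") for i in range(n)],
        "response": response,
        "os_time": np.round(os_time, 1),
        "os_event": os_event,
    }, index=cohort.sample_ids))
    return cohort, clinical, truth
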