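"""Core domain types and plain-text I/O.

The universal input is an :class:`ExpressionCohort`: a genes x samples matrix
of log2(normalized count + 1) expression values together with a tumor-group
label per sample.  Gene sets travel as :class:`GeneSignature` objects (GMT
files on disk), and treatment cohorts carry a :class:`ClinicalTable` of
RECIST response categories and overall-survival columns.

All readers validate eagerly and raise the named errors in
:mod:`culprit.errors`; nothing is coerced silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateIdError,
    InvalidConfigError,
    MalformedGeneSetError,
    MalformedHeaderError,
    NonNumericValueError,
    UnannotatedSampleError,
)

logger = logging.getLogger(__name__)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
#: RECIST v1.1 categories: complete/partial response, stable/progressive
#: disease, not evaluable.

T_SIG = ("CD8A", "CD8B", "CD3D", "CD3E")
C_SIG = ("GZMA", "GZMB", "GNLY", "PRF1")


@dataclass
class ExpressionCohort:
    """Grouped log2-expression matrix (genes x samples).

    Parameters
    ----------
    values
        DataFrame of log2(normalized count + 1) values; index = gene ids,
        columns = sample ids.  All entries finite and >= 0.
    group_of
        Series mapping sample id -> tumor-group label, covering every column.
    """

    values: pd.DataFrame
    group_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DuplicateIdError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise DuplicateIdError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise NonNumericValueError("expression matrix contains non-numeric cells")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise NonNumericValueError(
                "expression values must be finite and >= 0 (log2(count+1) scale)"
            )
        self.group_of = self.group_of.reindex(self.values.columns)
        missing = self.group_of.index[self.group_of.isna()]
        if len(missing):
            raise UnannotatedSampleError(
                f"samples without a group label: {list(missing[:5])!r}"
            )
        sizes = self.group_of.value_counts()
        small = sizes[sizes < 2]
        if len(small):
            raise InvalidConfigError(
                f"every group needs >= 2 samples; too small: {dict(small)!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> list:
        """Group labels in first-appearance order over samples."""
        return list(dict.fromkeys(self.group_of))

    def samples_in_group(self, group) -> pd.Index:
        return self.group_of.index[self.group_of == group]

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionCohort":
        ids = pd.Index(sample_ids)
        return ExpressionCohort(self.values.loc[:, ids], self.group_of.loc[ids])

    def subset_genes(self, gene_ids: Sequence) -> "ExpressionCohort":
        return ExpressionCohort(self.values.loc[pd.Index(gene_ids)], self.group_of)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, e.g. the 4-gene CD8 T-cell identity metagene."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise InvalidConfigError(f"signature {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations for a treatment cohort."""

    table: pd.DataFrame  # columns: cohort, timing, response, os_time, os_event

    REQUIRED = ("cohort", "timing", "response", "os_time", "os_event")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise DuplicateIdError("duplicate sample ids in clinical table")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise MalformedHeaderError(f"clinical table missing columns {missing}")
        bad = set(self.table["response"]) - set(RESPONSE_CATEGORIES)
        if bad:
            raise NonNumericValueError(f"unknown response categories {sorted(bad)}")
        if (self.table["os_time"] < 0).any():
            raise NonNumericValueError("os_time must be >= 0")
        if not self.table["os_event"].isin([0, 1]).all():
            raise NonNumericValueError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def responders(self) -> pd.Series:
        """Boolean per evaluable sample: response in {CR, PR}.  NE dropped."""
        evaluable = self.table[self.table["response"] != "NE"]
        return evaluable["response"].isin(["CR", "PR"])


@dataclass
class AnalysisParams:
    """Tunable thresholds of the discovery pipeline.

    Defaults reproduce the published analysis: the top percentile
    (``top_fraction = 0.01``) of a 20,501-gene universe, MPR selection at
    median percentile rank >= 75 with median BH q <= 0.1 by both ranking
    methods, EBP selection at recurrence k >= 5 of 23 groups, and
    synexpression clusters at average Spearman correlation >= 0.15.
    """

    top_fraction: float = 0.01
    universe_size: int = 20501
    mpr_min: float = 75.0
    median_q_max: float = 0.1
    min_k: int = 5
    mutex_or_cutoff: float = -1.0  # log2 units
    mutex_q_cutoff: float = 1e-30
    synexpr_min_corr: float = 0.15
    fdr_method: str = "fdr_bh"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction < 1):
            raise InvalidConfigError("top_fraction must lie in (0, 1)")
        if self.universe_size < 1:
            raise InvalidConfigError("universe_size must be >= 1")
        if not (0 <= self.mpr_min <= 100):
            raise InvalidConfigError("mpr_min must lie in [0, 100]")
        for name in ("median_q_max", "mutex_or_cutoff", "mutex_q_cutoff",
                     "synexpr_min_corr"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidConfigError(f"{name} must be finite")

    @classmethod
    def from_config(cls, path) -> "AnalysisParams":
        """Load parameters from a YAML-style ``key: value`` config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def log2_transform(raw_counts) -> np.ndarray:
    """Map normalized counts x -> log2(x + 1), the pipeline's input scale."""
    arr = np.asarray(raw_counts, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise NonNumericValueError("raw counts must be finite and >= 0")
    return np.log2(arr + 1.0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path, annotation_path) -> ExpressionCohort:
    """Read a genes x samples expression TSV plus a sample-annotation TSV.

    The matrix file has a header row of sample ids with gene ids in the
    first column (Firebrowse Level-3 layout); the annotation file has
    columns ``sample_id`` and ``group``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MalformedHeaderError(f"cannot parse expression TSV {path}: {exc}")
    if df.columns.empty or df.index.name is None:
        raise MalformedHeaderError("expression TSV needs a gene-id column and sample header")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise DuplicateIdError(f"duplicate gene ids {list(dups[:5])!r}")
    nonnum = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if nonnum or df.isna().any().any():
        raise NonNumericValueError(f"non-numeric cells in columns {nonnum[:5]!r}")

    ann = pd.read_csv(annotation_path, sep="\t")
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise MalformedHeaderError("annotation TSV needs sample_id and group columns")
    if ann["sample_id"].duplicated().any():
        raise DuplicateIdError("duplicate sample ids in annotation")
    group_of = ann.set_index("sample_id")["group"]
    unannotated = df.columns.difference(group_of.index)
    if len(unannotated):
        raise UnannotatedSampleError(f"unannotated samples {list(unannotated[:5])!r}")
    return ExpressionCohort(df, group_of.reindex(df.columns))


def write_expression_tsv(cohort: ExpressionCohort, path, annotation_path) -> None:
    cohort.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6f")
    (cohort.group_of.rename("group").rename_axis("sample_id")
     .reset_index().to_csv(annotation_path, sep="\t", index=False))


def read_gene_sets_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file: ``name <tab> description <tab> member...`` per line."""
    out: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedGeneSetError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 member"
                )
            members = [m for m in parts[2:] if m]
            if len(set(members)) < len(members):
                logger.warning("GMT line %d (%s): duplicate members dropped",
                               lineno, parts[0])
            out.append(GeneSignature(parts[0], frozenset(members)))
    return out


def write_gene_sets_gmt(signatures: Iterable[GeneSignature], path,
                        description: str = "na") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sorted(sig.members)]) + "\n")


def read_clinical_tsv(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise MalformedHeaderError("clinical TSV needs a sample_id column")
    return ClinicalTable(df.set_index("sample_id"))


def write_clinical_tsv(clinical: ClinicalTable, path) -> None:
    clinical.table.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False)


def write_run_summary(path, **quantities) -> None:
    """Write a JSON summary of a pipeline run (scalar quantities only)."""
    with open(path, "w") as fh:
        json.dump(quantities, fh, indent=2, default=float)
        fh.write("\n")
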