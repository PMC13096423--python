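"""Core in-memory containers shared across the pipeline.

The central object is :class:`AnalyteTable`: a samples x analytes value
matrix with per-sample metadata (genotype, treatment, sex, tissue, plate,
sample role) and per-analyte metadata (analytical method, analyte kind,
class label). Study samples carry exactly one tissue; quality-control (QC)
and blank wells belong to a plate but to no experimental group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "APP/PS1")
TREATMENTS = ("vehicle", "FTY720")

#: The four experimental groups of the factorial genotype x treatment design.
GROUPS = (
    "WT-vehicle",
    "WT-FTY720",
    "APP/PS1-vehicle",
    "APP/PS1-FTY720",
)

SEXES = ("male", "female")

#: Sample roles: biological study samples, kit QC repeats, and blank wells.
ROLES = ("study", "qc", "blank")

#: Plate analytical methods (chromatography vs flow injection).
METHODS = ("UHPLC", "FIA")

#: Analyte kinds: directly measured metabolites vs calculated indicators.
KINDS = ("metabolite", "indicator")

SAMPLE_META_COLUMNS = (
    "subject",
    "genotype",
    "treatment",
    "group",
    "sex",
    "tissue",
    "plate",
    "role",
)

ANALYTE_META_COLUMNS = ("method", "kind", "class_label")


def group_label(genotype: str, treatment: str) -> str:
    """Group is a deterministic function of (genotype, treatment)."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if treatment not in TREATMENTS:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )
    return f"{genotype}-{treatment}"


class ValidationError(ValueError):
    """Raised when an input table or configuration violates the schema."""


@dataclass
class AnalyteTable:
    """Samples x analytes matrix plus sample and analyte metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per analyte. Missing
        values are allowed and are never silently imputed.
    sample_meta
        DataFrame indexed by sample id with columns
        ``subject, genotype, treatment, group, sex, tissue, plate, role``.
        QC/blank rows have NA group/genotype/treatment/sex/tissue.
    analyte_meta
        DataFrame indexed by analyte with columns ``method`` (UHPLC or
        FIA), ``kind`` (metabolite or indicator) and ``class_label``; may
        carry extra columns such as ``expected_qc``.
    provenance
        Free-form record of processing steps applied, including unscaled
        QC/blank values retained by plate normalization.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    analyte_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ValidationError("values and sample_meta must share the sample index")
        missing_cols = set(SAMPLE_META_COLUMNS) - set(self.sample_meta.columns)
        if missing_cols:
            raise ValidationError(f"sample_meta missing columns: {sorted(missing_cols)}")
        extra = set(self.values.columns) - set(self.analyte_meta.index)
        if extra:
            raise ValidationError(
                f"analyte_meta missing entries for analytes: {sorted(extra)[:5]}..."
                if len(extra) > 5
                else f"analyte_meta missing entries for analytes: {sorted(extra)}"
            )
        roles = self.sample_meta["role"]
        bad_roles = set(roles.unique()) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        study = self.sample_meta[roles == "study"]
        if study["tissue"].isna().any():
            raise ValidationError("study samples must carry a tissue label")
        # group must be consistent with genotype/treatment on study rows
        expected = study["genotype"].str.cat(study["treatment"], sep="-")
        mismatch = study.index[expected != study["group"]]
        if len(mismatch):
            raise ValidationError(
                f"group label inconsistent with genotype/treatment for {list(mismatch[:3])}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def analytes(self) -> pd.Index:
        return self.values.columns

    @property
    def tissues(self) -> list:
        t = self.sample_meta.loc[self.sample_meta["role"] == "study", "tissue"]
        return list(pd.unique(t))

    def study_mask(self) -> pd.Series:
        return self.sample_meta["role"] == "study"

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "AnalyteTable":
        return AnalyteTable(
            self.values.loc[mask].copy(),
            self.sample_meta.loc[mask].copy(),
            self.analyte_meta,
            dict(self.provenance),
        )

    def subset_analytes(self, analytes: Sequence[str]) -> "AnalyteTable":
        analytes = list(analytes)
        return AnalyteTable(
            self.values[analytes].copy(),
            self.sample_meta,
            self.analyte_meta.loc[analytes].copy(),
            dict(self.provenance),
        )

    def copy(self) -> "AnalyteTable":
        return AnalyteTable(
            self.values.copy(),
            self.sample_meta.copy(),
            self.analyte_meta.copy(),
            dict(self.provenance),
        )


@dataclass(frozen=True)
class IndicatorFormula:
    """A derived analyte: a sum over metabolites or a ratio of two sums.

    Indicators act as proxies for pathway or enzyme activity, e.g. a
    spermidine-synthesis indicator defined as the ratio
    spermidine / putrescine.
    """

    name: str
    kind: str  # "sum" or "ratio"
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("sum", "ratio"):
            raise ValidationError(f"indicator kind must be sum or ratio, got {self.kind!r}")
        if not self.numerator:
            raise ValidationError(f"indicator {self.name!r} has an empty numerator")
        if self.kind == "sum" and self.denominator:
            raise ValidationError(f"sum indicator {self.name!r} must have no denominator")
        if self.kind == "ratio" and not self.denominator:
            raise ValidationError(f"ratio indicator {self.name!r} needs a denominator")

    def components(self) -> tuple[str, ...]:
        return tuple(self.numerator) + tuple(self.denominator)


@dataclass
class LodTable:
    """Per-analyte limits of detection, 3x the median blank signal."""

    lod: pd.Series  # index analyte, values >= 0
    source_n_blanks: int

    def __post_init__(self) -> None:
        if (self.lod.dropna() < 0).any():
            raise ValidationError("LOD values must be non-negative")


def long_to_wide(
    long: pd.DataFrame,
    value_col: str = "value",
    sample_col: str = "sample_id",
    analyte_col: str = "analyte",
) -> pd.DataFrame:
    """Pivot a long (sample_id, analyte, value) table into samples x analytes."""
    return long.pivot(index=sample_col, columns=analyte_col, values=value_col)


def wide_to_long(
    values: pd.DataFrame,
    sample_col: str = "sample_id",
    analyte_col: str = "analyte",
    value_col: str = "value",
) -> pd.DataFrame:
    out = values.stack(future_stack=True).rename(value_col).reset_index()
    out.columns = [sample_col, analyte_col, value_col]
    return out.dropna(subset=[value_col]).reset_index(drop=True)
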