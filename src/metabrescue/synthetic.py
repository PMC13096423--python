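"""Synthetic study generator with planted, recoverable ground truth.

Emulates a four-group (genotype x treatment) mouse metabolomics study:
two sexes, up to six tissues, log-normal analyte abundances, plate
structure with QC and blank wells, limit-of-detection censoring, and
per-subject phenotype measures coupled to chosen analytes.

Effects are planted on the log scale in units of the analyte's log-scale
standard deviation, so a planted genotype effect of -1.0 means the
transgenic-vehicle group mean sits one reference SD below wild-type
vehicle. The drug arm moves the transgenic group back toward wild type
by ``correction_fraction`` of the genotype displacement, which is exactly
the quantity the rescue classifier estimates as percent correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    AnalyteTable,
    GROUPS,
    SEXES,
    ValidationError,
    group_label,
    wide_to_long,
)

DEFAULT_TISSUES = (
    "cerebellum",
    "frontal cortex",
    "parietal cortex",
    "temporal cortex",
    "liver",
    "plasma",
)


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the simulated study.

    Defaults mirror the scale of the emulated experiment: 4 groups x
    2 sexes x 6 mice, 6 tissues, 200 analytes, 2 plates with QC repeats
    and blanks on each.
    """

    n_per_group_per_sex: int = 6
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_metabolites: int = 200
    n_plates: int = 2
    qc_per_plate: int = 3
    blanks_per_plate: int = 3
    seed: int = 0
    fraction_uhplc: float = 0.3
    plate_bias_sd: float = 0.15  # log-normal sd of multiplicative plate bias
    plate_biases: tuple[float, ...] | None = None  # explicit override

    def __post_init__(self) -> None:
        for name in ("n_per_group_per_sex", "n_metabolites", "n_plates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.qc_per_plate < 0 or self.blanks_per_plate < 0:
            raise ValidationError("qc_per_plate and blanks_per_plate must be >= 0")
        if not self.tissues:
            raise ValidationError("tissues must be non-empty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValidationError("tissue labels must be unique")
        if self.plate_biases is not None and len(self.plate_biases) != self.n_plates:
            raise ValidationError("plate_biases must have one entry per plate")

    @property
    def n_subjects(self) -> int:
        return self.n_per_group_per_sex * len(GROUPS) * len(SEXES)


def analyte_names(n: int) -> list[str]:
    return [f"M{i:03d}" for i in range(n)]


@dataclass
class PlantedTruth:
    """Ground truth planted into the generated data.

    ``genotype_effect`` and ``correction_fraction`` map analyte -> effect,
    either a scalar applied in every tissue or a ``{tissue: value}``
    mapping. Genotype effects are in reference-SD units on the log scale;
    correction fractions are the fraction of the genotype displacement
    reverted in the drug arm (may exceed 1 = overcorrection, or be
    negative = worsening). ``sex_interaction`` plants opposite-sign
    genotype shifts by sex (+s in males, -s in females), so a sex x group
    regression interaction recovers 2s. ``phenotype_loadings`` couple a
    per-subject phenotype measure to standardized analyte values in
    ``phenotype_tissue`` (default: first design tissue); with loading w and
    noise SD sigma the planted Pearson correlation is w / sqrt(w^2 + sigma^2).
    """

    genotype_effect: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    correction_fraction: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    sex_interaction: Mapping[str, float] = field(default_factory=dict)
    phenotype_loadings: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    phenotype_tissue: Mapping[str, str] = field(default_factory=dict)
    lod_censor_fraction: float = 0.0
    phenotype_noise_sd: float = 0.5
    sub_lod_policy: str = "draw"  # "draw" (truncated low-signal) or "zero"

    def __post_init__(self) -> None:
        if not 0 <= self.lod_censor_fraction < 1:
            raise ValidationError("lod_censor_fraction must be in [0, 1)")
        if self.sub_lod_policy not in ("draw", "zero"):
            raise ValidationError("sub_lod_policy must be 'draw' or 'zero'")

    def validate_against(self, design: StudyDesign) -> None:
        names = set(analyte_names(design.n_metabolites))
        tissues = set(design.tissues)
        for label, mapping in (
            ("genotype_effect", self.genotype_effect),
            ("correction_fraction", self.correction_fraction),
            ("sex_interaction", self.sex_interaction),
        ):
            for analyte, val in mapping.items():
                if analyte not in names:
                    raise ValidationError(f"{label} references unknown analyte {analyte!r}")
                if isinstance(val, Mapping):
                    unknown = set(val) - tissues
                    if unknown:
                        raise ValidationError(
                            f"{label}[{analyte!r}] references unknown tissues {sorted(unknown)}"
                        )
        for measure, loadings in self.phenotype_loadings.items():
            for analyte in loadings:
                if analyte not in names:
                    raise ValidationError(
                        f"phenotype_loadings[{measure!r}] references unknown analyte {analyte!r}"
                    )
            tissue = self.phenotype_tissue.get(measure)
            if tissue is not None and tissue not in tissues:
                raise ValidationError(
                    f"phenotype_tissue[{measure!r}] references unknown tissue {tissue!r}"
                )

    def effect_matrix(self, attr: str, design: StudyDesign) -> pd.DataFrame:
        """Expand a per-analyte (possibly per-tissue) map to analytes x tissues."""
        names = analyte_names(design.n_metabolites)
        out = pd.DataFrame(0.0, index=names, columns=list(design.tissues))
        for analyte, val in getattr(self, attr).items():
            if isinstance(val, Mapping):
                for tissue, v in val.items():
                    out.loc[analyte, tissue] = float(v)
            else:
                out.loc[analyte, :] = float(val)
        return out


@dataclass
class SyntheticStudy:
    """Generated study: analyte table, per-subject phenotypes, echoed truth."""

    table: AnalyteTable
    phenotypes: pd.DataFrame  # index subject; group/genotype/treatment/sex + measures
    truth: PlantedTruth
    design: StudyDesign
    lod_targets: pd.Series  # per-analyte censoring threshold used at generation


def _subject_frame(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for genotype, treatment in (
        ("WT", "vehicle"),
        ("WT", "FTY720"),
        ("APP/PS1", "vehicle"),
        ("APP/PS1", "FTY720"),
    ):
        for sex in SEXES:
            for _ in range(design.n_per_group_per_sex):
                rows.append(
                    {
                        "subject": f"m{i:03d}",
                        "genotype": genotype,
                        "treatment": treatment,
                        "group": group_label(genotype, treatment),
                        "sex": sex,
                    }
                )
                i += 1
    return pd.DataFrame(rows).set_index("subject")


def generate_blanks_and_qc(
    design: StudyDesign,
    *,
    rng: np.random.Generator | None = None,
    plate_biases: np.ndarray | None = None,
    expected_qc: pd.Series | None = None,
    blank_level: pd.Series | None = None,
) -> AnalyteTable:
    """Generate the QC and blank wells of every plate.

    QC signals scatter tightly around ``expected_qc x plate bias`` so that
    per-plate QC medians expose the bias that plate normalization must
    remove. Blank signals are low-level background around ``blank_level``,
    also scaled by the plate bias (background scales with instrument
    response), so LODs derived from normalized blanks are cross-plate
    consistent.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    names = analyte_names(design.n_metabolites)
    if plate_biases is None:
        plate_biases = _plate_biases(design, rng)
    if expected_qc is None:
        expected_qc = pd.Series(np.exp(rng.normal(3.0, 1.0, design.n_metabolites)), index=names)
    if blank_level is None:
        blank_level = expected_qc * 0.01

    rows, metas = [], []
    for p in range(design.n_plates):
        bias = plate_biases[p]
        for j in range(design.qc_per_plate):
            vals = expected_qc.to_numpy() * bias * np.exp(rng.normal(0, 0.05, len(names)))
            rows.append(vals)
            metas.append((f"QC_p{p}_{j}", p, "qc"))
        for j in range(design.blanks_per_plate):
            # tight background scatter keeps the realized 3x-median LOD close
            # to the planted censoring threshold
            vals = blank_level.to_numpy() * bias * np.exp(rng.normal(0, 0.05, len(names)))
            rows.append(vals)
            metas.append((f"BLANK_p{p}_{j}", p, "blank"))

    index = [m[0] for m in metas]
    values = pd.DataFrame(rows, index=index, columns=names)
    sample_meta = pd.DataFrame(
        {
            "subject": pd.NA,
            "genotype": pd.NA,
            "treatment": pd.NA,
            "group": pd.NA,
            "sex": pd.NA,
            "tissue": pd.NA,
            "plate": [m[1] for m in metas],
            "role": [m[2] for m in metas],
        },
        index=index,
    )
    analyte_meta = _analyte_meta(design, expected_qc)
    return AnalyteTable(values, sample_meta, analyte_meta)


def _plate_biases(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    if design.plate_biases is not None:
        return np.asarray(design.plate_biases, dtype=float)
    return np.exp(rng.normal(0.0, design.plate_bias_sd, design.n_plates))


def _analyte_meta(design: StudyDesign, expected_qc: pd.Series) -> pd.DataFrame:
    names = analyte_names(design.n_metabolites)
    n_uhplc = int(round(design.fraction_uhplc * design.n_metabolites))
    methods = ["UHPLC"] * n_uhplc + ["FIA"] * (design.n_metabolites - n_uhplc)
    return pd.DataFrame(
        {
            "method": methods,
            "kind": "metabolite",
            "class_label": ["small molecule"] * n_uhplc
            + ["lipid"] * (design.n_metabolites - n_uhplc),
            "expected_qc": expected_qc.reindex(names).to_numpy(),
        },
        index=pd.Index(names, name="analyte"),
    )


def generate_study(design: StudyDesign, truth: PlantedTruth) -> SyntheticStudy:
    """Generate one full study: analyte table + phenotypes + echoed truth.

    Deterministic: the same (design, truth) pair always yields bitwise
    identical tables. One study row per subject per tissue, plus QC and
    blank rows per plate.
    """
    truth.validate_against(design)
    rng = np.random.default_rng(design.seed)
    names = analyte_names(design.n_metabolites)
    tissues = list(design.tissues)
    subjects = _subject_frame(design, rng)
    n_subj = len(subjects)

    # per-analyte baseline abundance and dispersion on the log scale
    log_mean = rng.normal(3.0, 1.0, design.n_metabolites)
    log_sd = rng.uniform(0.2, 0.6, design.n_metabolites)
    expected_qc = pd.Series(np.exp(log_mean), index=names)
    plate_biases = _plate_biases(design, rng)

    gen_fx = truth.effect_matrix("genotype_effect", design)
    corr_frac = truth.effect_matrix("correction_fraction", design)
    sex_fx = pd.Series(
        {a: float(v) for a, v in truth.sex_interaction.items()}, dtype=float
    ).reindex(names, fill_value=0.0)

    is_app = (subjects["genotype"] == "APP/PS1").to_numpy()
    is_fty = (subjects["treatment"] == "FTY720").to_numpy()
    sex_sign = np.where(subjects["sex"].to_numpy() == "male", 1.0, -1.0)

    # clean per-(subject, tissue, analyte) log values, before plate bias/censoring
    log_values: dict[str, np.ndarray] = {}
    for t in tissues:
        shift = np.zeros((n_subj, design.n_metabolites))
        g = gen_fx[t].to_numpy()  # per-analyte genotype effect in this tissue
        c = corr_frac[t].to_numpy()
        # transgenic groups: vehicle gets the full genotype shift, the drug
        # arm keeps (1 - correction_fraction) of it
        shift[is_app & ~is_fty] = g
        shift[is_app & is_fty] = (1.0 - c) * g
        # sex-dependent genotype modifier: +s males, -s females, transgenics only
        shift[is_app] += np.outer(sex_sign[is_app], sex_fx.to_numpy())
        noise = rng.normal(0.0, 1.0, (n_subj, design.n_metabolites))
        log_values[t] = log_mean + log_sd * (shift + noise)

    # assemble study rows
    study_ids, study_meta_rows, study_vals = [], [], []
    for t_idx, t in enumerate(tissues):
        plate_of = rng.permuted(np.arange(n_subj) % design.n_plates)
        for s_idx, (subj, row) in enumerate(subjects.iterrows()):
            study_ids.append(f"{subj}_t{t_idx}")
            study_meta_rows.append(
                {
                    "subject": subj,
                    "genotype": row["genotype"],
                    "treatment": row["treatment"],
                    "group": row["group"],
                    "sex": row["sex"],
                    "tissue": t,
                    "plate": int(plate_of[s_idx]),
                    "role": "study",
                }
            )
            study_vals.append(np.exp(log_values[t][s_idx]))
    study_values = pd.DataFrame(np.asarray(study_vals), index=study_ids, columns=names)
    study_meta = pd.DataFrame(study_meta_rows, index=study_ids)

    # censoring threshold per analyte: the planted quantile of clean study values
    if truth.lod_censor_fraction > 0:
        lod_targets = study_values.quantile(truth.lod_censor_fraction)
    else:
        # negligible threshold far below the data so nothing is censored
        lod_targets = study_values.min() * 1e-3
    lod_targets.name = "lod_target"

    below = study_values.lt(lod_targets, axis=1)
    if truth.lod_censor_fraction > 0 and below.to_numpy().any():
        if truth.sub_lod_policy == "zero":
            study_values = study_values.mask(below, 0.0)
        else:
            # sub-LOD wells still produce a weak signal: truncated uniform draw
            sub = rng.uniform(0.2, 1.0, study_values.shape) * lod_targets.to_numpy()
            study_values = study_values.mask(below, pd.DataFrame(sub, index=study_values.index, columns=names))

    # plate bias applies to every well on the plate
    bias_per_row = plate_biases[study_meta["plate"].to_numpy()]
    study_values = study_values.mul(bias_per_row, axis=0)

    qc_blank = generate_blanks_and_qc(
        design,
        rng=rng,
        plate_biases=plate_biases,
        expected_qc=expected_qc,
        blank_level=lod_targets / 3.0,
    )

    values = pd.concat([study_values, qc_blank.values])
    sample_meta = pd.concat([study_meta, qc_blank.sample_meta])
    table = AnalyteTable(values, sample_meta, _analyte_meta(design, expected_qc))

    phenotypes = _generate_phenotypes(design, truth, subjects, log_values, log_sd, rng)

    return SyntheticStudy(table, phenotypes, truth, design, lod_targets)


def _generate_phenotypes(
    design: StudyDesign,
    truth: PlantedTruth,
    subjects: pd.DataFrame,
    log_values: Mapping[str, np.ndarray],
    log_sd: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotype = sum of loadings x standardized coupled analytes + noise."""
    names = analyte_names(design.n_metabolites)
    out = subjects.copy()
    for measure, loadings in truth.phenotype_loadings.items():
        tissue = truth.phenotype_tissue.get(measure, design.tissues[0])
        mat = log_values[tissue]
        signal = np.zeros(len(subjects))
        for analyte, w in loadings.items():
            col = mat[:, names.index(analyte)]
            z = (col - col.mean()) / col.std(ddof=0)
            signal += float(w) * z
        out[measure] = signal + rng.normal(0.0, truth.phenotype_noise_sd, len(subjects))
    return out


# -- serialization -------------------------------------------------------------

LONG_COLUMNS = ("sample_id", "tissue", "analyte", "value")


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study as stable long-format TSVs plus a truth JSON.

    Files: ``values.tsv`` (sample_id, tissue, analyte, value),
    ``sample_meta.tsv``, ``analyte_meta.tsv``, ``phenotypes.tsv``,
    ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = wide_to_long(study.table.values)
    long.insert(
        1, "tissue", study.table.sample_meta["tissue"].reindex(long["sample_id"]).to_numpy()
    )
    paths = {
        "values": outdir / "values.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "analyte_meta": outdir / "analyte_meta.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    long.to_csv(paths["values"], sep="\t", index=False)
    study.table.sample_meta.rename_axis("sample_id").to_csv(paths["sample_meta"], sep="\t")
    study.table.analyte_meta.rename_axis("analyte").to_csv(paths["analyte_meta"], sep="\t")
    study.phenotypes.rename_axis("subject").to_csv(paths["phenotypes"], sep="\t")
    truth_dict = asdict(study.truth)
    truth_dict["design"] = asdict(study.design)
    paths["truth"].write_text(json.dumps(truth_dict, indent=2, default=list))
    return paths


def read_study_tables(indir: str | Path) -> AnalyteTable:
    """Read back the TSVs written by :func:`write_study`."""
    indir = Path(indir)
    long = pd.read_csv(indir / "values.tsv", sep="\t")
    values = long.pivot(index="sample_id", columns="analyte", values="value")
    sample_meta = pd.read_csv(indir / "sample_meta.tsv", sep="\t", index_col="sample_id")
    analyte_meta = pd.read_csv(indir / "analyte_meta.tsv", sep="\t", index_col="analyte")
    values = values.reindex(sample_meta.index)
    return AnalyteTable(values, sample_meta, analyte_meta)
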