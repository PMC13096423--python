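"""End-to-end orchestration: simulate -> preprocess -> statistics -> reports.

`RunConfig` holds every threshold the analysis uses (FDR 0.05, nominal p
0.05, 50% correction, 50% consistency, top-10, fence k = 3, LOD
multiplier 3), all overridable; the config and seed are serialized into
the output directory so the manifest alone reproduces a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import ContrastSpec, run_differential
from .integration import phenotype_cross_correlation, score_analytes, top_k_report
from .io import read_formulas, write_table_tsv
from .phenotype_stats import phenotype_auc_table, phenotype_group_tests
from .preprocess import PreprocessConfig, run_preprocessing
from .rescue import classify_rescue
from .synthetic import PlantedTruth, StudyDesign, generate_study, write_study
from .tables import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration with the analysis defaults."""

    outdir: str = "metabrescue_run"
    seed: int = 0
    # synthetic design (used when no input tables are given)
    design: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    # inputs (optional; override simulation)
    values_path: str | None = None
    sample_meta_path: str | None = None
    analyte_meta_path: str | None = None
    phenotype_path: str | None = None
    formula_registry: str | None = None
    # thresholds
    fdr_threshold: float = 0.05
    p_threshold: float = 0.05
    correction_threshold_pct: float = 50.0
    consistency_fraction: float = 0.5
    top_k: int = 10
    fence_k: float = 3.0
    lod_multiplier: float = 3.0
    boxcox_lambda_grid: tuple[float, float, float] = (-3.0, 3.0, 0.01)
    reference_group: str = "WT-vehicle"
    shift_policy: str = "shift"
    quartile_method: str = "linear"
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate",
        "preprocess",
        "differential",
        "rescue",
        "integrate",
        "phenotype",
    )
    phenotype_measures: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "phenotype_measures" in raw:
            raw["phenotype_measures"] = tuple(raw["phenotype_measures"])
        if "boxcox_lambda_grid" in raw:
            raw["boxcox_lambda_grid"] = tuple(raw["boxcox_lambda_grid"])
        return cls(**raw)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            lod_multiplier=self.lod_multiplier,
            boxcox_lambda_grid=self.boxcox_lambda_grid,
            fence_k=self.fence_k,
            shift_policy=self.shift_policy,
            quartile_method=self.quartile_method,
            reference_group=self.reference_group,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def render_forest_table(results: pd.DataFrame) -> pd.DataFrame:
    """Tabular analogue of a forest plot: one row per analyte x tissue
    with the coefficient, CI and a significance marker (FDR / p / ns)."""
    out = results.copy()

    def marker(row):
        if pd.notna(row.get("q")) and row["q"] <= 0.05:
            return "FDR"
        if pd.notna(row.get("p")) and row["p"] <= 0.05:
            return "p"
        return "ns"

    out["significance"] = out.apply(marker, axis=1)
    cols = [
        "analyte", "tissue", "contrast", "beta", "ci95_low", "ci95_high",
        "p", "q", "significance", "n_used",
    ]
    return out[[c for c in cols if c in out.columns]]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the toggled stages and write all outputs.

    Outputs: stage TSVs, a run log, and ``manifest.json`` with package
    version, seed and config hash. Deterministic: the same config + seed
    produce byte-identical tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    if "integrate" in config.stages and "simulate" not in config.stages and not config.phenotype_path:
        raise ValidationError(
            "integrate stage enabled but no phenotype table configured"
        )

    phenotypes = None
    if "simulate" in config.stages:
        design = StudyDesign(seed=config.seed, **config.design)
        truth = PlantedTruth(**config.truth)
        study = generate_study(design, truth)
        write_study(study, outdir / "synthetic")
        table = study.table
        phenotypes = study.phenotypes
        log_lines.append(f"simulate: {table.values.shape[0]} wells x {table.values.shape[1]} analytes")
    else:
        from .io import read_analyte_table

        if not (config.values_path and config.sample_meta_path and config.analyte_meta_path):
            raise ValidationError("input table paths required when simulate is disabled")
        table = read_analyte_table(
            config.values_path, config.sample_meta_path, config.analyte_meta_path
        )
        if config.phenotype_path:
            phenotypes = pd.read_csv(config.phenotype_path, sep="\t", index_col=0)
        log_lines.append("inputs: tables loaded")

    formulas = read_formulas(config.formula_registry) if config.formula_registry else []

    processed = table
    if "preprocess" in config.stages:
        result = run_preprocessing(table, formulas, config.preprocess_config())
        processed = result.table
        write_table_tsv(result.removed.reset_index(), outdir / "lod_removal_report.tsv")
        write_table_tsv(
            result.boxcox_lambdas.rename_axis("analyte").reset_index(),
            outdir / "boxcox_lambdas.tsv",
        )
        log_lines.extend(result.log)

    if "differential" in config.stages:
        from .differential import DRUG_CONTRAST, GENOTYPE_CONTRAST

        results = run_differential(processed, [GENOTYPE_CONTRAST, DRUG_CONTRAST])
        write_table_tsv(results, outdir / "differential_results.tsv")
        forest = render_forest_table(results)
        if forest.empty:
            (outdir / "forest_table.tsv").write_text("# no rows\n")
        else:
            write_table_tsv(forest, outdir / "forest_table.tsv")
        log_lines.append(f"differential: {len(results)} fitted rows")

    if "rescue" in config.stages:
        calls = classify_rescue(
            processed,
            fdr_threshold=config.fdr_threshold,
            p_threshold=config.p_threshold,
            improvement_threshold=config.correction_threshold_pct,
        )
        write_table_tsv(calls, outdir / "rescue_calls.tsv")
        log_lines.append(f"rescue: {len(calls)} calls")

    measures = list(config.phenotype_measures)
    if phenotypes is not None and not measures:
        skip = {"subject", "genotype", "treatment", "group", "sex"}
        measures = [c for c in phenotypes.columns if c not in skip]

    if "integrate" in config.stages:
        if phenotypes is None or not measures:
            raise ValidationError("integrate stage needs a phenotype table with measures")
        all_scores = []
        for m in measures:
            scores = score_analytes(
                processed, phenotypes, m,
                top_k=config.top_k, consistency_fraction=config.consistency_fraction,
            )
            all_scores.append(scores)
            write_table_tsv(top_k_report(scores, config.top_k), outdir / f"top{config.top_k}_{m}.tsv")
        scores_df = pd.concat(all_scores, ignore_index=True)
        write_table_tsv(scores_df, outdir / "correspondence_scores.tsv")
        if len(measures) > 1:
            write_table_tsv(
                phenotype_cross_correlation(phenotypes, measures),
                outdir / "phenotype_cross_correlation.tsv",
            )
        log_lines.append(f"integrate: {len(scores_df)} scored rows over {len(measures)} measure(s)")

    if "phenotype" in config.stages and phenotypes is not None and measures:
        tests = phenotype_group_tests(phenotypes, measures)
        write_table_tsv(tests, outdir / "phenotype_welch_tests.tsv")
        aucs = phenotype_auc_table(phenotypes, measures)
        write_table_tsv(aucs, outdir / "phenotype_auc.tsv")
        log_lines.append(
            f"phenotype: {len(tests)} Welch comparisons, {len(aucs)} AUC rows"
        )

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = {
        "package": "metabrescue",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages_run": list(config.stages),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    return outdir
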