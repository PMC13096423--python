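"""Preprocessing: raw plate signals -> analysis-ready standardized table.

Stage order is fixed and logged:

1. plate normalization against QC medians,
2. LOD computation from blanks and the below-LOD filter,
3. indicator computation (sums and ratios of metabolites),
4. Box-Cox transformation per analyte per tissue,
5. Tukey fencing of remote outliers (winsorization, k = 3),
6. standardization to the reference group (WT-vehicle by default).

Missing values are carried through, never imputed; downstream models use
complete cases per analyte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import AnalyteTable, IndicatorFormula, LodTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing choices.

    shift_policy
        How to handle nonpositive values before Box-Cox: "shift" adds half
        the smallest positive observed value, "error" raises.
    quartile_method
        Quartile convention for Tukey fencing; "linear" interpolates
        between order statistics (numpy's default percentile method).
    """

    lod_multiplier: float = 3.0
    lod_filter_fraction: float = 0.5  # strict: removed iff fraction > this in ALL subgroups
    boxcox_lambda_grid: tuple[float, float, float] = (-3.0, 3.0, 0.01)
    shift_policy: str = "shift"  # "shift" | "error"
    fence_k: float = 3.0
    quartile_method: str = "linear"
    reference_group: str = "WT-vehicle"

    def lambda_grid(self) -> np.ndarray:
        lo, hi, step = self.boxcox_lambda_grid
        return np.arange(lo, hi + step / 2, step)


@dataclass
class PreprocessResult:
    table: AnalyteTable  # study rows only, standardized values
    lods: LodTable
    removed: pd.DataFrame  # removal report: analyte x subgroup below-LOD fractions
    boxcox_lambdas: pd.DataFrame  # analyte x tissue lambda estimates
    skipped_indicators: list[str]
    log: list[str] = field(default_factory=list)


# -- plate normalization -------------------------------------------------------


def normalize_plates(
    table: AnalyteTable, expected_qc: pd.Series | None = None
) -> AnalyteTable:
    """Scale each plate so its per-analyte QC median maps to the expected
    QC concentration. The same linear factor is applied to every well on
    the plate, which also converts signals to concentration scale. Raw
    QC/blank values are kept in the provenance record.

    A plate without a usable QC value for an analyte gets that analyte
    flagged missing on that plate (with a logged warning).
    """
    if expected_qc is None:
        if "expected_qc" not in table.analyte_meta.columns:
            raise ValidationError(
                "expected QC concentrations required: pass expected_qc or add an "
                "'expected_qc' column to analyte_meta"
            )
        expected_qc = table.analyte_meta["expected_qc"]
    expected_qc = expected_qc.reindex(table.analytes)

    out = table.copy()
    qc_mask = table.sample_meta["role"] == "qc"
    blank_mask = table.sample_meta["role"] == "blank"
    out.provenance["raw_qc_blank"] = table.values.loc[qc_mask | blank_mask].copy()

    plates = table.sample_meta["plate"].dropna().unique()
    for p in plates:
        on_plate = table.sample_meta["plate"] == p
        qc_vals = table.values.loc[on_plate & qc_mask]
        if qc_vals.empty:
            raise ValidationError(f"plate {p!r} has no QC samples; cannot normalize")
        qc_median = qc_vals.median()
        factor = qc_median / expected_qc  # divide out the plate bias
        unusable = ~np.isfinite(factor) | (factor <= 0)
        if unusable.any():
            bad = list(factor.index[unusable])
            logger.warning(
                "plate %s: no usable QC for %d analyte(s) (%s...); flagged missing",
                p,
                len(bad),
                bad[:3],
            )
            out.values.loc[on_plate, bad] = np.nan
            factor = factor.mask(unusable, 1.0)
        out.values.loc[on_plate] = out.values.loc[on_plate].div(factor, axis=1)
    out.provenance.setdefault("stages", []).append("normalize_plates")
    return out


# -- LOD -----------------------------------------------------------------------


def compute_lod(
    blank_signals: pd.DataFrame | dict[str, Sequence[float]],
    multiplier: float = 3.0,
) -> LodTable:
    """LOD per analyte = multiplier x median blank signal (default 3x)."""
    if isinstance(blank_signals, dict):
        blank_signals = pd.DataFrame(
            {k: pd.Series(v, dtype=float) for k, v in blank_signals.items()}
        )
    if blank_signals.empty or blank_signals.shape[0] == 0:
        raise ValidationError("no blank samples available to compute LODs")
    counts = blank_signals.notna().sum()
    if (counts == 0).any():
        missing = list(counts.index[counts == 0])
        raise ValidationError(f"no blank values for analytes: {missing[:5]}")
    lod = multiplier * blank_signals.median()
    return LodTable(lod=lod, source_n_blanks=int(blank_signals.shape[0]))


def lod_from_table(table: AnalyteTable, multiplier: float = 3.0) -> LodTable:
    blanks = table.values.loc[table.sample_meta["role"] == "blank"]
    return compute_lod(blanks, multiplier)


def filter_below_lod(
    table: AnalyteTable,
    lods: LodTable,
    subgroup_keys: Sequence[str] = ("tissue", "group"),
    fraction: float = 0.5,
) -> tuple[AnalyteTable, pd.DataFrame]:
    """Remove metabolites with more than ``fraction`` of values strictly
    below LOD in *every* subgroup; surviving below-LOD values are left
    unchanged (they remain the best relative estimate of the true value).

    The boundary is strict: exactly 50% below LOD in all subgroups retains
    the analyte. Returns the filtered table and a per-subgroup report.
    """
    unknown = set(subgroup_keys) - set(table.sample_meta.columns)
    if unknown:
        raise ValidationError(f"unknown subgroup keys: {sorted(unknown)}")
    missing_lod = set(table.analytes) - set(lods.lod.index)
    if missing_lod:
        raise ValidationError(f"LOD undefined for analytes: {sorted(missing_lod)[:5]}")

    study = table.values.loc[table.study_mask()]
    meta = table.sample_meta.loc[table.study_mask()]
    below = study.lt(lods.lod.reindex(study.columns), axis=1)

    keys = meta[list(subgroup_keys)].astype(str).agg("|".join, axis=1)
    frac_below = below.groupby(keys).mean()  # subgroup x analyte
    # count only subgroups where the analyte was observed at all
    observed = study.notna().groupby(keys).sum() > 0
    exceeds = frac_below.gt(fraction) | ~observed
    remove = exceeds.all(axis=0) & observed.any(axis=0)

    removed_analytes = list(remove.index[remove])
    report = frac_below.T
    report.index.name = "analyte"
    report["removed"] = remove
    if removed_analytes:
        logger.info("LOD filter removed %d analyte(s)", len(removed_analytes))
    kept = [a for a in table.analytes if a not in removed_analytes]
    return table.subset_analytes(kept), report


# -- indicators ----------------------------------------------------------------


def compute_indicators(
    table: AnalyteTable, formulas: Iterable[IndicatorFormula]
) -> tuple[AnalyteTable, list[str]]:
    """Append one derived analyte per formula.

    Sums: missing component => missing result. Ratios: numerator-sum over
    denominator-sum, missing when the denominator is zero (ratios with
    zeros are treated as missing and excluded from models). Formulas whose
    components are absent (e.g. filtered out) are skipped with a warning.

    Indicators inherit plate normalization automatically because they are
    computed from already-normalized component values; their method label
    is the majority method of their components and their kind is
    "indicator".
    """
    out = table.copy()
    skipped: list[str] = []
    new_cols: dict[str, pd.Series] = {}
    new_meta: list[dict] = []
    for f in formulas:
        missing = [c for c in f.components() if c not in table.analytes]
        if missing:
            logger.warning("indicator %r skipped: missing components %s", f.name, missing)
            skipped.append(f.name)
            continue
        num = table.values[list(f.numerator)].sum(axis=1, min_count=len(f.numerator))
        if f.kind == "sum":
            vals = num
        else:
            den = table.values[list(f.denominator)].sum(axis=1, min_count=len(f.denominator))
            vals = num / den.where(den != 0)
        methods = table.analyte_meta.loc[list(f.components()), "method"]
        new_cols[f.name] = vals
        new_meta.append(
            {
                "analyte": f.name,
                "method": methods.mode().iloc[0],
                "kind": "indicator",
                "class_label": "indicator",
            }
        )
    if new_cols:
        out.values = pd.concat([out.values, pd.DataFrame(new_cols)], axis=1)
        meta_add = pd.DataFrame(new_meta).set_index("analyte")
        out.analyte_meta = pd.concat([out.analyte_meta, meta_add])
    out.provenance.setdefault("stages", []).append("compute_indicators")
    return out, skipped


# -- Box-Cox -------------------------------------------------------------------


def _boxcox_llf_grid(x: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox model at each candidate lambda.

    llf(lam) = (lam - 1) * sum(log x) - n/2 * log(var(y_lam)), evaluated
    for the whole grid in one vectorized pass (agrees with
    scipy.stats.boxcox_llf evaluated pointwise).
    """
    n = len(x)
    logx = np.log(x)
    sum_logx = logx.sum()
    # y has shape (n, L); the lam == 0 column is the log transform
    with np.errstate(over="ignore", invalid="ignore"):
        y = np.where(
            np.abs(lambdas) < 1e-12,
            logx[:, None],
            (np.exp(np.outer(logx, lambdas)) - 1.0) / np.where(np.abs(lambdas) < 1e-12, 1.0, lambdas),
        )
    var = y.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        llf = (lambdas - 1.0) * sum_logx - n / 2.0 * np.log(var)
    return np.where(np.isfinite(llf), llf, -np.inf)


def boxcox_transform(
    values: pd.Series | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    shift_policy: str = "shift",
    name: str = "",
) -> tuple[pd.Series, float]:
    """Power-transform toward normality; lambda by profile likelihood on a
    fixed grid (default -3..3, step 0.01).

    y -> (y^lambda - 1)/lambda for lambda != 0, log(y) at lambda = 0. The
    transform is monotone, so ranks are preserved. Nonpositive values are
    shifted by half the smallest positive observed value under the default
    policy, or raise under policy "error".
    """
    if lambda_grid is None:
        lambda_grid = PreprocessConfig().lambda_grid()
    x = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    obs = x.dropna()
    if len(obs) < 5:
        raise ValidationError(f"Box-Cox needs >= 5 non-missing values ({name or 'input'})")
    if (obs <= 0).any():
        if shift_policy == "error":
            raise ValidationError(
                f"nonpositive values encountered before Box-Cox ({name or 'input'})"
            )
        positive = obs[obs > 0]
        if positive.empty:
            raise ValidationError(f"no positive values to anchor the shift ({name or 'input'})")
        shift = positive.min() / 2 - obs.min()
        obs = obs + shift
        x = x + shift
    lam_hat = float(lambda_grid[int(np.argmax(_boxcox_llf_grid(obs.to_numpy(), lambda_grid)))])
    if abs(lam_hat) < 1e-12:
        transformed = np.log(x)
        lam_hat = 0.0
    else:
        transformed = (np.power(x, lam_hat) - 1.0) / lam_hat
    return transformed, lam_hat


# -- Tukey fencing -------------------------------------------------------------


def tukey_fence(
    values: pd.Series | np.ndarray,
    k: float = 3.0,
    quartile_method: str = "linear",
) -> pd.Series:
    """Clamp remote outliers to Q1 - k*IQR / Q3 + k*IQR (winsorization).

    Outliers are adjusted to the fence rather than removed: this protects
    group means from extreme values without the variance loss of outright
    removal. With IQR = 0 all values are left untouched. Idempotent.
    """
    x = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    obs = x.dropna()
    if len(obs) < 4:
        return x
    q1, q3 = np.percentile(obs, [25, 75], method=quartile_method)
    iqr = q3 - q1
    if iqr == 0:
        return x
    return x.clip(lower=q1 - k * iqr, upper=q3 + k * iqr)


# -- standardization -----------------------------------------------------------


def standardize(
    values: pd.Series | np.ndarray,
    reference_mask: pd.Series | np.ndarray,
    name: str = "",
) -> pd.Series:
    """z = (y - mean_ref) / sd_ref, so values are in reference-group SD
    units and the reference subset has mean 0 and SD 1 exactly."""
    x = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    mask = np.asarray(reference_mask, dtype=bool)
    ref = x[mask].dropna()
    if len(ref) < 2:
        raise ValidationError(f"reference group needs >= 2 non-missing values ({name})")
    sd = ref.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError(f"reference group SD is zero ({name})")
    return (x - ref.mean()) / sd


# -- full pipeline -------------------------------------------------------------


def run_preprocessing(
    table: AnalyteTable,
    formulas: Iterable[IndicatorFormula] = (),
    config: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Apply the full stage chain and return the standardized study table.

    Box-Cox, fencing and standardization run per analyte per tissue on
    study samples only (tissues are analyzed separately throughout).
    Analytes whose reference group degenerates in a tissue (zero SD, too
    few values) are flagged non-analyzable there: their values for that
    tissue become missing, with the reason logged.
    """
    config = config or PreprocessConfig()
    log: list[str] = []

    normalized = normalize_plates(table)
    log.append("normalize_plates: QC-median scaling applied")

    lods = lod_from_table(normalized, config.lod_multiplier)
    filtered, report = filter_below_lod(
        normalized, lods, ("tissue", "group"), config.lod_filter_fraction
    )
    n_removed = int(report["removed"].sum())
    log.append(f"filter_below_lod: removed {n_removed} analyte(s)")

    with_ind, skipped = compute_indicators(filtered, formulas)
    log.append(f"compute_indicators: added {len(with_ind.analytes) - len(filtered.analytes)}, skipped {len(skipped)}")

    study = with_ind.subset_samples(with_ind.study_mask())
    grid = config.lambda_grid()
    tissues = study.tissues
    lambdas = pd.DataFrame(np.nan, index=study.analytes, columns=tissues)
    values = study.values.copy()
    ref_mask_all = study.sample_meta["group"] == config.reference_group

    for t in tissues:
        in_tissue = (study.sample_meta["tissue"] == t).to_numpy()
        for a in study.analytes:
            col = values.loc[in_tissue, a]
            if col.notna().sum() < 5:
                values.loc[in_tissue, a] = np.nan
                log.append(f"{a}/{t}: dropped (fewer than 5 observations)")
                continue
            try:
                transformed, lam = boxcox_transform(
                    col, grid, config.shift_policy, name=f"{a}/{t}"
                )
                lambdas.loc[a, t] = lam
                fenced = tukey_fence(transformed, config.fence_k, config.quartile_method)
                z = standardize(fenced, ref_mask_all[in_tissue], name=f"{a}/{t}")
                values.loc[in_tissue, a] = z.to_numpy()
            except ValidationError as exc:
                values.loc[in_tissue, a] = np.nan
                log.append(f"{a}/{t}: non-analyzable ({exc})")

    out = AnalyteTable(values, study.sample_meta, study.analyte_meta, dict(study.provenance))
    out.provenance.setdefault("stages", []).extend(
        ["boxcox_transform", "tukey_fence", "standardize"]
    )
    for line in log:
        logger.info(line)
    return PreprocessResult(out, lods, report, lambdas, skipped, log)
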