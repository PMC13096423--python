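"""Rank analytes whose variation best tracks phenotype recovery.

Among transgenic (APP/PS1) mice only, each analyte x tissue column is
correlated (Pearson) with a behavioral or electrophysiological measure.
A consistency filter requires the correlation magnitude within each
treatment subgroup (vehicle, drug) to be no less than half the magnitude
among all transgenic mice — the pattern expected of a relationship that
holds along the whole recovery trajectory rather than one driven by the
group split alone. An auxiliary sex-adjusted regression of the phenotype
on the analyte plus a treatment-group indicator yields beta_extra, the
group effect not explained by the analyte (ideally zero). The final
score,

    score = |r| / range(|r|)  -  |beta_extra| / range(|beta_extra|)

with ranges taken as max - min of the absolute values across all scored
analytes, ranks analytes; the top 10 per measure are reported. Scores are
comparable only within one (measure, run) because of the range
normalization. Analyte-tissue columns from all tissues compete in one
ranking per measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AnalyteTable, ValidationError

logger = logging.getLogger(__name__)

CONSISTENCY_FRACTION = 0.5  # subgroup |r| must be >= this fraction of |r_all|
TOP_K = 10

SCORE_COLUMNS = [
    "analyte",
    "tissue",
    "measure",
    "r_all",
    "p_r",
    "r_vehicle",
    "r_fty",
    "beta_extra",
    "passes_consistency",
    "score",
    "rank",
    "n",
]


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-tailed t-test p (n - 2 df)."""
    if len(x) < 3:
        return np.nan, np.nan
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_phenotype(
    analyte_values: pd.Series,
    phenotype_values: pd.Series,
    treatment: pd.Series,
    min_pairs: int = 4,
    min_subgroup: int = 3,
) -> dict | None:
    """r among all transgenic mice plus within-treatment subgroup r's.

    Inputs are aligned by subject; complete pairs only. Returns None
    (exclusion) when fewer than ``min_pairs`` complete pairs exist, a
    subgroup has fewer than ``min_subgroup``, or either variable is
    degenerate.
    """
    df = pd.DataFrame(
        {"x": analyte_values, "y": phenotype_values, "treatment": treatment}
    ).dropna(subset=["x", "y"])
    if len(df) < min_pairs:
        return None
    veh = df[df["treatment"] == "vehicle"]
    fty = df[df["treatment"] == "FTY720"]
    if len(veh) < min_subgroup or len(fty) < min_subgroup:
        return None
    if df["x"].std() == 0 or df["y"].std() == 0:
        return None
    r_all, p_r = pearson_with_p(df["x"].to_numpy(), df["y"].to_numpy())
    r_veh, _ = pearson_with_p(veh["x"].to_numpy(), veh["y"].to_numpy())
    r_fty, _ = pearson_with_p(fty["x"].to_numpy(), fty["y"].to_numpy())
    if not (np.isfinite(r_all) and np.isfinite(r_veh) and np.isfinite(r_fty)):
        return None
    return {
        "r_all": r_all,
        "p_r": p_r,
        "r_vehicle": r_veh,
        "r_fty": r_fty,
        "n": len(df),
    }


def consistency_filter(
    r_all: float, r_vehicle: float, r_fty: float, fraction: float = CONSISTENCY_FRACTION
) -> bool:
    """Both subgroup correlation magnitudes must be no less than
    ``fraction`` of |r_all| (inclusive boundary)."""
    threshold = fraction * abs(r_all)
    return abs(r_vehicle) >= threshold and abs(r_fty) >= threshold


def extra_group_effect(
    phenotype: pd.Series,
    analyte: pd.Series,
    treatment: pd.Series,
    sex: pd.Series,
) -> float:
    """Treatment-group coefficient from phenotype ~ analyte + group + sex.

    Fitted among transgenic mice; a residual group effect means the
    phenotype difference between drug and vehicle arms is not mediated by
    this analyte. Raises on rank deficiency.
    """
    df = pd.DataFrame(
        {"y": phenotype, "x": analyte, "treatment": treatment, "sex": sex}
    ).dropna()
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["x"].to_numpy(float),
            (df["treatment"] == "FTY720").to_numpy(float),
            (df["sex"] == "male").to_numpy(float),
        ]
    )
    if len(df) <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient auxiliary regression")
    beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(float), rcond=None)
    return float(beta[2])


def final_score(
    r_all: pd.Series, beta_extra: pd.Series, top_k: int = TOP_K
) -> pd.DataFrame:
    """Composite score and rank for analytes that passed the filter.

    Each term is normalized by the max - min range of its absolute values
    across all scored analytes; a degenerate range sets that term to 0
    everywhere (with a warning). Ties break by larger |r|, then by
    analyte name.
    """
    if len(r_all) < 2:
        raise ValidationError("need >= 2 scored analytes to define ranges")
    abs_r = r_all.abs()
    abs_b = beta_extra.abs()
    r_range = abs_r.max() - abs_r.min()
    b_range = abs_b.max() - abs_b.min()
    if r_range == 0:
        logger.warning("degenerate |r| range; correlation term set to 0")
        r_term = pd.Series(0.0, index=r_all.index)
    else:
        r_term = abs_r / r_range
    if b_range == 0:
        logger.warning("degenerate |beta| range; group-effect term set to 0")
        b_term = pd.Series(0.0, index=r_all.index)
    else:
        b_term = abs_b / b_range
    score = r_term - b_term
    out = pd.DataFrame({"score": score, "_abs_r": abs_r})
    out["_name"] = out.index.map(lambda ix: ix if isinstance(ix, str) else "|".join(map(str, ix)))
    out = out.sort_values(["score", "_abs_r", "_name"], ascending=[False, False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    out["top_k"] = out["rank"] <= top_k
    return out[["score", "rank", "top_k"]]


def score_analytes(
    table: AnalyteTable,
    phenotypes: pd.DataFrame,
    measure: str,
    top_k: int = TOP_K,
    consistency_fraction: float = CONSISTENCY_FRACTION,
) -> pd.DataFrame:
    """Full integrative ranking of analyte x tissue columns for one measure.

    ``phenotypes`` is indexed by subject with ``treatment``/``sex``
    columns and the measure column; only transgenic subjects enter. All
    tissues pool into a single ranking. Returns one row per analyte x
    tissue with correlations, the consistency flag, beta_extra, score and
    rank (rank only among passing analytes).
    """
    if measure not in phenotypes.columns:
        raise ValidationError(f"phenotype table has no measure {measure!r}")
    app = phenotypes[phenotypes["genotype"] == "APP/PS1"]
    study = table.sample_meta["role"] == "study"
    rows: list[dict] = []
    for tissue in table.tissues:
        mask = study & (table.sample_meta["tissue"] == tissue) & (
            table.sample_meta["genotype"] == "APP/PS1"
        )
        meta = table.sample_meta.loc[mask]
        vals = table.values.loc[mask].set_axis(meta["subject"], axis=0)
        pheno = app[measure].reindex(vals.index)
        treat = app["treatment"].reindex(vals.index)
        sex = app["sex"].reindex(vals.index)
        for a in table.analytes:
            stats_d = correlate_phenotype(vals[a], pheno, treat)
            if stats_d is None:
                continue
            passes = consistency_filter(
                stats_d["r_all"], stats_d["r_vehicle"], stats_d["r_fty"], consistency_fraction
            )
            try:
                beta = extra_group_effect(pheno, vals[a], treat, sex)
            except ValidationError:
                logger.info("%s/%s excluded: auxiliary regression degenerate", a, tissue)
                continue
            rows.append(
                {
                    "analyte": a,
                    "tissue": tissue,
                    "measure": measure,
                    **stats_d,
                    "beta_extra": beta,
                    "passes_consistency": passes,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    out["score"] = np.nan
    out["rank"] = pd.NA
    passing = out[out["passes_consistency"]]
    if len(passing) >= 2:
        keyed = passing.set_index(["analyte", "tissue"])
        ranked = final_score(keyed["r_all"], keyed["beta_extra"], top_k)
        out = out.set_index(["analyte", "tissue"])
        out.loc[ranked.index, "score"] = ranked["score"]
        out.loc[ranked.index, "rank"] = ranked["rank"]
        out = out.reset_index()
    return out[SCORE_COLUMNS]


def top_k_report(scores: pd.DataFrame, k: int = TOP_K) -> pd.DataFrame:
    ranked = scores.dropna(subset=["rank"])
    return ranked[ranked["rank"] <= k].sort_values("rank").reset_index(drop=True)


def phenotype_cross_correlation(
    phenotypes: pd.DataFrame, measures: list[str]
) -> pd.DataFrame:
    """Pairwise Pearson r between measures among transgenic mice.

    Reported so users can verify that measures analyzed separately are
    not proxies for one another (near-zero r supports separate analyses).
    """
    app = phenotypes[phenotypes["genotype"] == "APP/PS1"]
    rows = []
    for i, m1 in enumerate(measures):
        for m2 in measures[i + 1 :]:
            df = app[[m1, m2]].dropna()
            r, p = pearson_with_p(df[m1].to_numpy(), df[m2].to_numpy())
            rows.append({"measure_1": m1, "measure_2": m2, "r": r, "p": p, "n": len(df)})
    return pd.DataFrame(rows)
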