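"""Four-group rescue classification: which genotype alterations does the
drug correct?

The analysis uses all four groups. Eligibility (a detected genotype
alteration) is arm-specific:

* improvement arm: the transgenic-vehicle group differs from wild-type
  vehicle at FDR <= 0.05 (direct route), or differs from all other
  subjects at FDR <= 0.05 while the direct contrast reaches nominal
  p <= 0.05 (pooled route, which borrows power from all samples);
* non-improvement arm: the direct FDR route, or all transgenic subjects
  differ from all wild-type subjects at FDR <= 0.05 with direct p <= 0.05.

The percent correction Delta is computed from one sex-adjusted model on
all four groups with three group dummies against WT-vehicle, so the
genotype displacement (APP/PS1-vehicle vs WT-vehicle) and the drug
displacement (APP/PS1-FTY720 vs APP/PS1-vehicle) share a scale:

    Delta = 100 * beta_correction / (-beta_genotype)

positive when the drug moves the transgenic group toward wild type.
Delta >= 50 (inclusive) classifies as improved; overcorrection
(Delta > 100) still counts as improved, i.e. as normalization past the
wild-type mean. Delta gets no multiple-testing control of its own; FDR
applies only to the eligibility contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import (
    ContrastSpec,
    FDR_THRESHOLD,
    P_THRESHOLD,
    _batch_ols,
    compute_qvalues,
    fit_contrast,
)
from .tables import AnalyteTable, ValidationError

logger = logging.getLogger(__name__)

IMPROVEMENT_THRESHOLD = 50.0  # percent of the genotype effect, inclusive

#: Eligibility contrasts: direct (transgenic-vehicle vs wild-type
#: vehicle), transgenic-vehicle vs all others (improvement arm), and
#: all transgenic vs all wild type (non-improvement arm).
DIRECT = ContrastSpec(
    "direct", case_groups=("APP/PS1-vehicle",), reference_groups=("WT-vehicle",)
)
POOLED_IMPROVE = ContrastSpec(
    "appveh_vs_rest",
    case_groups=("APP/PS1-vehicle",),
    reference_groups=("WT-vehicle", "WT-FTY720", "APP/PS1-FTY720"),
)
POOLED_NONIMPROVE = ContrastSpec(
    "app_vs_wt",
    case_groups=("APP/PS1-vehicle", "APP/PS1-FTY720"),
    reference_groups=("WT-vehicle", "WT-FTY720"),
)

RESCUE_COLUMNS = [
    "analyte",
    "tissue",
    "beta_genotype",
    "beta_correction",
    "delta_pct",
    "p_direct",
    "q_direct",
    "q_pooled_improve",
    "q_pooled_nonimprove",
    "eligibility_route",
    "category",
]


def compute_delta(beta_genotype: float, beta_correction: float) -> float:
    """Percent of the genotype displacement reverted by the drug.

    The correction displacement is projected onto the direction from the
    transgenic-vehicle mean toward the wild-type-vehicle mean, then
    normalized by the genotype displacement magnitude. Values above 100
    mean overcorrection; negative values mean worsening.
    """
    if not np.isfinite(beta_genotype) or abs(beta_genotype) < 1e-12:
        raise ValidationError("delta undefined: genotype effect is (numerically) zero")
    return 100.0 * beta_correction / (-beta_genotype)


def fit_four_group(table: AnalyteTable) -> pd.DataFrame:
    """One sex-adjusted OLS on all four groups per analyte per tissue.

    Group dummies against WT-vehicle; values standardized to the
    WT-vehicle complete cases. Returns beta_genotype (transgenic-vehicle
    dummy) and beta_correction (transgenic-drug minus transgenic-vehicle
    dummy) per analyte and tissue.
    """
    study = table.sample_meta["role"] == "study"
    rows = []
    for tissue in table.tissues:
        mask = study & (table.sample_meta["tissue"] == tissue)
        meta = table.sample_meta.loc[mask]
        vals = table.values.loc[mask]
        notna = vals.notna().to_numpy()
        patterns: dict[bytes, list[int]] = {}
        for j in range(vals.shape[1]):
            patterns.setdefault(notna[:, j].tobytes(), []).append(j)
        for key, col_idx in patterns.items():
            keep = np.frombuffer(key, dtype=bool)
            sub = meta.loc[keep]
            names = vals.columns[col_idx]
            counts = sub["group"].value_counts()
            if (counts.reindex(
                ["WT-vehicle", "WT-FTY720", "APP/PS1-vehicle", "APP/PS1-FTY720"]
            ).fillna(0) < 3).any():
                for a in names:
                    rows.append({"analyte": a, "tissue": tissue, "beta_genotype": np.nan,
                                 "beta_correction": np.nan, "note": "too few complete cases"})
                continue
            g = sub["group"]
            X = np.column_stack(
                [
                    np.ones(len(sub)),
                    (g == "APP/PS1-vehicle").to_numpy(float),
                    (g == "APP/PS1-FTY720").to_numpy(float),
                    (g == "WT-FTY720").to_numpy(float),
                    (sub["sex"] == "male").to_numpy(float),
                ]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                for a in names:
                    rows.append({"analyte": a, "tissue": tissue, "beta_genotype": np.nan,
                                 "beta_correction": np.nan, "note": "rank-deficient design"})
                continue
            Y = vals.iloc[:, col_idx].loc[keep].to_numpy(float)
            ref = (g == "WT-vehicle").to_numpy()
            mu, sd = Y[ref].mean(axis=0), Y[ref].std(axis=0, ddof=1)
            good = np.isfinite(sd) & (sd > 0)
            Yz = (Y[:, good] - mu[good]) / sd[good]
            XtX_inv = np.linalg.inv(X.T @ X)
            B = XtX_inv @ (X.T @ Yz)
            beta_gen = B[1]
            beta_corr = B[2] - B[1]  # drug arm minus vehicle arm, same scale
            good_names = np.asarray(names)[good]
            for i, a in enumerate(good_names):
                rows.append({"analyte": a, "tissue": tissue,
                             "beta_genotype": beta_gen[i],
                             "beta_correction": beta_corr[i], "note": ""})
            for a in np.asarray(names)[~good]:
                rows.append({"analyte": a, "tissue": tissue, "beta_genotype": np.nan,
                             "beta_correction": np.nan, "note": "zero reference SD"})
    return pd.DataFrame(rows)


def assess_eligibility(
    merged: pd.DataFrame,
    arm: str,
    fdr_threshold: float = FDR_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.Series:
    """Eligibility route per row for the given arm ("improve"/"non_improve").

    Route "direct_fdr": direct contrast q <= threshold. Route
    "pooled_fdr_plus_p": the arm's pooled contrast q <= threshold AND
    direct p <= threshold. Otherwise empty (not eligible).
    """
    if arm not in ("improve", "non_improve"):
        raise ValidationError(f"unknown arm {arm!r}")
    pooled_col = "q_pooled_improve" if arm == "improve" else "q_pooled_nonimprove"
    for col in ("q_direct", "p_direct", pooled_col):
        if col not in merged.columns:
            raise ValidationError(f"missing required contrast column {col!r}")
    route = pd.Series("", index=merged.index, dtype=object)
    pooled = (merged[pooled_col] <= fdr_threshold) & (merged["p_direct"] <= p_threshold)
    route[pooled] = "pooled_fdr_plus_p"
    route[merged["q_direct"] <= fdr_threshold] = "direct_fdr"
    return route


def classify_rescue(
    table: AnalyteTable,
    fdr_threshold: float = FDR_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    improvement_threshold: float = IMPROVEMENT_THRESHOLD,
) -> pd.DataFrame:
    """Run the full four-group rescue analysis.

    Fits the three eligibility contrasts (with stratified q-values), the
    four-group model for the two displacement coefficients, computes
    Delta, and classifies every eligible analyte: improved when
    Delta >= 50 under improvement-arm eligibility, not improved when
    Delta < 50 under non-improvement-arm eligibility. Analytes eligible
    only under the arm whose Delta criterion they fail receive no call
    (only the improved and not-improved sets are reported). Output is sorted
    by tissue then |beta_genotype| descending.
    """
    contrasts = {}
    for spec in (DIRECT, POOLED_IMPROVE, POOLED_NONIMPROVE):
        res = fit_contrast(table, spec)
        contrasts[spec.name] = compute_qvalues(res, table.analyte_meta)

    merged = contrasts["direct"][["analyte", "tissue", "p", "q"]].rename(
        columns={"p": "p_direct", "q": "q_direct"}
    )
    merged = merged.merge(
        contrasts["appveh_vs_rest"][["analyte", "tissue", "q"]].rename(
            columns={"q": "q_pooled_improve"}
        ),
        on=["analyte", "tissue"],
        how="outer",
    )
    merged = merged.merge(
        contrasts["app_vs_wt"][["analyte", "tissue", "q"]].rename(
            columns={"q": "q_pooled_nonimprove"}
        ),
        on=["analyte", "tissue"],
        how="outer",
    )
    betas = fit_four_group(table)
    merged = merged.merge(
        betas[["analyte", "tissue", "beta_genotype", "beta_correction"]],
        on=["analyte", "tissue"],
        how="left",
    )

    route_improve = assess_eligibility(merged, "improve", fdr_threshold, p_threshold)
    route_nonimprove = assess_eligibility(merged, "non_improve", fdr_threshold, p_threshold)

    records = []
    for i, row in merged.iterrows():
        r_imp, r_non = route_improve[i], route_nonimprove[i]
        if not r_imp and not r_non:
            continue
        try:
            delta = compute_delta(row["beta_genotype"], row["beta_correction"])
        except ValidationError as exc:
            logger.warning("%s/%s: %s; call suppressed", row["analyte"], row["tissue"], exc)
            continue
        if delta >= improvement_threshold and r_imp:
            category, route = "improved", r_imp
        elif delta < improvement_threshold and r_non:
            category, route = "not_improved", r_non
        else:
            continue
        records.append(
            {
                "analyte": row["analyte"],
                "tissue": row["tissue"],
                "beta_genotype": row["beta_genotype"],
                "beta_correction": row["beta_correction"],
                "delta_pct": delta,
                "p_direct": row["p_direct"],
                "q_direct": row["q_direct"],
                "q_pooled_improve": row["q_pooled_improve"],
                "q_pooled_nonimprove": row["q_pooled_nonimprove"],
                "eligibility_route": route,
                "category": category,
            }
        )
    calls = pd.DataFrame(records, columns=RESCUE_COLUMNS)
    if not calls.empty:
        calls = calls.sort_values(
            ["tissue", "beta_genotype"],
            key=lambda s: -s.abs() if s.name == "beta_genotype" else s,
        ).reset_index(drop=True)
    return calls
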