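"""Group comparisons for phenotype measures and univariate AUC separability.

Welch's t-test (unequal variances, Satterthwaite degrees of freedom)
compares behavioral/electrophysiological measures between groups. The
area under the ROC curve, the probability that a random case sample
exceeds a random control sample (ties counted one half), quantifies
separation, with confidence intervals from DeLong's structural-components
variance estimator. Case/control orientation is always explicit — the
module never flips direction automatically, so AUC < 0.5 is reportable
and means the case group tends lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ValidationError


@dataclass
class AucResult:
    """AUC with a DeLong confidence interval.

    The normal-theory interval degenerates at AUC = 1 with small samples;
    it is truncated to [0, 1] (a reported interval like 90%-100% reflects
    that truncation).
    """

    label: str
    case_group: str
    control_group: str
    auc: float
    ci95_low: float
    ci95_high: float
    n_case: int
    n_control: int


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's t-test: returns (t, Satterthwaite df, two-tailed p)."""
    a = np.asarray(pd.Series(a).dropna(), dtype=float)
    b = np.asarray(pd.Series(b).dropna(), dtype=float)
    if len(a) < 2 or np.var(a, ddof=1) == 0:
        raise ValidationError("first sample is degenerate (n < 2 or zero variance)")
    if len(b) < 2 or np.var(b, ddof=1) == 0:
        raise ValidationError("second sample is degenerate (n < 2 or zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with two-tailed t-based p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValidationError("Pearson test needs >= 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("degenerate variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_auc_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values.

    V10[i] = fraction of controls below case i (ties 1/2); V01[j] = fraction
    of cases above control j. var(AUC) = S10/m + S01/n.
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    rank_all = _midrank(combined)
    rank_cases = _midrank(cases)
    rank_controls = _midrank(controls)
    v10 = (rank_all[:m] - rank_cases) / n
    v01 = 1.0 - (rank_all[m:] - rank_controls) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_with_ci(
    values,
    labels,
    case_label,
    control_label,
    measure: str = "",
    alpha: float = 0.05,
) -> AucResult:
    """Univariate AUC of ``values`` separating case from control samples.

    Equals the Mann-Whitney U probability estimate (concordant-pair
    fraction with ties counted one half). The CI is DeLong's, truncated
    to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    cases = values[labels == case_label]
    controls = values[labels == control_label]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError(
            f"both classes required: {case_label!r} n={len(cases)}, "
            f"{control_label!r} n={len(controls)}"
        )
    auc, var = _delong_auc_variance(cases, controls)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return AucResult(
        label=measure,
        case_group=str(case_label),
        control_group=str(control_label),
        auc=auc,
        ci95_low=float(max(0.0, auc - half)),
        ci95_high=float(min(1.0, auc + half)),
        n_case=len(cases),
        n_control=len(controls),
    )


def phenotype_group_tests(
    phenotypes: pd.DataFrame,
    measures: list[str],
    pairs: list[tuple[str, str]] = (
        ("WT-vehicle", "APP/PS1-vehicle"),
        ("APP/PS1-vehicle", "APP/PS1-FTY720"),
    ),
) -> pd.DataFrame:
    """Welch comparisons of each measure for each group pair."""
    rows = []
    for measure in measures:
        for g1, g2 in pairs:
            a = phenotypes.loc[phenotypes["group"] == g1, measure]
            b = phenotypes.loc[phenotypes["group"] == g2, measure]
            try:
                t, df, p = welch_test(a, b)
            except ValidationError as exc:
                rows.append({"measure": measure, "group_1": g1, "group_2": g2,
                             "t": np.nan, "df": np.nan, "p": np.nan, "note": str(exc)})
                continue
            rows.append({"measure": measure, "group_1": g1, "group_2": g2,
                         "t": t, "df": df, "p": p,
                         "n_1": int(a.notna().sum()), "n_2": int(b.notna().sum()),
                         "note": ""})
    return pd.DataFrame(rows)


def phenotype_auc_table(
    phenotypes: pd.DataFrame,
    measures: list[str],
    pairs: list[tuple[str, str]] = (
        ("APP/PS1-vehicle", "WT-vehicle"),
        ("APP/PS1-vehicle", "APP/PS1-FTY720"),
    ),
) -> pd.DataFrame:
    """Univariate AUC separability of each measure for each (case,
    control) group pair, with DeLong confidence intervals."""
    rows = []
    for measure in measures:
        for case, control in pairs:
            sub = phenotypes[phenotypes["group"].isin([case, control])]
            try:
                res = auc_with_ci(
                    sub[measure].to_numpy(float),
                    sub["group"].to_numpy(),
                    case, control, measure=measure,
                )
            except ValidationError as exc:
                rows.append({"measure": measure, "case_group": case,
                             "control_group": control, "auc": np.nan,
                             "ci95_low": np.nan, "ci95_high": np.nan,
                             "n_case": 0, "n_control": 0, "note": str(exc)})
                continue
            rows.append({"measure": measure, "case_group": case,
                         "control_group": control, "auc": res.auc,
                         "ci95_low": res.ci95_low, "ci95_high": res.ci95_high,
                         "n_case": res.n_case, "n_control": res.n_control,
                         "note": ""})
    return pd.DataFrame(rows)
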