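"""Sex-adjusted linear-model contrasts, stratified q-values, significance.

Each analyte in each tissue gets its own ordinary-least-squares model of
the standardized value on a group indicator plus sex. Because values are
standardized to the reference group, the group coefficient is in units of
one reference-group standard deviation and is comparable across analytes.

False-discovery control uses Storey q-values, computed separately within
each stratum of plate analytical method (UHPLC, FIA) x analyte kind
(measured metabolite, calculated indicator). An effect is called
significant either directly (q <= 0.05) or via the cross-tissue route:
p <= 0.05 while another tissue shows q <= 0.05 for the same analyte and
contrast with the same coefficient sign.

The per-analyte fits share a design matrix within each missingness
pattern, so the module solves them as batched least squares; a unit test
cross-checks the coefficients, standard errors and p-values against
statsmodels OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats, interpolate

from .tables import AnalyteTable, ValidationError

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class ContrastSpec:
    """A case-vs-reference group contrast, always adjusted for sex.

    The reference group(s) define the standardization target: values are
    re-standardized to the pooled reference before fitting, so the
    coefficient reads as the case-group displacement in reference SDs.
    """

    name: str
    case_groups: tuple[str, ...]
    reference_groups: tuple[str, ...]
    covariates: tuple[str, ...] = ("sex",)
    interaction: bool = False

    def __post_init__(self) -> None:
        if set(self.case_groups) & set(self.reference_groups):
            raise ValidationError(
                f"contrast {self.name!r}: case and reference groups overlap"
            )

RESULT_COLUMNS = [
    "analyte",
    "tissue",
    "contrast",
    "beta",
    "se",
    "ci95_low",
    "ci95_high",
    "p",
    "n_used",
    "note",
]


def _batch_ols(X: np.ndarray, Y: np.ndarray, coef_idx: int) -> dict[str, np.ndarray]:
    """OLS of every column of Y on the shared design X.

    Returns the coefficient of column ``coef_idx`` with its standard
    error, t-based two-tailed p and 95% CI (residual degrees of freedom).
    """
    n, k = X.shape
    df = n - k
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)  # (k, m)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(XtX_inv[coef_idx, coef_idx] * sigma2)
    beta = B[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return {
        "beta": beta,
        "se": se,
        "p": p,
        "ci95_low": beta - tcrit * se,
        "ci95_high": beta + tcrit * se,
        "n": np.full(Y.shape[1], n),
    }


def _design_matrix(
    meta: pd.DataFrame, case_groups: Sequence[str], interaction: bool
) -> tuple[np.ndarray, int, str | None]:
    """Build [1, case, sex_male(, case x sex)] and report the target column.

    Returns (X, index of the coefficient of interest, skip reason or None).
    """
    case = meta["group"].isin(case_groups).to_numpy(dtype=float)
    sex_male = (meta["sex"] == "male").to_numpy(dtype=float)
    cols = [np.ones(len(meta)), case, sex_male]
    coef_idx = 1
    if interaction:
        # center sex so the interaction column is orthogonal to the main terms
        cols.append(case * (sex_male - sex_male.mean()))
        coef_idx = 3
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return X, coef_idx, "rank-deficient design (e.g. single-sex subset)"
    return X, coef_idx, None


def fit_contrast(
    table: AnalyteTable,
    spec: ContrastSpec,
    min_cell: int = 3,
) -> pd.DataFrame:
    """Fit the contrast per analyte per tissue; complete cases per analyte.

    Analytes with a degenerate design (rank deficiency, too few complete
    cases per modeled cell, zero reference SD) are skipped with the reason
    recorded in the ``note`` column.
    """
    study = table.sample_meta["role"] == "study"
    in_contrast = table.sample_meta["group"].isin(
        spec.case_groups + spec.reference_groups
    )
    rows: list[dict] = []
    for tissue in table.tissues:
        mask = study & in_contrast & (table.sample_meta["tissue"] == tissue)
        meta = table.sample_meta.loc[mask]
        vals = table.values.loc[mask]
        if meta.empty:
            continue
        is_ref = meta["group"].isin(spec.reference_groups).to_numpy()
        # group analytes by missingness pattern to share design matrices
        notna = vals.notna().to_numpy()
        patterns: dict[bytes, list[int]] = {}
        for j in range(vals.shape[1]):
            patterns.setdefault(notna[:, j].tobytes(), []).append(j)
        for key, col_idx in patterns.items():
            keep = np.frombuffer(key, dtype=bool)
            sub_meta = meta.loc[keep]
            analyte_names = vals.columns[col_idx]
            n_case = int(sub_meta["group"].isin(spec.case_groups).sum())
            n_ref = int(sub_meta["group"].isin(spec.reference_groups).sum())
            skip = None
            if n_case < min_cell or n_ref < min_cell:
                skip = f"fewer than {min_cell} complete cases in a cell"
            else:
                X, coef_idx, skip = _design_matrix(
                    sub_meta, spec.case_groups, spec.interaction
                )
            if skip is None and sub_meta.shape[0] - X.shape[1] < 1:
                skip = "no residual degrees of freedom"
            if skip:
                for a in analyte_names:
                    rows.append(
                        dict.fromkeys(RESULT_COLUMNS)
                        | {"analyte": a, "tissue": tissue, "contrast": spec.name, "note": skip}
                    )
                logger.info("%s/%s: skipped %d analyte(s): %s", spec.name, tissue, len(col_idx), skip)
                continue
            Y = vals.iloc[:, col_idx].loc[keep].to_numpy(dtype=float)
            # re-standardize to the pooled reference within complete cases
            ref_rows = is_ref[keep]
            mu = Y[ref_rows].mean(axis=0)
            sd = Y[ref_rows].std(axis=0, ddof=1)
            good = np.isfinite(sd) & (sd > 0)
            Yz = (Y[:, good] - mu[good]) / sd[good]
            fit = _batch_ols(X, Yz, coef_idx)
            good_names = list(analyte_names[good])
            for i, a in enumerate(good_names):
                rows.append(
                    {
                        "analyte": a,
                        "tissue": tissue,
                        "contrast": spec.name,
                        "beta": fit["beta"][i],
                        "se": fit["se"][i],
                        "ci95_low": fit["ci95_low"][i],
                        "ci95_high": fit["ci95_high"][i],
                        "p": fit["p"][i],
                        "n_used": int(fit["n"][i]),
                        "note": "",
                    }
                )
            for a in analyte_names[~good]:
                rows.append(
                    dict.fromkeys(RESULT_COLUMNS)
                    | {"analyte": a, "tissue": tissue, "contrast": spec.name, "note": "zero reference SD"}
                )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out


def fit_sex_interaction(table: AnalyteTable, spec: ContrastSpec) -> pd.DataFrame:
    """Refit with a sex x group interaction and report that coefficient.

    With planted opposite-sign effects (+s in males, -s in females) the
    interaction coefficient recovers 2s.
    """
    inter_spec = ContrastSpec(
        name=f"{spec.name}:sex",
        case_groups=spec.case_groups,
        reference_groups=spec.reference_groups,
        covariates=spec.covariates,
        interaction=True,
    )
    return fit_contrast(table, inter_spec)


# -- q-values ------------------------------------------------------------------


def storey_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 with the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over lambda = 0.05,
    0.10, ..., 0.95; a cubic smoothing spline is evaluated at the largest
    lambda. Falls back to 1.0 (Benjamini-Hochberg behavior) when the
    estimate is unstable or there are too few tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    if m < 10:
        return 1.0
    pi0_lam = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    try:
        spline = interpolate.UnivariateSpline(lambdas, pi0_lam, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:  # degenerate spline fit
        pi0 = float(pi0_lam[-1])
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(pvalues: Sequence[float], pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with pi0 = 1 these equal Benjamini-Hochberg
    step-up adjusted p-values. Monotone non-decreasing in p."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1] and be non-missing")
    if pi0 is None:
        pi0 = storey_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0, 1)
    out = np.empty(m)
    out[order] = q
    return out


def compute_qvalues(
    results: pd.DataFrame,
    analyte_meta: pd.DataFrame,
    p_col: str = "p",
    strata_cols: tuple[str, ...] = ("method", "kind"),
    min_stratum: int = 10,
) -> pd.DataFrame:
    """Attach q-values computed separately per (method, kind) stratum.

    Each contrast is its own family: q-values are computed within
    (contrast, method, kind), pooling tissues, so one stratum's p-values
    never influence another stratum's q-values.
    """
    out = results.copy()
    meta = analyte_meta[list(strata_cols)]
    out = out.merge(meta, left_on="analyte", right_index=True, how="left")
    out["q"] = np.nan
    fitted = out[p_col].notna()
    for _, idx in out.loc[fitted].groupby(["contrast", *strata_cols], dropna=False).groups.items():
        p = out.loc[idx, p_col].to_numpy(dtype=float)
        pi0 = storey_pi0(p) if len(p) >= min_stratum else 1.0
        out.loc[idx, "q"] = storey_qvalues(p, pi0)
    return out


# -- significance rule ---------------------------------------------------------


def call_significance(
    results: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Assign ``sig_route`` per (analyte, contrast, tissue).

    "fdr" when q <= threshold; "p_with_cross_tissue" when p <= threshold
    and another tissue reaches q <= threshold for the same analyte and
    contrast with the same coefficient sign; otherwise "none".
    """
    out = results.copy()
    out["sig_route"] = "none"
    fdr_hit = out["q"] <= fdr_threshold
    out.loc[fdr_hit, "sig_route"] = "fdr"
    for (_, _), grp in out.groupby(["analyte", "contrast"], sort=False):
        hits = grp[fdr_hit.loc[grp.index]]
        if hits.empty:
            continue
        for i in grp.index:
            if out.at[i, "sig_route"] != "none":
                continue
            p, beta = out.at[i, "p"], out.at[i, "beta"]
            if pd.isna(p) or p > p_threshold:
                continue
            others = hits[hits["tissue"] != out.at[i, "tissue"]]
            if (np.sign(others["beta"]) == np.sign(beta)).any():
                out.at[i, "sig_route"] = "p_with_cross_tissue"
    return out


def run_differential(
    table: AnalyteTable,
    specs: Iterable[ContrastSpec],
) -> pd.DataFrame:
    """Fit all contrasts, attach stratified q-values, call significance."""
    parts = [fit_contrast(table, s) for s in specs]
    results = pd.concat(parts, ignore_index=True)
    results = compute_qvalues(results, table.analyte_meta)
    return call_significance(results)


#: The study's two headline contrasts.
GENOTYPE_CONTRAST = ContrastSpec(
    "genotype", case_groups=("APP/PS1-vehicle",), reference_groups=("WT-vehicle",)
)
DRUG_CONTRAST = ContrastSpec(
    "drug", case_groups=("APP/PS1-FTY720",), reference_groups=("APP/PS1-vehicle",)
)
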