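"""Simulation studies that verify the pipeline recovers planted truth.

Each function runs many replicate synthetic studies at the emulated
experiment's scale and measures a recovery property end to end: effect
estimation bias, null false-discovery behavior, rescue classification
accuracy, and integrative ranking recovery. They power both the test
suite and the reproduction script.

Replicate seeds are derived from a base seed via ``numpy``'s
``SeedSequence`` spawning, so every study stays deterministic given the
base seed while replicates are mutually independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import (
    ContrastSpec,
    GENOTYPE_CONTRAST,
    call_significance,
    compute_qvalues,
    fit_contrast,
)
from .integration import score_analytes, top_k_report
from .rescue import classify_rescue
from .synthetic import PlantedTruth, StudyDesign, generate_study


def _child_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _log_study(design: StudyDesign, truth: PlantedTruth, normalize: bool = False):
    """Generate a study and return study rows on the log scale (the
    generator's abundances are log-normal; contrast fitting standardizes
    internally).

    With ``normalize`` the QC-median plate normalization runs first.
    Group contrasts do not need it — plate offsets are additive on the
    log scale and symmetric across groups — and the factor estimated
    from a handful of QC wells adds shared noise; the integrative
    ranking does need it, because residual plate bias acts as analyte
    measurement error and leaks into the auxiliary group coefficient."""
    s = generate_study(design, truth)
    table = s.table
    if normalize:
        from .preprocess import normalize_plates

        table = normalize_plates(table)
    study = table.subset_samples(table.study_mask())
    study.values = np.log(study.values)
    return study, s.phenotypes


def effect_recovery(
    effects: dict[str, float] = {"M000": -1.78, "M001": -1.37, "M002": 0.0},
    n_per_group_per_sex: int = 6,
    n_replicates: int = 200,
    base_seed: int = 0,
    full_preprocessing: bool = False,
) -> pd.DataFrame:
    """Mean estimated genotype beta per planted effect over replicates.

    Effect sizes default to the scale of the emulated study's
    spermidine-synthesis result (-1.78 and -1.37 SD) plus a null analyte.
    By default the contrast is fitted on the generator's log-scale values
    (the differential module standardizes internally), isolating the
    estimator itself; with ``full_preprocessing`` each replicate also
    runs the whole chain (plate normalization through standardization),
    which adds a small extra |beta| inflation from transform estimation.
    """
    from .preprocess import run_preprocessing

    names = list(effects)
    betas = {a: [] for a in names}
    for seed in _child_seeds(base_seed, n_replicates):
        design = StudyDesign(
            n_per_group_per_sex=n_per_group_per_sex,
            tissues=("parietal cortex",),
            n_metabolites=len(names),
            seed=seed,
        )
        truth = PlantedTruth(genotype_effect=dict(effects))
        if full_preprocessing:
            s = generate_study(design, truth)
            table = run_preprocessing(s.table).table
        else:
            table, _ = _log_study(design, truth)
        res = fit_contrast(table, GENOTYPE_CONTRAST).set_index("analyte")
        for a in names:
            betas[a].append(res.loc[a, "beta"])
    return pd.DataFrame(
        {
            "analyte": names,
            "planted": [effects[a] for a in names],
            "mean_beta": [float(np.mean(betas[a])) for a in names],
            "sd_beta": [float(np.std(betas[a], ddof=1)) for a in names],
            "n_replicates": n_replicates,
        }
    )


def null_fdr(
    n_analytes: int = 500,
    n_replicates: int = 200,
    n_per_group_per_sex: int = 6,
    base_seed: int = 0,
) -> dict:
    """Fraction of tests rejected at q <= 0.05 on fully null panels.

    Every rejection on null data is a false discovery, so the mean
    rejected fraction is the realized false-discovery mass; it should be
    far below the nominal 0.05 under full-null truth.
    """
    fracs, any_rej = [], []
    for seed in _child_seeds(base_seed, n_replicates):
        design = StudyDesign(
            n_per_group_per_sex=n_per_group_per_sex,
            tissues=("frontal cortex",),
            n_metabolites=n_analytes,
            seed=seed,
        )
        table, _ = _log_study(design, PlantedTruth())
        res = fit_contrast(table, GENOTYPE_CONTRAST)
        res = compute_qvalues(res, table.analyte_meta)
        rejected = (res["q"] <= 0.05).sum()
        fracs.append(rejected / len(res))
        any_rej.append(rejected > 0)
    return {
        "mean_rejected_fraction": float(np.mean(fracs)),
        "replicates_with_any_rejection": float(np.mean(any_rej)),
        "n_analytes": n_analytes,
        "n_replicates": n_replicates,
    }


def rescue_recovery(
    correction_fractions: tuple[float, ...] = (0.1, 0.5, 0.9),
    genotype_effect: float = -1.5,
    n_per_group_per_sex: int = 25,
    n_analytes: int = 12,
    n_replicates: int = 200,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Classification rates for planted correction fractions.

    One analyte per correction fraction is planted with a strong genotype
    effect in every replicate (n = 50/group by default); the remaining
    analytes are null background for the q-value strata.
    """
    names = [f"M{i:03d}" for i in range(len(correction_fractions))]
    counts = {a: {"improved": 0, "not_improved": 0, "no_call": 0} for a in names}
    for seed in _child_seeds(base_seed, n_replicates):
        design = StudyDesign(
            n_per_group_per_sex=n_per_group_per_sex,
            tissues=("frontal cortex",),
            n_metabolites=n_analytes,
            seed=seed,
        )
        truth = PlantedTruth(
            genotype_effect={a: genotype_effect for a in names},
            correction_fraction=dict(zip(names, correction_fractions)),
        )
        table, _ = _log_study(design, truth)
        calls = classify_rescue(table).set_index("analyte")
        for a in names:
            if a in calls.index:
                counts[a][str(calls.loc[a, "category"])] += 1
            else:
                counts[a]["no_call"] += 1
    rows = []
    for a, cf in zip(names, correction_fractions):
        rows.append(
            {
                "analyte": a,
                "correction_fraction": cf,
                "improved_rate": counts[a]["improved"] / n_replicates,
                "not_improved_rate": counts[a]["not_improved"] / n_replicates,
                "no_call_rate": counts[a]["no_call"] / n_replicates,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)


def driver_ranking(
    loading: float = 0.9,
    n_noise_analytes: int = 200,
    n_per_group_per_sex: int = 6,
    n_replicates: int = 100,
    top_k: int = 10,
    base_seed: int = 0,
) -> dict:
    """How often a planted phenotype-driver analyte lands in the top-k.

    One analyte carries the full phenotype coupling; the other analytes
    are uncorrelated noise competing in the same ranking.
    """
    hits = 0
    for seed in _child_seeds(base_seed, n_replicates):
        design = StudyDesign(
            n_per_group_per_sex=n_per_group_per_sex,
            tissues=("temporal cortex",),
            n_metabolites=n_noise_analytes + 1,
            seed=seed,
        )
        truth = PlantedTruth(phenotype_loadings={"ltp": {"M000": loading}})
        table, phenotypes = _log_study(design, truth, normalize=True)
        scores = score_analytes(table, phenotypes, "ltp", top_k=top_k)
        top = top_k_report(scores, top_k)
        hits += bool((top["analyte"] == "M000").any())
    return {
        "top_k_hit_rate": hits / n_replicates,
        "n_noise_analytes": n_noise_analytes,
        "n_replicates": n_replicates,
        "top_k": top_k,
    }
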