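import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabrescue.synthetic import PlantedTruth, StudyDesign, generate_study

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(
        n_per_group_per_sex=4,
        tissues=("frontal cortex", "plasma"),
        n_metabolites=20,
        n_plates=2,
        qc_per_plate=3,
        blanks_per_plate=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def null_study(small_design):
    """No planted effects: group differences are pure sampling noise."""
    return generate_study(small_design, PlantedTruth())


@pytest.fixture(scope="session")
def effect_study():
    """Strong planted genotype effect with near-full correction."""
    design = StudyDesign(
        n_per_group_per_sex=25,
        tissues=("frontal cortex",),
        n_metabolites=15,
        seed=13,
    )
    truth = PlantedTruth(
        genotype_effect={"M000": -1.5, "M001": 1.2},
        correction_fraction={"M000": 1.0, "M001": 0.1},
        phenotype_loadings={"ltp": {"M002": 0.9}},
    )
    return generate_study(design, truth)


def make_table(values: pd.DataFrame, meta: pd.DataFrame, analyte_meta=None):
    """Assemble an AnalyteTable from hand-built frames (test helper)."""
    from metabrescue.tables import AnalyteTable

    if analyte_meta is None:
        analyte_meta = pd.DataFrame(
            {"method": "UHPLC", "kind": "metabolite", "class_label": "x"},
            index=values.columns,
        )
    return AnalyteTable(values, meta, analyte_meta)
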