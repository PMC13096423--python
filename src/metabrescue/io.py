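"""Readers and writers for the package's on-disk formats.

All tables are plain TSV with documented, stable column names; the
indicator registry is JSON (a list of objects) or 4-column TSV
(name, kind, numerator, denominator — lists comma-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .tables import AnalyteTable, IndicatorFormula, ValidationError


def read_formulas(path: str | Path) -> list[IndicatorFormula]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries = [
            {
                "name": r["name"],
                "kind": r["kind"],
                "numerator": [s for s in r["numerator"].split(",") if s],
                "denominator": [s for s in r.get("denominator", "").split(",") if s],
            }
            for _, r in df.iterrows()
        ]
    formulas = []
    for e in entries:
        formulas.append(
            IndicatorFormula(
                name=e["name"],
                kind=e["kind"],
                numerator=tuple(e["numerator"]),
                denominator=tuple(e.get("denominator", ())),
            )
        )
    return formulas


def write_formulas(formulas: list[IndicatorFormula], path: str | Path) -> None:
    entries = [
        {
            "name": f.name,
            "kind": f.kind,
            "numerator": list(f.numerator),
            "denominator": list(f.denominator),
        }
        for f in formulas
    ]
    Path(path).write_text(json.dumps(entries, indent=2))


def read_analyte_table(
    values_path: str | Path,
    sample_meta_path: str | Path,
    analyte_meta_path: str | Path,
) -> AnalyteTable:
    """Read a study from long-format values + metadata TSVs."""
    long = pd.read_csv(values_path, sep="\t")
    required = {"sample_id", "analyte", "value"}
    if not required <= set(long.columns):
        raise ValidationError(f"values table needs columns {sorted(required)}")
    values = long.pivot(index="sample_id", columns="analyte", values="value")
    sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col="sample_id")
    analyte_meta = pd.read_csv(analyte_meta_path, sep="\t", index_col="analyte")
    values = values.reindex(index=sample_meta.index, columns=analyte_meta.index)
    return AnalyteTable(values, sample_meta, analyte_meta)


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
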