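"""Bundled reference data for the eleven vitiligo-treatment drugs.

Ships, as versioned CSV fixtures, the published study data this pipeline
reproduces: the nine topological index values per drug, the physicochemical
property table (refractivity, enthalpy, molar volume, polarity, complexity,
plus an unused boiling-point column), the two fully worked edge partitions
(psoralen and azathioprine), the printed regression statistics used by the
agreement report, and an explicit ledger of the source's internal
inconsistencies (the same quantity printed with two different values).

Values are stored exactly as printed, including 2-dp rounding of the
non-integer indices; downstream regressions run on these printed values.
Drug keys are normalised to lowercase-with-hyphens; display names are kept
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

from .indices import IndexVector
from .molgraph import EdgePartition

__all__ = [
    "MODELED_PROPERTIES",
    "PROPERTY_UNITS",
    "DiscrepancyRecord",
    "load_ti_table",
    "load_ti_vectors",
    "load_property_table",
    "load_worked_partitions",
    "load_printed_statistics",
    "known_discrepancies",
]

#: Properties actually modelled; boiling point is shipped but never regressed.
MODELED_PROPERTIES: tuple[str, ...] = (
    "refractivity",
    "enthalpy",
    "molar_volume",
    "polarity",
    "complexity",
)

#: Units as printed in the source tables (carried as opaque labels).
PROPERTY_UNITS: dict[str, str] = {
    "refractivity": "m3/mol",
    "enthalpy": "degC",
    "molar_volume": "cm3",
    "polarity": "cm3",
    "complexity": "",
    "boiling_point": "degC",
}

# Alternative property values printed in the actual-vs-computed comparison
# tables where they conflict with the main property table.
_VARIANT_TABLES15_18: dict[str, dict[str, float]] = {
    "monobenzone": {"polarity": 35.50},
    "azathioprine": {"refractivity": 59.94},
    "fluticasone": {"molar_volume": 336.6},
}


@dataclass(frozen=True)
class DiscrepancyRecord:
    """One internal conflict of the source: a quantity printed twice, differently."""

    quantity: str
    location_a: str
    value_a: str
    location_b: str
    value_b: str
    default_choice: str
    note: str


def _data(name: str):
    return files("topoqspr.data").joinpath(name)


def load_ti_table() -> pd.DataFrame:
    """The published index values: 11 drugs x 9 indices, as printed.

    Indexed by normalised drug key, with a ``display_name`` column followed
    by the nine canonical index columns.
    """
    with _data("table1_indices.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, index_col="drug")


def load_ti_vectors() -> dict[str, IndexVector]:
    """The same index table as one :class:`IndexVector` per drug key."""
    df = load_ti_table()
    return {
        drug: IndexVector(*row.iloc[1:].astype(float))
        for drug, row in df.iterrows()
    }


def load_property_table(variant: str = "table2") -> pd.DataFrame:
    """The physicochemical property table; blank cells are missing (NaN).

    ``variant="table2"`` (default) returns the main property table;
    ``variant="tables15-18"`` substitutes the three conflicting values
    printed in the actual-vs-computed tables (monobenzone polarity 35.50,
    azathioprine refractivity 59.94, fluticasone molar volume 336.6) so the
    effect of either reading can be probed.
    """
    with _data("table2_properties.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col="drug")
    if variant == "tables15-18":
        for drug, repl in _VARIANT_TABLES15_18.items():
            for col, val in repl.items():
                df.loc[drug, col] = val
    elif variant != "table2":
        raise ValueError(f"unknown variant {variant!r}; use 'table2' or 'tables15-18'")
    return df


def load_worked_partitions() -> dict[str, EdgePartition]:
    """The two edge partitions worked in full in the source (psoralen, azathioprine)."""
    with _data("worked_partitions.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    out: dict[str, EdgePartition] = {}
    for drug, grp in df.groupby("drug", sort=False):
        out[drug] = EdgePartition(
            {(int(r.m), int(r.n)): int(r.count) for r in grp.itertuples()}
        )
    return out


def load_printed_statistics() -> pd.DataFrame:
    """The printed regression statistics (45 models), values kept as strings.

    String storage preserves each cell's printed precision so the agreement
    report can compare a recomputed value at exactly that precision.
    """
    with _data("printed_statistics.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype=str)


def known_discrepancies() -> list[DiscrepancyRecord]:
    """The ledger of internal conflicts in the published tables."""
    with _data("discrepancies.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    return [DiscrepancyRecord(**row) for row in df.to_dict(orient="records")]
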