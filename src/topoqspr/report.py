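"""CSV report generation and the printed-table agreement check.

Everything tabular the pipeline emits goes through :func:`write_csv`, which
prepends a ``#``-comment metadata header (package version, input digests,
options) and refuses to overwrite existing files unless forced. The
agreement machinery re-derives every statistic from the bundled fixtures
and compares each cell with the printed value *at the precision it was
printed* (a cell matches when the recomputed value rounds, half-up, to the
printed string), cross-referencing mismatches to the discrepancy ledger.
"""

from __future__ import annotations

import hashlib
from importlib.metadata import PackageNotFoundError, version
from importlib.resources import files
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import paper_data, qspr
from .indices import INDEX_NAMES, compute_all, round_half_up
from .molgraph import EdgePartition

__all__ = [
    "OutputExistsError",
    "write_csv",
    "read_csv",
    "descriptor_table",
    "qspr_report",
    "agreement_report",
]


class OutputExistsError(FileExistsError):
    """An output file already exists and ``force`` was not given."""


def _pkg_version() -> str:
    try:
        return version("topoqspr")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def input_digests(paths) -> dict[str, str]:
    """Short sha256 digests of input files, for the run-metadata header."""
    return {str(p): _digest(p) for p in paths}


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    force: bool = False,
    index: bool = True,
) -> Path:
    """Write a report table with a commented metadata header."""
    path = Path(path)
    if path.exists() and not force:
        raise OutputExistsError(f"{path} exists; pass force=True / --force to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# topoqspr {_pkg_version()}"]
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}: {v}")
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=index)
    return path


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read back a table written by :func:`write_csv` (skips the header comments)."""
    return pd.read_csv(path, comment="#", **kwargs)


def descriptor_table(
    partitions: Mapping[str, EdgePartition], round_digits: int | None = None
) -> pd.DataFrame:
    """One descriptor row per molecule, columns in canonical index order."""
    rows = {}
    for name, part in partitions.items():
        vec = compute_all(part)
        rows[name] = vec.rounded(round_digits).to_dict() if round_digits is not None else vec.to_dict()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_NAMES))
    df.index.name = "name"
    return df


def qspr_report(
    ti: pd.DataFrame,
    props: pd.DataFrame,
    outdir: str | Path,
    properties: tuple[str, ...] | None = None,
    coef_digits: int | None = 3,
    force: bool = False,
    metadata: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write the full report bundle for one descriptor/property pairing.

    Emits one parameter table per index, the correlation / SE / r² matrices
    and one actual-vs-computed table per property: 9 + 3 + len(properties)
    CSV files. Returns the written paths.
    """
    outdir = Path(outdir)
    properties = tuple(properties) if properties is not None else tuple(props.columns)
    fits = qspr.fit_all(ti, props, properties)
    diag = qspr.diagnostics_tables(fits)
    r_table, n_table = qspr.correlation_table(ti, props, properties)
    meta = dict(metadata or {})
    written: list[Path] = []

    for idx in INDEX_NAMES:
        written.append(
            write_csv(diag.params[idx], outdir / f"table_params_{idx}.csv",
                      {**meta, "table": f"regression parameters, {idx}"}, force)
        )
    corr = r_table.copy()
    corr.index.name = "index"
    written.append(write_csv(corr, outdir / "table_correlation.csv",
                             {**meta, "table": "correlation coefficients"}, force))
    se = diag.se.copy()
    se.index.name = "index"
    written.append(write_csv(se, outdir / "table_se.csv",
                             {**meta, "table": "standard error of estimate"}, force))
    r2 = diag.r2.copy()
    r2.index.name = "index"
    written.append(write_csv(r2, outdir / "table_r2.csv",
                             {**meta, "table": "coefficient of determination"}, force))
    for prop in properties:
        pred = qspr.prediction_table(ti, props, prop, fits, coef_digits)
        written.append(
            write_csv(pred, outdir / f"table_pred_{prop}.csv",
                      {**meta, "table": f"actual vs computed, {prop}",
                       "coef_digits": coef_digits}, force)
        )
    return written


# --- agreement with the printed tables -------------------------------------

# ledger cross-references: printed cells known to conflict internally
_INDEX_CELL_LEDGER = {
    ("azathioprine", "ABC"): "azathioprine ABC",
    ("azathioprine", "GA"): "azathioprine GA",
    ("psoralen", "RA"): "psoralen Randic RA",
}
_PROPERTY_LEDGER = {
    "polarity": "monobenzone polarity",
    "refractivity": "azathioprine refractivity",
    "molar_volume": "fluticasone molar volume",
}


def _printed_decimals(s: str) -> int:
    s = s.strip()
    return len(s.split(".", 1)[1]) if "." in s else 0

def _matches(computed: float, printed: str) -> bool:
    d = _printed_decimals(printed)
    return f"{round_half_up(computed, d):.{d}f}" == f"{float(printed):.{d}f}"


def _ti_table_printed() -> pd.DataFrame:
    with files("topoqspr.data").joinpath("table1_indices.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh, index_col="drug", dtype=str)


def agreement_report(variant: str = "table2") -> pd.DataFrame:
    """Recompute every reproducible quantity and flag disagreements cell by cell.

    Sections: ``index`` (the nine indices recomputed from the two worked
    edge partitions vs the printed per-drug values), ``regression``
    (A, b, r, r², F, p of all 45 fits on the bundled tables vs the printed
    statistics) and ``se`` (standard error of estimate). Each row carries
    the printed string, the recomputed value, a match flag at printed
    precision, and the discrepancy-ledger entry it maps to, if any.
    """
    rows: list[dict] = []

    printed_ti = _ti_table_printed()
    for drug, part in paper_data.load_worked_partitions().items():
        computed = compute_all(part).to_dict()
        for idx in INDEX_NAMES:
            printed = printed_ti.loc[drug, idx]
            rows.append(
                {
                    "section": "index",
                    "cell": f"{drug}/{idx}",
                    "printed": printed,
                    "computed": computed[idx],
                    "match": _matches(computed[idx], printed),
                    "ledger": _INDEX_CELL_LEDGER.get((drug, idx), ""),
                }
            )

    ti = paper_data.load_ti_table()[list(INDEX_NAMES)]
    props = paper_data.load_property_table(variant)
    fits = qspr.fit_all(ti, props, paper_data.MODELED_PROPERTIES)
    printed_stats = paper_data.load_printed_statistics().set_index(["index", "property"])
    for (idx, prop), printed_row in printed_stats.iterrows():
        fit = fits[(idx, prop)]
        ledger = _PROPERTY_LEDGER.get(prop, "")
        if (idx, prop) == ("H", "polarity"):
            ledger = "H-polarity correlation"
        for col, value in (
            ("A", fit.intercept),
            ("b", fit.slope),
            ("r", fit.r),
            ("r2", fit.r2),
            ("F", fit.f_stat),
            ("p", fit.p_value),
        ):
            rows.append(
                {
                    "section": "regression",
                    "cell": f"{idx}/{prop}/{col}",
                    "printed": printed_row[col],
                    "computed": value,
                    "match": _matches(value, printed_row[col]),
                    "ledger": ledger,
                }
            )
        rows.append(
            {
                "section": "se",
                "cell": f"{idx}/{prop}/se",
                "printed": printed_row["se"],
                "computed": fit.se,
                "match": _matches(fit.se, printed_row["se"]),
                "ledger": ledger,
            }
        )
    return pd.DataFrame(rows)
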