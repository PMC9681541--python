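"""Univariate linear structure-property models and their diagnostic tables.

The model is the one-descriptor line ``P = A + b * TI`` fitted by ordinary
least squares, one fit per (index, property) pair, with pairwise deletion of
molecules missing either value. Reported per fit: intercept A, slope b,
sample size n, Pearson r, r², the standard error of estimate
``se = sqrt(SSE / (n - 2))``, the single-predictor F statistic with
(1, n-2) degrees of freedom, and its upper-tail p-value.

No multiple-testing correction is applied: the 45 models are reported as
independent univariate screens, and significance is flagged by the working
convention ``p < 0.05 OR r > 0.6`` with both sub-conditions recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import INDEX_NAMES, round_half_up

__all__ = [
    "RegressionFit",
    "InsufficientDataError",
    "DegeneratePredictorError",
    "DegenerateResponseError",
    "fit_simple_linear",
    "predict",
    "fit_all",
    "correlation_table",
    "diagnostics_tables",
    "prediction_table",
    "Diagnostics",
    "P_THRESHOLD",
    "R_THRESHOLD",
]

#: Significance conventions: flag a model when p < P_THRESHOLD or r > R_THRESHOLD.
P_THRESHOLD = 0.05
R_THRESHOLD = 0.6


class InsufficientDataError(ValueError):
    """Fewer than 3 complete (x, y) pairs after pairwise deletion."""


class DegeneratePredictorError(ValueError):
    """The descriptor has zero variance; the slope is unidentifiable."""


class DegenerateResponseError(ValueError):
    """The response has zero variance; r is undefined."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one property on one topological index."""

    intercept: float
    slope: float
    n: int
    r: float
    r2: float
    se: float
    f_stat: float
    p_value: float

    def significant(self) -> bool:
        return self.p_value < P_THRESHOLD or self.r > R_THRESHOLD


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"x and y must be paired; got lengths {x.size} and {y.size}")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def fit_simple_linear(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Fit ``y = A + b x`` by OLS after pairwise deletion of missing values.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 complete pairs remain.
    DegeneratePredictorError, DegenerateResponseError
        If x (resp. y) has zero variance among the retained pairs.
    """
    xc, yc = _pairwise_complete(x, y)
    n = xc.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(xc) == 0:
        raise DegeneratePredictorError("descriptor has zero variance")
    if np.ptp(yc) == 0:
        raise DegenerateResponseError("response has zero variance; r undefined")

    res = stats.linregress(xc, yc)
    r = float(res.rvalue)
    r2 = r * r
    resid = yc - (res.intercept + res.slope * xc)
    sse = float(resid @ resid)
    se = math.sqrt(sse / (n - 2))
    if r2 >= 1.0 or sse == 0.0:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p_value = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        n=int(n),
        r=r,
        r2=r2,
        se=se,
        f_stat=f_stat,
        p_value=p_value,
    )


def predict(fit: RegressionFit, x, coef_digits: int | None = None):
    """Evaluate ``A + b x`` elementwise.

    ``coef_digits`` rounds the coefficients (half-up) before predicting;
    printed comparison tables in the QSPR literature are routinely generated
    from the published rounded coefficients, and this switch reproduces that
    convention. ``None`` keeps full precision.
    """
    a, b = fit.intercept, fit.slope
    if coef_digits is not None:
        a = round_half_up(a, coef_digits)
        b = round_half_up(b, coef_digits)
    x = np.asarray(x, dtype=float)
    out = a + b * x
    return float(out) if out.ndim == 0 else out


def _join(ti: pd.DataFrame, props: pd.DataFrame) -> pd.DataFrame:
    joined = ti.join(props, how="inner")
    if joined.empty:
        raise InsufficientDataError("descriptor and property tables share no molecules")
    return joined


def fit_all(
    ti: pd.DataFrame,
    props: pd.DataFrame,
    properties: Sequence[str] | None = None,
) -> dict[tuple[str, str], RegressionFit]:
    """Fit every (index, property) pair, joining the tables on molecule key.

    ``ti`` must carry the nine canonical index columns; ``props`` the property
    columns (NaN = missing). Returns a dict keyed by ``(index, property)``.
    """
    properties = list(properties) if properties is not None else list(props.columns)
    joined = _join(ti, props)
    fits: dict[tuple[str, str], RegressionFit] = {}
    for idx in INDEX_NAMES:
        for prop in properties:
            fits[(idx, prop)] = fit_simple_linear(joined[idx], joined[prop])
    return fits


def correlation_table(
    ti: pd.DataFrame,
    props: pd.DataFrame,
    properties: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r per (index, property) cell, with the per-cell sample size.

    Returns ``(r_table, n_table)``: 9 x len(properties) frames indexed by
    index name. Each cell is the r of the corresponding univariate fit
    (pairwise deletion per cell).
    """
    properties = list(properties) if properties is not None else list(props.columns)
    fits = fit_all(ti, props, properties)
    r = pd.DataFrame(index=list(INDEX_NAMES), columns=properties, dtype=float)
    n = pd.DataFrame(index=list(INDEX_NAMES), columns=properties, dtype="Int64")
    for (idx, prop), fit in fits.items():
        r.loc[idx, prop] = fit.r
        n.loc[idx, prop] = fit.n
    return r, n


@dataclass(frozen=True)
class Diagnostics:
    """The full report bundle for a set of univariate fits.

    ``params`` holds one frame per index (rows = properties, columns
    N/A/b/r/r2/F/p/significant plus the two sub-condition flags); ``se`` and
    ``r2`` are 9 x properties matrices of the standard error of estimate and
    the coefficient of determination.
    """

    params: dict[str, pd.DataFrame]
    se: pd.DataFrame
    r2: pd.DataFrame


def diagnostics_tables(fits: dict[tuple[str, str], RegressionFit]) -> Diagnostics:
    """Assemble per-index parameter tables and the SE / r² matrices."""
    properties = list(dict.fromkeys(prop for _, prop in fits))
    params: dict[str, pd.DataFrame] = {}
    se = pd.DataFrame(index=list(INDEX_NAMES), columns=properties, dtype=float)
    r2 = pd.DataFrame(index=list(INDEX_NAMES), columns=properties, dtype=float)
    for idx in INDEX_NAMES:
        rows = []
        for prop in properties:
            fit = fits[(idx, prop)]
            rows.append(
                {
                    "property": prop,
                    "N": fit.n,
                    "A": fit.intercept,
                    "b": fit.slope,
                    "r": fit.r,
                    "r2": fit.r2,
                    "F": fit.f_stat,
                    "p": fit.p_value,
                    "sig_p": fit.p_value < P_THRESHOLD,
                    "sig_r": fit.r > R_THRESHOLD,
                    "indicator": "Significant" if fit.significant() else "Not significant",
                }
            )
            se.loc[idx, prop] = fit.se
            r2.loc[idx, prop] = fit.r2
        params[idx] = pd.DataFrame(rows).set_index("property")
    return Diagnostics(params=params, se=se, r2=r2)


def prediction_table(
    ti: pd.DataFrame,
    props: pd.DataFrame,
    prop: str,
    fits: dict[tuple[str, str], RegressionFit] | None = None,
    coef_digits: int | None = 3,
) -> pd.DataFrame:
    """Actual vs model-computed values of one property, one column per index.

    Predictions are made for every molecule with a descriptor value,
    including those whose observed property is missing (the fit itself uses
    only complete pairs). ``coef_digits`` defaults to 3, the precision at
    which published model coefficients are typically quoted.
    """
    if fits is None:
        fits = fit_all(ti, props, [prop])
    joined = _join(ti, props[[prop]])
    out = pd.DataFrame(index=joined.index)
    out["actual"] = joined[prop]
    for idx in INDEX_NAMES:
        out[idx] = predict(fits[(idx, prop)], joined[idx].to_numpy(), coef_digits)
    return out
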