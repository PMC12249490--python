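"""Per-timepoint removal of the linear dependence of enrichment on N_EH.

At every labeling duration the enrichment values of a peptide group (one
protein, or the whole dataset) are regressed on the peptides' N_EH counts by
ordinary least squares.  The fitted linear component is then subtracted about
the regression centroid,

    px_adj_i = px_i - slope * (neh_i - mean(neh)),

which rotates the regression line flat while preserving both the residuals
and the per-timepoint mean enrichment.  Refitting the regression on adjusted
values gives a slope of zero to machine precision, and the operation is
idempotent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

REGRESSION_MIN_POINTS = 3


@dataclass
class NehRegression:
    """OLS of enrichment (or rate) on N_EH at one labeling duration."""

    time: float
    slope: float
    intercept: float
    slope_stderr: float
    slope_ci95: tuple[float, float]
    p_value: float
    n_peptides: int
    scope: str
    neh_mean: float
    estimable: bool = True
    message: str = ""
    group: str = ""

    @classmethod
    def not_estimable(cls, time: float, scope: str, n: int, message: str) -> "NehRegression":
        return cls(
            time=time, slope=0.0, intercept=math.nan, slope_stderr=math.nan,
            slope_ci95=(math.nan, math.nan), p_value=math.nan, n_peptides=n,
            scope=scope, neh_mean=math.nan, estimable=False, message=message,
        )


def fit_neh_regression(
    px_values,
    neh_values,
    time: float = math.nan,
    scope: str = "global",
) -> NehRegression:
    """Ordinary least-squares regression of enrichment on N_EH.

    Returns slope/intercept with the slope's standard error, two-sided
    t-test p-value against slope = 0, and 95% confidence interval.  Fewer
    than three points, or a single distinct N_EH value, yield a
    not-estimable result instead of raising.
    """
    px = np.asarray(px_values, dtype=float)
    neh = np.asarray(neh_values, dtype=float)
    if px.shape != neh.shape:
        raise ValueError("px_values and neh_values must have equal length")
    ok = np.isfinite(px) & np.isfinite(neh)
    px, neh = px[ok], neh[ok]
    n = int(px.size)
    if n < REGRESSION_MIN_POINTS:
        return NehRegression.not_estimable(
            time, scope, n, f"{n} points < minimum {REGRESSION_MIN_POINTS}"
        )
    if np.ptp(neh) == 0:
        return NehRegression.not_estimable(
            time, scope, n, "all N_EH values identical; slope undefined"
        )
    res = stats.linregress(neh, px)
    tcrit = stats.t.ppf(0.975, df=n - 2) if n > 2 else math.nan
    half = tcrit * res.stderr
    p_value = float(res.pvalue)
    if not math.isfinite(p_value):
        # perfect fit (zero residual): the slope test is degenerate
        p_value = 1.0 if res.slope == 0.0 else 0.0
    return NehRegression(
        time=time,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_stderr=float(res.stderr),
        slope_ci95=(float(res.slope - half), float(res.slope + half)),
        p_value=p_value,
        n_peptides=n,
        scope=scope,
        neh_mean=float(neh.mean()),
    )


def adjust_enrichment(px_values, neh_values, regression: NehRegression) -> np.ndarray:
    """Subtract the fitted N_EH-linear component about the regression centroid.

    Residuals are preserved and the mean enrichment is unchanged.  A
    not-estimable regression passes the values through unchanged with a
    logged warning.
    """
    px = np.asarray(px_values, dtype=float)
    neh = np.asarray(neh_values, dtype=float)
    if px.shape != neh.shape:
        raise ValueError("px_values and neh_values must have equal length")
    if not regression.estimable:
        log.warning(
            "N_EH regression at t=%s not estimable (%s); enrichment left unadjusted",
            regression.time, regression.message,
        )
        return px.copy()
    return px - regression.slope * (neh - regression.neh_mean)


def debias_dataset(
    data: pd.DataFrame,
    scope: str = "per_protein",
    px_col: str = "px",
    out_col: str = "px_adj",
) -> tuple[pd.DataFrame, list[NehRegression]]:
    """Apply the per-timepoint N_EH regression adjustment to a long table.

    ``data`` needs columns ``protein_id``, ``peptide``, ``time_days``,
    ``neh`` and ``px_col``.  ``scope="per_protein"`` fits one regression per
    (protein, timepoint); ``scope="global"`` pools all peptides at each
    timepoint.  Returns a copy with ``out_col`` added plus the regression
    audit trail.  Undersized groups are passed through unchanged.
    """
    if scope not in ("per_protein", "global"):
        raise ValueError(f"scope must be 'per_protein' or 'global', got {scope!r}")
    required = {"protein_id", "peptide", "time_days", "neh", px_col}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    out = data.copy()
    out[out_col] = out[px_col].astype(float)
    keys = ["time_days"] if scope == "global" else ["protein_id", "time_days"]
    audit: list[NehRegression] = []
    for key, group in out.groupby(keys, sort=True):
        if scope == "global":
            time, label = float(key[0]), "all"
        else:
            time, label = float(key[1]), str(key[0])
        reg = fit_neh_regression(
            group[px_col].to_numpy(float), group["neh"].to_numpy(float),
            time=time, scope=scope,
        )
        reg.group = label
        audit.append(reg)
        if reg.estimable:
            out.loc[group.index, out_col] = adjust_enrichment(
                group[px_col].to_numpy(float), group["neh"].to_numpy(float), reg
            )
    return out, audit


def audit_table(regressions: list[NehRegression]) -> pd.DataFrame:
    """Tabular audit trail of per-timepoint regressions."""
    return pd.DataFrame(
        {
            "time_days": [r.time for r in regressions],
            "scope": [r.scope for r in regressions],
            "group": [r.group for r in regressions],
            "slope": [r.slope for r in regressions],
            "intercept": [r.intercept for r in regressions],
            "slope_stderr": [r.slope_stderr for r in regressions],
            "ci95_low": [r.slope_ci95[0] for r in regressions],
            "ci95_high": [r.slope_ci95[1] for r in regressions],
            "p_value": [r.p_value for r in regressions],
            "n_peptides": [r.n_peptides for r in regressions],
            "estimable": [r.estimable for r in regressions],
        }
    )
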