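"""Dataset-level orchestration shared by the CLI and the benchmark study.

Works on long/tidy tables with one row per (peptide, timepoint):
``protein_id, peptide, time_days, i0, neh`` and optionally ``i0_natural``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from turnoverkit.chemistry import PeptideRecord
from turnoverkit.enrichment import EnrichmentSeries, TimeCourse, extract_enrichment
from turnoverkit.kinetics import (
    MIN_TIMEPOINTS,
    KineticFit,
    LabelingParameters,
    fit_adjusted,
    fit_classical_px,
    fit_classical_ra,
)
from turnoverkit.protein_stats import (
    NotSummarizableError,
    ProteinSummary,
    summarize_protein,
)

log = logging.getLogger(__name__)

MODELS = ("classical", "proposed", "both")


def peptide_references(
    data: pd.DataFrame, use_theoretical: bool = False
) -> pd.Series:
    """Per-peptide reference RA I0(0), indexed by (protein_id, peptide).

    Default is the measured 0-day observation (duplicates averaged); falls
    back to the ``i0_natural`` column when no 0-day row exists, and uses
    ``i0_natural`` for everything when ``use_theoretical`` is set.
    """
    keys = ["protein_id", "peptide"]
    theoretical = (
        data.groupby(keys)["i0_natural"].first()
        if "i0_natural" in data.columns
        else pd.Series(dtype=float)
    )
    if use_theoretical:
        if theoretical.empty:
            raise ValueError("use_theoretical requires an i0_natural column")
        return theoretical
    at_zero = data[data["time_days"] == 0]
    measured = at_zero.groupby(keys)["i0"].mean()
    all_keys = data.groupby(keys).size().index
    ref = measured.reindex(all_keys)
    if ref.isna().any() and not theoretical.empty:
        ref = ref.fillna(theoretical.reindex(all_keys))
    if ref.isna().any():
        missing = ref[ref.isna()].index.tolist()[:5]
        raise ValueError(
            f"no 0-day observation or i0_natural for peptides, e.g. {missing}"
        )
    return ref


def attach_enrichment(
    data: pd.DataFrame,
    params: LabelingParameters,
    mode: str = "verbatim",
    use_theoretical_reference: bool = False,
) -> pd.DataFrame:
    """Add a ``px`` column (excess enrichment) to a long time-course table."""
    ref = peptide_references(data, use_theoretical=use_theoretical_reference)
    out = data.reset_index(drop=True).copy()
    px = np.empty(len(out))
    for (key, group) in out.groupby(["protein_id", "peptide"], sort=False):
        px_vals = extract_enrichment(
            group["i0"].to_numpy(float),
            float(ref.loc[key]),
            float(group["neh"].iloc[0]),
            params.p_h,
            mode=mode,
        )
        px[out.index.get_indexer(group.index)] = px_vals
    out["px"] = px
    return out


def _peptide_record(group: pd.DataFrame, ref: float) -> PeptideRecord:
    return PeptideRecord(
        sequence=str(group["peptide"].iloc[0]),
        protein_id=str(group["protein_id"].iloc[0]),
        n_eh=float(group["neh"].iloc[0]),
        i0_natural=min(max(ref, 1e-12), 1.0),
    )


def fit_dataset(
    data: pd.DataFrame,
    params: LabelingParameters,
    model: str = "both",
    px_col: str = "px",
    min_points: int = MIN_TIMEPOINTS,
    use_theoretical_reference: bool = False,
) -> pd.DataFrame:
    """Fit turnover rates for every peptide in a long table.

    ``model`` selects the classical RA fit, the proposed (N_EH-rescaled)
    enrichment fit, or both.  Returns one row per peptide with the fitted
    rate(s), standard errors, and convergence flags; fit objects are kept in
    ``attrs['fits']`` keyed by (protein_id, peptide, model).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    ref = peptide_references(data, use_theoretical=use_theoretical_reference)
    rows = []
    fits: dict[tuple[str, str, str], KineticFit] = {}
    for key, group in data.groupby(["protein_id", "peptide"], sort=False):
        group = group.sort_values("time_days")
        peptide = _peptide_record(group, float(ref.loc[key]))
        times = group["time_days"].to_numpy(float)
        row: dict[str, object] = {
            "protein_id": key[0],
            "peptide": key[1],
            "neh": peptide.n_eh,
            "n_obs": len(group),
        }
        if model in ("classical", "both"):
            tc = TimeCourse(
                peptide=peptide, times=times,
                i0_values=group["i0"].to_numpy(float),
                i0_reference=float(ref.loc[key]),
            )
            fit = fit_classical_ra(tc, params, min_points=min_points)
            fits[(key[0], key[1], "classical")] = fit
            row.update(
                k_classical=fit.k, k_classical_stderr=fit.k_stderr,
                classical_converged=fit.converged, classical_status=fit.status.value,
            )
        if model in ("proposed", "both"):
            es = EnrichmentSeries(
                peptide=peptide, times=times,
                px_values=group[px_col].to_numpy(float),
            )
            fit = fit_adjusted(es, params, min_points=min_points)
            fits[(key[0], key[1], "proposed")] = fit
            row.update(
                k_proposed=fit.k, k_proposed_stderr=fit.k_stderr,
                proposed_converged=fit.converged, proposed_status=fit.status.value,
            )
        rows.append(row)
    result = pd.DataFrame(rows)
    result.attrs["fits"] = fits
    return result


def fit_dataset_classical_px(
    data: pd.DataFrame,
    params: LabelingParameters,
    px_col: str = "px",
    min_points: int = MIN_TIMEPOINTS,
) -> pd.DataFrame:
    """Classical kinetics fitted in the transformed enrichment space."""
    rows = []
    for key, group in data.groupby(["protein_id", "peptide"], sort=False):
        group = group.sort_values("time_days")
        peptide = _peptide_record(group, 1.0)
        es = EnrichmentSeries(
            peptide=peptide,
            times=group["time_days"].to_numpy(float),
            px_values=group[px_col].to_numpy(float),
        )
        fit = fit_classical_px(es, params, min_points=min_points)
        rows.append(
            {
                "protein_id": key[0], "peptide": key[1], "neh": peptide.n_eh,
                "k_classical_px": fit.k, "classical_px_converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def summarize_fits(
    fit_table: pd.DataFrame, which: str
) -> dict[str, ProteinSummary]:
    """Protein summaries from a ``fit_dataset`` result for one model column."""
    k_col = f"k_{which}"
    conv_col = f"{which}_converged"
    fits = fit_table.attrs.get("fits", {})
    summaries: dict[str, ProteinSummary] = {}
    for protein_id, group in fit_table.groupby("protein_id", sort=True):
        triples = []
        for _, row in group.iterrows():
            fit = fits.get((row["protein_id"], row["peptide"], which))
            if fit is None:
                fit = KineticFit(
                    k=float(row[k_col]), model=which,  # type: ignore[arg-type]
                    converged=bool(row[conv_col]),
                )
            triples.append((row["peptide"], fit, float(row["neh"])))
        try:
            summaries[str(protein_id)] = summarize_protein(triples, str(protein_id))
        except NotSummarizableError:
            log.warning("protein %s has no converged %s fits", protein_id, which)
    return summaries


def summary_table(summaries: dict[str, ProteinSummary]) -> pd.DataFrame:
    """Flat protein summary table for text export."""
    from turnoverkit.protein_stats import slope_test_k_vs_neh

    rows = []
    for pid, s in summaries.items():
        reg = slope_test_k_vs_neh(s)
        rows.append(
            {
                "protein_id": pid,
                "n_peptides": s.n_peptides,
                "k_mean": s.k_mean,
                "k_median": s.k_median,
                "k_sd": s.k_sd,
                "model": s.model,
                "slope_vs_neh": reg.slope if reg.estimable else math.nan,
                "slope_p": reg.p_value if reg.estimable else math.nan,
            }
        )
    return pd.DataFrame(rows)
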