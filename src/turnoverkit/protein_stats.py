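"""Protein-level aggregation of peptide fits and comparison statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from turnoverkit.debias import NehRegression, fit_neh_regression
from turnoverkit.kinetics import KineticFit


class NotSummarizableError(ValueError):
    """No converged peptide fits to aggregate."""


class NotEstimableError(ValueError):
    """Too few values for the requested statistic."""


@dataclass
class ProteinSummary:
    """Summary of one protein's peptide-level turnover rates.

    Only converged fits are counted; ``k_sd`` uses the sample (n-1)
    denominator and is reported as 0 with ``single_peptide=True`` when only
    one peptide converged.
    """

    protein_id: str
    n_peptides: int
    k_mean: float
    k_median: float
    k_sd: float
    model: str
    per_peptide: list[tuple[str, KineticFit, float]] = field(default_factory=list)
    single_peptide: bool = False


@dataclass
class MethodComparison:
    """Per-protein SD of peptide rates under the two fitting approaches."""

    protein_id: str
    sd_existing: float
    sd_proposed: float
    relative_difference: float
    defined: bool = True


class TwoConditionTest(NamedTuple):
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def summarize_protein(
    fits: Sequence[tuple[str, KineticFit, float]],
    protein_id: str,
) -> ProteinSummary:
    """Aggregate converged peptide fits into protein-level rate statistics."""
    converged = [(pep, fit, neh) for pep, fit, neh in fits if fit.converged]
    if not converged:
        raise NotSummarizableError(f"no converged fits for protein {protein_id!r}")
    ks = np.array([fit.k for _, fit, _ in converged], dtype=float)
    model = converged[0][1].model
    single = ks.size == 1
    return ProteinSummary(
        protein_id=protein_id,
        n_peptides=int(ks.size),
        k_mean=float(ks.mean()),
        k_median=float(np.median(ks)),
        k_sd=0.0 if single else float(ks.std(ddof=1)),
        model=str(getattr(model, "value", model)),
        per_peptide=list(converged),
        single_peptide=single,
    )


def slope_test_k_vs_neh(summary: ProteinSummary) -> NehRegression:
    """OLS regression of peptide turnover rate on N_EH with slope p-value."""
    ks = [fit.k for _, fit, _ in summary.per_peptide]
    nehs = [neh for _, _, neh in summary.per_peptide]
    return fit_neh_regression(ks, nehs, time=math.nan, scope="per_protein")


def compare_methods(existing: ProteinSummary, proposed: ProteinSummary) -> MethodComparison:
    """Relative SD difference (sd_existing - sd_proposed) / sd_existing."""
    if existing.protein_id != proposed.protein_id:
        raise ValueError(
            f"protein mismatch: {existing.protein_id!r} vs {proposed.protein_id!r}"
        )
    if existing.k_sd == 0.0:
        return MethodComparison(
            protein_id=existing.protein_id,
            sd_existing=0.0,
            sd_proposed=proposed.k_sd,
            relative_difference=math.nan,
            defined=False,
        )
    rel = (existing.k_sd - proposed.k_sd) / existing.k_sd
    return MethodComparison(
        protein_id=existing.protein_id,
        sd_existing=existing.k_sd,
        sd_proposed=proposed.k_sd,
        relative_difference=rel,
    )


def two_condition_test(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    equal_var: bool = False,
) -> TwoConditionTest:
    """Two-sample t-test on peptide-level rates across two conditions.

    Welch's unequal-variance test by default; set ``equal_var=True`` for the
    pooled Student variant.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise NotEstimableError(
            f"need >= 2 rates per group, got {a.size} and {b.size}"
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TwoConditionTest(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )
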