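"""Kinetic models for first-order protein turnover under heavy-water labeling.

Three fits share one bounded single-parameter nonlinear least-squares core:

* ``fit_classical_ra``  — exponential decay of the monoisotopic RA towards a
  plateau fixed by the body-water enrichment and N_EH.
* ``fit_classical_px``  — the same kinetics written on the transformed
  observable ((1 - p_X)/(1 - p_H))**N_EH; identical k on noiseless data.
* ``fit_adjusted``      — the N_EH-rescaled model: p_X is replaced by
  p_X/N_EH, which makes the fitted rate practically independent of N_EH.

Analytic diagnostics (``half_life_ratio_*``) evaluate, at the true protein
half-life, the modeled fraction of unlabeled protein relative to the labeling
plateau.  An unbiased model gives exactly 1/2; the classical model drifts
below it as N_EH grows while the rescaled model stays at ~0.495.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from turnoverkit.chemistry import DEFAULT_P_H
from turnoverkit.enrichment import EnrichmentSeries, TimeCourse

#: Default bounds for the turnover rate, day^-1.
K_BOUNDS = (1e-6, 10.0)
#: Default minimum number of usable timepoints for a fit.
MIN_TIMEPOINTS = 4


class FitModel(str, Enum):
    CLASSICAL_RA = "classical_ra"
    CLASSICAL_PX = "classical_px"
    ADJUSTED_PX = "adjusted_px"


class FitStatus(str, Enum):
    OK = "ok"
    NOT_FITTABLE = "not_fittable"
    NO_CONVERGENCE = "no_convergence"


@dataclass(frozen=True)
class LabelingParameters:
    """Body-water enrichment p_W and natural deuterium abundance p_H."""

    p_w: float
    p_h: float = DEFAULT_P_H

    def __post_init__(self) -> None:
        if not (0.0 < self.p_w < 0.1):
            raise ValueError(f"p_w must be in (0, 0.1), got {self.p_w}")
        if not (0.0 <= self.p_h < self.p_w):
            raise ValueError(f"p_h must satisfy 0 <= p_h < p_w, got {self.p_h}")


@dataclass
class KineticFit:
    """A fitted turnover rate with diagnostics.

    ``half_life`` is derived (ln 2 / k) and always satisfies
    ``half_life * k == ln 2`` exactly.
    """

    k: float
    model: FitModel
    k_stderr: float = math.nan
    residual_sse: float = math.nan
    n_points: int = 0
    converged: bool = False
    p_w_used: float = math.nan
    status: FitStatus = FitStatus.OK
    message: str = ""

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.k

    @classmethod
    def not_fittable(cls, model: FitModel, message: str, n_points: int = 0) -> "KineticFit":
        return cls(
            k=math.nan, model=model, n_points=n_points,
            converged=False, status=FitStatus.NOT_FITTABLE, message=message,
        )


def asymptote_classical(i0_0: float, params: LabelingParameters, n_eh: float) -> float:
    """Plateau monoisotopic RA at complete labeling equilibrium."""
    if n_eh <= 0:
        raise ValueError("n_eh must be positive")
    return i0_0 * ((1.0 - params.p_w) / (1.0 - params.p_h)) ** n_eh


def _initial_rate(t: np.ndarray, y: np.ndarray, plateau: float, start: float) -> float:
    """Log-linear starting value for k from the interior of the decay."""
    span = start - plateau
    if span == 0:
        return 0.1
    frac = (y - plateau) / span
    ok = (frac > 1e-12) & (frac < 1.0) & (t > 0)
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(frac[ok]), 1)[0]
        k0 = -slope
    elif ok.sum() == 1:
        k0 = -math.log(float(frac[ok][0])) / float(t[ok][0])
    else:
        k0 = 0.1
    return float(min(max(k0, K_BOUNDS[0] * 10), K_BOUNDS[1] / 10))


def _fit_exponential_approach(
    t: np.ndarray,
    y: np.ndarray,
    plateau: float,
    start: float,
    model: FitModel,
    p_w_used: float,
    min_points: int = MIN_TIMEPOINTS,
) -> KineticFit:
    """Least-squares fit of y(t) = plateau + (start - plateau) * exp(-k t)."""
    mask = np.isfinite(y) & np.isfinite(t)
    t, y = t[mask], y[mask]
    n = int(t.size)
    if n < min_points:
        return KineticFit.not_fittable(
            model, f"{n} usable timepoints < minimum {min_points}", n_points=n
        )
    if math.isclose(start, plateau):
        return KineticFit.not_fittable(
            model, "degenerate series: start equals plateau, no decay information",
            n_points=n,
        )

    span = start - plateau

    def residuals(theta: np.ndarray) -> np.ndarray:
        return plateau + span * np.exp(-theta[0] * t) - y

    k0 = _initial_rate(t, y, plateau, start)
    res = least_squares(
        residuals, x0=[k0], bounds=([K_BOUNDS[0]], [K_BOUNDS[1]]),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    sse = float(2.0 * res.cost)
    k = float(res.x[0])
    stderr = math.nan
    if n > 1:
        jtj = float(np.asarray(res.jac.T @ res.jac).reshape(()))
        if jtj > 0:
            stderr = math.sqrt(max(sse, 0.0) / (n - 1) / jtj)
    converged = bool(res.success)
    at_bound = k > K_BOUNDS[1] * 0.99 or k < K_BOUNDS[0] * 1.01
    status = FitStatus.OK if converged else FitStatus.NO_CONVERGENCE
    message = "k at bound" if at_bound else ""
    return KineticFit(
        k=k, model=model, k_stderr=stderr, residual_sse=sse, n_points=n,
        converged=converged and not at_bound, p_w_used=p_w_used,
        status=status, message=message,
    )


def fit_classical_ra(
    tc: TimeCourse,
    params: LabelingParameters,
    min_points: int = MIN_TIMEPOINTS,
) -> KineticFit:
    """Fit the exponential decay of the monoisotopic RA.

    The plateau is fixed analytically from p_W and the peptide's N_EH; the
    only free parameter is the turnover rate k.
    """
    mask = tc.valid_mask
    plateau = asymptote_classical(tc.i0_reference, params, tc.peptide.n_eh)
    return _fit_exponential_approach(
        tc.times[mask], tc.i0_values[mask],
        plateau=plateau, start=tc.i0_reference,
        model=FitModel.CLASSICAL_RA, p_w_used=params.p_w, min_points=min_points,
    )


def fit_classical_px(
    es: EnrichmentSeries,
    params: LabelingParameters,
    min_points: int = MIN_TIMEPOINTS,
) -> KineticFit:
    """Fit the growth-to-plateau kinetics of the excess enrichment.

    The observable is transformed to ((1 - p_X)/(1 - p_H))**N_EH, which the
    model describes as A + (1 - A) exp(-k t) with A the normalized plateau.
    """
    n_eh = es.peptide.n_eh
    y = ((1.0 - es.px_values) / (1.0 - params.p_h)) ** n_eh
    a = ((1.0 - params.p_w) / (1.0 - params.p_h)) ** n_eh
    return _fit_exponential_approach(
        es.times, y, plateau=a, start=1.0,
        model=FitModel.CLASSICAL_PX, p_w_used=params.p_w, min_points=min_points,
    )


def fit_adjusted(
    es: EnrichmentSeries,
    params: LabelingParameters,
    min_points: int = MIN_TIMEPOINTS,
) -> KineticFit:
    """Fit the N_EH-rescaled kinetics (p_X replaced by p_X / N_EH).

    The observable is ((1 - p_X/N_EH)/(1 - p_H))**N_EH fitted to
    A' + (1 - A') exp(-k t) with A' = ((1 - p_W/N_EH)/(1 - p_H))**N_EH.
    The series may be raw or debias-adjusted.
    """
    n_eh = es.peptide.n_eh
    y = ((1.0 - es.px_values / n_eh) / (1.0 - params.p_h)) ** n_eh
    a = ((1.0 - params.p_w / n_eh) / (1.0 - params.p_h)) ** n_eh
    return _fit_exponential_approach(
        es.times, y, plateau=a, start=1.0,
        model=FitModel.ADJUSTED_PX, p_w_used=params.p_w, min_points=min_points,
    )


def _plateau_ratio(x_half: float, x_full: float, p_h: float, n_eh: float) -> float:
    a = ((1.0 - x_half) / (1.0 - p_h)) ** n_eh
    b = ((1.0 - x_full) / (1.0 - p_h)) ** n_eh
    denom = 1.0 - b
    if denom == 0.0:
        raise ZeroDivisionError(
            "half-life ratio undefined when p_w equals p_h (no labeling contrast)"
        )
    return (a - b) / denom


def half_life_ratio_classical(n_eh: float, params: LabelingParameters) -> float:
    """Classical model's unlabeled-relative-to-plateau fraction at the half-life.

    Equals 1/2 for an unbiased model; decreases with N_EH at practical body
    water enrichments (e.g. 0.43 at N_EH=15 and 0.38 at N_EH=25 for
    p_W=0.04), which is the analytic signature of the N_EH bias.
    """
    if n_eh <= 0:
        raise ValueError("n_eh must be positive")
    return _plateau_ratio(params.p_w / 2.0, params.p_w, params.p_h, n_eh)


def half_life_ratio_adjusted(n_eh: float, params: LabelingParameters) -> float:
    """Same diagnostic for the N_EH-rescaled model; ~0.495 for all N_EH."""
    if n_eh <= 0:
        raise ValueError("n_eh must be positive")
    return _plateau_ratio(
        params.p_w / (2.0 * n_eh), params.p_w / n_eh, params.p_h, n_eh
    )


def fractional_synthesis(i0_t: float, i0_0: float, i0_asymp: float) -> float:
    """Fraction of newly synthesized protein implied by an RA observation.

    f(t) = 1 - (I0(t) - I0_asymp) / (I0(0) - I0_asymp); the unlabeled
    fraction is 1 - f.
    """
    denom = i0_0 - i0_asymp
    if denom == 0.0:
        raise ZeroDivisionError("fractional synthesis undefined: I0(0) equals the plateau")
    return 1.0 - (i0_t - i0_asymp) / denom


def taylor_limit_enrichment(p_w: float, k: float, t) -> float | np.ndarray:
    """First-order (small p_W) limit of the enrichment kinetics.

    p_X(t) = p_W (1 - exp(-k t)); valid for the rescaled model whenever
    N_EH * p_W**2 << 1, i.e. for N_EH up to several hundred.
    """
    t = np.asarray(t, dtype=float)
    out = p_w * (1.0 - np.exp(-k * t))
    return float(out) if out.ndim == 0 else out


def adjusted_model_enrichment(
    k: float, t, n_eh: float, params: LabelingParameters
) -> float | np.ndarray:
    """Exact p_X(t) implied by the N_EH-rescaled kinetics at rate ``k``."""
    t = np.asarray(t, dtype=float)
    a = ((1.0 - params.p_w / n_eh) / (1.0 - params.p_h)) ** n_eh
    y = a + (1.0 - a) * np.exp(-k * t)
    px = n_eh * (1.0 - (1.0 - params.p_h) * y ** (1.0 / n_eh))
    return float(px) if px.ndim == 0 else px


def classical_model_enrichment(
    k: float, t, n_eh: float, params: LabelingParameters
) -> float | np.ndarray:
    """Exact p_X(t) implied by the classical kinetics at rate ``k``."""
    t = np.asarray(t, dtype=float)
    a = ((1.0 - params.p_w) / (1.0 - params.p_h)) ** n_eh
    y = a + (1.0 - a) * np.exp(-k * t)
    px = 1.0 - (1.0 - params.p_h) * y ** (1.0 / n_eh)
    return float(px) if px.ndim == 0 else px
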