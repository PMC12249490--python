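"""Conversion between monoisotopic relative abundance and excess deuterium
enrichment.

The forward model maps an enrichment p_X to a monoisotopic RA,

    I0(t) = I0(0) * ((1 - p_X) / (1 - p_H)) ** N_EH

and the extraction inverts it.  Two inversion modes exist: ``"verbatim"``,

    p_X = (1 - p_H) * (1 - (I0(t)/I0(0)) ** (1/N_EH)),

which is the form conventionally printed, and ``"exact"``,

    p_X = 1 - (1 - p_H) * (I0(t)/I0(0)) ** (1/N_EH),

the algebraic inverse of the forward model.  The two differ by O(p_H).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from turnoverkit.chemistry import DEFAULT_P_H, PeptideRecord

EXTRACTION_MODES = ("verbatim", "exact")


@dataclass
class TimeCourse:
    """Observed monoisotopic RA of one peptide over labeling durations (days)."""

    peptide: PeptideRecord
    times: np.ndarray
    i0_values: np.ndarray
    i0_reference: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.i0_values = np.asarray(self.i0_values, dtype=float)
        if self.times.shape != self.i0_values.shape:
            raise ValueError("times and i0_values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.i0_reference > 0:
            raise ValueError("i0_reference must be positive")

    @property
    def valid_mask(self) -> np.ndarray:
        """True where the observation is usable (finite and positive)."""
        return np.isfinite(self.i0_values) & (self.i0_values > 0)


@dataclass
class EnrichmentSeries:
    """Per-peptide excess enrichment p_X over labeling durations.

    Values may be slightly negative after noise or adjustment; they are kept
    as-is so downstream regression sees unbiased errors.
    """

    peptide: PeptideRecord
    times: np.ndarray
    px_values: np.ndarray
    adjusted: bool = field(default=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.px_values = np.asarray(self.px_values, dtype=float)
        if self.times.shape != self.px_values.shape:
            raise ValueError("times and px_values must have equal length")


def predict_monoisotope(p_x, n_eh: float, p_h: float = DEFAULT_P_H, i0_0: float = 1.0):
    """Monoisotopic RA implied by enrichment ``p_x`` (forward model).

    Accepts scalars or arrays for ``p_x``.
    """
    p_x = np.asarray(p_x, dtype=float)
    if np.any(p_x >= 1.0):
        raise ValueError("p_x must be < 1")
    if n_eh <= 0:
        raise ValueError("n_eh must be positive")
    out = i0_0 * ((1.0 - p_x) / (1.0 - p_h)) ** n_eh
    return float(out) if out.ndim == 0 else out


def extract_enrichment(
    i0_t,
    i0_0: float,
    n_eh: float,
    p_h: float = DEFAULT_P_H,
    mode: str = "verbatim",
    clip_negative: bool = False,
):
    """Excess deuterium enrichment from a monoisotopic RA observation.

    Non-positive ``i0_t`` values are returned as NaN (missing observation)
    rather than raising, so batch processing can proceed.  ``i0_t > i0_0``
    yields a negative p_X which is retained unless ``clip_negative`` is set.
    """
    if mode not in EXTRACTION_MODES:
        raise ValueError(f"mode must be one of {EXTRACTION_MODES}, got {mode!r}")
    if not i0_0 > 0:
        raise ValueError("i0_0 must be positive")
    if n_eh <= 0:
        raise ValueError("n_eh must be positive")
    i0_t = np.asarray(i0_t, dtype=float)
    ratio = np.where(i0_t > 0, i0_t / i0_0, np.nan)
    root = ratio ** (1.0 / n_eh)
    if mode == "verbatim":
        px = (1.0 - p_h) * (1.0 - root)
    else:
        px = 1.0 - (1.0 - p_h) * root
    if clip_negative:
        px = np.where(np.isnan(px), px, np.maximum(px, 0.0))
    return float(px) if px.ndim == 0 else px


def series_from_timecourse(
    tc: TimeCourse,
    p_h: float = DEFAULT_P_H,
    mode: str = "verbatim",
    clip_negative: bool = False,
) -> EnrichmentSeries:
    """Convert an observed RA time course into an enrichment series."""
    px = extract_enrichment(
        tc.i0_values, tc.i0_reference, tc.peptide.n_eh, p_h,
        mode=mode, clip_negative=clip_negative,
    )
    return EnrichmentSeries(peptide=tc.peptide, times=tc.times, px_values=px)


def timecourse_from_series(
    es: EnrichmentSeries,
    p_h: float = DEFAULT_P_H,
    i0_0: float | None = None,
) -> TimeCourse:
    """Map an enrichment series back to monoisotopic-RA space (forward model)."""
    ref = es.peptide.i0_natural if i0_0 is None else i0_0
    i0 = predict_monoisotope(es.px_values, es.peptide.n_eh, p_h, ref)
    return TimeCourse(peptide=es.peptide, times=es.times, i0_values=i0, i0_reference=ref)
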