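"""Analytical method-validation arithmetic: linearity, LOD/LOQ, recovery, RSD.

Implements the numeric side of GC-MS/MS method validation for residue
analysis. Instrument data acquisition is out of scope; these routines only
reduce already-measured numbers.

Conventions: LOD/LOQ use the blank-based rule mean + 3*SD / mean + 10*SD
(the standard IUPAC convention); SDs use the n-1 denominator throughout.
Left-censored results (below LOD) are substituted before downstream
statistics, by default with LOD/2.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError, InsufficientDataError, InvalidParameterError

__all__ = [
    "CalibrationSeries",
    "QcReport",
    "fit_calibration",
    "compute_lod_loq",
    "compute_recovery",
    "compute_rsd",
    "substitute_censored",
]


@dataclasses.dataclass(frozen=True)
class CalibrationSeries:
    """Paired (spiked concentration, instrument response) calibration points."""

    concentrations: np.ndarray  # ng/mL
    responses: np.ndarray  # arbitrary signal units

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise DataError("concentrations and responses must be paired 1-D arrays")
        if np.unique(conc).size < 3:
            raise InsufficientDataError(
                "calibration needs >= 3 distinct concentration levels"
            )
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)


@dataclasses.dataclass(frozen=True)
class QcReport:
    """One congener's validation figures (Table-2-style row)."""

    slope: float
    intercept: float
    r_squared: float
    lod: float  # ng/g
    loq: float  # ng/g
    recovery_pct: float
    rsd_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lod <= self.loq):
            raise InvalidParameterError("require 0 <= LOD <= LOQ")
        if not (self.recovery_pct > 0.0 and self.rsd_pct >= 0.0):
            raise InvalidParameterError("recovery must be > 0 and RSD >= 0")


def fit_calibration(series: CalibrationSeries) -> tuple[float, float, float]:
    """Ordinary least-squares calibration line; returns (slope, intercept, r^2).

    ``r^2`` is the squared Pearson correlation of response with concentration.
    """
    conc, resp = series.concentrations, series.responses
    if np.std(conc) == 0.0:
        raise DataError("calibration series has zero variance in concentration")
    fit = stats.linregress(conc, resp)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def compute_lod_loq(blank_values: Sequence[float]) -> tuple[float, float]:
    """Blank-based detection limits: (mean + 3*SD, mean + 10*SD).

    Requires at least 3 blank measurements; SD uses the n-1 denominator.
    """
    blanks = np.asarray(blank_values, dtype=float)
    if blanks.size < 3:
        raise InsufficientDataError(f"need >= 3 blanks, got {blanks.size}")
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    return mean + 3.0 * sd, mean + 10.0 * sd


def compute_recovery(measured: float, spiked: float) -> float:
    """Recovery in percent: 100 * measured / spiked."""
    if not (spiked > 0.0):
        raise InvalidParameterError(f"spiked amount must be > 0, got {spiked}")
    return 100.0 * measured / spiked


def compute_rsd(replicates: Sequence[float]) -> float:
    """Relative standard deviation (CV) in percent, sample SD over mean."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise InsufficientDataError(f"need >= 2 replicates, got {reps.size}")
    mean = float(reps.mean())
    if mean == 0.0:
        raise InvalidParameterError("replicate mean is zero; RSD undefined")
    if np.ptp(reps) == 0.0:  # identical replicates: exactly zero spread
        return 0.0
    return 100.0 * float(reps.std(ddof=1)) / mean


def substitute_censored(
    values: Sequence[float],
    censored: Sequence[bool],
    lod: float,
    loq: float | None = None,
    rule: str = "half_lod",
) -> np.ndarray:
    """Replace left-censored (below-LOD) values per a substitution rule.

    Rules: ``half_lod`` (default, LOD/2), ``lod``, ``zero``. Values between
    LOD and LOQ are quantifiable-with-caution and are retained as reported.
    Idempotent: substituted values are never above LOD, so a second pass
    changes nothing.
    """
    if loq is None:
        loq = lod
    if not (0.0 <= lod <= loq):
        raise InvalidParameterError(f"require 0 <= lod <= loq, got {lod}, {loq}")
    replacements = {"half_lod": lod / 2.0, "lod": lod, "zero": 0.0}
    if rule not in replacements:
        raise InvalidParameterError(
            f"unknown rule {rule!r}; expected one of {sorted(replacements)}"
        )
    vals = np.asarray(values, dtype=float).copy()
    mask = np.asarray(censored, dtype=bool)
    if mask.shape != vals.shape:
        raise DataError("censoring mask must match values in shape")
    vals[mask] = replacements[rule]
    return vals
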