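"""DPPH and MTT assay statistics and the logarithmic dose-response fit.

The radical-scavenging assay reports percent inhibition relative to a
solvent control; the cell-viability assay reports percent of the
untreated-control optical density.  Dose-response curves are modelled as

    response = a * ln(concentration) + b

(an explicitly logarithmic, not sigmoidal, form) and the IC50 is the
concentration at which the fitted response crosses 50%:

    IC50 = exp((50 - b) / a)

Concentrations are ug/mL throughout; no unit inference is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "DoseResponsePoint",
    "LogFit",
    "percent_inhibition",
    "percent_viability",
    "aggregate_replicates",
    "fit_log_response",
    "fit_per_replicate",
    "ic50",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (concentration, mean response) observation, optionally with the
    underlying replicate values."""

    concentration: float  # ug/mL, > 0
    response: float  # percent
    replicate_values: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")


@dataclass(frozen=True)
class LogFit:
    """Parameters of the fit response = a*ln(x) + b, with derived IC50."""

    a: float  # slope, % per ln(ug/mL)
    b: float  # intercept, %
    r2: float
    ic50: float  # ug/mL
    ic50_note: str = ""


def percent_inhibition(a_control: float, a_sample: float) -> float:
    """DPPH scavenging: 100 * (A_control - A_sample) / A_control.

    May be negative when the sample absorbs more than the control.
    """
    if not (math.isfinite(a_control) and math.isfinite(a_sample)):
        raise ValueError("absorbances must be finite")
    if a_control <= 0:
        raise DegenerateInputError(f"control absorbance must be > 0, got {a_control}")
    return 100.0 * (a_control - a_sample) / a_control


def percent_viability(od_sample: float, od_control: float) -> float:
    """MTT viability: 100 * OD_sample / OD_control."""
    if od_control <= 0:
        raise DegenerateInputError(f"control OD must be > 0, got {od_control}")
    return 100.0 * od_sample / od_control


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n)).

    A single replicate yields SEM 0 with a warning rather than an error so
    n=1 pilot columns still flow through reports.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no replicate values given")
    mean = float(values.mean())
    if values.size == 1:
        warnings.warn("single replicate: SEM reported as 0", stacklevel=2)
        return mean, 0.0
    sem = float(values.std(ddof=1) / math.sqrt(values.size))
    return mean, sem


def _solve_ic50(a: float, b: float) -> float:
    return math.exp((50.0 - b) / a)


def fit_log_response(points: list[DoseResponsePoint]) -> LogFit:
    """OLS fit of response on ln(concentration), with IC50 at response=50.

    r2 is the squared Pearson correlation of fitted vs observed response.
    A non-positive slope while the responses span 50% makes the solved
    IC50 an extrapolation against the trend; it is returned but flagged in
    ``ic50_note``.
    """
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 dose-response points, got {len(points)}")
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise DegenerateInputError("all concentrations equal: log-fit is singular")
    res = stats.linregress(np.log(x), y)
    a, b = float(res.slope), float(res.intercept)
    note = ""
    if a == 0.0:
        raise DegenerateInputError("zero slope: IC50 undefined")
    if a < 0 and y.min() < 50.0 < y.max():
        note = "unreliable: negative slope with responses spanning 50%"
    return LogFit(a=a, b=b, r2=float(res.rvalue) ** 2,
                  ic50=_solve_ic50(a, b), ic50_note=note)


def fit_per_replicate(points: list[DoseResponsePoint]) -> tuple[list[LogFit], float, float]:
    """Fit each replicate series separately; return the fits plus the mean
    and SEM of the per-replicate IC50s.

    Requires every point to carry the same number of replicate values.
    """
    n_reps = {len(p.replicate_values or ()) for p in points}
    if len(n_reps) != 1 or 0 in n_reps:
        raise ValueError("all points must carry the same, non-zero replicate count")
    (k,) = n_reps
    fits = []
    for j in range(k):
        series = [
            DoseResponsePoint(p.concentration, p.replicate_values[j]) for p in points
        ]
        fits.append(fit_log_response(series))
    mean, sem = aggregate_replicates([f.ic50 for f in fits])
    return fits, mean, sem


def ic50(fit: LogFit) -> float:
    """IC50 of an existing fit: exp((50 - b) / a)."""
    if fit.a == 0:
        raise DegenerateInputError("zero slope: IC50 undefined")
    return _solve_ic50(fit.a, fit.b)
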