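"""Post-processing of wet-lab readouts.

Three independent analyses used downstream of the computational pipeline:

* four-parameter logistic (4PL) dose-response fitting for IC50
  determination, y = bottom + (top - bottom) / (1 + (x / ic50)^hill),
  fitted by least squares in log10-dose space;
* selectivity index SI = IC50(non-tumor) / IC50(tumor), with exact
  propagation of censored ("> c") non-tumor values as lower bounds;
* Annexin V / propidium iodide quadrant gating of two-channel cytometry
  events into viable, early-apoptotic, late-apoptotic and necrotic
  fractions (exact rational arithmetic on counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponse",
    "CytometryEvents",
    "SelectivityIndex",
    "fit_4pl",
    "four_pl",
    "selectivity_index",
    "quadrant_gate",
]


def four_pl(x, bottom: float, top: float, ic50: float, hill: float):
    """Four-parameter logistic: bottom + (top-bottom)/(1 + (x/ic50)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


@dataclass
class DoseResponse:
    """Dose-response data and its 4PL fit."""

    doses: np.ndarray  # uM, strictly positive
    responses: np.ndarray  # percent
    bottom: float = float("nan")
    top: float = float("nan")
    ic50: float = float("nan")
    hill: float = float("nan")
    fit_ok: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        if self.fit_ok and not self.ic50 > 0:
            raise ValueError("fitted ic50 must be positive")

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.bottom, self.top, self.ic50, self.hill)


def fit_4pl(doses, responses, hill_bounds: tuple[float, float] = (0.1, 10.0)) -> DoseResponse:
    """Least-squares 4PL fit on a log10-dose grid.

    Initialization: bottom/top from the response extremes, ic50 from the
    dose nearest half-maximal response, hill = 1; the Hill slope is
    bounded (default [0.1, 10]).  Non-convergence is reported via
    ``fit_ok=False`` rather than an exception.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if len(np.unique(doses)) < 5:
        raise ValueError("need at least 5 distinct doses")
    logx = np.log10(doses)

    def model(lx, bottom, top, log_ic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (lx - log_ic50)))

    lo, hi = responses.min(), responses.max()
    half = (lo + hi) / 2.0
    log_ic50_0 = logx[np.argmin(np.abs(responses - half))]
    p0 = [lo, hi, log_ic50_0, 1.0]
    span = logx.max() - logx.min() + 1.0
    bounds = (
        [-np.inf, -np.inf, logx.min() - 2 * span, hill_bounds[0]],
        [np.inf, np.inf, logx.max() + 2 * span, hill_bounds[1]],
    )
    try:
        popt, _ = curve_fit(model, logx, responses, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return DoseResponse(doses=doses, responses=responses, fit_ok=False)
    bottom, top, log_ic50, hill = popt
    return DoseResponse(
        doses=doses,
        responses=responses,
        bottom=float(bottom),
        top=float(top),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        fit_ok=True,
    )


@dataclass(frozen=True)
class SelectivityIndex:
    """Ratio of non-tumor to tumor IC50; >1 favors tumor selectivity."""

    value: float  # 2-decimal ratio (lower bound if censored)
    censored: bool

    def __str__(self) -> str:
        return f">{self.value:.2f}" if self.censored else f"{self.value:.2f}"


def selectivity_index(ic50_nontumor, ic50_tumor: float) -> SelectivityIndex:
    """SI = IC50(non-tumor) / IC50(tumor), reported to 2 decimals.

    A censored non-tumor IC50 given as the string ``">c"`` propagates as a
    lower bound (">c/ic50_tumor").  A censored tumor IC50 is not
    supported: the ratio would be an uninformative upper bound.
    """
    if isinstance(ic50_tumor, str):
        raise ValueError("censored tumor IC50 is unsupported")
    if not ic50_tumor > 0:
        raise ValueError("tumor IC50 must be positive")
    censored = False
    if isinstance(ic50_nontumor, str):
        text = ic50_nontumor.strip()
        if not text.startswith(">"):
            raise ValueError(f"cannot parse non-tumor IC50 {ic50_nontumor!r}")
        ic50_nontumor = float(text[1:])
        censored = True
    if not ic50_nontumor > 0:
        raise ValueError("non-tumor IC50 must be positive")
    ratio = round(ic50_nontumor / ic50_tumor, 2)
    return SelectivityIndex(value=ratio, censored=censored)


@dataclass
class CytometryEvents:
    """Two-channel (Annexin V, PI) event intensities with gate thresholds."""

    av_intensity: np.ndarray
    pi_intensity: np.ndarray
    av_thr: float
    pi_thr: float

    def __post_init__(self) -> None:
        self.av_intensity = np.asarray(self.av_intensity, dtype=float)
        self.pi_intensity = np.asarray(self.pi_intensity, dtype=float)
        if self.av_intensity.shape != self.pi_intensity.shape:
            raise ValueError("channel arrays must have the same length")
        if not (
            np.all(np.isfinite(self.av_intensity))
            and np.all(np.isfinite(self.pi_intensity))
        ):
            raise ValueError("intensities must be finite")


def quadrant_gate(events: CytometryEvents) -> dict[str, Fraction]:
    """Quadrant fractions: viable, early/late apoptosis, necrosis.

    AV-/PI- -> normal, AV+/PI- -> early apoptosis, AV+/PI+ -> late
    apoptosis, AV-/PI+ -> necrosis.  Events exactly on a threshold count
    as positive.  Fractions are exact rationals and sum to 1.
    """
    n = len(events.av_intensity)
    if n == 0:
        raise ValueError("no events to gate")
    av_pos = events.av_intensity >= events.av_thr
    pi_pos = events.pi_intensity >= events.pi_thr
    counts = {
        "normal": int(np.sum(~av_pos & ~pi_pos)),
        "early_apoptosis": int(np.sum(av_pos & ~pi_pos)),
        "late_apoptosis": int(np.sum(av_pos & pi_pos)),
        "necrosis": int(np.sum(~av_pos & pi_pos)),
    }
    return {k: Fraction(v, n) for k, v in counts.items()}
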