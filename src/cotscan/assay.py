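"""Flow-cytometry biosynthesis-inhibition assay model.

Normalization mirrors the assay arithmetic: subtract the untransfected
background from every channel, subtract the cycloheximide signal (protein
already made at t0 of treatment) and express the treated signal as percent
of the DMSO control. The concentration-response is a four-parameter
logistic in log-concentration,

    y(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill),

with top fixed at 100 by default (the data are DMSO-normalized) and bottom
free in [0, 100) because inhibition is usually incomplete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .core import DoseResponseDataset, ValidationError


@dataclass(frozen=True)
class CytometryReadout:
    """Raw fluorescence totals (arbitrary units) for one condition."""

    treated: float
    dmso_control: float
    cycloheximide_control: float
    untransfected_background: float
    concentration: Optional[float] = None  # μM

    def __post_init__(self) -> None:
        for label in ("treated", "dmso_control", "cycloheximide_control", "untransfected_background"):
            if getattr(self, label) < 0:
                raise ValidationError(f"{label} must be >= 0")


def normalize_readout(readout: CytometryReadout) -> float:
    """Treated signal as percent of the DMSO control.

    percent = 100 × (treated − bg − (chx − bg)) / (dmso − bg − (chx − bg));
    the background cancels, so the result is invariant to adding a
    constant to all four channels.
    """
    bg = readout.untransfected_background
    chx_net = readout.cycloheximide_control - bg
    dmso_net = readout.dmso_control - bg - chx_net
    if dmso_net <= 0:
        raise ValidationError("non-positive DMSO net signal; assay not interpretable")
    return 100.0 * (readout.treated - bg - chx_net) / dmso_net


@dataclass(frozen=True)
class DoseResponseParams:
    ic50: float  # μM
    hill: float = 1.0
    top: float = 100.0  # percent
    bottom: float = 0.0  # percent

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValidationError("ic50 must be positive")
        if not self.top > self.bottom:
            raise ValidationError("top must exceed bottom")


def response(conc, params: DoseResponseParams):
    """Sigmoidal inhibition curve; accepts scalars or arrays (μM → %)."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        y = params.bottom + (params.top - params.bottom) / (1.0 + (c / params.ic50) ** params.hill)
    return float(y) if np.isscalar(conc) else y


@dataclass
class FitResult:
    params: Optional[DoseResponseParams]
    converged: bool
    message: str = ""
    standard_errors: dict = field(default_factory=dict)
    residuals: Optional[np.ndarray] = None

    @property
    def ic50(self) -> Optional[float]:
        return self.params.ic50 if self.params is not None else None


def fit_ic50(
    dataset: DoseResponseDataset,
    fixed_top: Optional[float] = 100.0,
    fixed_bottom: Optional[float] = None,
    error_model: str = "auto",
) -> FitResult:
    """Least-squares four-parameter-logistic fit on log-concentration.

    IC50 is fitted on a log scale for stability. Needs ≥ 4 distinct
    concentrations. Degenerate data (no decrease with concentration)
    yields a flagged fit-failure result rather than an exception.

    ``error_model`` selects the residual scale: fluorescence-derived
    readouts have noise roughly proportional to the signal, so ``"log"``
    (residuals on log response) is the matched error model; ``"absolute"``
    uses plain percent residuals. The default ``"auto"`` fits on the log
    scale whenever every response is positive.
    """
    conc = np.asarray(dataset.concentration, dtype=float)
    y = np.asarray(dataset.response_percent, dtype=float)
    if len(np.unique(conc)) < 4:
        return FitResult(None, False, "need >= 4 distinct concentrations")
    # Quick degeneracy screen: response must actually fall with dose.
    order = np.argsort(conc)
    lo_mean = float(np.mean(y[order][: max(1, len(y) // 4)]))
    hi_mean = float(np.mean(y[order][-max(1, len(y) // 4):]))
    if hi_mean >= lo_mean - 1e-9 or np.ptp(y) < 1e-9:
        return FitResult(None, False, "no concentration-dependent decrease in the data")

    if error_model not in ("auto", "log", "absolute"):
        raise ValidationError(f"unknown error model {error_model!r}")
    use_log = error_model == "log" or (error_model == "auto" and np.all(y > 0))
    if error_model == "log" and not np.all(y > 0):
        return FitResult(None, False, "log error model needs positive responses")

    log_c = np.log(conc)

    free: list[str] = ["log_ic50", "hill"]
    if fixed_top is None:
        free.append("top")
    if fixed_bottom is None:
        free.append("bottom")

    def model(lc, *theta):
        names = dict(zip(free, theta))
        top = fixed_top if fixed_top is not None else names["top"]
        bottom = fixed_bottom if fixed_bottom is not None else names["bottom"]
        return bottom + (top - bottom) / (1.0 + np.exp(names["hill"] * (lc - names["log_ic50"])))

    def objective(lc, *theta):
        pred = model(lc, *theta)
        return np.log(np.maximum(pred, 1e-12)) if use_log else pred

    target = np.log(y) if use_log else y

    p0 = {"log_ic50": float(np.median(log_c)), "hill": 1.0, "top": float(np.max(y)),
          "bottom": float(max(0.0, np.min(y)))}
    lower = {"log_ic50": -np.inf, "hill": 0.05, "top": 0.0, "bottom": 0.0}
    upper = {"log_ic50": np.inf, "hill": 20.0, "top": np.inf,
             "bottom": (fixed_top if fixed_top is not None else np.inf)}
    try:
        popt, pcov = curve_fit(
            objective,
            log_c,
            target,
            p0=[p0[n] for n in free],
            bounds=([lower[n] for n in free], [upper[n] for n in free]),
            maxfev=20000,
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
        )
    except (RuntimeError, ValueError) as exc:
        return FitResult(None, False, f"optimizer failure: {exc}")
    names = dict(zip(free, popt))
    params = DoseResponseParams(
        ic50=math.exp(names["log_ic50"]),
        hill=names["hill"],
        top=fixed_top if fixed_top is not None else names["top"],
        bottom=fixed_bottom if fixed_bottom is not None else names["bottom"],
    )
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    errors = dict(zip(free, se))
    # Delta method: SE on the natural IC50 scale.
    if "log_ic50" in errors:
        errors["ic50"] = params.ic50 * errors.pop("log_ic50")
    residuals = y - model(log_c, *popt)
    return FitResult(params, True, "converged", errors, residuals)
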