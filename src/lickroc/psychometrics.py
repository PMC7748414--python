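"""Weibull psychometric fitting of aROC against contrast, and silencing indices.

The psychometric function is

    Psi(x; alpha, beta, gamma, lam) = gamma + (1 - gamma - lam) * F_w(x)
    F_w(x) = 1 - exp(-(x / alpha)^beta)

with contrast x in percent, detection threshold alpha, slope beta, lower
asymptote gamma (the aROC at 0% contrast, chance = 0.5) and lapse rate lam.
The silencing effect on the threshold is summarized by the modulation index
MI = (on - off) / (on + off) and the fold change on/off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .roc import UndefinedResultError, session_aroc
from .trials import BLANK, STIMULUS, Session, Trial

__all__ = [
    "PsychometricData",
    "PsychometricFit",
    "FitError",
    "weibull",
    "fit_psychometric",
    "modulation_index",
    "threshold_fold_change",
    "psychometric_data_from_sessions",
]

CONTRAST_SERIES_PCT = (0.0, 4.0, 8.0, 16.0, 32.0, 64.0, 100.0)

ALPHA_STARTS = (4.0, 8.0, 16.0, 32.0, 64.0)
ALPHA_BOUNDS = (1e-3, 100.0)
BETA_BOUNDS = (1e-3, 10.0)
LAM_BOUNDS = (0.0, 0.1)


class FitError(RuntimeError):
    """Raised when no optimizer start converges to a usable fit."""


@dataclass
class PsychometricData:
    """Per-contrast aROC values for one condition (control or silenced).

    ``contrasts`` are percent values, ascending; 0% (the blank anchor) may
    be present and is used only to pin gamma, never as a fit point.
    """

    contrasts: np.ndarray
    aroc: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        self.aroc = np.asarray(self.aroc, dtype=float)
        if self.contrasts.shape != self.aroc.shape:
            raise ValueError("contrasts and aroc must have equal length")
        if np.any(np.diff(self.contrasts) <= 0):
            raise ValueError("contrasts must be strictly ascending")


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted Weibull parameters; the detection threshold is ``alpha``."""

    alpha: float
    beta: float
    gamma: float
    lam: float
    rss: float
    at_bound: bool = False

    @property
    def threshold(self) -> float:
        return self.alpha

    def predict(self, x) -> np.ndarray:
        return weibull(x, self.alpha, self.beta, self.gamma, self.lam)


def weibull(x, alpha: float, beta: float, gamma: float, lam: float):
    """Evaluate Psi(x) = gamma + (1 - gamma - lam)(1 - exp(-(x/alpha)^beta))."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    xv = np.asarray(x, dtype=float)
    fw = 1.0 - np.exp(-np.power(np.clip(xv, 0.0, None) / alpha, beta))
    out = gamma + (1.0 - gamma - lam) * fw
    return out if out.ndim else float(out)


def fit_psychometric(
    data: PsychometricData,
    gamma: float | None = None,
    lam_max: float = LAM_BOUNDS[1],
) -> PsychometricFit:
    """Least-squares Weibull fit of aROC against contrast.

    gamma is fixed: to ``gamma`` if given, else to the measured 0%-contrast
    aROC when present, else to chance (0.5). alpha, beta and the lapse rate
    are free within bounds; the fit is multi-started over a log-spaced grid
    of alpha values and the lowest-RSS solution is returned. ``at_bound``
    flags an uninformative fit with alpha pinned at the upper bound.
    """
    nz = data.contrasts > 0
    x, y = data.contrasts[nz], data.aroc[nz]
    if x.size < 4:
        raise ValueError("need >= 4 non-zero-contrast points")
    if gamma is None:
        gamma = float(data.aroc[~nz][0]) if np.any(~nz) else 0.5

    def residuals(theta):
        alpha, beta, lam = theta
        return weibull(x, alpha, beta, gamma, lam) - y

    lower = np.array([ALPHA_BOUNDS[0], BETA_BOUNDS[0], LAM_BOUNDS[0]])
    upper = np.array([ALPHA_BOUNDS[1], BETA_BOUNDS[1], lam_max])
    best = None
    for alpha0 in ALPHA_STARTS:
        for beta0 in (1.0, 2.0):
            try:
                res = optimize.least_squares(
                    residuals,
                    x0=np.clip([alpha0, beta0, 0.02], lower, upper),
                    bounds=(lower, upper),
                    method="trf",
                )
            except Exception:
                continue
            if not res.success:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[1]:
                best = (res.x, rss)
    if best is None:
        raise FitError(
            f"psychometric fit failed for condition {data.condition!r} "
            f"(n={x.size}, gamma={gamma:.3f})"
        )
    (alpha, beta, lam), rss = best
    return PsychometricFit(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        lam=float(lam),
        rss=rss,
        at_bound=bool(alpha > 0.999 * ALPHA_BOUNDS[1]),
    )


def modulation_index(threshold_on: float, threshold_off: float) -> float:
    """Silencing modulation index (on - off) / (on + off) of the threshold."""
    if threshold_on <= 0 or threshold_off <= 0:
        raise ValueError("thresholds must be positive")
    return float((threshold_on - threshold_off) / (threshold_on + threshold_off))


def threshold_fold_change(threshold_on: float, threshold_off: float) -> float:
    """Multiplicative threshold shift on/off under silencing."""
    if threshold_on <= 0 or threshold_off <= 0:
        raise ValueError("thresholds must be positive")
    return float(threshold_on / threshold_off)


def psychometric_data_from_sessions(
    sessions: Iterable[Session],
    led_on: bool,
    contrasts: Sequence[float] | None = None,
) -> PsychometricData:
    """Per-contrast aROC from contrast-series sessions, split by LED state.

    For each non-zero contrast, aROC compares stimulus trials of that
    contrast (same LED state) against all blank trials of the same LED
    state; the 0% entry is the blank-vs-blank anchor, 0.5 by construction.
    """
    all_trials: list[Trial] = [t for s in sessions for t in s.trials]
    pool = [t for t in all_trials if t.led_on == led_on]
    blanks = [t for t in pool if t.kind == BLANK]
    if contrasts is None:
        contrasts = sorted({round(t.contrast * 100.0, 6) for t in pool})
    values = []
    kept = []
    for c in contrasts:
        if c == 0:
            kept.append(0.0)
            values.append(0.5)
            continue
        stim = [t for t in pool if t.kind == STIMULUS and abs(t.contrast * 100 - c) < 1e-6]
        if not stim or not blanks:
            continue
        try:
            values.append(session_aroc(stim + blanks))
        except UndefinedResultError:
            continue
        kept.append(float(c))
    return PsychometricData(
        contrasts=np.asarray(kept),
        aroc=np.asarray(values),
        condition="silenced" if led_on else "control",
    )
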