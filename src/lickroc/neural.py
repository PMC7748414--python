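"""Superior-colliculus activity analysis: PSTHs, evoked responses, contrast-
response fits and a depth profile of silencing impact, with a synthetic
multi-unit spike generator.

The contrast-response function is the hyperbolic ratio (Naka-Rushton) form

    r(x) = r_max * x^n / (x^n + x50^n)

with semi-saturation contrast x50 and exponent n. Evoked responses are
baseline-subtracted firing rates: mean rate in the first 100 ms after
stimulus onset minus the 100 ms immediately before, normalized to the
maximum across contrasts in the control (LED off) condition. The synthetic
generator mixes a retinal drive (strong in the superficial gray layer) and
a cortical drive (confined to the cortico-recipient optic/intermediate
layers) whose weight shrinks with prolonged training; silencing visual
cortex removes the cortical term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TrialEvent",
    "SpikeRecord",
    "CRFFit",
    "psth",
    "evoked_response",
    "fit_crf",
    "silencing_depth_profile",
    "simulate_sc_activity",
    "hyperbolic_ratio",
]

EVOKED_WINDOW_S = (0.0, 0.1)
BASELINE_WINDOW_S = (-0.1, 0.0)

RMAX_BOUNDS = (1e-6, 2.0)
N_BOUNDS = (1e-3, 6.0)
X50_BOUNDS = (1e-3, 100.0)

#: Default layer boundaries (µm below surface): superficial gray (SGS),
#: optic (SO), intermediate gray (SI). Functional (CSD-based) alignment is
#: out of scope, so these are nominal coordinates.
LAYER_RANGES_UM = {"SGS": (0, 300), "SO": (300, 500), "SI": (500, 900)}


class FitError(RuntimeError):
    """Raised when the CRF fit does not converge from any start."""


@dataclass(frozen=True)
class TrialEvent:
    onset_s: float
    contrast_pct: float
    led_on: bool


@dataclass
class SpikeRecord:
    """Multi-unit spike times at one recording depth, with trial events."""

    depth_um: float
    spike_times_s: np.ndarray
    trial_events: tuple[TrialEvent, ...]

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.depth_um <= 0:
            raise ValueError("depth must be positive (µm below surface)")
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError("spike times must be ascending")
        self.trial_events = tuple(
            e if isinstance(e, TrialEvent) else TrialEvent(*e)
            for e in self.trial_events
        )


@dataclass(frozen=True)
class CRFFit:
    """Hyperbolic-ratio parameters for a contrast-response curve."""

    r_max: float
    n_exp: float
    x50: float
    rss: float

    def predict(self, x) -> np.ndarray:
        return hyperbolic_ratio(x, self.r_max, self.n_exp, self.x50)


def hyperbolic_ratio(x, r_max: float, n_exp: float, x50: float):
    """r(x) = r_max * x^n / (x^n + x50^n), x in percent contrast."""
    xv = np.clip(np.asarray(x, dtype=float), 0.0, None)
    xn = np.power(xv, n_exp)
    out = r_max * xn / (xn + x50**n_exp)
    return out if out.ndim else float(out)


def _select_events(
    events: Sequence[TrialEvent],
    contrast_pct: float | None = None,
    led_on: bool | None = None,
) -> list[TrialEvent]:
    out = [
        e
        for e in events
        if (led_on is None or e.led_on == led_on)
        and (contrast_pct is None or abs(e.contrast_pct - contrast_pct) < 1e-9)
    ]
    if not out:
        raise ValueError(
            f"no trials with contrast={contrast_pct}, led_on={led_on}"
        )
    return out


def psth(
    record: SpikeRecord,
    pre_s: float = 0.5,
    post_s: float = 0.5,
    bin_s: float = 0.02,
    contrast_pct: float | None = None,
    led_on: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram (Hz) aligned to stimulus onsets.

    Returns (bin_centers_s, rate_hz). The bin width must divide the
    [-pre, post] window evenly.
    """
    n_bins = (pre_s + post_s) / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_s must divide the PSTH window evenly")
    n_bins = int(round(n_bins))
    edges = -pre_s + bin_s * np.arange(n_bins + 1)
    events = _select_events(record.trial_events, contrast_pct, led_on)
    counts = np.zeros(n_bins)
    for e in events:
        rel = record.spike_times_s - e.onset_s
        sel = rel[(rel >= -pre_s) & (rel < post_s)]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / (len(events) * bin_s)
    centers = edges[:-1] + bin_s / 2.0
    return centers, rate


def _mean_rate(record: SpikeRecord, events: Sequence[TrialEvent], window) -> float:
    lo, hi = window
    total = 0
    for e in events:
        rel = record.spike_times_s - e.onset_s
        total += int(np.count_nonzero((rel >= lo) & (rel < hi)))
    return total / (len(events) * (hi - lo))


def evoked_response(
    record: SpikeRecord,
    led_on: bool = False,
    evoked_window: tuple[float, float] = EVOKED_WINDOW_S,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_S,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted response per contrast, for one LED condition.

    Returns (contrasts_pct, responses). When ``normalize`` is set, responses
    are divided by the maximum across contrasts of the *control* (LED off)
    condition so both conditions share a scale.
    """
    contrasts = sorted({e.contrast_pct for e in record.trial_events})
    deltas = []
    for c in contrasts:
        events = _select_events(record.trial_events, c, led_on)
        deltas.append(
            _mean_rate(record, events, evoked_window)
            - _mean_rate(record, events, baseline_window)
        )
    out = np.asarray(deltas)
    if normalize:
        ctrl = out
        if led_on:
            ctrl_deltas = []
            for c in contrasts:
                events = _select_events(record.trial_events, c, False)
                ctrl_deltas.append(
                    _mean_rate(record, events, evoked_window)
                    - _mean_rate(record, events, baseline_window)
                )
            ctrl = np.asarray(ctrl_deltas)
        peak = float(np.max(ctrl))
        if peak <= 0:
            raise ValueError("control responses have no positive maximum to normalize by")
        out = out / peak
    return np.asarray(contrasts), out


def fit_crf(contrasts: Sequence[float], responses: Sequence[float]) -> CRFFit:
    """Bounded least-squares hyperbolic-ratio fit, multi-started."""
    x = np.asarray(contrasts, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 points for a CRF fit")

    def residuals(theta):
        return hyperbolic_ratio(x, *theta) - y

    lower = np.array([RMAX_BOUNDS[0], N_BOUNDS[0], X50_BOUNDS[0]])
    upper = np.array([RMAX_BOUNDS[1], N_BOUNDS[1], X50_BOUNDS[1]])
    r0 = max(float(np.max(y)), 0.1)
    best = None
    for n0 in (1.0, 2.0, 4.0):
        for x50_0 in (10.0, 20.0, 40.0):
            try:
                res = optimize.least_squares(
                    residuals,
                    x0=np.clip([r0, n0, x50_0], lower, upper),
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
        raise FitError("CRF fit failed from all starts")
    (r_max, n_exp, x50), rss = best
    return CRFFit(r_max=float(r_max), n_exp=float(n_exp), x50=float(x50), rss=rss)


def silencing_depth_profile(
    records: Iterable[SpikeRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized evoked activity versus depth, control and silenced.

    For each depth, the evoked response at the highest contrast is computed
    for both LED conditions and the silenced value is expressed relative to
    control (control = 1 per depth). Returns (depths_um, control, silenced)
    sorted by depth.
    """
    records = sorted(records, key=lambda r: r.depth_um)
    if len(records) < 2:
        raise ValueError("need >= 2 depths for a profile")
    depths, ctrl, sil = [], [], []
    for rec in records:
        contrasts, off = evoked_response(rec, led_on=False, normalize=False)
        _, on = evoked_response(rec, led_on=True, normalize=False)
        top = int(np.argmax(contrasts))
        if off[top] <= 0:
            raise ValueError(f"no positive control response at depth {rec.depth_um}")
        depths.append(rec.depth_um)
        ctrl.append(1.0)
        sil.append(on[top] / off[top])
    return np.asarray(depths), np.asarray(ctrl), np.asarray(sil)


def simulate_sc_activity(
    depths_um: Sequence[float],
    contrasts_pct: Sequence[float] = (4.0, 8.0, 16.0, 32.0, 64.0, 100.0),
    cortical_weight_by_depth: Sequence[float] | None = None,
    retinal_weight_by_depth: Sequence[float] | None = None,
    training_scale: float = 1.0,
    n_trials: int = 50,
    seed: int | np.random.SeedSequence = 0,
    baseline_hz: float = 5.0,
    gain_hz: float = 40.0,
    crf_n: float = 2.0,
    crf_x50: float = 20.0,
    stim_duration_s: float = 0.5,
    trial_period_s: float = 2.0,
) -> list[SpikeRecord]:
    """Generate Poisson multi-unit records across collicular depths.

    Per trial, the rate during the stimulus epoch is

        baseline + gain * [retinal(d) + cortical(d) * training_scale * (1 - led)]
                 * x^n / (x^n + x50^n)

    so silencing (led) removes exactly the cortical contribution, and the
    cortical contribution itself shrinks as ``training_scale`` decreases with
    prolonged training. ``n_trials`` trials are generated per contrast and
    LED condition; the same seed reproduces identical spike trains.
    """
    depths = np.asarray(depths_um, dtype=float)
    if cortical_weight_by_depth is None:
        # cortical drive confined to the cortico-recipient SO/SI depths
        cortical_weight_by_depth = np.where(depths >= 300.0, 0.6, 0.05)
    if retinal_weight_by_depth is None:
        # retinal drive strongest superficially
        retinal_weight_by_depth = np.where(depths < 300.0, 0.9, 0.35)
    cort = np.asarray(cortical_weight_by_depth, dtype=float)
    ret = np.asarray(retinal_weight_by_depth, dtype=float)
    if not (cort.shape == ret.shape == depths.shape):
        raise ValueError("weight arrays must match depths")
    if np.any((cort < 0) | (cort > 1)) or np.any((ret < 0) | (ret > 1)):
        raise ValueError("weights must lie in [0, 1]")
    if not 0.0 <= training_scale <= 1.0:
        raise ValueError("training_scale must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records = []
    for depth, w_c, w_r, child in zip(depths, cort, ret, ss.spawn(len(depths))):
        rng = np.random.default_rng(child)
        conditions = [
            (c, led) for c in contrasts_pct for led in (False, True)
        ]
        events = []
        spikes = []
        t = 0.0
        for c, led in conditions:
            for _ in range(n_trials):
                onset = t + trial_period_s / 2.0
                crf = hyperbolic_ratio(c, 1.0, crf_n, crf_x50)
                drive = w_r + (0.0 if led else w_c * training_scale)
                evoked = gain_hz * drive * crf
                for lo, hi, rate in (
                    (t, onset, baseline_hz),
                    (onset, onset + stim_duration_s, baseline_hz + evoked),
                    (onset + stim_duration_s, t + trial_period_s, baseline_hz),
                ):
                    n_sp = rng.poisson(rate * (hi - lo))
                    spikes.append(np.sort(rng.uniform(lo, hi, size=n_sp)))
                events.append(TrialEvent(onset_s=onset, contrast_pct=float(c), led_on=led))
                t += trial_period_s
        records.append(
            SpikeRecord(
                depth_um=float(depth),
                spike_times_s=np.sort(np.concatenate(spikes)) if spikes else np.empty(0),
                trial_events=tuple(events),
            )
        )
    return records
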