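"""Trial and session domain types, outcome classification, tabular I/O.

A behavioral session is a sequence of go/no-go detection trials: on stimulus
trials a drifting grating appears for up to ``response_window_s`` seconds and
the animal reports detection with a lick; blank trials present nothing. The
first lick inside the response window decides the outcome (Hit on stimulus
trials, False Alarm on blanks); licking during the pre-stimulus timeout
window aborts the trial. Times are seconds relative to stimulus onset;
pre-stimulus licks are negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "Outcome",
    "Session",
    "MalformedTrialError",
    "SessionParseError",
    "classify_trial",
    "outcome_counts",
    "read_sessions",
    "write_sessions",
]

STIMULUS = "stimulus"
BLANK = "blank"

HIT = "Hit"
MISS = "Miss"
FA = "FA"
CR = "CR"
ABORTED = "Aborted"

#: Default pre-stimulus window whose licks abort (re-initiate) a trial.
DEFAULT_TIMEOUT_WINDOW_S = 1.5

_CSV_COLUMNS = [
    "animal_id",
    "group",
    "day",
    "trial_index",
    "kind",
    "contrast",
    "led_on",
    "delay_s",
    "response_window_s",
    "lick_times_s",
    "iti_s",
    "jitter_max_s",
    "pre_stim_timeout_window_s",
]


class MalformedTrialError(ValueError):
    """Raised for trials violating structural invariants (e.g. unsorted licks)."""


class SessionParseError(ValueError):
    """Raised when a sessions table cannot be parsed; names the offending row."""


@dataclass(frozen=True)
class Trial:
    """One behavioral trial.

    Parameters
    ----------
    index
        Ordinal position of the trial within its session.
    kind
        ``"stimulus"`` or ``"blank"``.
    contrast
        Stimulus contrast as a fraction in [0, 1]; 0 for blank trials.
    led_on
        True when cortical silencing light was on for this trial.
    delay_s
        Post-onset delay during which licks are not rewarded (s).
    response_window_s
        Maximal stimulus duration / response period (s).
    lick_times_s
        Strictly ascending lick times relative to stimulus onset; may be
        empty and may contain negative (pre-stimulus) entries.
    """

    index: int
    kind: str
    contrast: float
    led_on: bool
    delay_s: float
    response_window_s: float
    lick_times_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (STIMULUS, BLANK):
            raise MalformedTrialError(f"unknown trial kind {self.kind!r}")
        if self.kind == BLANK and self.contrast != 0:
            raise MalformedTrialError(
                f"blank trial {self.index} has nonzero contrast {self.contrast}"
            )
        if not 0 <= self.contrast <= 1:
            raise MalformedTrialError(
                f"trial {self.index}: contrast {self.contrast} outside [0, 1]"
            )
        if not 0 <= self.delay_s < self.response_window_s:
            raise MalformedTrialError(
                f"trial {self.index}: delay {self.delay_s} not in "
                f"[0, {self.response_window_s})"
            )
        licks = tuple(float(t) for t in self.lick_times_s)
        if any(b <= a for a, b in zip(licks, licks[1:])):
            raise MalformedTrialError(
                f"trial {self.index}: lick times not strictly ascending: {licks}"
            )
        object.__setattr__(self, "lick_times_s", licks)


@dataclass(frozen=True)
class Outcome:
    """Classification of a trial: label plus first-lick latency when licked."""

    label: str
    first_lick_latency_s: float | None = None

    def __post_init__(self) -> None:
        if self.label in (HIT, FA) and self.first_lick_latency_s is None:
            raise ValueError(f"{self.label} outcome requires a latency")
        if self.label in (MISS, CR) and self.first_lick_latency_s is not None:
            raise ValueError(f"{self.label} outcome cannot carry a latency")


@dataclass
class Session:
    """An ordered set of trials for one animal on one training day."""

    animal_id: str
    day: int
    group: str
    trials: list[Trial]
    iti_s: float = 5.0
    jitter_max_s: float = 2.0
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"training day must be >= 1, got {self.day}")
        if not self.trials:
            raise ValueError("a session needs at least one trial")
        windows = {t.response_window_s for t in self.trials}
        if len(windows) > 1:
            raise ValueError(
                f"trials disagree on response_window_s within session: {windows}"
            )

    @property
    def response_window_s(self) -> float:
        return self.trials[0].response_window_s


def classify_trial(
    trial: Trial,
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S,
) -> Outcome:
    """Classify one trial into Hit / Miss / FA / CR / Aborted.

    Any lick inside the pre-stimulus timeout window ``[-timeout, 0)`` aborts
    the trial (such trials are excluded from all downstream metrics). The
    response interval is the closed ``[delay_s, response_window_s]``; licks
    before the delay but after onset are ignored, as are pre-stimulus licks
    earlier than the timeout window.
    """
    licks = np.asarray(trial.lick_times_s, dtype=float)
    if np.any((licks >= -pre_stim_timeout_window_s) & (licks < 0)):
        return Outcome(ABORTED)
    in_window = licks[(licks >= trial.delay_s) & (licks <= trial.response_window_s)]
    if trial.kind == STIMULUS:
        if in_window.size:
            return Outcome(HIT, float(in_window[0]))
        return Outcome(MISS)
    if in_window.size:
        return Outcome(FA, float(in_window[0]))
    return Outcome(CR)


def outcome_counts(
    trials: Iterable[Trial],
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S,
) -> dict[str, int]:
    """Count outcome labels over a collection of trials."""
    counts = {HIT: 0, MISS: 0, FA: 0, CR: 0, ABORTED: 0}
    for trial in trials:
        counts[classify_trial(trial, pre_stim_timeout_window_s).label] += 1
    return counts


def _format_licks(licks: Sequence[float]) -> str:
    return ";".join(repr(float(t)) for t in licks)


def _parse_licks(cell: object, row: int) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    try:
        return tuple(float(tok) for tok in str(cell).split(";") if tok != "")
    except ValueError as exc:
        raise SessionParseError(f"row {row}: bad lick_times_s cell {cell!r}") from exc


def write_sessions(sessions: Iterable[Session], path) -> None:
    """Serialize sessions to a flat CSV, one row per trial.

    Lick trains go into a single semicolon-joined column using ``repr`` so
    that ``read_sessions`` round-trips every latency bit-exactly.
    """
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "day": s.day,
                    "trial_index": t.index,
                    "kind": t.kind,
                    "contrast": repr(t.contrast),
                    "led_on": int(t.led_on),
                    "delay_s": repr(t.delay_s),
                    "response_window_s": repr(t.response_window_s),
                    "lick_times_s": _format_licks(t.lick_times_s),
                    "iti_s": repr(s.iti_s),
                    "jitter_max_s": repr(s.jitter_max_s),
                    "pre_stim_timeout_window_s": repr(s.pre_stim_timeout_window_s),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_sessions(path) -> list[Session]:
    """Read sessions from the CSV layout written by :func:`write_sessions`.

    Trials are restored in ``trial_index`` order regardless of row order.
    An empty file yields an empty list. Missing columns or non-numeric
    fields raise :class:`SessionParseError` naming the row.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    required = _CSV_COLUMNS[:10]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionParseError(f"missing column(s): {', '.join(missing)}")

    def _num(row_idx: int, col: str, cast=float):
        cell = df.at[row_idx, col]
        try:
            return cast(cell)
        except (TypeError, ValueError) as exc:
            raise SessionParseError(
                f"row {row_idx}: non-numeric {col} value {cell!r}"
            ) from exc

    sessions: list[Session] = []
    df["_row"] = np.arange(len(df))
    for (animal, group, day), block in df.groupby(
        ["animal_id", "group", "day"], sort=True
    ):
        block = block.sort_values("trial_index", key=lambda s: s.astype(int))
        trials = []
        for row_idx in block["_row"]:
            try:
                trial = Trial(
                    index=_num(row_idx, "trial_index", int),
                    kind=df.at[row_idx, "kind"],
                    contrast=_num(row_idx, "contrast"),
                    led_on=bool(_num(row_idx, "led_on", int)),
                    delay_s=_num(row_idx, "delay_s"),
                    response_window_s=_num(row_idx, "response_window_s"),
                    lick_times_s=_parse_licks(df.at[row_idx, "lick_times_s"], row_idx),
                )
            except MalformedTrialError as exc:
                raise SessionParseError(f"row {row_idx}: {exc}") from exc
            trials.append(trial)
        first = block["_row"].iloc[0]
        kwargs = {}
        for col in ("iti_s", "jitter_max_s", "pre_stim_timeout_window_s"):
            if col in df.columns and df.at[first, col] != "":
                kwargs[col] = _num(first, col)
        sessions.append(
            Session(
                animal_id=str(animal),
                day=int(day),
                group=str(group),
                trials=trials,
                **kwargs,
            )
        )
    return sessions
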