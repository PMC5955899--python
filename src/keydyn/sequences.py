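"""Keystroke-dynamics variable sequences: HT, FT, NFT and NP.

Given press/release timestamp sequences t^p_n, t^r_n (n = 1..N) and the
normalised pressure NP(t^p_n) of a typing session, the variables are

* hold time        HT_n  = t^r_n - t^p_n                (n = 1..N)
* flight time      FT_n  = t^p_{n+1} - t^r_n            (n = 1..N-1)
* normalised       NP_n  = NP(t^p_n)                    (n = 1..N)
  pressure

Flight times are dominated by reading pauses and typing dexterity, so they
are conditionally filtered into the normalised flight time (NFT) sequence in
three ordered steps: values above 3 s are removed, the surviving values are
detrended by subtracting their mean, and detrended values outside
[-1.27, 1.7] s (the 99% interval of a real-life reference distribution,
taken as a fixed constant) are dropped. Hold times and pressures are used raw.

All values are in seconds (pressure is unitless); each element carries the
anchor timestamps used later for window assignment, expressed relative to the
session's first press.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyAfterFilteringError, InsufficientEventsError
from .session_io import TypingSession

__all__ = [
    "VariableSequence",
    "hold_times",
    "flight_times",
    "pressures",
    "normalise_flight_times",
    "FT_MAX_S",
    "NFT_INTERVAL_S",
]

#: Flight times above this threshold (s) are removed before detrending.
FT_MAX_S = 3.0
#: Detrended flight times outside this interval (s) are filtered out.
NFT_INTERVAL_S = (-1.27, 1.7)


@dataclass
class VariableSequence:
    """One derived variable of a session, with per-element anchor times.

    ``starts``/``ends`` bound the keystroke interval each element spans, in
    seconds relative to the session's first press. For HT the anchors are the
    key's press and release; for NP both anchors are the press; for FT/NFT
    they are the first key's release and the next key's press.
    """

    variable: str  # "HT", "FT", "NFT" or "NP"
    values: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def _times_ms(session: TypingSession) -> tuple[np.ndarray, np.ndarray]:
    press = np.array([e.t_press for e in session.events], dtype=float)
    release = np.array([e.t_release for e in session.events], dtype=float)
    return press, release


def hold_times(session: TypingSession) -> VariableSequence:
    """HT_n = t^r_n - t^p_n; no filtering or normalisation is applied."""
    press, release = _times_ms(session)
    t0 = press[0]
    # differences taken in ms before scaling, so equal ms intervals give
    # bit-identical values wherever they fall in the session
    return VariableSequence(
        "HT", (release - press) / 1000.0, (press - t0) / 1000.0, (release - t0) / 1000.0
    )


def flight_times(session: TypingSession) -> VariableSequence:
    """FT_n = t^p_{n+1} - t^r_n; negative values (overlapping taps) kept."""
    if session.n_chars < 2:
        raise InsufficientEventsError("flight times need at least two events")
    press, release = _times_ms(session)
    t0 = press[0]
    return VariableSequence(
        "FT",
        (press[1:] - release[:-1]) / 1000.0,
        (release[:-1] - t0) / 1000.0,
        (press[1:] - t0) / 1000.0,
    )


def pressures(session: TypingSession) -> VariableSequence:
    """NP_n = normalised pressure at each key press."""
    press, _ = _times_ms(session)
    anchor = (press - press[0]) / 1000.0
    values = np.array([e.pressure for e in session.events], dtype=float)
    return VariableSequence("NP", values, anchor, anchor.copy())


def normalise_flight_times(
    ft: VariableSequence,
    ft_max: float = FT_MAX_S,
    interval: tuple[float, float] = NFT_INTERVAL_S,
) -> VariableSequence:
    """Conditionally filter and detrend an FT sequence into NFT.

    Steps, in order: (1) remove elements exceeding ``ft_max``; (2) subtract
    the mean of the survivors (a single global detrend, so the result is
    exactly zero-mean when step 3 removes nothing); (3) remove detrended
    elements outside ``interval``. Anchor times are dropped in lockstep.
    Raises :class:`EmptyAfterFilteringError` when nothing survives.
    """
    if ft.variable != "FT":
        raise ValueError(f"expected an FT sequence, got {ft.variable}")
    keep = ft.values <= ft_max
    values, starts, ends = ft.values[keep], ft.starts[keep], ft.ends[keep]
    if values.size == 0:
        raise EmptyAfterFilteringError("all flight times exceed the 3 s threshold")
    values = values - values.mean()
    lo, hi = interval
    keep = (values >= lo) & (values <= hi)
    values, starts, ends = values[keep], starts[keep], ends[keep]
    if values.size == 0:
        raise EmptyAfterFilteringError("no detrended flight time inside the interval")
    return VariableSequence("NFT", values, starts, ends)
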