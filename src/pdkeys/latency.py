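"""Latency series extracted from a typing session.

Writing the press instants of the ordered keystrokes as P_1..P_N and the
release instants as R_1..R_N, four interval series are defined:

* hold latency       ``HL_n = R_n - P_n``        (key held down)
* interkey latency   ``IL_n = P_{n+1} - R_n``    ("flight time"; negative
  under rollover typing, when the next key goes down before the previous
  one comes up)
* press latency      ``PL_n = P_{n+1} - P_n``
* release latency    ``RL_n = R_{n+1} - R_n``

so that ``PL_n = HL_n + IL_n`` and ``RL_n = IL_n + HL_{n+1}`` identically.
Consecutiveness is defined by press-time order over ALL keys, including
specials such as backspace and shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import TypingSession

__all__ = ["LatencySeries", "LATENCY_KINDS", "extract_latencies", "typing_speed_and_words"]

LATENCY_KINDS = ("HL", "IL", "PL", "RL")


class InsufficientEventsError(ValueError):
    pass


@dataclass(frozen=True)
class LatencySeries:
    """One interval sequence, in seconds, with event-pair provenance.

    ``pair_index[i]`` gives the indices of the session events that produced
    ``values[i]`` (``(n, n)`` for HL, ``(n, n+1)`` for IL/PL/RL), so filters
    and outlier reports can trace every value back to its keystrokes.
    """

    kind: str
    values: np.ndarray
    pair_index: np.ndarray  # shape (len(values), 2), int

    def __post_init__(self) -> None:
        if self.kind not in LATENCY_KINDS:
            raise ValueError(f"kind must be one of {LATENCY_KINDS}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "pair_index", np.asarray(self.pair_index, dtype=int))
        if self.pair_index.shape != (len(self.values), 2):
            raise ValueError("pair_index must have shape (n_values, 2)")

    def __len__(self) -> int:
        return len(self.values)

    def take(self, idx: np.ndarray) -> "LatencySeries":
        """Sub-series at positions ``idx`` (order preserved)."""
        return replace(self, values=self.values[idx], pair_index=self.pair_index[idx])


def extract_latencies(session: TypingSession) -> dict[str, LatencySeries]:
    """Compute the four latency series of a session.

    Requires at least two events.  HL values are non-negative by
    construction (the reader rejects release < press); IL may be negative
    under rollover.
    """
    n = len(session)
    if n < 2:
        raise InsufficientEventsError(
            f"session {session.subject_id}: need >= 2 events, got {n}"
        )
    p = session.press_times
    r = session.release_times
    i = np.arange(n)
    pairs = np.column_stack([i[:-1], i[1:]])
    return {
        "HL": LatencySeries("HL", r - p, np.column_stack([i, i])),
        "IL": LatencySeries("IL", p[1:] - r[:-1], pairs),
        "PL": LatencySeries("PL", np.diff(p), pairs),
        "RL": LatencySeries("RL", np.diff(r), pairs),
    }


def typing_speed_and_words(
    session: TypingSession, convention: str = "space_plus_one"
) -> tuple[float, int]:
    """Typing speed (words/min) and word count for a session.

    The raw logs carry no text, so "word" is a convention:

    * ``"space_plus_one"`` (default): number of space presses, plus one if
      any non-space key was typed — i.e. spaces delimit words and a trailing
      word needs no closing space.
    * ``"token_runs"``: number of maximal runs of non-space keystrokes.

    Speed is word count divided by elapsed minutes, elapsed being last
    release minus first press.
    """
    if len(session) < 2:
        raise InsufficientEventsError("need >= 2 events for typing speed")
    keys = session.key_ids
    n_space = sum(k == "space" for k in keys)
    if convention == "space_plus_one":
        word_count = n_space + (1 if any(k != "space" for k in keys) else 0)
    elif convention == "token_runs":
        word_count = 0
        in_run = False
        for k in keys:
            if k != "space" and not in_run:
                word_count += 1
            in_run = k != "space"
    else:
        raise ValueError(f"unknown word-count convention {convention!r}")
    elapsed = float(session.release_times.max()) - float(session.press_times[0])
    if elapsed <= 0:
        raise ValueError("session has zero elapsed time")
    speed = word_count / (elapsed / 60.0)
    return speed, word_count
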