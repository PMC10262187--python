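"""Clock-time arithmetic on a 24-hour circle.

Times are decimal hours after midnight. Mid-sleep phases are reported in a
canonical window (-6, 18] so that typical population mid-sleeps (2-6 AM)
form a continuous scale for regression instead of wrapping at midnight.
"""

from __future__ import annotations

import re

import numpy as np

#: Upper edge of the canonical window for mid-sleep phases, hours.
CANONICAL_MAX = 18.0

_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})\s*$")


class ClockParseError(ValueError):
    """Raised when a clock-time string cannot be parsed."""


def parse_clock_time(text: str, field: str = "clock time") -> float:
    """Parse ``H:MM`` / ``HH:MM`` (24-hour) into decimal hours in [0, 24).

    Minutes are converted exactly as ``m / 60``.

    Raises
    ------
    ClockParseError
        If the string is malformed or hour/minute are out of range; the
        message names ``field``.
    """
    if not isinstance(text, str):
        raise ClockParseError(f"{field}: expected a string, got {type(text).__name__}")
    m = _CLOCK_RE.match(text)
    if m is None:
        raise ClockParseError(f"{field}: malformed clock time {text!r} (expected HH:MM)")
    hour, minute = int(m.group(1)), int(m.group(2))
    if hour > 23:
        raise ClockParseError(f"{field}: hour {hour} out of range 0-23 in {text!r}")
    if minute > 59:
        raise ClockParseError(f"{field}: minute {minute} out of range 0-59 in {text!r}")
    return hour + minute / 60.0


def format_clock_time(hours: float) -> str:
    """Inverse of :func:`parse_clock_time` to the nearest minute."""
    total = int(round((hours % 24.0) * 60.0)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


def to_canonical_window(hours):
    """Map hours (mod 24) into the canonical window (-6, 18]."""
    h = np.asarray(hours, dtype=float) % 24.0
    h = np.where(h > CANONICAL_MAX, h - 24.0, h)
    if h.ndim == 0:
        return float(h)
    return h


def circular_abs_diff(a, b):
    """Minimal absolute difference between two clock times on the 24 h circle."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 24.0
    d = np.minimum(d, 24.0 - d)
    if d.ndim == 0:
        return float(d)
    return d


def sleep_interval(onset: float, offset: float) -> tuple[float, float]:
    """Duration and midpoint of a sleep episode given onset/offset clock times.

    Returns
    -------
    (duration, midpoint)
        Duration in (0, 24) hours; midpoint mapped to the canonical window.

    Raises
    ------
    ValueError
        If onset equals offset (degenerate interval).
    """
    duration = (float(offset) - float(onset)) % 24.0
    if duration == 0.0:
        raise ValueError(
            f"degenerate sleep interval: onset == offset == {format_clock_time(onset)}"
        )
    midpoint = to_canonical_window((float(onset) + duration / 2.0) % 24.0)
    return duration, midpoint
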