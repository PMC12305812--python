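"""Anaemia severity states and haemoglobin-based categorisation.

Severity follows the WHO classification for children 6-59 months:
haemoglobin (Hb) below 11 g/dL is anaemic, subdivided into mild
(10-10.9 g/dL), moderate (7-9.9 g/dL) and severe (< 7 g/dL).
Intervals are half-open and lower-closed, e.g. mild = [10, 11).
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "AnaemiaState",
    "STATE_NAMES",
    "HB_INTERVALS",
    "categorize_anaemia",
    "categorize_anaemia_array",
]


class AnaemiaState(IntEnum):
    """Four anaemia severity states, totally ordered by severity."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return STATE_NAMES[self.value]


STATE_NAMES = ["none", "mild", "moderate", "severe"]
N_STATES = 4

#: Hb interval (g/dL) consistent with each state; half-open [low, high).
#: The outer bounds (3, 25) delimit physiologically plausible infant Hb.
HB_INTERVALS = {
    AnaemiaState.NONE: (11.0, 25.0),
    AnaemiaState.MILD: (10.0, 11.0),
    AnaemiaState.MODERATE: (7.0, 10.0),
    AnaemiaState.SEVERE: (3.0, 7.0),
}

_THRESHOLDS = (7.0, 10.0, 11.0)  # severe < 7 <= moderate < 10 <= mild < 11 <= none


def categorize_anaemia(hb: float) -> AnaemiaState:
    """Map a haemoglobin concentration (g/dL) to an anaemia severity state.

    Parameters
    ----------
    hb : float
        Haemoglobin in g/dL; must be finite and positive.

    Returns
    -------
    AnaemiaState
        SEVERE if hb < 7, MODERATE if 7 <= hb < 10, MILD if 10 <= hb < 11,
        NONE if hb >= 11.

    Raises
    ------
    ValueError
        If ``hb`` is not a finite positive number.
    """
    hb = float(hb)
    if not np.isfinite(hb) or hb <= 0.0:
        raise ValueError(f"haemoglobin must be finite and positive, got {hb!r}")
    if hb < _THRESHOLDS[0]:
        return AnaemiaState.SEVERE
    if hb < _THRESHOLDS[1]:
        return AnaemiaState.MODERATE
    if hb < _THRESHOLDS[2]:
        return AnaemiaState.MILD
    return AnaemiaState.NONE


def categorize_anaemia_array(hb: np.ndarray) -> np.ndarray:
    """Vectorised :func:`categorize_anaemia`; returns integer state codes."""
    hb = np.asarray(hb, dtype=float)
    if not np.all(np.isfinite(hb)) or np.any(hb <= 0.0):
        raise ValueError("haemoglobin values must be finite and positive")
    # np.digitize with right-open bins matches the half-open convention
    codes = np.digitize(hb, _THRESHOLDS, right=False)  # 0=severe .. 3=none
    return (3 - codes).astype(np.int64)
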