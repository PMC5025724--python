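"""Canonical frequency bands of the analysis.

Five bands: theta 4–7, alpha 8–13, beta 13–30, low gamma 30–50 and high gamma
70–150 Hz.  The printed edges overlap at 13 and 30 Hz and leave gaps at 7–8
and 50–70 Hz; membership is made deterministic by treating every band as
half-open on its upper edge except high gamma, which includes 150 Hz:
13 Hz belongs to beta, 30 Hz to low gamma, and bins in the gaps belong to no
band.  The delta band is excluded (epochs are too short to resolve it).
"""

from __future__ import annotations

import numpy as np

#: band name -> (low_hz, high_hz)
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 50.0),
    "high_gamma": (70.0, 150.0),
}

BAND_NAMES = tuple(BANDS)

#: power decreases (ERD) are quantified in the low bands, increases (ERS) in the gamma bands
ERD_BANDS = ("theta", "alpha", "beta")
ERS_BANDS = ("low_gamma", "high_gamma")


def band_members(freq_hz: np.ndarray, band: str) -> np.ndarray:
    """Boolean membership of frequency bins in a band (half-open upper edge,
    inclusive for high gamma)."""
    lo, hi = BANDS[band]
    f = np.asarray(freq_hz, float)
    if band == "high_gamma":
        return (f >= lo) & (f <= hi)
    return (f >= lo) & (f < hi)
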