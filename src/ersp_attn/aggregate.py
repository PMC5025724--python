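"""Reduce full time–frequency maps to the 5-band × 8-window analysis grid.

Windows are 200 ms long with 100 ms overlap, onsets 0–700 ms post stimulus
(eight windows).  A time bin belongs to a window when its center timestamp
falls in the half-open interval [onset, onset + 200); a frequency bin belongs
to at most one band (see :mod:`ersp_attn.bands`).  Cell-level significance is
a fresh t-test on the cell-averaged per-trial dB values, not a vote over
bin-level masks, so each cell carries a well-defined statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import BAND_NAMES, ERD_BANDS, ERS_BANDS, band_members
from .spectral import SignificanceMask, TimeFrequencyMap, significance_mask

WINDOW_LENGTH_MS = 200.0
WINDOW_STEP_MS = 100.0
WINDOW_ONSETS_MS = tuple(float(o) for o in range(0, 800, 100))  # 8 windows
N_WINDOWS = len(WINDOW_ONSETS_MS)

#: default Bonferroni family for cell-level tests: 5 bands × 8 windows
CELL_FAMILY = len(BAND_NAMES) * N_WINDOWS


@dataclass
class BandWindowSummary:
    """Per-electrode band × window grid of mean ERSP with significance.

    ``values``: 5 × 8 mean dB; ``significant``/``sign``: outcome of the
    cell-level Bonferroni t-test; ``trial_values``: per-trial cell averages
    (n_trials × 5 × 8), kept for re-testing under other family sizes.
    """

    values: np.ndarray
    significant: np.ndarray
    sign: np.ndarray
    p_values: np.ndarray
    trial_values: np.ndarray
    bands: tuple[str, ...] = BAND_NAMES
    window_onsets_ms: tuple[float, ...] = WINDOW_ONSETS_MS
    alpha: float = 0.05
    family: int = CELL_FAMILY
    channel: str | None = None


def window_members(time_ms: np.ndarray, onset_ms: float) -> np.ndarray:
    """Boolean membership of time bins (by center) in one analysis window."""
    t = np.asarray(time_ms, float)
    return (t >= onset_ms - 1e-9) & (t < onset_ms + WINDOW_LENGTH_MS - 1e-9)


def band_window_reduce(
    trial_db: TimeFrequencyMap,
    alpha: float = 0.05,
    family: int = CELL_FAMILY,
    windows_ms: tuple[float, ...] = WINDOW_ONSETS_MS,
) -> BandWindowSummary:
    """Average per-trial dB maps into band × window cells and test each cell.

    ``trial_db`` must hold per-trial dB values (trials × time × freq).  Every
    cell must contain at least one (time, frequency) bin.
    """
    if trial_db.values.ndim != 3:
        raise ValueError("trial_db.values must be (trials, time, freq)")
    n_trials = trial_db.values.shape[0]
    n_bands, n_windows = len(BAND_NAMES), len(windows_ms)
    trial_cells = np.empty((n_trials, n_bands, n_windows))
    for bi, band in enumerate(BAND_NAMES):
        fsel = band_members(trial_db.freq_hz, band)
        if not fsel.any():
            raise ValueError(f"no frequency bins in band {band!r}")
        for wi, onset in enumerate(windows_ms):
            tsel = window_members(trial_db.time_ms, onset)
            if not tsel.any():
                raise ValueError(f"no time bins in window starting at {onset} ms")
            trial_cells[:, bi, wi] = trial_db.values[:, tsel][:, :, fsel].mean(axis=(1, 2))
    cell_mask: SignificanceMask = significance_mask(trial_cells, alpha=alpha, family=family)
    return BandWindowSummary(
        values=trial_cells.mean(axis=0),
        significant=cell_mask.mask != 0,
        sign=cell_mask.mask.astype(int),
        p_values=cell_mask.p_values,
        trial_values=trial_cells,
        window_onsets_ms=tuple(windows_ms),
        alpha=alpha,
        family=family,
        channel=trial_db.channel,
    )


def classify_electrode(summary: BandWindowSummary) -> np.ndarray:
    """Label each band × window cell 'ERD', 'ERS' or 'none' for counting.

    ERD (significant power decrease) is quantified only in the low bands
    (theta, alpha, beta); ERS (significant increase) only in the gamma bands.
    A significant change of the non-quantified sign for a band maps to 'none'
    for counting purposes — the raw signed summary retains it.
    """
    labels = np.full(summary.values.shape, "none", dtype="<U4")
    for bi, band in enumerate(summary.bands):
        for wi in range(len(summary.window_onsets_ms)):
            if not summary.significant[bi, wi]:
                continue
            if summary.sign[bi, wi] < 0 and band in ERD_BANDS:
                labels[bi, wi] = "ERD"
            elif summary.sign[bi, wi] > 0 and band in ERS_BANDS:
                labels[bi, wi] = "ERS"
    return labels
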