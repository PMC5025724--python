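"""Synthetic electrode atlas: 8 regional boxes in a Talairach-like frame.

Real subdural grids are localized by MRI/CT coregistration and normalized to a
template brain; here electrodes are placed inside axis-aligned coordinate
boxes, one per (hemisphere, region) group, covering the four lobes analyzed:
frontal, superior parietal (SPL), inferior parietal (IPL), and temporal.
Coordinates are in mm; x < 0 is the left hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROIS = ("frontal", "superior_parietal", "inferior_parietal", "temporal")
HEMISPHERES = ("L", "R")

# (y_min, y_max, z_min, z_max) in mm, Talairach-like: +y anterior, +z superior.
_ROI_BOXES = {
    "frontal": (5.0, 65.0, 5.0, 60.0),
    "superior_parietal": (-70.0, -40.0, 45.0, 70.0),
    "inferior_parietal": (-70.0, -40.0, 20.0, 44.0),
    "temporal": (-60.0, 0.0, -30.0, -2.0),
}
# lateral |x| range: subdural electrodes sit on the convexity
_X_RANGE = (35.0, 65.0)

#: electrodes per (hemisphere, roi) group in the default atlas
DEFAULT_COUNTS = {
    ("L", "frontal"): 166,
    ("R", "frontal"): 186,
    ("L", "inferior_parietal"): 20,
    ("R", "inferior_parietal"): 30,
    ("L", "superior_parietal"): 7,
    ("R", "superior_parietal"): 41,
    ("L", "temporal"): 56,
    ("R", "temporal"): 22,
}

_COLUMNS = ["channel", "x", "y", "z", "hemisphere", "roi"]


@dataclass(frozen=True)
class ElectrodeAtlas:
    """Channel coordinate table with (hemisphere, roi) labels.

    ``table`` columns: channel (unique id str), x, y, z (mm),
    hemisphere ('L'/'R'), roi (one of :data:`ROIS`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = set(_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        if t["channel"].duplicated().any():
            dupes = t.loc[t["channel"].duplicated(), "channel"].tolist()
            raise ValueError(f"duplicate channel ids: {dupes}")
        if not np.isfinite(t[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite electrode coordinates")
        bad_roi = set(t["roi"]) - set(ROIS)
        if bad_roi:
            raise ValueError(f"unknown roi labels: {sorted(bad_roi)}")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def channel_ids(self) -> list[str]:
        return self.table["channel"].tolist()

    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    def group_counts(self) -> pd.Series:
        """Electrode count per (hemisphere, roi)."""
        return self.table.groupby(["hemisphere", "roi"], sort=True).size()

    def channels_in(self, hemisphere: str, roi: str) -> np.ndarray:
        """Row indices of the channels in one regional group."""
        t = self.table
        return np.flatnonzero((t["hemisphere"] == hemisphere) & (t["roi"] == roi))

    def subsample(self, n_channels: int, rng_seed: int = 0) -> "ElectrodeAtlas":
        """Smaller atlas keeping every non-empty group, proportional allocation."""
        if not 0 < n_channels <= self.n_channels:
            raise ValueError("n_channels out of range")
        counts = self.group_counts()
        # largest-remainder allocation, at least 1 per existing group
        quota = counts / counts.sum() * n_channels
        alloc = np.maximum(1, np.floor(quota).astype(int))
        while alloc.sum() > n_channels:
            alloc[alloc.idxmax()] -= 1
        rem = (quota - alloc).sort_values(ascending=False)
        for key in rem.index:
            if alloc.sum() >= n_channels:
                break
            alloc[key] += 1
        rng = np.random.default_rng(rng_seed)
        keep: list[np.ndarray] = []
        for (hemi, roi), k in alloc.items():
            idx = self.channels_in(hemi, roi)
            keep.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
        rows = np.sort(np.concatenate(keep))
        return ElectrodeAtlas(self.table.iloc[rows].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeAtlas":
        return cls(pd.read_csv(path, sep="\t", dtype={"channel": str}))


def default_atlas(
    counts: dict[tuple[str, str], int] | None = None, rng_seed: int = 0
) -> ElectrodeAtlas:
    """Atlas with the packaged per-region electrode counts (528 total).

    Electrodes are scattered uniformly inside each regional box with a seeded
    generator, so coordinates are reproducible.  Channel ids encode the group,
    e.g. ``R_superior_parietal_03``.
    """
    if counts is None:
        counts = DEFAULT_COUNTS
    rng = np.random.default_rng(rng_seed)
    rows = []
    for hemi in HEMISPHERES:
        for roi in ROIS:
            n = counts.get((hemi, roi), 0)
            if n == 0:
                continue
            y0, y1, z0, z1 = _ROI_BOXES[roi]
            x = rng.uniform(*_X_RANGE, size=n)
            if hemi == "L":
                x = -x
            y = rng.uniform(y0, y1, size=n)
            z = rng.uniform(z0, z1, size=n)
            for i in range(n):
                rows.append(
                    {
                        "channel": f"{hemi}_{roi}_{i:03d}",
                        "x": x[i],
                        "y": y[i],
                        "z": z[i],
                        "hemisphere": hemi,
                        "roi": roi,
                    }
                )
    return ElectrodeAtlas(pd.DataFrame(rows, columns=_COLUMNS))
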