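"""On-disk bundles: HDF5 arrays with TSV/JSON sidecars.

A recording or epoch set is stored as a directory holding ``*.h5`` (arrays +
scalar attributes), ``channels.tsv`` (the electrode table) and ``events.tsv``
(BIDS-style event log), so every non-array artifact stays plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .atlas import ElectrodeAtlas
from .preprocess import EpochSet, Recording


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_recording(out_dir, recording: Recording) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "recording.h5", "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip")
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["condition"] = recording.condition or ""
    recording.channel_table.to_tsv(out / "channels.tsv")
    write_events_tsv(recording.events, out / "events.tsv")
    return out


def load_recording(in_dir) -> Recording:
    d = Path(in_dir)
    with h5py.File(d / "recording.h5", "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["sampling_rate"])
        condition = str(f.attrs.get("condition", "")) or None
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_table=ElectrodeAtlas.from_tsv(d / "channels.tsv"),
        events=read_events_tsv(d / "events.tsv"),
        condition=condition,
    )


def save_epochs(out_dir, epochs: EpochSet) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "epochs.h5", "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("rejected", data=epochs.rejected)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["t0_offset_ms"] = epochs.t0_offset_ms
        f.attrs["condition"] = epochs.condition or ""
    epochs.channel_table.to_tsv(out / "channels.tsv")
    write_events_tsv(epochs.events, out / "events.tsv")
    return out


def load_epochs(in_dir) -> EpochSet:
    d = Path(in_dir)
    with h5py.File(d / "epochs.h5", "r") as f:
        data = f["data"][()]
        rejected = f["rejected"][()]
        fs = float(f.attrs["sampling_rate"])
        t0 = float(f.attrs["t0_offset_ms"])
        condition = str(f.attrs.get("condition", "")) or None
    return EpochSet(
        data=data,
        sampling_rate=fs,
        t0_offset_ms=t0,
        rejected=rejected,
        events=read_events_tsv(d / "events.tsv"),
        channel_table=ElectrodeAtlas.from_tsv(d / "channels.tsv"),
        condition=condition,
    )


def save_ground_truth(path, ground_truth) -> None:
    payload = {
        "artifact_trials": np.asarray(ground_truth.artifact_trials).tolist(),
        "effects": [
            {
                "hemisphere": eff.hemisphere,
                "roi": eff.roi,
                "band": eff.band,
                "direction": eff.direction,
                "power_ratio": eff.power_ratio,
                "window_ms": list(eff.window_ms),
                "channel_rows": np.asarray(rows).tolist(),
            }
            for eff, rows in ground_truth.effect_channels
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def save_channel_results(
    path, channel_ids, mean_db, masks, time_ms, freq_hz, summaries
) -> None:
    """ERSP result bundle for one condition: per-channel mean dB maps, signed
    bin masks, axes, and the band × window summaries."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mean_db", data=np.asarray(mean_db, np.float32),
                         compression="gzip")
        f.create_dataset("mask", data=np.asarray(masks, np.int8), compression="gzip")
        f.create_dataset("time_ms", data=time_ms)
        f.create_dataset("freq_hz", data=freq_hz)
        f.create_dataset("channel", data=np.array(channel_ids, dtype="S"))
        f.create_dataset("cell_values", data=np.array([s.values for s in summaries]))
        f.create_dataset("cell_sign", data=np.array([s.sign for s in summaries]))
        f.create_dataset(
            "cell_significant", data=np.array([s.significant for s in summaries])
        )


def load_channel_results(path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "mean_db": f["mean_db"][()],
            "mask": f["mask"][()],
            "time_ms": f["time_ms"][()],
            "freq_hz": f["freq_hz"][()],
            "channel": [c.decode() for c in f["channel"][()]],
            "cell_values": f["cell_values"][()],
            "cell_sign": f["cell_sign"][()],
            "cell_significant": f["cell_significant"][()],
        }
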