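"""End-to-end orchestration: simulate → preprocess → ERSP → counts → maps.

The :class:`PipelineConfig` schema validates every tunable before any compute
runs; a resolved copy is written next to the outputs of each run so results
are reproducible from the output directory alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as eio
from .aggregate import (
    CELL_FAMILY,
    WINDOW_ONSETS_MS,
    BandWindowSummary,
    band_window_reduce,
    classify_electrode,
)
from .atlas import ElectrodeAtlas, default_atlas
from .bands import BAND_NAMES, BANDS
from .paradigm import generate_paradigm
from .preprocess import (
    EpochSet,
    Recording,
    bandpass,
    common_average_reference,
    epoch,
    reject_noisy_epochs,
)
from .roistats import (
    ContrastResult,
    count_fractions,
    hemisphere_contrast,
    spl_ipl_contrast,
    task_contrast,
)
from .simulate import EffectSpec, SimulationConfig, simulate_recording
from .spectral import ersp, significance_mask, stft_power
from .topomap import hemisphere_mesh, nearest_neighbor_field, render_panel

logger = logging.getLogger(__name__)


class EffectModel(BaseModel):
    hemisphere: str
    roi: str
    band: str
    direction: str
    power_ratio: float = Field(gt=0)
    window_ms: tuple[float, float] = (400.0, 600.0)

    def to_spec(self) -> EffectSpec:
        return EffectSpec(**self.model_dump())


def default_effect_maps() -> dict[str, list[EffectModel]]:
    """Condition-specific ERD/ERS layouts: the spatial map is dominated by
    the right superior parietal lobule, the nonspatial map by the right
    inferior parietal lobule plus bilateral frontal cortex."""
    return {
        "spatial": [
            EffectModel(hemisphere="R", roi="superior_parietal", band="alpha",
                        direction="ERD", power_ratio=0.5),
            EffectModel(hemisphere="R", roi="superior_parietal", band="high_gamma",
                        direction="ERS", power_ratio=2.0),
        ],
        "nonspatial": [
            EffectModel(hemisphere="R", roi="inferior_parietal", band="alpha",
                        direction="ERD", power_ratio=0.5),
            EffectModel(hemisphere="L", roi="frontal", band="alpha",
                        direction="ERD", power_ratio=0.6),
            EffectModel(hemisphere="R", roi="frontal", band="alpha",
                        direction="ERD", power_ratio=0.6),
        ],
    }


class PipelineConfig(BaseModel):
    """Validated parameter set for a full pipeline run."""

    # paradigm / simulation
    conditions: tuple[str, ...] = ("spatial", "nonspatial")
    n_trials: int = 100
    n_targets: int = 40
    n_channels: int | None = 64  # None = full default atlas (528)
    sampling_rate: float = 1000.0
    background_exponent: float = 2.0
    background_rms: float = 8.0
    artifact_rate: float = 0.02
    effects: dict[str, list[EffectModel]] = Field(default_factory=default_effect_maps)
    # preprocessing
    filter_low_hz: float = 1.0
    filter_high_hz: float = 200.0
    exclude_channels: tuple[str, ...] = ()
    epoch_pre_ms: float = 500.0
    epoch_post_ms: float = 1500.0
    reject_z: float = 6.0
    trial_selection: str = "nontarget"  # 'nontarget' | 'target' | 'all'
    # spectral
    stft_window_ms: float = 500.0
    stft_shift_ms: float = 7.5
    freq_range: tuple[float, float] = (2.0, 150.0)
    baseline_ms: tuple[float, float] = (-500.0, 0.0)
    alpha: float = 0.05
    bin_family: int | None = None  # None = number of bins per electrode
    cell_family: int = CELL_FAMILY
    # reporting
    report_band: str = "alpha"
    report_window_ms: str = "400-600"
    fade_radius_mm: float = 15.0
    seed: int = 0

    @field_validator("alpha")
    @classmethod
    def _alpha_open(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha must be in (0, 1)")
        return v

    @field_validator("conditions")
    @classmethod
    def _known_conditions(cls, v):
        for c in v:
            if c not in ("spatial", "nonspatial"):
                raise ValueError(f"unknown condition {c!r}")
        return v

    @field_validator("trial_selection")
    @classmethod
    def _known_selection(cls, v: str) -> str:
        if v not in ("nontarget", "target", "all"):
            raise ValueError("trial_selection must be nontarget|target|all")
        return v

    @field_validator("report_band")
    @classmethod
    def _known_band(cls, v: str) -> str:
        if v not in BANDS:
            raise ValueError(f"report_band must be one of {BAND_NAMES}")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        if not 0 < self.filter_low_hz < self.filter_high_hz < self.sampling_rate / 2:
            raise ValueError("need 0 < filter_low_hz < filter_high_hz < Nyquist")
        if not self.freq_range[0] < self.freq_range[1]:
            raise ValueError("invalid freq_range")
        if not self.baseline_ms[0] < self.baseline_ms[1] <= 0:
            raise ValueError("baseline must be a pre-stimulus interval")
        for cond, effs in self.effects.items():
            for e in effs:
                e.to_spec()  # raises on invalid band/roi/ratio combinations
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.dump(self.model_dump(mode="json"), sort_keys=True))


@dataclass
class ChannelAnalysis:
    """Spectral results for one electrode."""

    channel: str
    mean_db: np.ndarray  # time x freq
    mask: np.ndarray  # signed int8, time x freq
    summary: BandWindowSummary
    labels: np.ndarray  # 5 x 8 of 'ERD'/'ERS'/'none'


@dataclass
class ConditionResult:
    condition: str
    epochs: EpochSet
    channels: list[ChannelAnalysis]
    fractions: pd.DataFrame
    time_ms: np.ndarray
    freq_hz: np.ndarray


@dataclass
class PipelineResult:
    config: PipelineConfig
    conditions: dict[str, ConditionResult]
    fractions: pd.DataFrame
    contrasts: pd.DataFrame


def build_atlas(config: PipelineConfig) -> ElectrodeAtlas:
    atlas = default_atlas()
    if config.n_channels is not None and config.n_channels < atlas.n_channels:
        atlas = atlas.subsample(config.n_channels, rng_seed=config.seed)
    return atlas


def simulate_condition(
    config: PipelineConfig, condition: str, atlas: ElectrodeAtlas, seed: int
):
    """Paradigm + recording for one condition with that condition's effect map."""
    paradigm = generate_paradigm(
        condition, n_trials=config.n_trials, n_targets=config.n_targets, rng_seed=seed
    )
    sim = SimulationConfig(
        atlas=atlas,
        sampling_rate=config.sampling_rate,
        background_exponent=config.background_exponent,
        background_rms=config.background_rms,
        effects=tuple(e.to_spec() for e in config.effects.get(condition, [])),
        artifact_rate=config.artifact_rate,
        rng_seed=seed,
    )
    return simulate_recording(paradigm, sim)


def preprocess_recording(config: PipelineConfig, recording: Recording) -> EpochSet:
    rec = bandpass(recording, config.filter_low_hz, config.filter_high_hz)
    rec = common_average_reference(rec, exclude_channels=config.exclude_channels)
    epochs = epoch(rec, pre_ms=config.epoch_pre_ms, post_ms=config.epoch_post_ms)
    epochs = reject_noisy_epochs(epochs, amplitude_z_threshold=config.reject_z)
    if config.trial_selection != "all":
        want_target = config.trial_selection == "target"
        epochs = epochs.select(
            (epochs.events["trial_type"] == "target").to_numpy() == want_target
        )
    return epochs


def analyze_channel(
    epoch_data: np.ndarray, config: PipelineConfig, channel: str | None = None,
    chunk: int = 32,
) -> ChannelAnalysis:
    """Full spectral chain for one channel: STFT → per-trial ERSP → bin mask →
    band × window summary → ERD/ERS labels.  Trials are processed in chunks
    to bound memory."""
    parts = []
    tf0 = None
    for s in range(0, epoch_data.shape[0], chunk):
        tf = stft_power(
            epoch_data[s : s + chunk],
            sampling_rate=config.sampling_rate,
            window_ms=config.stft_window_ms,
            shift_ms=config.stft_shift_ms,
            freq_range=config.freq_range,
            t0_offset_ms=-config.epoch_pre_ms,
            dtype=np.float32,
        )
        tf0 = tf0 or tf
        parts.append(tf.values)
    tf0.values = np.concatenate(parts, axis=0)
    tf0.channel = channel
    mean_map, trial_db = ersp(tf0, baseline_ms=config.baseline_ms)
    mask = significance_mask(trial_db, alpha=config.alpha, family=config.bin_family)
    summary = band_window_reduce(trial_db, alpha=config.alpha, family=config.cell_family)
    return ChannelAnalysis(
        channel=channel or "",
        mean_db=mean_map.values,
        mask=mask.mask,
        summary=summary,
        labels=classify_electrode(summary),
    )


def analyze_epochs(epochs: EpochSet, config: PipelineConfig) -> ConditionResult:
    """Per-channel spectral analysis of the retained trials, then ROI counts."""
    data = epochs.retained_data()
    if data.shape[0] < 10:
        raise ValueError("fewer than 10 retained trials")
    results = []
    for ci, cid in enumerate(epochs.channel_table.channel_ids):
        results.append(analyze_channel(data[:, ci, :], config, channel=cid))
    labels = np.stack([r.labels for r in results])
    fractions = count_fractions(labels, epochs.channel_table, epochs.condition or "?")
    # axes from a probe STFT of one trial
    probe = stft_power(
        data[0, 0], sampling_rate=config.sampling_rate,
        window_ms=config.stft_window_ms, shift_ms=config.stft_shift_ms,
        freq_range=config.freq_range, t0_offset_ms=-config.epoch_pre_ms,
    )
    return ConditionResult(
        condition=epochs.condition or "?",
        epochs=epochs,
        channels=results,
        fractions=fractions,
        time_ms=probe.time_ms,
        freq_hz=probe.freq_hz,
    )


def _contrast_row(result: ContrastResult, condition: str, band: str, window: str) -> dict:
    return {
        "contrast": result.contrast,
        "condition": condition,
        "group_a": result.group_a,
        "group_b": result.group_b,
        "band": band,
        "window_ms": window,
        "sig_a": result.table[0, 0],
        "total_a": result.table[0].sum(),
        "sig_b": result.table[1, 0],
        "total_b": result.table[1].sum(),
        "test": result.test,
        "p": result.p_value,
        "significant": result.significant,
    }


def all_contrasts(fractions: pd.DataFrame, conditions: tuple[str, ...]) -> pd.DataFrame:
    """The three contrast families per band × window, uncorrected at 0.05."""
    rows = []
    windows = sorted(fractions["window_ms"].unique())
    rois = sorted(fractions["roi"].unique())
    for band in BAND_NAMES:
        for window in windows:
            if len(conditions) == 2:
                for hemi in ("L", "R"):
                    for roi in rois:
                        res = task_contrast(
                            fractions, conditions[0], conditions[1], hemi, roi,
                            band, window,
                        )
                        rows.append(_contrast_row(res, "both", band, window)
                                    | {"group_a": f"{conditions[0]} {hemi} {roi}",
                                       "group_b": f"{conditions[1]} {hemi} {roi}"})
            for cond in conditions:
                for roi in rois:
                    res = hemisphere_contrast(fractions, cond, roi, band, window)
                    rows.append(_contrast_row(res, cond, band, window))
                if {"superior_parietal", "inferior_parietal"} <= set(rois):
                    res = spl_ipl_contrast(fractions, cond, band, window)
                    rows.append(_contrast_row(res, cond, band, window))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Simulate, preprocess and analyze every condition; write the bundle.

    Outputs under ``out_dir``: per-condition ``<cond>/ersp.h5`` (maps, masks,
    summaries), ``fractions.tsv``, ``contrasts.tsv``, a topographic panel per
    condition for the reporting band/window, and ``config.yaml`` (resolved).
    Deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    atlas = build_atlas(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.conditions))
    cond_results: dict[str, ConditionResult] = {}
    for cond, seed in zip(config.conditions, seeds):
        logger.info("condition %s: simulating %d trials x %d channels",
                    cond, config.n_trials, atlas.n_channels)
        recording, truth = simulate_condition(config, cond, atlas, int(seed) % (2**31))
        epochs = preprocess_recording(config, recording)
        result = analyze_epochs(epochs, config)
        cond_results[cond] = result
        cdir = out / cond
        cdir.mkdir(exist_ok=True)
        eio.save_channel_results(
            cdir / "ersp.h5",
            atlas.channel_ids,
            [r.mean_db for r in result.channels],
            [r.mask for r in result.channels],
            result.time_ms,
            result.freq_hz,
            [r.summary for r in result.channels],
        )
        eio.write_events_tsv(epochs.events, cdir / "events.tsv")
        _render_condition_map(config, atlas, result, cdir / "topomap.png")

    fractions = pd.concat([r.fractions for r in cond_results.values()],
                          ignore_index=True)
    fractions.to_csv(out / "fractions.tsv", sep="\t", index=False)
    contrasts = all_contrasts(fractions, tuple(config.conditions))
    contrasts.to_csv(out / "contrasts.tsv", sep="\t", index=False)
    return PipelineResult(
        config=config, conditions=cond_results, fractions=fractions,
        contrasts=contrasts,
    )


def _render_condition_map(
    config: PipelineConfig, atlas: ElectrodeAtlas, result: ConditionResult, path
) -> None:
    """Right-hemisphere panel of the reporting band/window cell values."""
    bi = BAND_NAMES.index(config.report_band)
    wi = [f"{o:.0f}-{o + 200:.0f}" for o in WINDOW_ONSETS_MS].index(
        config.report_window_ms
    )
    right = atlas.table["hemisphere"] == "R"
    if not right.any():
        return
    values = np.array(
        [r.summary.values[bi, wi] * (r.summary.significant[bi, wi])
         for r in result.channels]
    )[right.to_numpy()]
    mesh = hemisphere_mesh("R")
    field = nearest_neighbor_field(
        mesh, atlas.coordinates()[right.to_numpy()], values,
        fade_radius_mm=config.fade_radius_mm,
    )
    render_panel(mesh, field, path,
                 title=f"{result.condition}: {config.report_band} "
                       f"{config.report_window_ms} ms")
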