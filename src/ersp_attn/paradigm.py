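"""Sustained-attention task paradigm.

Each trial presents one of five circular patterns at one of five vertical
screen positions.  Stimuli appear every ``isi`` seconds and stay on screen for
``stim_duration`` seconds.  In the *spatial* condition the subject responds to
stimuli at designated target positions regardless of pattern; in the
*nonspatial* condition to designated target patterns regardless of position.
The default schedule has 500 trials (200 targets, 300 nontargets) with every
pattern and every position occurring exactly 100 times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_PATTERNS = 5
N_POSITIONS = 5

CONDITIONS = ("spatial", "nonspatial")


@dataclass(frozen=True)
class TaskParadigm:
    """Trial schedule for one attention condition.

    ``trials`` has columns ``onset_s``, ``pattern_id``, ``position_id``,
    ``is_target`` (pattern/position ids are 1-based).
    """

    condition: str
    trials: pd.DataFrame
    isi: float = 2.0
    stim_duration: float = 1.0
    target_ids: tuple[int, ...] = (1, 2)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_targets(self) -> int:
        return int(self.trials["is_target"].sum())

    @property
    def duration(self) -> float:
        """Recording span needed to cover the schedule, in seconds."""
        return float(self.trials["onset_s"].iloc[-1] + self.isi)

    def onsets_samples(self, sampling_rate: float) -> np.ndarray:
        return np.round(self.trials["onset_s"].to_numpy() * sampling_rate).astype(int)

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, ...)."""
        t = self.trials
        return pd.DataFrame(
            {
                "onset": t["onset_s"],
                "duration": self.stim_duration,
                "trial_type": np.where(t["is_target"], "target", "nontarget"),
                "pattern_id": t["pattern_id"],
                "position_id": t["position_id"],
                "condition": self.condition,
            }
        )


def generate_paradigm(
    condition: str,
    n_trials: int = 500,
    n_targets: int = 200,
    rng_seed: int = 0,
    isi: float = 2.0,
    stim_duration: float = 1.0,
    target_ids: tuple[int, ...] | None = None,
    first_onset: float | None = None,
) -> TaskParadigm:
    """Build a balanced trial schedule.

    Every (pattern, position) pair occurs ``n_trials / 25`` times, so each
    pattern id and each position id occurs ``n_trials / 5`` times.  Target
    assignment follows the condition rule: in the spatial condition the trials
    at ``target_ids`` *positions* are targets; in the nonspatial condition the
    trials showing ``target_ids`` *patterns* are.  ``n_targets`` must therefore
    be a multiple of ``n_trials / 5``; the number of designated ids is
    ``n_targets / (n_trials / 5)``.  Which ids are designated is a free
    parameter (``target_ids``), defaulting to the lowest ones.

    The trial order is a seeded permutation; onsets are regular at ``isi``
    starting at ``first_onset`` (default ``isi``, leaving a pre-stimulus
    margin for epoching the first trial).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if n_trials % (N_PATTERNS * N_POSITIONS) != 0:
        raise ValueError(
            f"n_trials must be divisible by {N_PATTERNS * N_POSITIONS} "
            f"for a balanced pattern x position design, got {n_trials}"
        )
    if not 0 < n_targets < n_trials:
        raise ValueError("n_targets must be in (0, n_trials)")
    per_id = n_trials // N_PATTERNS
    if n_targets % per_id != 0:
        raise ValueError(
            f"n_targets must be a multiple of n_trials/5 = {per_id} so that "
            "whole target positions/patterns can be designated"
        )
    n_designated = n_targets // per_id
    if target_ids is None:
        target_ids = tuple(range(1, n_designated + 1))
    target_ids = tuple(int(i) for i in target_ids)
    if len(target_ids) != n_designated or not all(1 <= i <= 5 for i in target_ids):
        raise ValueError(
            f"target_ids must name {n_designated} distinct ids in 1..5, got {target_ids}"
        )

    pattern, position = np.meshgrid(
        np.arange(1, N_PATTERNS + 1), np.arange(1, N_POSITIONS + 1), indexing="ij"
    )
    pattern = np.repeat(pattern.ravel(), n_trials // 25)
    position = np.repeat(position.ravel(), n_trials // 25)

    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_trials)
    pattern, position = pattern[order], position[order]

    if condition == "spatial":
        is_target = np.isin(position, target_ids)
    else:
        is_target = np.isin(pattern, target_ids)

    if first_onset is None:
        first_onset = isi
    onsets = first_onset + isi * np.arange(n_trials)
    trials = pd.DataFrame(
        {
            "onset_s": onsets,
            "pattern_id": pattern,
            "position_id": position,
            "is_target": is_target,
        }
    )
    return TaskParadigm(
        condition=condition,
        trials=trials,
        isi=isi,
        stim_duration=stim_duration,
        target_ids=target_ids,
    )
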