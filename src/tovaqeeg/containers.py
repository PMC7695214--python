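"""Core data containers shared across the pipeline stages.

`EEGRecording` is a labeled multichannel time series in microvolts;
`TOVASession` is the trial schedule of a Test of Variables of Attention run,
optionally with behavioral responses attached; `TrialSet` is the stack of
fixed-length EEG epochs cut from a recording, one per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Trial classification labels: correct press on a target, correct
#: withhold on a nontarget, missed target, press on a nontarget.
TARGET_CORRECT = "target_correct"
NONTARGET_CORRECT = "nontarget_correct"
OMISSION = "omission"
COMMISSION = "commission"
RESTING = "resting"

TRIAL_CLASSES = (TARGET_CORRECT, NONTARGET_CORRECT, OMISSION, COMMISSION)

#: Recording state tags.
STATE_RESTING = "resting"
STATE_TOVA = "tova"


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts.

    data has shape (n_channels, n_samples); labels gives the channel name of
    each row; fs is the sampling rate in Hz; state_tag distinguishes the
    eyes-open resting baseline from the task recording.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    state_tag: str = STATE_TOVA
    subject_id: str | None = None

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with `data` substituted (same labels/fs)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class TOVASession:
    """TOVA trial schedule, optionally with behavioral responses.

    trials is a DataFrame with one row per trial:
      trial_index, onset_s, quarter (0..3), stimulus ('target'/'nontarget'),
    and, after response simulation or loading a response log:
      press_latency_ms (NaN when no press), classification (one of
      TRIAL_CLASSES).
    """

    trials: pd.DataFrame
    trial_period: float = 2.0
    subject_id: str | None = None

    REQUIRED = ("trial_index", "onset_s", "quarter", "stimulus")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.trials.columns]
        if missing:
            raise ValueError(f"session missing columns {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_targets(self) -> int:
        return int((self.trials["stimulus"] == "target").sum())

    @property
    def has_responses(self) -> bool:
        return "classification" in self.trials.columns

    @property
    def duration(self) -> float:
        """Schedule span in seconds (last onset + one trial period)."""
        return float(self.trials["onset_s"].iloc[-1]) + self.trial_period

    def class_counts(self) -> dict[str, int]:
        if not self.has_responses:
            raise ValueError("session has no responses")
        counts = self.trials["classification"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in TRIAL_CLASSES}


@dataclass
class TrialSet:
    """Stack of equal-length EEG epochs with per-epoch class labels."""

    epochs: np.ndarray  # (n_epochs, n_channels, samples_per_trial)
    classes: np.ndarray  # (n_epochs,) str labels
    labels: tuple[str, ...]
    fs: float
    subject_id: str | None = None
    state_tag: str = STATE_TOVA

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        if len(self.classes) != self.epochs.shape[0]:
            raise ValueError("one class label required per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_trial(self) -> int:
        return self.epochs.shape[2]

    def select(self, *classes: str) -> "TrialSet":
        """Sub-TrialSet containing only epochs of the given classes."""
        mask = np.isin(self.classes, classes)
        return TrialSet(
            self.epochs[mask], self.classes[mask], self.labels, self.fs,
            subject_id=self.subject_id, state_tag=self.state_tag,
        )
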