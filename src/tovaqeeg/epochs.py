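"""Trial epoching and TOVA behavioral scoring.

Recordings are cut into 2 s epochs — one per TOVA trial, starting at
stimulus onset (no pre-stimulus offset; at 256 Hz a 2 s trial is exactly
19 x 512 samples) — and into consecutive non-overlapping 2 s windows for the
resting baseline.  The five behavioral metrics are the omission rate,
commission rate, mean response time, response-time variability and the
signal-detection sensitivity d'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .containers import (
    COMMISSION,
    EEGRecording,
    NONTARGET_CORRECT,
    OMISSION,
    RESTING,
    TARGET_CORRECT,
    TOVASession,
    TrialSet,
)


@dataclass
class TOVAScores:
    """The five TOVA summary metrics for one subject.

    Rates are percentages; mean_rt and rt_variability (SD of correct-target
    latencies) are in ms and are NaN when no target was answered correctly;
    d_prime is z(hit rate) - z(false-alarm rate) with rates clipped away
    from 0 and 1 by 1/(2N) before the normal quantile.
    """

    omission_rate: float
    commission_rate: float
    mean_rt: float
    rt_variability: float
    d_prime: float
    n_targets: int
    n_nontargets: int


def segment(rec: EEGRecording, session: TOVASession) -> TrialSet:
    """One epoch per trial, [onset, onset + trial_period), classes attached."""
    spt = int(round(session.trial_period * rec.fs))
    onsets = session.trials["onset_s"].to_numpy()
    starts = np.round(onsets * rec.fs).astype(int)
    over = starts + spt > rec.n_samples
    if over.any():
        bad = int(session.trials["trial_index"].to_numpy()[over][0])
        raise ValueError(
            f"trial {bad} extends beyond the end of the recording")
    epochs = np.stack([rec.data[:, s:s + spt] for s in starts])
    if session.has_responses:
        classes = session.trials["classification"].to_numpy(dtype=object)
    else:
        classes = np.array([None] * len(starts), dtype=object)
    return TrialSet(epochs, classes, rec.labels, rec.fs,
                    subject_id=rec.subject_id, state_tag=rec.state_tag)


def resting_segment(rec: EEGRecording, trial_period: float = 2.0,
                    min_duration: float | None = None) -> TrialSet:
    """Cut a resting recording into consecutive non-overlapping windows.

    A trailing remainder shorter than one window is dropped.  `min_duration`
    (default: one window) raises when the recording is shorter.
    """
    spt = int(round(trial_period * rec.fs))
    need = spt if min_duration is None else int(round(min_duration * rec.fs))
    if rec.n_samples < max(spt, need):
        raise ValueError(
            f"resting recording too short: {rec.duration:.1f} s")
    n_win = rec.n_samples // spt
    epochs = rec.data[:, :n_win * spt].reshape(
        rec.n_channels, n_win, spt).transpose(1, 0, 2)
    classes = np.array([RESTING] * n_win, dtype=object)
    return TrialSet(epochs.copy(), classes, rec.labels, rec.fs,
                    subject_id=rec.subject_id, state_tag="resting")


def d_prime(hit_rate: float, fa_rate: float, n_targets: int,
            n_nontargets: int) -> float:
    """Signal-detection d' with extreme rates clipped by 1/(2N)."""
    h = np.clip(hit_rate, 1.0 / (2 * n_targets), 1 - 1.0 / (2 * n_targets))
    f = np.clip(fa_rate, 1.0 / (2 * n_nontargets),
                1 - 1.0 / (2 * n_nontargets))
    return float(norm.ppf(h) - norm.ppf(f))


def score_tova(session: TOVASession) -> TOVAScores:
    """Compute the five TOVA metrics from a responded session."""
    if not session.has_responses:
        raise ValueError("session has no responses to score")
    counts = session.class_counts()
    n_t = counts[TARGET_CORRECT] + counts[OMISSION]
    n_nt = counts[NONTARGET_CORRECT] + counts[COMMISSION]
    if n_t == 0 or n_nt == 0:
        raise ValueError("session needs at least one target and one nontarget")
    omission_rate = 100.0 * counts[OMISSION] / n_t
    commission_rate = 100.0 * counts[COMMISSION] / n_nt
    correct = session.trials["classification"] == TARGET_CORRECT
    lat = session.trials.loc[correct, "press_latency_ms"].to_numpy(float)
    if lat.size:
        mean_rt = float(np.mean(lat))
        rt_var = float(np.std(lat, ddof=1)) if lat.size > 1 else 0.0
    else:
        mean_rt = float("nan")   # undefined, flagged missing rather than zero
        rt_var = float("nan")
    dp = d_prime(counts[TARGET_CORRECT] / n_t, counts[COMMISSION] / n_nt,
                 n_t, n_nt)
    return TOVAScores(omission_rate, commission_rate, mean_rt, rt_var, dp,
                      n_targets=n_t, n_nontargets=n_nt)
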