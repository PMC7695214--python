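"""Plain-text I/O for recordings, sessions and clinical scores.

Recordings travel as long-format CSV (time_s, channel, uV); EDF files can be
read when mne is installed (there is no EDF writer dependency, so CSV is the
canonical output format).  Session logs and clinical scores are ordinary CSV
tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, TOVASession


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    n = rec.n_samples
    t = np.repeat(np.arange(n) / rec.fs, rec.n_channels)
    ch = np.tile(np.array(rec.labels, dtype=object), n)
    uv = rec.data.T.reshape(-1)
    pd.DataFrame({"time_s": t, "channel": ch, "uV": uv}).to_csv(
        path, index=False)


def read_recording_csv(path: str | Path, fs: float | None = None,
                       state_tag: str = "tova",
                       subject_id: str | None = None) -> EEGRecording:
    df = pd.read_csv(path)
    labels = tuple(pd.unique(df["channel"]))
    times = pd.unique(df["time_s"])
    if fs is None:
        if len(times) < 2:
            raise ValueError("cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(times)))
    wide = df.pivot(index="time_s", columns="channel", values="uV")
    data = wide[list(labels)].to_numpy().T
    return EEGRecording(labels, float(round(fs, 6)), data,
                        state_tag=state_tag, subject_id=subject_id)


def read_recording_edf(path: str | Path, state_tag: str = "tova",
                       subject_id: str | None = None) -> EEGRecording:
    """Read an EDF recording (requires mne). Signals are converted to uV."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(tuple(raw.ch_names), float(raw.info["sfreq"]), data,
                        state_tag=state_tag, subject_id=subject_id)


def read_recording(path: str | Path, **kw) -> EEGRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, **kw)
    return read_recording_csv(path, **kw)


def write_session_csv(session: TOVASession, path: str | Path) -> None:
    session.trials.to_csv(path, index=False)


def read_session_csv(path: str | Path, trial_period: float = 2.0,
                     subject_id: str | None = None) -> TOVASession:
    trials = pd.read_csv(path)
    return TOVASession(trials, trial_period=trial_period,
                       subject_id=subject_id)


def write_adjacency_json(adj: dict[str, tuple[str, ...]],
                         path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps({k: list(v) for k, v in adj.items()},
                                     indent=2, sort_keys=True))


def read_adjacency_json(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Editable channel-neighbor map; validated for symmetry on load."""
    import json

    from .montage import validate_adjacency

    raw = json.loads(Path(path).read_text())
    adj = {k: tuple(v) for k, v in raw.items()}
    validate_adjacency(adj, labels=tuple(adj))
    return adj


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Per-subject clinical scores; requires subject_id and group columns."""
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    return df
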