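"""Preprocessing chain: baseline wander, line interference, EOG artifacts.

Three stages, applied per channel in this order:

1. remove_baseline — the baseline-wander estimate is a cascade of two
   running median filters (a small 0.04 s window followed by a large 0.2 s
   window, reflect padding) subtracted from the signal.  The cascade tracks
   slow drift while medians ignore oscillatory activity.
2. remove_line — linear-phase FIR band-reject around 60 Hz, applied
   forward-backward so the output is zero-phase.
3. remove_eog — ocular artifact cancellation: the four EOG-related
   channels (Fp1, Fp2, F7, F8) are decomposed by ICA; components that track
   the low-frequency (< 4 Hz) frontal envelope are taken as EOG references;
   every channel is then passed through a recursive-least-squares (RLS)
   adaptive filter with those references as regressors and the fitted ocular
   contribution subtracted.  When no component clears the detection
   threshold the recording is returned unchanged (nothing to remove).

All stages preserve shape, labels, sampling rate and channel order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter
from sklearn.decomposition import FastICA

from .containers import EEGRecording
from .montage import EOG_CHANNELS


@dataclass
class FilterConfig:
    """Tunable parameters of the preprocessing chain (seconds / Hz / taps)."""

    median_window_large: float = 0.2
    median_window_small: float = 0.04
    notch_center: float = 60.0
    notch_halfwidth: float = 2.0
    fir_order: int = 257          # taps; odd so a band-stop design is valid
    rls_forgetting: float = 0.999
    rls_order: int = 3            # taps per EOG reference regressor
    eog_channels: tuple[str, ...] = EOG_CHANNELS
    eog_corr_threshold: float = 0.7   # |r| needed to accept an ICA component
    ica_max_iter: int = 500
    ica_seed: int = 0
    # raise on ICA non-convergence instead of treating the recording as
    # having no separable ocular component (non-convergence is the expected
    # outcome on blink-free, near-Gaussian data)
    ica_strict: bool = False

    def __post_init__(self):
        if self.median_window_large <= 0 or self.median_window_small <= 0:
            raise ValueError("median windows must be positive")
        if not 0.0 < self.rls_forgetting <= 1.0:
            raise ValueError("rls_forgetting must be in (0, 1]")


def _odd_window(seconds: float, fs: float) -> int:
    w = int(round(seconds * fs))
    return max(w | 1, 1)


def remove_baseline(rec: EEGRecording, cfg: FilterConfig | None = None,
                    ) -> EEGRecording:
    """Subtract the two-median-filter baseline estimate from each channel."""
    cfg = cfg or FilterConfig()
    small = _odd_window(cfg.median_window_small, rec.fs)
    large = _odd_window(cfg.median_window_large, rec.fs)
    n = rec.n_samples
    if max(small, large) >= n:
        raise ValueError(
            f"median window ({max(small, large)} samples) must be shorter "
            f"than the signal ({n} samples)")
    baseline = median_filter(rec.data, size=(1, small), mode="reflect")
    baseline = median_filter(baseline, size=(1, large), mode="reflect")
    return rec.with_data(rec.data - baseline)


def design_band_reject(cfg: FilterConfig, fs: float) -> np.ndarray:
    """Linear-phase FIR band-reject taps around notch_center."""
    nyq = fs / 2.0
    if cfg.notch_center >= nyq:
        raise ValueError(
            f"notch center {cfg.notch_center} Hz is at or above the Nyquist "
            f"frequency {nyq} Hz")
    ntaps = cfg.fir_order | 1  # band-stop FIR needs odd length (type I)
    edges = [cfg.notch_center - 2.0 * cfg.notch_halfwidth,
             cfg.notch_center + 2.0 * cfg.notch_halfwidth]
    return signal.firwin(ntaps, edges, fs=fs, pass_zero="bandstop",
                         window="hamming")


def remove_line(rec: EEGRecording, cfg: FilterConfig | None = None,
                ) -> EEGRecording:
    """Zero-phase FIR band-reject of the line-frequency interference.

    The designed linear-phase taps are applied circularly through the
    frequency domain (multiplying the spectrum by |H(f)|^2, the zero-phase
    forward-backward response).  Unlike reflect-padded filtering this leaves
    no boundary ringing, so a steady line tone is removed to the filter's
    full stop-band depth along the whole recording.
    """
    cfg = cfg or FilterConfig()
    taps = design_band_reject(cfg, rec.fs)
    n = rec.n_samples
    h = np.fft.rfft(taps, n)
    out = np.fft.irfft(np.fft.rfft(rec.data, axis=1) * np.abs(h) ** 2,
                       n, axis=1)
    return rec.with_data(out)


def rls_cancel(x: np.ndarray, refs: np.ndarray, order: int = 3,
               forgetting: float = 0.999, delta: float = 1e-2) -> np.ndarray:
    """Recursive-least-squares noise cancellation.

    x: (n_channels, n) signals to clean; refs: (n_refs, n) reference noise
    signals.  Each channel is modeled as w . u(t) + clean(t) where u(t)
    stacks `order` most recent samples of each reference; the RLS recursion
    adapts w per channel and the error (signal minus fitted reference
    contribution) is returned.  Because every channel sees the same
    regressor vector, the inverse-correlation update is shared and only the
    weight vectors are per-channel.
    """
    n_ch, n = x.shape
    n_refs = refs.shape[0]
    p = order * n_refs
    # unit-variance references for numerical conditioning
    scale = refs.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    r = refs / scale
    # build the lagged regressor matrix once: (p, n)
    u_all = np.empty((p, n))
    for k in range(n_refs):
        for lag in range(order):
            row = np.zeros(n)
            row[lag:] = r[k, :n - lag] if lag else r[k]
            u_all[k * order + lag] = row
    lam = forgetting
    pmat = np.eye(p) / delta
    w = np.zeros((p, n_ch))
    out = np.empty_like(x)
    for t in range(n):
        u = u_all[:, t]
        pu = pmat @ u
        gain = pu / (lam + u @ pu)
        err = x[:, t] - w.T @ u
        out[:, t] = err
        w += np.outer(gain, err)
        pmat = (pmat - np.outer(gain, pu)) / lam
        pmat = 0.5 * (pmat + pmat.T)
    return out


def _eog_references(rec: EEGRecording, cfg: FilterConfig) -> np.ndarray | None:
    """ICA the EOG-related channels; return components tracking the
    low-frequency frontal envelope, or None when none clears the threshold."""
    idx = []
    for ch in cfg.eog_channels:
        if ch not in rec.labels:
            raise ValueError(f"EOG channel {ch!r} missing from recording")
        idx.append(rec.labels.index(ch))
    eog = rec.data[idx]
    ica = FastICA(n_components=len(idx), whiten="unit-variance",
                  max_iter=cfg.ica_max_iter, tol=1e-4,
                  random_state=cfg.ica_seed)
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning
    with np.errstate(over="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(eog.T).T  # (n_comp, n)
    if ica.n_iter_ >= cfg.ica_max_iter and cfg.ica_strict:
        raise RuntimeError(
            f"ICA did not converge within {ica.n_iter_} iterations")
    # low-frequency frontal envelope: < 4 Hz content of the mean EOG channel
    sos = signal.butter(4, 4.0, btype="lowpass", fs=rec.fs, output="sos")
    envelope = signal.sosfiltfilt(sos, eog.mean(axis=0))
    env = envelope - envelope.mean()
    env_norm = np.linalg.norm(env)
    corrs = np.zeros(sources.shape[0])
    if env_norm > 0:
        for i, s in enumerate(sources):
            sc = s - s.mean()
            denom = np.linalg.norm(sc) * env_norm
            corrs[i] = abs(sc @ env) / denom if denom > 0 else 0.0
    keep = corrs >= cfg.eog_corr_threshold
    if not keep.any():
        return None
    return sources[keep]


def remove_eog(rec: EEGRecording, cfg: FilterConfig | None = None,
               ) -> EEGRecording:
    """Cancel ocular artifacts via ICA references + RLS adaptive filtering.

    Requires at least 30 s of signal for a stable ICA decomposition.  When
    the recording carries no detectable ocular component the data pass
    through unchanged.
    """
    cfg = cfg or FilterConfig()
    if rec.duration < 30.0:
        raise ValueError(
            f"recording too short for ICA-based EOG removal "
            f"({rec.duration:.1f} s < 30 s)")
    refs = _eog_references(rec, cfg)
    if refs is None:
        return rec.with_data(rec.data.copy())
    cleaned = rls_cancel(rec.data, refs, order=cfg.rls_order,
                         forgetting=cfg.rls_forgetting)
    return rec.with_data(cleaned)


def preprocess(rec: EEGRecording, cfg: FilterConfig | None = None,
               ) -> EEGRecording:
    """Full chain: baseline -> line -> EOG."""
    cfg = cfg or FilterConfig()
    return remove_eog(remove_line(remove_baseline(rec, cfg), cfg), cfg)
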