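"""Seeded synthetic EEG / TOVA cohort generator.

The study design this package analyzes — 19-channel 256 Hz EEG recorded
during a 5 min eyes-open rest and a 648-trial Test of Variables of Attention
(TOVA), with per-subject behavioral logs and Beck Depression Inventory (BDI)
scores — has no public recordings, so every downstream stage is exercised on
synthetic cohorts with the statistical structure the analysis assumes:

* band-limited Gaussian oscillators (delta/theta/alpha/beta) pushed through a
  group- and state-dependent spatial mixing matrix, giving controllable
  per-channel band power and a controllable degree of spatial-covariance
  regularity;
* frontal-weighted blink transients, slow baseline drift (< 0.5 Hz) and 60 Hz
  line interference — the three artifact classes the preprocessing stage
  removes;
* a TOVA schedule of 2 s trials in four quarters with configurable
  target/nontarget ratios, and behavioral responses with group-dependent
  omission/commission rates and response-time distributions.

The spatial-regularity knob is realized by blending a smooth spatial kernel
mixing (high regularity: neighboring channels covary smoothly, the covariance
image has few color gaps) with a seeded random mixing (low regularity:
irregular covariance pattern).  This gives the monotone control that the
covariance-image approximate-entropy score is designed to detect.

Everything is a pure function of (inputs, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .containers import (
    COMMISSION,
    EEGRecording,
    NONTARGET_CORRECT,
    OMISSION,
    STATE_RESTING,
    STATE_TOVA,
    TARGET_CORRECT,
    TOVASession,
)
from .montage import CHANNELS_19, blink_topography

# ---------------------------------------------------------------------------
# frequency bands (Hz, half-open [lo, hi)) — shared with the spectral module
# ---------------------------------------------------------------------------

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 16.0),
}
BAND_NAMES = tuple(BANDS)

#: Response window bounds for a button press, ms after stimulus onset.
RT_BOUNDS_MS = (100.0, 1900.0)

#: Length scale (in channel-order steps) of the smooth covariance kernel.
#: The montage is ordered front-to-occipital, so channel-index distance is a
#: coarse proxy for anatomical distance; a kernel on index distance makes the
#: covariance approximately constant along matrix diagonals — the repetitive
#: ("regular") pattern the two-scale entropy score is designed to detect.
CHANNEL_ORDER_KERNEL_SCALE = 3.0

#: Weight of the random covariance component at regularity 0.
IRREGULARITY_MAX_WEIGHT = 0.5


def default_band_power(delta=30.0, theta=15.0, alpha=20.0, beta=8.0,
                       n_channels=19) -> np.ndarray:
    """Flat per-channel band power profile (uV^2), shape (n_channels, 4)."""
    return np.tile(np.array([delta, theta, alpha, beta]), (n_channels, 1))


# ---------------------------------------------------------------------------
# profiles and cohort specification
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Generating parameters of one study arm.

    band_power_profile: (19, 4) target band power per channel, uV^2.
    covariance_regularity_rest / _task: in [0, 1]; 1 = fully smooth spatial
        mixing (repetitive covariance pattern), 0 = fully random mixing.
    omission_rate / commission_rate: per-trial probabilities in [0, 1].
    rt_mean / rt_sd: response-time distribution, ms (truncated normal within
        the 100-1900 ms response window).
    bdi_mean / bdi_sd: Beck Depression Inventory score distribution.
    blink_rate: blink transients per minute; drift_amplitude: RMS of the
        < 0.5 Hz baseline wander, uV; line_amplitude: 60 Hz sinusoid
        amplitude, uV.
    """

    band_power_profile: np.ndarray = field(default_factory=default_band_power)
    covariance_regularity_rest: float = 0.6
    covariance_regularity_task: float = 0.6
    omission_rate: float = 0.017
    commission_rate: float = 0.0206
    rt_mean: float = 363.0
    rt_sd: float = 47.8
    bdi_mean: float = 6.22
    bdi_sd: float = 6.76
    blink_rate: float = 12.0
    drift_amplitude: float = 20.0
    line_amplitude: float = 5.0

    def __post_init__(self):
        self.band_power_profile = np.asarray(self.band_power_profile, float)
        for name in ("omission_rate", "commission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("covariance_regularity_rest", "covariance_regularity_task"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rt_mean <= 0:
            raise ValueError("rt_mean must be positive")
        if (self.band_power_profile < 0).any():
            raise ValueError("band powers must be nonnegative")

    def regularity(self, state: str) -> float:
        return (self.covariance_regularity_rest if state == STATE_RESTING
                else self.covariance_regularity_task)


def study_profiles(theta_f7_boost: float = 1.6,
                   artifacts: bool = True) -> dict[str, GroupProfile]:
    """The documented "study" preset: two arms with the crossover.

    Behavioral parameters are typical group summaries for healthy controls
    and depressed adults on this task (control omission 1.70%, commission
    2.06%, RT 363 +- 47.8 ms, BDI 6.22 +- 6.76; patient omission 7.29%,
    commission 3.33%, RT 450 +- 92.5 ms, BDI 30.8 +- 11.7).  Spatial
    regularity crosses over between states: the
    patient arm is *less* regular than controls during the task but *more*
    regular at rest, which makes the covariance-image entropy score higher
    for patients in task conditions and higher for controls at rest.  The
    patient profile also carries elevated F7 theta power (left-frontal theta
    excess), the cordance contrast the analysis looks for.

    artifacts=False zeroes blink/drift/line amplitudes — the preset used
    when studying the analysis layer on its own, without the preprocessing
    stage in front of it.
    """
    control = GroupProfile(
        covariance_regularity_rest=0.5,
        covariance_regularity_task=0.8,
    )
    mdd_power = default_band_power()
    f7 = CHANNELS_19.index("F7")
    theta = BAND_NAMES.index("theta")
    mdd_power[f7, theta] *= theta_f7_boost
    mdd = GroupProfile(
        band_power_profile=mdd_power,
        covariance_regularity_rest=0.65,
        covariance_regularity_task=0.25,
        omission_rate=0.0729,
        commission_rate=0.0333,
        rt_mean=450.0,
        rt_sd=92.5,
        bdi_mean=30.8,
        bdi_sd=11.7,
    )
    profiles = {"control": control, "mdd": mdd}
    if not artifacts:
        for p in profiles.values():
            p.blink_rate = 0.0
            p.drift_amplitude = 0.0
            p.line_amplitude = 0.0
    return profiles


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the study conditions: 18 + 18 subjects, 256 Hz,
    19-channel 10-20 montage, 5 min rest, 648 TOVA trials every 2 s with
    324 targets split over four quarters (two target-infrequent quarters
    followed by two target-frequent quarters).
    """

    n_control: int = 18
    n_patient: int = 18
    fs: float = 256.0
    channel_labels: tuple[str, ...] = CHANNELS_19
    rest_duration: float = 300.0
    trial_period: float = 2.0
    n_trials: int = 648
    n_targets: int = 324
    quarter_target_ratios: tuple[float, ...] = (0.225, 0.225, 0.775, 0.775)
    group_profiles: dict[str, GroupProfile] = field(
        default_factory=study_profiles)
    seed: int = 0

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.n_targets > self.n_trials:
            raise ValueError("n_targets cannot exceed n_trials")
        if any(not 0.0 <= r <= 1.0 for r in self.quarter_target_ratios):
            raise ValueError("quarter target ratios must be in [0, 1]")
        if len(self.quarter_target_ratios) != 4:
            raise ValueError("exactly four quarter target ratios required")


# ---------------------------------------------------------------------------
# schedule and responses
# ---------------------------------------------------------------------------

def _quarter_sizes(n_trials: int) -> np.ndarray:
    base, extra = divmod(n_trials, 4)
    return np.array([base + (q < extra) for q in range(4)])


def _quarter_target_counts(spec: CohortSpec) -> np.ndarray:
    """Targets per quarter: ratios scaled so the total is exactly n_targets,
    rounded by largest remainder, capped at the quarter size."""
    sizes = _quarter_sizes(spec.n_trials)
    ideal = np.asarray(spec.quarter_target_ratios, float) * sizes
    total_ideal = ideal.sum()
    if total_ideal == 0:
        if spec.n_targets == 0:
            return np.zeros(4, dtype=int)
        raise ValueError(
            "quarter target ratios are all zero in quarter 1-4 but "
            f"n_targets={spec.n_targets}")
    ideal *= spec.n_targets / total_ideal
    counts = np.minimum(np.floor(ideal).astype(int), sizes)
    remainder = spec.n_targets - counts.sum()
    # distribute the remainder by largest fractional part among quarters
    # that both want targets (ratio > 0) and still have room
    order = np.argsort(-(ideal - np.floor(ideal)))
    while remainder > 0:
        progressed = False
        for q in order:
            if remainder == 0:
                break
            if ideal[q] > 0 and counts[q] < sizes[q]:
                counts[q] += 1
                remainder -= 1
                progressed = True
        if not progressed:
            q_full = int(np.argmax(counts >= sizes))
            raise ValueError(
                f"quarter {q_full + 1} cannot hold the targets required by "
                f"the ratios ({spec.n_targets} targets over {spec.n_trials} "
                "trials)")
    return counts


def make_schedule(spec: CohortSpec, seed: int | None = None,
                  subject_id: str | None = None) -> TOVASession:
    """Build a TOVA stimulus schedule (no responses yet).

    Trials start at k * trial_period; target counts per quarter follow
    quarter_target_ratios scaled to a total of exactly n_targets; the
    target/nontarget order within each quarter is randomized by `seed`.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes = _quarter_sizes(spec.n_trials)
    counts = _quarter_target_counts(spec)
    stimulus: list[str] = []
    quarter: list[int] = []
    for q in range(4):
        block = np.array(
            ["target"] * counts[q] + ["nontarget"] * (sizes[q] - counts[q]),
            dtype=object)
        rng.shuffle(block)
        stimulus.extend(block)
        quarter.extend([q] * sizes[q])
    trials = pd.DataFrame({
        "trial_index": np.arange(spec.n_trials),
        "onset_s": np.arange(spec.n_trials) * spec.trial_period,
        "quarter": np.array(quarter, dtype=int),
        "stimulus": stimulus,
    })
    return TOVASession(trials, trial_period=spec.trial_period,
                       subject_id=subject_id)


def simulate_responses(schedule: TOVASession, profile: GroupProfile,
                       seed: int) -> TOVASession:
    """Attach behavioral responses to a schedule.

    Each target is omitted independently with probability omission_rate,
    otherwise pressed at a latency drawn from a truncated normal
    (rt_mean, rt_sd) within the 100-1900 ms response window; each nontarget
    draws a commission press with probability commission_rate.
    """
    rng = np.random.default_rng(seed)
    trials = schedule.trials.copy()
    n = len(trials)
    is_target = (trials["stimulus"] == "target").to_numpy()
    u = rng.random(n)
    pressed = np.where(is_target, u >= profile.omission_rate,
                       u < profile.commission_rate)
    lo, hi = RT_BOUNDS_MS
    a = (lo - profile.rt_mean) / profile.rt_sd
    b = (hi - profile.rt_mean) / profile.rt_sd
    latency = np.full(n, np.nan)
    if pressed.any():
        latency[pressed] = truncnorm.rvs(
            a, b, loc=profile.rt_mean, scale=profile.rt_sd,
            size=int(pressed.sum()), random_state=rng)
    classification = np.where(
        is_target,
        np.where(pressed, TARGET_CORRECT, OMISSION),
        np.where(pressed, COMMISSION, NONTARGET_CORRECT),
    )
    trials["press_latency_ms"] = latency
    trials["classification"] = classification
    return TOVASession(trials, trial_period=schedule.trial_period,
                       subject_id=schedule.subject_id)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                fs: float, lo: float, hi: float) -> np.ndarray:
    """Gaussian noise strictly band-limited to [lo, hi) Hz, unit-ish variance.

    Built in the frequency domain (random Gaussian spectrum on the band's
    bins, zero elsewhere), so essentially all power lies inside the band.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    spec = np.zeros((n_rows, freqs.size), dtype=complex)
    k = int(mask.sum())
    if k == 0:
        return np.zeros((n_rows, n_samples))
    spec[:, mask] = rng.standard_normal((n_rows, k)) + \
        1j * rng.standard_normal((n_rows, k))
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    return x


def smooth_spatial_kernel(n_channels: int = 19,
                          scale: float = CHANNEL_ORDER_KERNEL_SCALE,
                          ) -> np.ndarray:
    """Smooth covariance kernel over the front-to-occipital channel order.

    Gaussian in channel-index distance, so the kernel is Toeplitz: every
    pair of channels the same number of positions apart covaries equally,
    and the covariance image is repetitive along its diagonals.
    """
    idx = np.arange(n_channels)
    return np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * scale**2))


def mixing_matrix(regularity: float, rng: np.random.Generator,
                  labels=CHANNELS_19,
                  max_irregular_weight: float = IRREGULARITY_MAX_WEIGHT,
                  ) -> np.ndarray:
    """Spatial mixing matrix for a given covariance regularity in [0, 1].

    The target channel covariance is a convex blend of the smooth
    channel-order kernel (regularity 1: repetitive pattern) and a seeded
    random Wishart matrix (regularity 0: irregular pattern); the returned
    mixing is its Cholesky factor, so mixing @ mixing.T equals the blend.
    """
    n = len(labels)
    kern = smooth_spatial_kernel(n)
    a = rng.standard_normal((n, n)) / np.sqrt(n)
    wish = a @ a.T
    wish *= np.trace(kern) / np.trace(wish)
    w = (1.0 - regularity) * max_irregular_weight
    cov = (1.0 - w) * kern + w * wish
    cov /= np.trace(cov)
    return np.linalg.cholesky(cov + 1e-9 * np.eye(n))


def simulate_recording(schedule: TOVASession | None, profile: GroupProfile,
                       spec: CohortSpec, seed: int,
                       state: str = STATE_TOVA,
                       subject_id: str | None = None,
                       mixing: np.ndarray | None = None) -> EEGRecording:
    """Synthesize one EEG recording for a subject in one state.

    The signal is a sum of four band-limited Gaussian oscillator fields,
    each mixed through the state's spatial mixing matrix and scaled per
    channel to the profile's band-power targets, plus frontal-weighted blink
    transients at blink_rate, < 0.5 Hz baseline drift at drift_amplitude RMS
    and a 60 Hz sinusoid at line_amplitude.  The task recording covers the
    schedule span; the resting recording covers rest_duration.  Deterministic
    under `seed`.
    """
    rng = np.random.default_rng(seed)
    labels = spec.channel_labels
    n_ch = len(labels)
    fs = spec.fs
    if state == STATE_RESTING:
        duration = spec.rest_duration
    else:
        if schedule is None:
            raise ValueError("task-state recording requires a schedule")
        duration = schedule.duration
    n = int(round(duration * fs))

    if mixing is None:
        mixing = mixing_matrix(profile.regularity(state), rng, labels)
    data = np.zeros((n_ch, n))
    power = profile.band_power_profile
    for b, (lo, hi) in enumerate(BANDS.values()):
        src = _band_noise(rng, n_ch, n, fs, lo, hi)
        y = mixing @ src
        var = y.var(axis=1)
        scale = np.sqrt(np.divide(power[:, b], var, out=np.zeros(n_ch),
                                  where=var > 0))
        data += scale[:, None] * y

    # blink transients, frontal-weighted
    if profile.blink_rate > 0:
        topo = blink_topography(labels)
        blink_len = int(round(0.25 * fs))
        template = np.hanning(blink_len) ** 2
        n_blinks = rng.poisson(profile.blink_rate * duration / 60.0)
        if n > blink_len:
            starts = rng.integers(0, n - blink_len, size=n_blinks)
            amps = 120.0 * rng.uniform(0.7, 1.3, size=n_blinks)
            for s, a in zip(starts, amps):
                data[:, s:s + blink_len] += a * topo[:, None] * template

    # slow baseline drift (< 0.5 Hz), per channel, scaled to RMS amplitude
    if profile.drift_amplitude > 0:
        drift = _band_noise(rng, n_ch, n, fs, 0.02, 0.5)
        rms = np.sqrt(drift.var(axis=1))
        rms[rms == 0] = 1.0
        data += profile.drift_amplitude * drift / rms[:, None]

    # 60 Hz line interference, common phase across channels
    if profile.line_amplitude > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += profile.line_amplitude * np.sin(2 * np.pi * 60.0 * t + phase)

    return EEGRecording(labels, fs, data, state_tag=state,
                        subject_id=subject_id)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    group: str
    resting: EEGRecording
    tova: EEGRecording
    session: TOVASession
    bdi: float
    seeds: dict[str, int]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]

    def groups(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects})


def _subject_seeds(root_seed: int, n_subjects: int) -> np.ndarray:
    """Deterministic (n_subjects, 5) table of 31-bit seeds."""
    ss = np.random.SeedSequence(root_seed)
    state = ss.generate_state(5 * n_subjects, dtype=np.uint32)
    return (state.reshape(n_subjects, 5) >> np.uint32(1)).astype(np.int64)


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None,
                    ) -> Cohort:
    """Generate the full synthetic cohort (recordings, sessions, scores).

    Subjects h01.. are controls, m01.. are patients.  BDI scores are drawn
    from each arm's profile (clipped to the instrument's 0-63 range).  When
    `out_dir` is given, all per-subject files plus a manifest.json listing
    files and seeds are written there; the manifest is byte-identical across
    runs with the same spec.
    """
    roster = ([("control", f"h{i + 1:02d}") for i in range(spec.n_control)]
              + [("mdd", f"m{i + 1:02d}") for i in range(spec.n_patient)])
    seeds = _subject_seeds(spec.seed, max(len(roster), 1))
    subjects: list[Subject] = []
    for k, (group, sid) in enumerate(roster):
        profile = spec.group_profiles[group]
        s_sched, s_resp, s_rest, s_task, s_bdi = (int(v) for v in seeds[k])
        schedule = make_schedule(spec, seed=s_sched, subject_id=sid)
        session = simulate_responses(schedule, profile, seed=s_resp)
        resting = simulate_recording(None, profile, spec, seed=s_rest,
                                     state=STATE_RESTING, subject_id=sid)
        tova = simulate_recording(session, profile, spec, seed=s_task,
                                  state=STATE_TOVA, subject_id=sid)
        bdi = float(np.clip(
            np.random.default_rng(s_bdi).normal(profile.bdi_mean,
                                                profile.bdi_sd),
            0.0, 63.0))
        subjects.append(Subject(sid, group, resting, tova, session, bdi,
                                seeds={"schedule": s_sched, "responses": s_resp,
                                       "resting": s_rest, "tova": s_task,
                                       "bdi": s_bdi}))
    cohort = Cohort(spec, subjects)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Persist a cohort as long-CSV recordings + CSV logs + manifest.json."""
    from . import io as tio  # local import: io depends on containers only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "root_seed": cohort.spec.seed,
        "fs": cohort.spec.fs,
        "channel_labels": list(cohort.spec.channel_labels),
        "subjects": [],
    }
    clin_rows = []
    for s in cohort.subjects:
        files = {}
        for state, rec in (("resting", s.resting), ("tova", s.tova)):
            fname = f"{s.subject_id}_{state}_eeg.csv"
            tio.write_recording_csv(rec, out / fname)
            files[state] = fname
        sess_name = f"{s.subject_id}_session.csv"
        tio.write_session_csv(s.session, out / sess_name)
        files["session"] = sess_name
        clin_rows.append({"subject_id": s.subject_id, "group": s.group,
                          "bdi": s.bdi})
        manifest["subjects"].append(
            {"subject_id": s.subject_id, "group": s.group,
             "seeds": s.seeds, "files": files})
    pd.DataFrame(clin_rows).to_csv(out / "clinical.csv", index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
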