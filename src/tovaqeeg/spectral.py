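"""Band power, neighbor-averaged ("reorganized") power, z-scores, cordance.

Per 2 s epoch and channel, absolute power is the periodogram power summed
over each of the four half-open bands delta [1,4), theta [4,8), alpha [8,12)
and beta [12,16) Hz; relative power is each band's fraction of the four-band
total.  Powers are averaged over the epochs of a condition (correct-target,
correct-nontarget, or resting), then each channel is averaged with its
neighbors on the 10-20 grid — e.g. F3 <- (F3 + Fp1 + F7 + Fz + C3)/5 — so
the value describes the electrode relative to its surroundings.  The
reorganized absolute and relative powers are z-scored across the 19 channels
(per band, per subject and condition), and cordance is their sum:

    cordance(ch) = z_abs(ch) + z_rel(ch)

Because both terms are within-subject z-scores, cordance is invariant to any
global gain applied to the raw signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .containers import NONTARGET_CORRECT, RESTING, TARGET_CORRECT, TrialSet
from .montage import DEFAULT_ADJACENCY, validate_adjacency
from .synth import BAND_NAMES, BANDS

#: Analysis conditions and the trial classes each aggregates over.
CONDITION_CLASSES: dict[str, tuple[str, ...]] = {
    "resting": (RESTING,),
    "target": (TARGET_CORRECT,),
    "nontarget": (NONTARGET_CORRECT,),
}

METRICS = ("abs", "rel", "abs_reorg", "rel_reorg", "z_abs", "z_rel",
           "cordance")


@dataclass
class BandPowerTable:
    """Per-channel x band spectral metrics for one subject and condition.

    `table` is indexed by channel label with MultiIndex columns
    (metric, band); metrics appear as the pipeline adds them: abs/rel after
    aggregation, abs_reorg/rel_reorg after neighbor averaging, z_abs/z_rel/
    cordance after z-scoring.
    """

    subject_id: str | None
    condition: str
    table: pd.DataFrame
    n_epochs: int = 0

    def values(self, metric: str) -> np.ndarray:
        """(n_channels, n_bands) array of one metric."""
        return self.table[metric][list(BAND_NAMES)].to_numpy(float)

    def set_values(self, metric: str, arr: np.ndarray) -> None:
        for j, band in enumerate(BAND_NAMES):
            self.table[(metric, band)] = arr[:, j]

    def to_tidy(self) -> pd.DataFrame:
        tidy = (self.table.stack(level=[0, 1], future_stack=True)
                .rename("value").reset_index())
        tidy.columns = ["channel", "metric", "band", "value"]
        tidy.insert(0, "condition", self.condition)
        tidy.insert(0, "subject_id", self.subject_id)
        return tidy


def band_power(trialset: TrialSet) -> np.ndarray:
    """Per-epoch absolute band power, shape (n_epochs, n_channels, 4).

    Boxcar periodogram per epoch (no detrending), integrated over each
    band's frequency bins, so the total over all bins equals the epoch's
    mean-square amplitude (Parseval).
    """
    if trialset.n_epochs == 0:
        raise ValueError("empty trial set")
    freqs, pxx = periodogram(trialset.epochs, fs=trialset.fs,
                             window="boxcar", detrend=False,
                             scaling="density", axis=2)
    df = freqs[1] - freqs[0]
    out = np.empty(trialset.epochs.shape[:2] + (len(BANDS),))
    for b, (lo, hi) in enumerate(BANDS.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, :, b] = pxx[:, :, mask].sum(axis=2) * df
    return out


def aggregate_condition(trial_powers: np.ndarray, classes: np.ndarray,
                        condition: str, labels: tuple[str, ...],
                        subject_id: str | None = None) -> BandPowerTable:
    """Average per-epoch powers over a condition's epochs; add rel power."""
    keep = np.isin(np.asarray(classes, dtype=object),
                   CONDITION_CLASSES[condition])
    if not keep.any():
        raise ValueError(f"no epochs in condition {condition!r}")
    abs_power = trial_powers[keep].mean(axis=0)  # (n_ch, 4)
    totals = abs_power.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, abs_power / totals, np.nan)
    if (totals == 0).any():
        warnings.warn("zero total band power on some channel; relative "
                      "power undefined there", RuntimeWarning, stacklevel=2)
    cols = pd.MultiIndex.from_product([["abs", "rel"], BAND_NAMES],
                                      names=["metric", "band"])
    table = pd.DataFrame(np.hstack([abs_power, rel]), index=list(labels),
                         columns=cols)
    return BandPowerTable(subject_id, condition, table,
                          n_epochs=int(keep.sum()))


def neighbor_average(bpt: BandPowerTable,
                     adjacency: dict[str, tuple[str, ...]] | None = None,
                     ) -> BandPowerTable:
    """Reorganize abs and rel power: each channel averaged with neighbors."""
    adj = DEFAULT_ADJACENCY if adjacency is None else adjacency
    labels = tuple(bpt.table.index)
    validate_adjacency(adj, labels)
    out = BandPowerTable(bpt.subject_id, bpt.condition, bpt.table.copy(),
                         n_epochs=bpt.n_epochs)
    index = {ch: i for i, ch in enumerate(labels)}
    for metric in ("abs", "rel"):
        vals = bpt.values(metric)
        reorg = np.empty_like(vals)
        for ch, i in index.items():
            rows = [i] + [index[nb] for nb in adj.get(ch, ())]
            reorg[i] = vals[rows].mean(axis=0)
        out.set_values(f"{metric}_reorg", reorg)
    return out


def zscore_and_cordance(bpt: BandPowerTable,
                        pool_bands: bool = False) -> BandPowerTable:
    """z-score reorganized powers across channels; cordance = z_abs + z_rel.

    z-scores use the population SD across the 19 channels, per band by
    default (`pool_bands=True` pools the four bands into one distribution).
    """
    if "abs_reorg" not in bpt.table.columns.get_level_values(0):
        bpt = neighbor_average(bpt)
    out = BandPowerTable(bpt.subject_id, bpt.condition, bpt.table.copy(),
                         n_epochs=bpt.n_epochs)
    for metric in ("abs", "rel"):
        vals = bpt.values(f"{metric}_reorg")
        if pool_bands:
            mu, sd = vals.mean(), vals.std()
            mu = np.full(vals.shape[1], mu)
            sd = np.full(vals.shape[1], sd)
        else:
            mu = vals.mean(axis=0)
            sd = vals.std(axis=0)  # population SD
        if (sd == 0).any():
            warnings.warn("zero variance across channels; z-scores undefined "
                          "for some band", RuntimeWarning, stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (vals - mu) / sd, np.nan)
        out.set_values(f"z_{metric}", z)
    out.set_values("cordance", out.values("z_abs") + out.values("z_rel"))
    return out


def band_power_table(trialset: TrialSet, condition: str,
                     adjacency: dict[str, tuple[str, ...]] | None = None,
                     pool_bands: bool = False) -> BandPowerTable:
    """One-shot pipeline: band power -> aggregate -> reorganize -> cordance."""
    powers = band_power(trialset)
    bpt = aggregate_condition(powers, trialset.classes, condition,
                              trialset.labels, subject_id=trialset.subject_id)
    return zscore_and_cordance(neighbor_average(bpt, adjacency),
                               pool_bands=pool_bands)
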