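"""Covariance-matrix images: per-trial scatter, trial averaging, 8-bit map.

For each 2 s trial X (channels x samples), the trace-normalized scatter
matrix X X^T / trace(X X^T) captures the between-channel interaction pattern
with unit trace.  Averaging these matrices over a condition's correct trials
(signal averaging) raises the signal-to-noise ratio; the averaged matrix is
then min-max mapped to 8-bit gray levels (0..255, rounding half up) and
histogram-equalized with the standard discrete cumulative-histogram formula.
Rows and columns follow the fixed front-to-occipital electrode order, so
images are comparable cell by cell across subjects.

The scatter (non-centered) product is the default; `centered=True` switches
to the mean-subtracted covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import TrialSet


@dataclass
class CovarianceImage:
    """Per-subject, per-condition 19 x 19 covariance image.

    raw: trial-averaged trace-normalized matrix (symmetric PSD, trace 1);
    image8: raw min-max mapped to integers 0..255; equalized: image8 after
    histogram equalization.
    """

    raw: np.ndarray
    image8: np.ndarray
    equalized: np.ndarray
    n_trials_used: int
    condition: str | None = None
    subject_id: str | None = None


def trial_cov(epoch: np.ndarray, centered: bool = False) -> np.ndarray:
    """Trace-normalized (scatter) covariance of one epoch.

    epoch is (channels x samples) with at least two samples; the result is
    symmetric with trace exactly 1.
    """
    x = np.asarray(epoch, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("epoch must be 2-D with at least 2 samples")
    if centered:
        x = x - x.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr == 0:
        raise ValueError("all-zero epoch has zero trace")
    c /= tr
    return 0.5 * (c + c.T)


def average_cov(trialset: TrialSet, class_filter: str | tuple[str, ...],
                centered: bool = False) -> np.ndarray:
    """Elementwise mean of per-trial matrices over the given class(es)."""
    classes = ((class_filter,) if isinstance(class_filter, str)
               else tuple(class_filter))
    sub = trialset.select(*classes)
    if sub.n_epochs == 0:
        raise ValueError(f"no epochs of class {class_filter!r}")
    return np.mean([trial_cov(e, centered=centered) for e in sub.epochs],
                   axis=0)


def to_image(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a raw matrix to (image8, equalized) 8-bit integer images.

    image8 is the linear min-max map to [0, 255], rounded half up; a
    constant matrix maps to all zeros (flagged with a warning).  equalized
    applies discrete cumulative-histogram equalization over 256 levels,
    which is a monotone nondecreasing relabeling of image8.
    """
    raw = np.asarray(raw, float)
    if not np.isfinite(raw).all():
        raise ValueError("raw matrix contains non-finite values")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("constant covariance matrix; image set to all zeros",
                      RuntimeWarning, stacklevel=2)
        image8 = np.zeros(raw.shape, dtype=np.uint8)
    else:
        scaled = 255.0 * (raw - lo) / (hi - lo)
        image8 = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    hist = np.bincount(image8.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    npix = image8.size
    if npix == cdf_min:
        equalized = np.zeros_like(image8)
    else:
        lut = np.floor((cdf - cdf_min) / (npix - cdf_min) * 255.0 + 0.5)
        equalized = np.clip(lut, 0, 255).astype(np.uint8)[image8]
    return image8, equalized


def covariance_image(trialset: TrialSet,
                     class_filter: str | tuple[str, ...],
                     condition: str | None = None,
                     centered: bool = False) -> CovarianceImage:
    """Full pipeline: per-trial scatter -> trial average -> 8-bit images."""
    classes = ((class_filter,) if isinstance(class_filter, str)
               else tuple(class_filter))
    sub = trialset.select(*classes)
    if sub.n_epochs == 0:
        raise ValueError(f"no epochs of class {class_filter!r}")
    raw = average_cov(sub, classes, centered=centered)
    image8, equalized = to_image(raw)
    return CovarianceImage(raw, image8, equalized, n_trials_used=sub.n_epochs,
                           condition=condition, subject_id=trialset.subject_id)


def save_image(img: CovarianceImage, png_path, csv_path=None,
               which: str = "equalized") -> None:
    """Persist an image as 8-bit grayscale PNG (plus raw values as CSV)."""
    from PIL import Image

    arr = getattr(img, which)
    Image.fromarray(np.asarray(arr, dtype=np.uint8), mode="L").save(png_path)
    if csv_path is not None:
        np.savetxt(csv_path, img.raw, delimiter=",")


def load_image_csv(csv_path) -> np.ndarray:
    """Raw covariance values back from the CSV sidecar."""
    return np.loadtxt(csv_path, delimiter=",")


def adjacent_color_gap(image: np.ndarray) -> float:
    """Mean absolute difference between horizontally adjacent pixels.

    A coarse regularity diagnostic: smooth spatial covariance produces small
    gaps between adjacent channels' colors, irregular covariance large ones.
    """
    img = np.asarray(image, float)
    return float(np.abs(np.diff(img, axis=1)).mean())
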