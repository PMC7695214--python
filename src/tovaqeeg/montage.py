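"""The 19-channel International 10-20 montage used throughout the package.

Channels are kept in a fixed front-to-occipital order so that covariance
matrices from different subjects are comparable cell by cell. 2-D positions
are the usual schematic head layout (unit head radius, +y toward the nasion);
they are used by the synthetic generator for spatially smooth mixing and for
the frontal weighting of blink artifacts, not for source localization.
"""

from __future__ import annotations

import numpy as np

#: Fixed electrode order, frontal to occipital.
CHANNELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Schematic 2-D electrode positions (x lateral, y anterior), unit head radius.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.36, 0.50), "Fz": (0.0, 0.48),
    "F4": (0.36, 0.50), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.36, -0.50), "Pz": (0.0, -0.48),
    "P4": (0.36, -0.50), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: Default nearest-neighbor adjacency on the 10-20 grid. Symmetric, no
#: self-neighbors. The F3 row is the convention anchor: F3 averages with
#: Fp1, F7, Fz and C3.
DEFAULT_ADJACENCY: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F7", "F3"),
    "Fp2": ("Fp1", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("F3", "F4", "Cz"),
    "F4": ("Fp2", "Fz", "F8", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "Cz", "T4", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4"),
    "P4": ("C4", "Pz", "T6", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
}

#: Frontal channels used for the "frontal" cordance aggregate.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")

#: Channels carrying most of the ocular (EOG) artifact.
EOG_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F8")


def positions_array(labels=CHANNELS_19) -> np.ndarray:
    """(n, 2) array of schematic positions for `labels`."""
    return np.array([CHANNEL_POSITIONS[c] for c in labels], dtype=float)


def blink_topography(labels=CHANNELS_19) -> np.ndarray:
    """Fixed spatial loading of a blink transient across the montage.

    Loadings fall off with distance from the eyes (at roughly (+-0.35, 1.15)
    in the schematic layout), so Fp1/Fp2 load highest, then F7/F8, with
    negligible posterior contribution.
    """
    eyes = np.array([[-0.35, 1.15], [0.35, 1.15]])
    pos = positions_array(labels)
    d = np.minimum(
        np.linalg.norm(pos - eyes[0], axis=1),
        np.linalg.norm(pos - eyes[1], axis=1),
    )
    load = 1.0 / (1.0 + 4.0 * d**2)
    return load / load.max()


def validate_adjacency(adj: dict[str, tuple[str, ...]], labels=CHANNELS_19) -> None:
    """Raise ValueError if `adj` is not a symmetric, self-free neighbor map."""
    known = set(labels)
    for ch, neigh in adj.items():
        if ch not in known:
            raise ValueError(f"adjacency names unknown channel {ch!r}")
        for nb in neigh:
            if nb not in known:
                raise ValueError(f"adjacency of {ch!r} names unknown channel {nb!r}")
            if nb == ch:
                raise ValueError(f"channel {ch!r} listed as its own neighbor")
            if ch not in adj.get(nb, ()):
                raise ValueError(f"adjacency not symmetric: {ch!r}->{nb!r}")
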