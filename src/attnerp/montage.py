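"""Default channel layout: 32 scalp electrodes (10/20 system), two 6-electrode
earpieces, and one EOG channel.

The scalp coordinates are approximate planar (top-view) projections of the
10/20 positions on a unit head circle (x: left->right, y: back->front); they
are used only for building leadfield weight maps and the channel-adjacency
graph of the spatial cluster test, neither of which needs sub-centimetre
accuracy.  Ear electrode sites follow the in-ear naming convention
(A, B, C, T, E, I per earpiece).
"""

from __future__ import annotations

import math

import numpy as np

#: 32 scalp channels with planar coordinates.
SCALP_32: dict[str, tuple[float, float]] = {
    "Fp1": (-0.28, 0.85), "Fp2": (0.28, 0.85),
    "F7": (-0.73, 0.53), "F3": (-0.37, 0.47), "Fz": (0.0, 0.45),
    "F4": (0.37, 0.47), "F8": (0.73, 0.53),
    "FT9": (-0.95, 0.21), "FC5": (-0.57, 0.25), "FC1": (-0.20, 0.23),
    "FC2": (0.20, 0.23), "FC6": (0.57, 0.25), "FT10": (0.95, 0.21),
    "T7": (-0.90, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T8": (0.90, 0.0),
    "TP9": (-0.95, -0.21), "CP5": (-0.57, -0.25), "CP1": (-0.20, -0.23),
    "CP2": (0.20, -0.23), "CP6": (0.57, -0.25), "TP10": (0.95, -0.21),
    "P7": (-0.73, -0.53), "P3": (-0.37, -0.47), "Pz": (0.0, -0.45),
    "P4": (0.37, -0.47), "P8": (0.73, -0.53),
    "O1": (-0.28, -0.85), "Oz": (0.0, -0.90), "O2": (0.28, -0.85),
}

#: In-ear electrode site codes, identical for both earpieces.
EAR_SITES = ("A", "B", "C", "T", "E", "I")

EAR_LEFT = tuple(f"EL_{s}" for s in EAR_SITES)
EAR_RIGHT = tuple(f"ER_{s}" for s in EAR_SITES)

EOG_CHANNEL = "EOG"


def default_channels() -> tuple[list[str], dict[str, str]]:
    """Return (labels, group map) for the default 32+6+6+EOG setup."""
    labels = list(SCALP_32) + list(EAR_LEFT) + list(EAR_RIGHT) + [EOG_CHANNEL]
    groups = {c: "scalp" for c in SCALP_32}
    groups.update({c: "ear_left" for c in EAR_LEFT})
    groups.update({c: "ear_right" for c in EAR_RIGHT})
    groups[EOG_CHANNEL] = "eog"
    return labels, groups


def default_montage2d() -> dict[str, tuple[float, float]]:
    """Planar coordinates for scalp channels plus nominal ear positions.

    The ear electrodes sit close together near the ears; their positions
    are nominal (they are never used for scalp adjacency).
    """
    pos = dict(SCALP_32)
    for i, c in enumerate(EAR_LEFT):
        pos[c] = (-1.05, -0.10 - 0.04 * i)
    for i, c in enumerate(EAR_RIGHT):
        pos[c] = (1.05, -0.10 - 0.04 * i)
    pos[EOG_CHANNEL] = (0.0, 1.05)
    return pos


def _gauss2d(xy: tuple[float, float], center: tuple[float, float],
             sigma: float) -> float:
    d2 = (xy[0] - center[0]) ** 2 + (xy[1] - center[1]) ** 2
    return math.exp(-d2 / (2.0 * sigma ** 2))


def cognitive_leadfield(
    ear_attenuation: float = 0.15,
    ear_pattern: tuple[float, ...] = (1.0, 0.7, 0.4, -0.4, -0.7, -1.0),
) -> dict[str, float]:
    """Channel weights of the parietal cognitive (P3b-like) source.

    A parietal-maximal positive lobe (Gaussian around Pz) with an
    opposite-sign frontal lobe emulating the far end of the underlying
    dipole.  The scalp weights are centred to zero mean (a dipolar
    potential integrates to ~0 over the scalp, and a zero-mean field is
    unchanged by average referencing) and normalised so the Pz weight is
    exactly 1.  Ear channels get
    the Pz weight scaled by ``ear_attenuation`` and a per-ear sign
    pattern over the six sites (the in-ear projection of a distant dipole
    changes sign along the ear canal; a pattern with zero mean also
    survives within-ear average referencing).  The EOG channel carries no
    cognitive signal.
    """
    parietal = (0.0, -0.45)
    frontal = (0.0, 0.75)
    raw = {
        c: _gauss2d(xy, parietal, 0.50) - 0.45 * _gauss2d(xy, frontal, 0.45)
        for c, xy in SCALP_32.items()
    }
    mean = sum(raw.values()) / len(raw)
    scale = 1.0 / (raw["Pz"] - mean)
    weights = {c: (v - mean) * scale for c, v in raw.items()}
    for ear in (EAR_LEFT, EAR_RIGHT):
        for c, p in zip(ear, ear_pattern):
            weights[c] = ear_attenuation * p
    weights[EOG_CHANNEL] = 0.0
    return weights


def ocular_leadfield(ear_weight: float = 0.02) -> dict[str, float]:
    """Channel weights of the ocular (blink) source.

    Frontal-maximal, decaying towards the back of the head; the EOG
    channel sees the source with unit weight.
    """
    eyes = (0.0, 1.0)
    weights = {c: 0.9 * _gauss2d(xy, eyes, 0.42) for c, xy in SCALP_32.items()}
    for c in EAR_LEFT + EAR_RIGHT:
        weights[c] = ear_weight
    weights[EOG_CHANNEL] = 1.0
    return weights


def leadfield_vector(weights: dict[str, float], labels: list[str]) -> np.ndarray:
    missing = [c for c in labels if c not in weights]
    if missing:
        raise KeyError(f"leadfield missing channels: {missing}")
    return np.array([weights[c] for c in labels], dtype=float)
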