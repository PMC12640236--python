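"""64-channel 10-10 montage used throughout the package.

The scalp layout matches a standard 64-electrode actiCAP-style montage
(10-10 names), plus the two mastoids used as reference and two EOG
channels.  2-D positions come from MNE's built-in 10-05 montage via an
azimuthal-equidistant projection of the spherical positions; they are used
only for spatial adjacency, so the projection convention is not critical.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np

#: 64 scalp electrodes (10-10 names).
SCALP_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")
EOG: tuple[str, str] = ("EOG1", "EOG2")

#: Full recorded channel set: 64 scalp + 2 mastoids + 2 EOG.
RECORDED: tuple[str, ...] = SCALP_64 + MASTOIDS + EOG

#: Frontal electrode set where the congruency effect on Mu entrainment is
#: planted by default in the synthetic experiment.
FRONTAL_SET: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AFz", "AF4", "AF8", "F5", "FC3", "C5",
)

#: Central electrodes classically showing Mu suppression.
CENTRAL_SET: tuple[str, ...] = ("Cz", "C1", "C2", "C3")


@functools.lru_cache(maxsize=None)
def _standard_positions_3d() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1005")
    return {
        name: pos.copy() for name, pos in mont.get_positions()["ch_pos"].items()
    }


def positions_2d(labels: tuple[str, ...] | list[str] = SCALP_64) -> dict[str, tuple[float, float]]:
    """2-D electrode positions (azimuthal-equidistant projection), in metres.

    Only scalp/mastoid labels have positions; EOG labels raise KeyError.
    """
    pos3d = _standard_positions_3d()
    out: dict[str, tuple[float, float]] = {}
    for lab in labels:
        if lab not in pos3d:
            raise KeyError(f"no standard 10-05 position for channel {lab!r}")
        p = pos3d[lab]
        # project around the head centre used by the montage sphere
        x, y, z = p
        r = np.sqrt(x * x + y * y + z * z)
        rho = np.sqrt(x * x + y * y)
        theta = np.arccos(np.clip(z / r, -1.0, 1.0))  # polar angle from vertex
        if rho < 1e-12:
            out[lab] = (0.0, 0.0)
        else:
            scale = r * theta / rho
            out[lab] = (float(x * scale), float(y * scale))
    return out


def channel_weight(label: str, region: str) -> float:
    """Spatial weight of a channel for a rhythm source region.

    region 'occipital' weights the alpha generator (O/PO heavy), region
    'central' weights the intrinsic Mu rhythm (C/FC/CP heavy).  Weights are
    coarse by design; they only shape the synthetic topography.
    """
    if region == "occipital":
        if label.startswith(("O", "PO", "Iz")):
            return 1.0
        if label.startswith("P"):
            return 0.5
        return 0.1
    if region == "central":
        if label.startswith(("C", "FC", "CP")) and not label.startswith("CPz"):
            return 1.0
        if label in ("CPz", "FCz"):
            return 1.0
        if label.startswith(("F", "T", "P")):
            return 0.3
        return 0.1
    raise ValueError(f"unknown region {region!r}")
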