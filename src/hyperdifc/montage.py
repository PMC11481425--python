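"""Standard 10-20 electrode geometry for the 31-channel hyperscanning cap.

Positions come from MNE's built-in idealized 10-20 montage and are projected
onto the unit sphere (the head-centre origin of the template is close enough
to the sphere centre that plain normalization suffices for angular
interpolation between neighbouring electrodes).
"""

from __future__ import annotations

import warnings

import numpy as np

#: The 31 EEG electrodes of the dual 32-channel caps (31 EEG + 1 EOG per
#: subject).  TP9/TP10 are the left/right mastoids used as the offline
#: reference; the remaining 29 are analysis channels.
CHANNELS_31: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2",
)

MASTOIDS: tuple[str, str] = ("TP9", "TP10")

EOG_CHANNEL = "EOG"


def _load_template() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            mont = mne.channels.make_standard_montage("standard_1020")
        except ValueError:  # pragma: no cover - renamed in newer MNE
            mont = mne.channels.make_standard_montage("colin27_1020")
    return mont.get_positions()["ch_pos"]


_TEMPLATE: dict[str, np.ndarray] | None = None


def unit_positions(channels=CHANNELS_31) -> dict[str, np.ndarray]:
    """Unit-sphere 3-D positions for ``channels``.

    Parameters
    ----------
    channels
        Electrode names present in the extended 10-20 nomenclature.

    Returns
    -------
    dict mapping channel name to a unit-norm ``(3,)`` float array.
    """
    global _TEMPLATE
    if _TEMPLATE is None:
        _TEMPLATE = _load_template()
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        if ch not in _TEMPLATE:
            raise KeyError(f"channel {ch!r} not in the 10-20 template montage")
        p = np.asarray(_TEMPLATE[ch], dtype=float)
        out[ch] = p / np.linalg.norm(p)
    return out


def great_circle_distance(p0: np.ndarray, p1: np.ndarray) -> float:
    """Angle (radians) between two unit vectors."""
    return float(np.arccos(np.clip(np.dot(p0, p1), -1.0, 1.0)))
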