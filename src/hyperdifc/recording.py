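"""Core containers: a single subject's recording and a paired hyperscanning block."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import MASTOIDS

#: channel kinds
EEG, EOG, REFERENCE = "EEG", "EOG", "reference"

#: relationship coding used throughout (and by the classifier labels)
STRANGER, LOVER = 0, 1
RELATIONSHIP_CODE = {"stranger": STRANGER, "lover": LOVER}

HANDS = ("off", "on")


@dataclass
class Recording:
    """One subject's multichannel time series.

    Attributes
    ----------
    subject_id : str
    role : {"male", "female"}
        Seat within the dyad; the dIFC tensor axes are named after it.
    fs : float
        Sampling frequency in Hz.
    channels : list of (name, kind)
        Ordered channel descriptors; kind is ``"EEG"``, ``"EOG"`` or
        ``"reference"``.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (until normalization makes it dimensionless).
    montage : dict
        Channel name -> unit-sphere 3-D position for every EEG channel.
    """

    subject_id: str
    role: str
    fs: float
    channels: list[tuple[str, str]]
    data: np.ndarray
    montage: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channels)} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    # -- channel bookkeeping -------------------------------------------------
    @property
    def channel_names(self) -> list[str]:
        return [name for name, _ in self.channels]

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    @property
    def eeg_names(self) -> list[str]:
        """All EEG channels, mastoids included."""
        return [name for name, kind in self.channels if kind == EEG]

    @property
    def analysis_names(self) -> list[str]:
        """EEG channels entering connectivity analysis (no mastoids, no EOG)."""
        return [n for n in self.eeg_names if n not in MASTOIDS]

    @property
    def eog_name(self) -> str | None:
        for name, kind in self.channels:
            if kind == EOG:
                return name
        return None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.index(name)]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       channels=list(self.channels),
                       montage=dict(self.montage))


@dataclass
class PairedBlock:
    """Two simultaneous recordings of one dyad under one hand condition."""

    pair_id: str
    relationship: int  # 0 = stranger, 1 = lover
    hand: str  # "off" or "on"
    male: Recording
    female: Recording

    def __post_init__(self) -> None:
        if self.relationship not in (STRANGER, LOVER):
            raise ValueError(f"relationship must be 0/1, got {self.relationship!r}")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.male.fs != self.female.fs:
            raise ValueError("paired recordings must share the sampling rate")
        if self.male.n_samples != self.female.n_samples:
            raise ValueError("paired recordings must share the sample count")

    @property
    def fs(self) -> float:
        return self.male.fs

    @property
    def n_samples(self) -> int:
        return self.male.n_samples

    def copy(self) -> "PairedBlock":
        return replace(self, male=self.male.copy(), female=self.female.copy())
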