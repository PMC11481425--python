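"""Reading and writing BrainVision ``.vhdr/.vmrk/.eeg`` triplets.

The writer emits the vendor's plain-text header/marker files plus IEEE
float32 multiplexed binary data (microvolts, resolution 1.0), which is the
dialect the dual BrainAmp setup records.  The reader accepts that dialect
back and tags channel kinds from an explicit map (default: a channel named
``EOG`` is ocular, TP9/TP10 stay EEG and act as mastoid references).
"""

from __future__ import annotations

import configparser
import os
import re
import warnings
from pathlib import Path

import numpy as np

from .montage import EOG_CHANNEL, unit_positions
from .recording import EEG, EOG, Recording

__all__ = ["write_brainvision", "read_brainvision"]

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by hyperdifc

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,0
"""


def write_brainvision(rec: Recording, basepath: str | os.PathLike) -> Path:
    """Write ``basepath``.vhdr/.vmrk/.eeg; returns the header path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    lines = []
    for k, (name, _kind) in enumerate(rec.channels, start=1):
        lines.append(f"Ch{k}={name},,1,µV")
    header = _VHDR_TEMPLATE.format(
        stem=stem, n_channels=len(rec.channels),
        sampling_interval=int(round(1e6 / rec.fs)),
        channel_lines="\n".join(lines))
    (base.with_suffix(".vhdr")).write_text(header, encoding="utf-8")
    (base.with_suffix(".vmrk")).write_text(_VMRK_TEMPLATE.format(stem=stem),
                                           encoding="utf-8")
    rec.data.T.astype("<f4").tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def read_brainvision(path: str | os.PathLike, subject_id: str | None = None,
                     role: str = "male",
                     channel_kinds: dict[str, str] | None = None,
                     expected_fs: float | None = None) -> Recording:
    """Read a BrainVision triplet back into a :class:`Recording`.

    ``channel_kinds`` maps channel names to kinds for anything the default
    rule (name == ``EOG`` -> ocular, everything else EEG) gets wrong.  If
    ``expected_fs`` disagrees with the header, a warning is emitted and the
    header wins.
    """
    vhdr = Path(path)
    if vhdr.suffix != ".vhdr":
        vhdr = vhdr.with_suffix(".vhdr")
    if not vhdr.exists():
        raise FileNotFoundError(f"missing header file {vhdr}")

    cp = configparser.ConfigParser(strict=False, interpolation=None)
    text = vhdr.read_text(encoding="utf-8")
    cp.read_string(re.sub(r"^;.*$", "", text, flags=re.M).split("\n", 1)[1])
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError(f"{vhdr}: only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError(f"{vhdr}: only MULTIPLEXED orientation is supported")
    binfmt = cp["Binary Infos"].get("BinaryFormat", "").upper()
    if binfmt != "IEEE_FLOAT_32":
        raise ValueError(f"{vhdr}: unsupported BinaryFormat {binfmt!r}")

    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-9:
        warnings.warn(f"{vhdr}: header sampling rate {fs:g} Hz differs from "
                      f"expected {expected_fs:g} Hz; header wins")
    names, units = [], []
    for k in range(1, n_channels + 1):
        entry = cp["Channel Infos"][f"Ch{k}"]
        parts = entry.split(",")
        names.append(parts[0])
        unit = parts[3] if len(parts) > 3 and parts[3] else "µV"
        units.append(unit)
    bad_units = {u for u in units if u not in ("µV", "µV", "uV")}
    if bad_units:
        raise ValueError(f"{vhdr}: unsupported channel units {bad_units}")

    datafile = vhdr.parent / common["DataFile"]
    if not datafile.exists():
        raise FileNotFoundError(f"missing binary data file {datafile}")
    raw = np.fromfile(datafile, dtype="<f4")
    if raw.size % n_channels:
        raise ValueError(
            f"truncated binary file {datafile}: {raw.size} values do not "
            f"fill {n_channels} channels")
    data = raw.reshape(-1, n_channels).T.astype(float)

    channel_kinds = channel_kinds or {}
    channels = []
    for name in names:
        kind = channel_kinds.get(name, EOG if name == EOG_CHANNEL else EEG)
        channels.append((name, kind))
    eeg_names = [n for n, k in channels if k == EEG]
    montage = unit_positions(eeg_names)
    return Recording(subject_id=subject_id or vhdr.stem, role=role, fs=fs,
                     channels=channels, data=data, montage=montage)
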