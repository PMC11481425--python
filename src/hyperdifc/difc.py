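"""Static and dynamic interpersonal functional connectivity (sliding-window Pearson).

dIFC treats each (male electrode, female electrode) pair as an inter-brain
"connection" and tracks its Pearson correlation through a moving window; the
window axis is the timepoint axis (labelled tp1..tpN, 1-based in labels,
0-based internally).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .recording import PairedBlock

__all__ = [
    "WindowSpec",
    "DIFCTensor",
    "pearson_r",
    "sliding_windows",
    "compute_difc",
    "static_ifc",
    "split_halves",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``length`` samples advanced by ``step``."""

    length: int = 120
    step: int = 80

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("window length must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.length:
            raise ValueError(
                f"n_samples={n_samples} shorter than window length {self.length}")
        return (n_samples - self.length) // self.step + 1


@dataclass
class DIFCTensor:
    """male-channel x female-channel x window array of Pearson r.

    ``tp_offset`` keeps 1-based timepoint labels meaningful after a half
    split: window ``w`` of this tensor is timepoint ``tp_offset + w + 1``.
    """

    pair_id: str
    relationship: int
    hand: str
    male_channels: list[str]
    female_channels: list[str]
    values: np.ndarray
    window: WindowSpec
    tp_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(self.male_channels),
                                     len(self.female_channels)):
            raise ValueError("values shape inconsistent with channel lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    @property
    def tp_labels(self) -> list[str]:
        return [f"tp{self.tp_offset + w + 1}" for w in range(self.n_windows)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per (ch_male, ch_female, tp)."""
        mi, fi, wi = np.meshgrid(np.arange(len(self.male_channels)),
                                 np.arange(len(self.female_channels)),
                                 np.arange(self.n_windows), indexing="ij")
        return pd.DataFrame({
            "pair": self.pair_id,
            "relationship": self.relationship,
            "hand": self.hand,
            "ch_male": np.asarray(self.male_channels)[mi.ravel()],
            "ch_female": np.asarray(self.female_channels)[fi.ravel()],
            "tp": self.tp_offset + wi.ravel() + 1,
            "r": self.values.ravel(),
        })


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN for a constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    nx = np.sqrt((dx * dx).sum())
    ny = np.sqrt((dy * dy).sum())
    if nx == 0 or ny == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / (nx * ny), -1.0, 1.0))


def sliding_windows(n_samples: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open 0-based ``[start, start+length)`` ranges; a trailing partial
    window is discarded."""
    n_win = spec.n_windows(n_samples)
    return [(w * spec.step, w * spec.step + spec.length) for w in range(n_win)]


def _window_corr(M: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Pearson r between every row of M and every row of F (one window)."""
    M = M - M.mean(axis=1, keepdims=True)
    F = F - F.mean(axis=1, keepdims=True)
    nm = np.linalg.norm(M, axis=1)
    nf = np.linalg.norm(F, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (M @ F.T) / np.outer(nm, nf)
    R[~np.isfinite(R)] = np.nan
    return np.clip(R, -1.0, 1.0, out=R)


def compute_difc(block: PairedBlock,
                 spec: WindowSpec | None = None) -> DIFCTensor:
    """Sliding-window inter-brain Pearson correlation for one block.

    Analysis channels only (EOG and mastoids excluded).  Windows with a
    degenerate (constant) channel yield NaN for that channel's pairs.
    """
    spec = spec or WindowSpec()
    m_names = block.male.analysis_names
    f_names = block.female.analysis_names
    M = block.male.data[[block.male.index(n) for n in m_names]]
    F = block.female.data[[block.female.index(n) for n in f_names]]
    wins = sliding_windows(block.n_samples, spec)
    values = np.empty((len(m_names), len(f_names), len(wins)))
    for w, (a, b) in enumerate(wins):
        values[:, :, w] = _window_corr(M[:, a:b], F[:, a:b])
    return DIFCTensor(pair_id=block.pair_id, relationship=block.relationship,
                      hand=block.hand, male_channels=m_names,
                      female_channels=f_names, values=values, window=spec)


def static_ifc(block: PairedBlock) -> np.ndarray:
    """Whole-series inter-brain correlation matrix (single snapshot)."""
    spec = WindowSpec(length=block.n_samples, step=1)
    return compute_difc(block, spec).values[:, :, 0]


def tensors_from_dataframe(df: pd.DataFrame,
                           spec: WindowSpec | None = None) -> list[DIFCTensor]:
    """Rebuild per-block tensors from the long-format CSV export.

    The CSV does not carry the window geometry; pass the ``spec`` the
    tensors were computed with (defaults to the standard one).
    """
    spec = spec or WindowSpec()
    out = []
    for (pair, hand), sub in df.groupby(["pair", "hand"], sort=True):
        m_names = list(pd.unique(sub["ch_male"]))
        f_names = list(pd.unique(sub["ch_female"]))
        tps = np.sort(pd.unique(sub["tp"]))
        cube = (sub.set_index(["ch_male", "ch_female", "tp"])["r"]
                .unstack(["ch_female", "tp"])  # rows ch_male
                .reindex(index=m_names))
        values = np.empty((len(m_names), len(f_names), len(tps)))
        for j, f in enumerate(f_names):
            values[:, j, :] = cube[f].reindex(columns=tps).to_numpy()
        out.append(DIFCTensor(
            pair_id=str(pair), relationship=int(sub["relationship"].iloc[0]),
            hand=str(hand), male_channels=m_names, female_channels=f_names,
            values=values, window=spec, tp_offset=int(tps[0]) - 1))
    return out


def split_halves(tensor: DIFCTensor) -> tuple[DIFCTensor, DIFCTensor]:
    """First ``ceil(n/2)`` and remaining windows, timepoint labels preserved."""
    n = tensor.n_windows
    if n < 2:
        raise ValueError("cannot split a single-window tensor")
    k = (n + 1) // 2
    first = replace(tensor, values=tensor.values[:, :, :k])
    second = replace(tensor, values=tensor.values[:, :, k:],
                     tp_offset=tensor.tp_offset + k)
    return first, second
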