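"""Preprocessing chain from raw paired recordings to normalized, decimated signals.

Stage order (fixed): bad-channel detection and spherical interpolation ->
average-mastoid re-reference -> notch + band-pass filtering -> ICA-based
ocular/muscular artifact removal -> per-channel normalization -> moving-average
decimation -> baseline removal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .montage import MASTOIDS, great_circle_distance
from .recording import EEG, PairedBlock, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "detect_bad_channels",
    "slerp_interpolate",
    "interpolate_bad_channels",
    "rereference_mastoids",
    "notch_and_bandpass",
    "remove_ocular_muscular",
    "normalize_minmax",
    "normalize_zscore",
    "moving_average_decimate",
    "remove_baseline",
    "preprocess_block",
]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    ``normalization`` follows the min–max convention by default (signals end
    up in [0, 1]); ``"zscore"`` switches to true zero-mean/unit-variance
    scaling.
    """

    bad_channel_r: float = 0.95
    notch_freqs: tuple[float, ...] = (50.0, 150.0, 250.0)
    notch_halfwidth: float = 2.0
    band: tuple[float, float] = (1.0, 40.0)
    filter_order: int = 4
    run_ica: bool = True
    eog_corr_threshold: float = 0.7
    highband_cut: float = 20.0
    highband_frac_threshold: float = 0.7
    ica_max_samples: int = 20000
    ica_seed: int = 0
    normalization: str = "minmax"  # or "zscore"
    decimate_factor: int = 100
    decimate_mode: str = "decimate"  # or "smooth"
    baseline_ms: float = 500.0


# ---------------------------------------------------------------------------
# bad channels and spherical interpolation
# ---------------------------------------------------------------------------

def detect_bad_channels(rec: Recording, r_threshold: float = 0.95) -> list[str]:
    """Channels bridged/duplicated with a neighbour (|r| > ``r_threshold``).

    Within each over-correlated pair the member with the lower variance is
    flagged (ties break toward the later channel in montage order); constant
    channels, whose correlation is undefined, are flagged unconditionally.
    """
    names = rec.eeg_names
    if len(names) < 2:
        raise ValueError("need at least two EEG channels")
    idx = [rec.index(n) for n in names]
    X = rec.data[idx]
    var = X.var(axis=1)
    bad: set[str] = {names[i] for i in np.flatnonzero(var == 0)}

    live = [i for i in range(len(names)) if var[i] > 0]
    if len(live) >= 2:
        R = np.corrcoef(X[live])
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                if abs(R[a, b]) > r_threshold:
                    i, j = live[a], live[b]
                    if var[i] < var[j]:
                        bad.add(names[i])
                    elif var[j] < var[i]:
                        bad.add(names[j])
                    else:  # tie -> later channel in montage order
                        bad.add(names[j])
    return [n for n in names if n in bad]


def slerp_interpolate(montage: dict[str, np.ndarray], bad: str,
                      donors: tuple[str, str],
                      signals: dict[str, np.ndarray]) -> np.ndarray:
    """Reconstruct ``bad`` from two donors by spherical linear interpolation.

    The donors' unit-sphere positions span a great-circle arc; the bad
    electrode's normalized angular position along that arc (by projection
    onto the donors' plane) gives the interpolation parameter ``t``, and the
    output is ``sin((1-t)Ω)/sin(Ω) * s0 + sin(tΩ)/sin(Ω) * s1``.  For nearly
    coincident donors (``sin Ω < 1e-6``) the formula degenerates and the
    linear limit ``(1-t)s0 + t*s1`` is used instead.
    """
    d0, d1 = donors
    p0, p1 = montage[d0], montage[d1]
    pb = montage[bad]
    omega = great_circle_distance(p0, p1)
    if np.dot(p0, p1) < -1 + 1e-12:
        raise ValueError("antiparallel donor positions: great circle undefined")

    # normalized angular position of the bad electrode along the p0 -> p1 arc
    e1 = p0
    e2 = p1 - np.dot(p0, p1) * p0
    n2 = np.linalg.norm(e2)
    if n2 < 1e-12:
        t = 0.5
    else:
        e2 = e2 / n2
        theta = np.arctan2(np.dot(pb, e2), np.dot(pb, e1))
        t = float(np.clip(theta / omega, 0.0, 1.0)) if omega > 0 else 0.5

    s0, s1 = signals[d0], signals[d1]
    if np.sin(omega) < 1e-6:
        w0, w1 = 1.0 - t, t  # Ω -> 0 limit of the spherical weights
    else:
        w0 = np.sin((1.0 - t) * omega) / np.sin(omega)
        w1 = np.sin(t * omega) / np.sin(omega)
    return w0 * s0 + w1 * s1


def interpolate_bad_channels(rec: Recording, bad: list[str]) -> Recording:
    """Replace each bad channel by its slerp reconstruction from the two
    nearest good EEG electrodes (great-circle distance)."""
    out = rec.copy()
    good = [n for n in rec.eeg_names if n not in bad]
    if not bad:
        return out
    if len(good) < 2:
        raise ValueError("fewer than two good channels: recording unrecoverable")
    signals = {n: rec.get(n) for n in good}
    for ch in bad:
        dists = sorted(good,
                       key=lambda g: great_circle_distance(rec.montage[ch],
                                                           rec.montage[g]))
        donors = (dists[0], dists[1])
        out.data[out.index(ch)] = slerp_interpolate(rec.montage, ch, donors,
                                                    signals)
    return out


# ---------------------------------------------------------------------------
# reference and filtering
# ---------------------------------------------------------------------------

def rereference_mastoids(rec: Recording) -> Recording:
    """Re-reference every EEG channel to the average of TP9 and TP10.

    The reference is snapshot before subtraction, so the mastoids themselves
    are updated consistently; they stay in the recording but are excluded
    from the analysis channel set.
    """
    for m in MASTOIDS:
        if m not in rec.channel_names:
            raise ValueError(f"mastoid {m} missing: cannot re-reference")
    out = rec.copy()
    ref = (rec.get(MASTOIDS[0]) + rec.get(MASTOIDS[1])) / 2.0
    for name, kind in rec.channels:
        if kind == EEG:
            out.data[out.index(name)] = rec.get(name) - ref
    return out


def notch_and_bandpass(rec: Recording,
                       config: PreprocessConfig | None = None) -> Recording:
    """Zero-phase notch filtering (power-line harmonics) then 1–40 Hz band-pass.

    Notches above the Nyquist frequency are skipped with a logged warning.
    """
    config = config or PreprocessConfig()
    nyq = rec.fs / 2.0
    lo, hi = config.band
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz not below Nyquist {nyq} Hz")
    out = rec.copy()
    X = out.data

    for f0 in config.notch_freqs:
        hw = config.notch_halfwidth
        if f0 + hw >= nyq:
            logger.warning("skipping %.0f Hz notch: at or above Nyquist (%.0f Hz)",
                           f0, nyq)
            continue
        sos = sps.butter(config.filter_order, [f0 - hw, f0 + hw],
                         btype="bandstop", fs=rec.fs, output="sos")
        X = sps.sosfiltfilt(sos, X, axis=1)

    sos = sps.butter(config.filter_order, [lo, hi], btype="bandpass",
                     fs=rec.fs, output="sos")
    X = sps.sosfiltfilt(sos, X, axis=1)
    out.data = np.ascontiguousarray(X)
    return out


# ---------------------------------------------------------------------------
# ICA ocular / muscular artifact removal
# ---------------------------------------------------------------------------

def _highband_fraction(comp: np.ndarray, fs: float, cut: float) -> float:
    freqs, psd = sps.welch(comp, fs=fs, nperseg=min(len(comp), 2048))
    total = psd.sum()
    if total == 0:
        return 0.0
    return float(psd[freqs > cut].sum() / total)


def remove_ocular_muscular(rec: Recording,
                           config: PreprocessConfig | None = None) -> Recording:
    """Zero ICA components that track the EOG or are dominated by >20 Hz power.

    The decomposition runs on the EEG channels only; the EOG channel is used
    purely as the artifact template and is never modified.  On decomposition
    failure the recording passes through unchanged with a logged warning.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    config = config or PreprocessConfig()
    eog_name = rec.eog_name
    if eog_name is None:
        raise ValueError("EOG channel required for ocular artifact removal")
    out = rec.copy()
    idx = [rec.index(n) for n in rec.eeg_names]
    X = rec.data[idx].T  # samples x channels
    eog = rec.get(eog_name)

    step = max(1, X.shape[0] // config.ica_max_samples)
    try:
        with warnings.catch_warnings():
            # non-convergence still yields a usable approximate unmixing
            warnings.simplefilter("ignore", ConvergenceWarning)
            ica = FastICA(whiten="unit-variance", max_iter=1000, tol=1e-3,
                          random_state=config.ica_seed)
            ica.fit(X[::step])
        S = (X - ica.mean_) @ ica.components_.T
    except Exception as exc:  # decomposition failure -> pass-through
        logger.warning("ICA failed (%s); recording passed through unchanged", exc)
        return out

    n_comp = S.shape[1]
    drop = np.zeros(n_comp, dtype=bool)
    for k in range(n_comp):
        comp = S[:, k]
        if comp.std() == 0 or eog.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(comp, eog)[0, 1])
        if abs(r) > config.eog_corr_threshold:
            drop[k] = True
        elif _highband_fraction(comp, rec.fs, config.highband_cut) \
                > config.highband_frac_threshold:
            drop[k] = True

    if drop.any():
        S[:, drop] = 0.0
        X_clean = S @ ica.mixing_.T + ica.mean_
        out.data[idx] = X_clean.T
    return out


# ---------------------------------------------------------------------------
# normalization, decimation, baseline
# ---------------------------------------------------------------------------

def normalize_minmax(x: np.ndarray) -> np.ndarray:
    """Min–max scaling ``(x - min) / (max - min)`` onto [0, 1]."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant signal: min-max normalization undefined")
    return (x - lo) / (hi - lo)


def normalize_zscore(x: np.ndarray) -> np.ndarray:
    """True zero-mean unit-variance scaling (config alternative)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant signal: z-scoring undefined")
    return (x - x.mean()) / sd


def moving_average_decimate(x: np.ndarray, factor: int,
                            mode: str = "decimate") -> np.ndarray:
    """Moving-average smoothing/decimation.

    ``"decimate"`` returns non-overlapping block means (length ``n // factor``,
    any tail truncated); ``"smooth"`` returns a centred running mean of the
    same length as the input.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > n:
        raise ValueError(f"factor {factor} exceeds signal length {n}")
    if mode == "decimate":
        m = n // factor
        trimmed = x[..., : m * factor]
        return trimmed.reshape(*x.shape[:-1], m, factor).mean(axis=-1)
    if mode == "smooth":
        kernel = np.ones(factor) / factor
        if x.ndim == 1:
            return np.convolve(x, kernel, mode="same")
        return np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="same"), -1, x)
    raise ValueError(f"unknown mode {mode!r}")


def remove_baseline(x: np.ndarray, fs: float,
                    baseline_ms: float = 500.0) -> np.ndarray:
    """Subtract the mean of the first ``baseline_ms`` of the signal."""
    x = np.asarray(x, dtype=float)
    nb = int(round(fs * baseline_ms / 1000.0))
    if nb < 1:
        raise ValueError("baseline window shorter than one sample")
    if nb >= x.shape[-1]:
        raise ValueError("signal not longer than the baseline window")
    return x - x[..., :nb].mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _preprocess_recording(rec: Recording, config: PreprocessConfig,
                          info: dict) -> Recording:
    bad = detect_bad_channels(rec, config.bad_channel_r)
    info["bad_channels"] = bad
    rec = interpolate_bad_channels(rec, bad)
    rec = rereference_mastoids(rec)
    rec = notch_and_bandpass(rec, config)
    if config.run_ica:
        rec = remove_ocular_muscular(rec, config)

    norm = normalize_minmax if config.normalization == "minmax" else normalize_zscore
    for name, kind in rec.channels:
        if kind == EEG:
            rec.data[rec.index(name)] = norm(rec.get(name))

    rec.data = moving_average_decimate(rec.data, config.decimate_factor,
                                       config.decimate_mode)
    if config.decimate_mode == "decimate":
        rec.fs = rec.fs / config.decimate_factor
    rec.data = remove_baseline(rec.data, rec.fs, config.baseline_ms)
    return rec


def preprocess_block(block: PairedBlock,
                     config: PreprocessConfig | None = None,
                     info: dict | None = None) -> PairedBlock:
    """Run the full fixed-order preprocessing chain on both recordings.

    ``info``, if given, is filled with per-recording provenance (flagged
    channels, stage parameters).
    """
    config = config or PreprocessConfig()
    info = info if info is not None else {}
    info["stages"] = ["interpolate_bad", "rereference_mastoids",
                      "notch_and_bandpass",
                      "remove_ocular_muscular" if config.run_ica else "(ica skipped)",
                      f"normalize_{config.normalization}",
                      f"moving_average_{config.decimate_mode}",
                      "remove_baseline"]
    out = block.copy()
    for role in ("male", "female"):
        rinfo: dict = {}
        setattr(out, role, _preprocess_recording(getattr(out, role), config,
                                                 rinfo))
        info[role] = rinfo
    return out
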