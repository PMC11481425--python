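"""Group-level statistics: ROI t-tests, timepoint-wise mixed ANOVA with FDR,
trend interpolation, questionnaire scoring/reliability and a-priori power.

The mixed ANOVA (between factor: relationship; within factor: hand) is
computed from an explicit sums-of-squares decomposition so the decomposition
itself is unit-testable; for a two-level within factor its interaction F is
algebraically the squared pooled two-sample t on per-dyad difference scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from . import scales
from .difc import DIFCTensor
from .recording import PairedBlock, Recording

__all__ = [
    "ROIResult",
    "AnovaMap",
    "voltage_magnitude",
    "magnitude_table",
    "roi_ttest",
    "mixed_anova_interaction",
    "anova_map",
    "fdr_bh",
    "cubic_trend",
    "score_scale",
    "score_table",
    "reliability",
    "interaction_power",
    "required_sample_size",
]


# ---------------------------------------------------------------------------
# voltage magnitude and ROI selection
# ---------------------------------------------------------------------------

def voltage_magnitude(rec: Recording) -> pd.Series:
    """Mean absolute amplitude per analysis channel of one preprocessed block."""
    names = rec.analysis_names
    idx = [rec.index(n) for n in names]
    return pd.Series(np.abs(rec.data[idx]).mean(axis=1), index=names)


def magnitude_table(blocks: list[PairedBlock]) -> tuple[pd.DataFrame, pd.Series]:
    """Subject x channel magnitude matrix, hand conditions averaged.

    Each subject (two per dyad) contributes the mean of their hand-off and
    hand-on per-channel magnitudes; the returned labels give each subject's
    relationship group (0/1).
    """
    acc: dict[str, list[pd.Series]] = {}
    labels: dict[str, int] = {}
    for block in blocks:
        for role in ("male", "female"):
            rec = getattr(block, role)
            acc.setdefault(rec.subject_id, []).append(voltage_magnitude(rec))
            labels[rec.subject_id] = block.relationship
    rows = {sid: pd.concat(v, axis=1).mean(axis=1) for sid, v in acc.items()}
    table = pd.DataFrame(rows).T.sort_index()
    return table, pd.Series(labels).loc[table.index]


@dataclass
class ROIResult:
    channel: str
    t: float
    p: float
    q: float
    significant: bool


def roi_ttest(magnitudes: pd.DataFrame, labels: pd.Series,
              alpha: float = 0.05, welch: bool = False) -> list[ROIResult]:
    """Per-channel two-sample t on subject magnitudes, BH-FDR across channels.

    Student's pooled-variance t by default (``welch=True`` switches).  The
    significant channels are the data-driven region of interest.
    """
    labels = labels.loc[magnitudes.index]
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = magnitudes[labels == groups[0]]
    b = magnitudes[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    ts, ps = [], []
    for ch in magnitudes.columns:
        with np.errstate(invalid="ignore"):
            t, p = stats.ttest_ind(a[ch], b[ch], equal_var=not welch)
        if not np.isfinite(t):
            warnings.warn(f"degenerate variance in channel {ch}")
            t, p = np.nan, np.nan
        ts.append(float(t))
        ps.append(float(p))
    q, rej = fdr_bh(np.asarray(ps), alpha)
    return [ROIResult(ch, ts[k], ps[k], float(q[k]), bool(rej[k]))
            for k, ch in enumerate(magnitudes.columns)]


# ---------------------------------------------------------------------------
# mixed ANOVA from explicit sums of squares
# ---------------------------------------------------------------------------

def _interaction_ss(y: np.ndarray, groups: np.ndarray):
    """Sums of squares for the between x within interaction.

    ``y`` has shape ``(n_subjects, n_levels, *extra)``; the decomposition
    broadcasts over any trailing axes.  Returns (SS_interaction, SS_error,
    df1, df2) with the error term being the within-subject (level x subject
    within group) residual.
    """
    n, m = y.shape[0], y.shape[1]
    levels = np.unique(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("between factor needs at least two levels")
    if m < 2:
        raise ValueError("within factor needs at least two levels")

    S = y.mean(axis=1)                      # subject means, (n, *extra)
    C = y.mean(axis=0)                      # condition means (weighted), (m, *extra)
    GM = y.mean(axis=(0, 1))                # grand mean, (*extra)

    ss_int = np.zeros(y.shape[2:])
    ss_err = np.zeros(y.shape[2:])
    for gi in levels:
        sel = groups == gi
        n_i = int(sel.sum())
        if n_i < 2:
            raise ValueError("need >= 2 subjects per group")
        M = y[sel].mean(axis=0)             # cell means, (m, *extra)
        A = M.mean(axis=0)                  # group mean, (*extra)
        dev = M - A[None] - C + GM[None]
        ss_int = ss_int + n_i * (dev ** 2).sum(axis=0)
        resid = y[sel] - S[sel][:, None] - (M - A[None])[None]
        ss_err = ss_err + (resid ** 2).sum(axis=(0, 1))

    df1 = (g - 1) * (m - 1)
    df2 = (n - g) * (m - 1)
    return ss_int, ss_err, df1, df2


def mixed_anova_interaction(values: np.ndarray, groups) -> tuple[float, float, float]:
    """Interaction test of the 2 (between) x 2 (within) mixed design.

    Parameters
    ----------
    values : array, shape (n_pairs, n_conditions)
        One row per dyad, columns ordered by hand condition.
    groups : array-like, length n_pairs
        Relationship labels (two levels).

    Returns
    -------
    (F, p, partial eta squared); df = ((g-1)(m-1), (n-g)(m-1)).
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2:
        raise ValueError("values must be (n_pairs, n_conditions)")
    if len(groups) != y.shape[0]:
        raise ValueError("labels length mismatch")
    nan_rows = np.isnan(y).any(axis=1)
    if nan_rows.any():
        warnings.warn(f"excluding {int(nan_rows.sum())} pair(s) with a missing "
                      "condition")
        y, groups = y[~nan_rows], groups[~nan_rows]
    ss_int, ss_err, df1, df2 = _interaction_ss(y, groups)
    if df2 < 1:
        raise ValueError("not enough pairs for the error term")
    F = float((ss_int / df1) / (ss_err / df2)) if ss_err > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2))
    eta = float(ss_int / (ss_int + ss_err)) if (ss_int + ss_err) > 0 else 0.0
    return F, p, eta


@dataclass
class AnovaMap:
    """Timepoint-wise interaction maps over all inter-brain channel pairs."""

    male_channels: list[str]
    female_channels: list[str]
    tp_labels: list[str]
    F: np.ndarray        # (n_male, n_female, n_tp)
    p: np.ndarray
    eta: np.ndarray
    q: np.ndarray
    reject: np.ndarray
    df: tuple[int, int]
    alpha: float
    n_pairs: int

    @property
    def sig_count(self) -> np.ndarray:
        """Per channel-pair count of significant timepoints (heatmap value)."""
        return self.reject.sum(axis=2)

    def to_dataframe(self) -> pd.DataFrame:
        mi, fi, wi = np.meshgrid(np.arange(len(self.male_channels)),
                                 np.arange(len(self.female_channels)),
                                 np.arange(len(self.tp_labels)), indexing="ij")
        return pd.DataFrame({
            "ch_male": np.asarray(self.male_channels)[mi.ravel()],
            "ch_female": np.asarray(self.female_channels)[fi.ravel()],
            "tp": np.asarray(self.tp_labels)[wi.ravel()],
            "F": self.F.ravel(),
            "p": self.p.ravel(),
            "eta_p2": self.eta.ravel(),
            "q": self.q.ravel(),
            "significant": self.reject.ravel(),
        })


def _stack_design(tensors: list[DIFCTensor]):
    """Group per-pair hand-off/on tensors into (y, groups) ANOVA input.

    Returns y with shape (n_pairs, 2, n_male, n_female, n_tp), hand order
    (off, on), plus labels and axis metadata taken from the first tensor.
    """
    by_pair: dict[str, dict[str, DIFCTensor]] = {}
    for t in tensors:
        by_pair.setdefault(t.pair_id, {})[t.hand] = t
    ref = tensors[0]
    ys, groups = [], []
    for pid, hands in sorted(by_pair.items()):
        if set(hands) != {"off", "on"}:
            warnings.warn(f"pair {pid} missing a hand condition; excluded")
            continue
        ys.append(np.stack([hands["off"].values, hands["on"].values]))
        groups.append(hands["off"].relationship)
    y = np.stack(ys)  # (n_pairs, 2, nI, nJ, nT)
    return y, np.asarray(groups), ref


def anova_map(tensors: list[DIFCTensor], alpha: float = 0.05,
              family: str = "global") -> AnovaMap:
    """Mixed-ANOVA interaction at every (channel pair, timepoint), with BH-FDR.

    ``family`` controls the FDR correction family: ``"global"`` pools all
    channel pairs and timepoints into one family (default); ``"per_pair"``
    corrects across timepoints separately for each channel pair.
    """
    y, groups, ref = _stack_design(tensors)
    for gi, cnt in zip(*np.unique(groups, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"group {gi} has fewer than 2 pairs")

    if np.isnan(y).any():
        # NaN cells: recompute those cells with pairwise exclusion
        shape = y.shape[2:]
        F = np.full(shape, np.nan)
        p = np.full(shape, np.nan)
        eta = np.full(shape, np.nan)
        for idx in np.ndindex(shape):
            cell = y[(slice(None), slice(None)) + idx]
            ok = ~np.isnan(cell).any(axis=1)
            if ok.sum() >= 4 and len(np.unique(groups[ok])) == 2:
                F[idx], p[idx], eta[idx] = mixed_anova_interaction(
                    cell[ok], groups[ok])
        df = (1, y.shape[0] - 2)
    else:
        ss_int, ss_err, df1, df2 = _interaction_ss(y, groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_int / df1) / (ss_err / df2)
            eta = np.where(ss_int + ss_err > 0, ss_int / (ss_int + ss_err), 0.0)
        p = stats.f.sf(F, df1, df2)
        df = (df1, df2)

    q = np.full_like(p, np.nan)
    reject = np.zeros_like(p, dtype=bool)
    if family == "global":
        finite = np.isfinite(p)
        if finite.any():
            qv, rej = fdr_bh(p[finite], alpha)
            q[finite], reject[finite] = qv, rej
    elif family == "per_pair":
        for i in range(p.shape[0]):
            for j in range(p.shape[1]):
                finite = np.isfinite(p[i, j])
                if finite.any():
                    qv, rej = fdr_bh(p[i, j][finite], alpha)
                    q[i, j][finite], reject[i, j][finite] = qv, rej
    else:
        raise ValueError(f"unknown FDR family {family!r}")

    return AnovaMap(male_channels=ref.male_channels,
                    female_channels=ref.female_channels,
                    tp_labels=ref.tp_labels, F=F, p=p, eta=eta, q=q,
                    reject=reject, df=df, alpha=alpha, n_pairs=y.shape[0])


# ---------------------------------------------------------------------------
# FDR and trend interpolation
# ---------------------------------------------------------------------------

def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted q-values and rejection flags."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(p)
    q[order] = q_sorted
    return q.reshape(p.shape), (q <= alpha).reshape(p.shape)


def cubic_trend(timepoints: np.ndarray, values: np.ndarray) -> CubicSpline:
    """Piecewise-cubic interpolant through all (timepoint, value) knots.

    Knot-exact by construction; used to draw the dense dIFC trend lines.
    Requires >= 4 strictly increasing timepoints.
    """
    t = np.asarray(timepoints, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points for a cubic trend")
    if (np.diff(t) <= 0).any():
        raise ValueError("timepoints must be strictly increasing (no duplicates)")
    return CubicSpline(t, v)


# ---------------------------------------------------------------------------
# questionnaire scoring and reliability
# ---------------------------------------------------------------------------

def score_scale(items, instrument: str = "SDS") -> int:
    """Zung scale total: forward items as-is plus ``5 - item`` for
    reverse-keyed items."""
    items = np.asarray(items, dtype=int)
    if items.shape != (scales.N_ITEMS,):
        raise ValueError(f"expected {scales.N_ITEMS} items")
    if ((items < 1) | (items > 4)).any():
        raise ValueError("item responses must lie in 1..4")
    reversed_items = scales.REVERSED[instrument]
    total = 0
    for i, v in enumerate(items, start=1):
        total += (5 - v) if i in reversed_items else v
    return int(total)


def score_table(df: pd.DataFrame, instrument: str = "SDS") -> pd.Series:
    """Scored totals for an item-level response table (columns item_1..item_20)."""
    return df[scales.ITEM_COLUMNS].apply(
        lambda row: score_scale(row.to_numpy(), instrument), axis=1)


def recode_reversed(df: pd.DataFrame, instrument: str = "SDS") -> pd.DataFrame:
    """Flip reverse-keyed items (``5 - item``) so all items point the same
    way; reliability coefficients are conventionally computed on this form."""
    out = df.copy()
    for i in scales.REVERSED[instrument]:
        col = f"item_{i}"
        out[col] = 5 - out[col]
    return out


def reliability(items: np.ndarray) -> tuple[float, float]:
    """Internal consistency: Cronbach's alpha and McDonald's omega.

    Omega comes from a single-factor decomposition (sklearn FactorAnalysis):
    ``omega = (sum lambda)^2 / ((sum lambda)^2 + sum psi)``.
    """
    from sklearn.decomposition import FactorAnalysis

    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 respondents and >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    alpha = k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var)

    fa = FactorAnalysis(n_components=1, random_state=0)
    fa.fit(X)
    lam = fa.components_[0]
    if lam.sum() < 0:  # overall sign is indeterminate
        lam = -lam
    num = lam.sum() ** 2
    omega = num / (num + fa.noise_variance_.sum())
    return float(alpha), float(omega)


# ---------------------------------------------------------------------------
# a-priori power for the within-between interaction
# ---------------------------------------------------------------------------

def interaction_power(n_total: int, f: float, alpha: float = 0.05,
                      n_groups: int = 2, n_measures: int = 2,
                      corr: float = 0.5, epsilon: float = 1.0) -> float:
    """Noncentral-F power of the repeated-measures within-between interaction.

    Follows the G*Power convention for Cohen's f in repeated-measures
    designs: ``lambda = f^2 * N * m * epsilon / (1 - corr)`` with
    ``df1 = (g-1)(m-1)epsilon`` and ``df2 = (N-g)(m-1)epsilon``, where
    ``corr`` is the assumed correlation among repeated measures and
    ``epsilon`` the nonsphericity correction.
    """
    df1 = (n_groups - 1) * (n_measures - 1) * epsilon
    df2 = (n_total - n_groups) * (n_measures - 1) * epsilon
    if df2 < 1:
        return 0.0
    lam = f ** 2 * n_total * n_measures * epsilon / (1.0 - corr)
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(f: float, alpha: float = 0.05, power: float = 0.95,
                         n_groups: int = 2, n_measures: int = 2,
                         corr: float = 0.5, epsilon: float = 1.0,
                         even: bool = True, max_n: int = 1_000_000) -> int:
    """Smallest total N whose interaction power reaches the target.

    ``even=True`` (default) searches even totals only, i.e. equal-sized
    groups for the two-group design.
    """
    if not (f > 0 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("require f > 0 and alpha, power in (0, 1)")
    n = n_groups * 2
    if even and n % 2:
        n += 1
    step = 2 if even else 1
    while n <= max_n:
        if interaction_power(n, f, alpha, n_groups, n_measures, corr,
                             epsilon) >= power:
            return n
        n += step
    raise ValueError(f"target power unattainable below N={max_n}")
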