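"""Synthetic paired-EEG sessions with controllable inter-brain coupling.

The generator emulates the hyperscanning study design this package analyzes:
two groups of dyads (romantic lovers, opposite-sex strangers), each recorded
for one hand-off and one hand-on resting block with dual 31-EEG + 1-EOG caps
at 1000 Hz.  Every EEG channel of the female subject is a mixture of private
pink noise and the homologous male channel, weighted so that the expected
within-window inter-brain Pearson correlation equals the instantaneous
coupling coefficient c(t):

    female_i(t) = sqrt(1 - c(t)^2) * private_i(t) + c(t) * male_i(t)

(all components standardized to unit variance before mixing).  The coupling
follows a two-stage temporal profile: during the first half of a hand-on
block it fluctuates around the baseline (adaptation), during the second half
it settles at a group-specific level — raised for lovers, lowered for
strangers — while hand-off blocks keep the baseline coupling throughout.

Ocular artifacts (half-cosine blinks on the EOG with distance-decaying bleed
into frontal channels) and occasional near-duplicate "bridged" channels are
injected so the preprocessing stages have something real to do.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scales
from .montage import CHANNELS_31, EOG_CHANNEL, MASTOIDS, unit_positions
from .recording import EEG, EOG, LOVER, RELATIONSHIP_CODE, PairedBlock, Recording

__all__ = [
    "SynthConfig",
    "CouplingProfile",
    "coupling_at",
    "generate_pair_session",
    "generate_cohort",
    "generate_scale_responses",
    "pink_noise",
]


@dataclass
class CouplingProfile:
    """Two-stage coupling profile of a hand-on block.

    ``stage1`` (before ``stage_boundary`` x block length) draws a fresh
    coupling value around ``stage1_mean`` for every coupling segment —
    the "adaptation" fluctuation; ``stage2`` is deterministic.
    """

    stage_boundary: float = 0.5
    stage1_mean: float = 0.2
    stage1_sd: float = 0.1
    stage2_mean: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.stage_boundary < 1.0:
            raise ValueError("stage_boundary must lie strictly inside (0, 1)")
        for name in ("stage1_mean", "stage2_mean"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.stage1_sd < 0:
            raise ValueError("stage1_sd must be non-negative")


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Coupling magnitudes are free parameters of the generator (the study they
    emulate does not quantify them); the defaults give a moderate resting
    baseline with a clearly raised lover / suppressed stranger second stage.
    """

    n_lover_pairs: int = 18
    n_stranger_pairs: int = 21
    fs: float = 1000.0
    block_s: float = 240.0
    n_eeg: int = 31
    coupling_baseline: float = 0.2
    coupling_lover_on_stage2: float = 0.5
    coupling_lover_on_stage1_sd: float = 0.1
    coupling_stranger_on_stage2: float = 0.05
    artifact_rate: float = 12.0  # blink events per minute
    bad_channel_prob: float = 0.05  # per recording
    amplitude_uv: float = 10.0  # EEG pink-noise RMS, microvolts
    coupling_segment_s: float = 2.0  # stage-1 fluctuation timescale
    stage_boundary: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coupling_baseline", "coupling_lover_on_stage2",
                     "coupling_stranger_on_stage2"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        n = self.fs * self.block_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * block_s must be an integer sample count")
        if self.n_eeg < 4:
            raise ValueError("need >= 4 EEG channels (2 analysis + 2 mastoids)")
        if self.n_eeg > len(CHANNELS_31):
            raise ValueError(f"n_eeg capped at {len(CHANNELS_31)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.block_s))

    def channel_names(self) -> list[str]:
        """First ``n_eeg`` cap channels, always keeping both mastoids."""
        names = list(CHANNELS_31[: self.n_eeg])
        # guarantee both mastoids by overwriting tail channels if needed
        missing = [m for m in MASTOIDS if m not in names]
        tail = len(names) - 1
        for m in missing:
            while names[tail] in MASTOIDS:
                tail -= 1
            names[tail] = m
            tail -= 1
        return names

    def profile_for(self, relationship: int, hand: str) -> CouplingProfile:
        if hand == "off":
            return CouplingProfile(
                stage_boundary=self.stage_boundary,
                stage1_mean=self.coupling_baseline,
                stage1_sd=0.0,
                stage2_mean=self.coupling_baseline,
            )
        stage2 = (self.coupling_lover_on_stage2 if relationship == LOVER
                  else self.coupling_stranger_on_stage2)
        return CouplingProfile(
            stage_boundary=self.stage_boundary,
            stage1_mean=self.coupling_baseline,
            stage1_sd=self.coupling_lover_on_stage1_sd,
            stage2_mean=stage2,
        )


def coupling_at(t: float, profile: CouplingProfile, block_s: float,
                rng: np.random.Generator) -> float:
    """Instantaneous coupling coefficient at time ``t`` of a block.

    Stage 1 (``t`` in ``[0, boundary*block_s)``) draws from
    ``N(stage1_mean, stage1_sd)`` clipped to ``[0, 1)``; stage 2 returns
    ``stage2_mean`` deterministically.
    """
    if not 0 <= t < block_s:
        raise ValueError(f"t={t} outside [0, {block_s})")
    if t < profile.stage_boundary * block_s:
        c = profile.stage1_mean
        if profile.stage1_sd > 0:
            c = rng.normal(profile.stage1_mean, profile.stage1_sd)
        return float(np.clip(c, 0.0, 1.0 - 1e-9))
    return float(profile.stage2_mean)


def pink_noise(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pair_seed_seq(seed: int, pair_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), zlib.crc32(str(pair_id).encode())])


def _coupling_series(config: SynthConfig, profile: CouplingProfile,
                     rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant c(t), one draw per coupling segment."""
    n = config.n_samples
    seg = max(1, int(round(config.coupling_segment_s * config.fs)))
    c = np.empty(n)
    for start in range(0, n, seg):
        t = start / config.fs
        c[start:start + seg] = coupling_at(t, profile, config.block_s, rng)
    return c


def _eog_position(montage: dict[str, np.ndarray]) -> np.ndarray:
    """Approximate EOG electrode location: between and slightly above Fp1/Fp2."""
    p = montage["Fp1"] + montage["Fp2"]
    return p / np.linalg.norm(p)


def _blink_train(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Half-cosine blink deflections, ~300 ms each, on a zero baseline (µV)."""
    n = config.n_samples
    out = np.zeros(n)
    n_events = rng.poisson(config.artifact_rate * config.block_s / 60.0)
    width = int(round(0.3 * config.fs))
    if width < 2:
        width = 2
    pulse = np.sin(np.linspace(0, np.pi, width))  # half cosine lobe
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - width))
        amp = rng.uniform(80.0, 160.0)
        out[start:start + width] += amp * pulse
    return out


def _make_recording(config: SynthConfig, subject_id: str, role: str,
                    eeg: np.ndarray, names: list[str],
                    montage: dict[str, np.ndarray],
                    rng: np.random.Generator) -> Recording:
    """Assemble EEG + EOG channels and inject artifacts / bad channels."""
    eeg = eeg * config.amplitude_uv
    eog_base = 5.0 * pink_noise((config.n_samples,), rng)
    blinks = _blink_train(config, rng)
    eog = eog_base + blinks

    # blink bleed into EEG with distance-decaying gain from the EOG site
    eog_pos = _eog_position(montage)
    for i, name in enumerate(names):
        d = np.arccos(np.clip(np.dot(montage[name], eog_pos), -1, 1))
        gain = 0.5 * np.exp(-d / 0.6)
        eeg[i] += gain * blinks

    # occasional bridged channel: near-duplicate of the nearest neighbour
    if rng.uniform() < config.bad_channel_prob:
        candidates = [i for i, nm in enumerate(names) if nm not in MASTOIDS]
        bad = int(rng.choice(candidates))
        dists = [np.arccos(np.clip(np.dot(montage[names[bad]], montage[nm]), -1, 1))
                 if j != bad else np.inf
                 for j, nm in enumerate(names)]
        donor = int(np.argmin(dists))
        eeg[bad] = eeg[donor] + 0.02 * config.amplitude_uv * rng.standard_normal(
            config.n_samples)

    channels = [(nm, EEG) for nm in names] + [(EOG_CHANNEL, EOG)]
    data = np.vstack([eeg, eog[None, :]])
    return Recording(subject_id=subject_id, role=role, fs=config.fs,
                     channels=channels, data=data, montage=dict(montage))


def _generate_block(config: SynthConfig, pair_id: str, relationship: int,
                    hand: str, seq: np.random.SeedSequence) -> PairedBlock:
    rng = np.random.Generator(np.random.PCG64(seq))
    names = config.channel_names()
    montage = unit_positions(names)
    n_ch, n = len(names), config.n_samples

    male_u = pink_noise((n_ch, n), rng)
    private_u = pink_noise((n_ch, n), rng)
    profile = config.profile_for(relationship, hand)
    c = _coupling_series(config, profile, rng)
    female_u = np.sqrt(1.0 - c**2)[None, :] * private_u + c[None, :] * male_u

    male = _make_recording(config, f"{pair_id}-M", "male", male_u, names,
                           montage, rng)
    female = _make_recording(config, f"{pair_id}-F", "female", female_u, names,
                             montage, rng)
    return PairedBlock(pair_id=pair_id, relationship=relationship, hand=hand,
                       male=male, female=female)


def generate_pair_session(config: SynthConfig, pair_id: str,
                          relationship: int | str) -> tuple[PairedBlock, PairedBlock]:
    """Generate the (hand_off, hand_on) blocks of one dyad.

    Deterministic in ``(config.seed, pair_id)``: the same pair regenerated
    under the same configuration is bit-identical.
    """
    if isinstance(relationship, str):
        try:
            relationship = RELATIONSHIP_CODE[relationship]
        except KeyError:
            raise ValueError(f"unknown relationship {relationship!r}") from None
    if relationship not in (0, 1):
        raise ValueError(f"relationship must be 0/1, got {relationship!r}")
    seq_off, seq_on = _pair_seed_seq(config.seed, pair_id).spawn(2)
    off = _generate_block(config, pair_id, relationship, "off", seq_off)
    on = _generate_block(config, pair_id, relationship, "on", seq_on)
    return off, on


def generate_cohort(config: SynthConfig) -> list[PairedBlock]:
    """All blocks of the configured cohort (2 blocks per dyad)."""
    blocks: list[PairedBlock] = []
    for k in range(config.n_lover_pairs):
        blocks.extend(generate_pair_session(config, f"L{k + 1:02d}", LOVER))
    for k in range(config.n_stranger_pairs):
        blocks.extend(generate_pair_session(config, f"S{k + 1:02d}", 0))
    return blocks


def generate_scale_responses(groups, genders, group_effect: float = 0.0,
                             gender_effect: float = 0.0,
                             rng: np.random.Generator | None = None,
                             seed: int | None = 0) -> dict[str, pd.DataFrame]:
    """Item-level SDS and SAS response tables for ``len(groups)`` subjects.

    A latent severity trait carries the configured group and gender mean
    shifts (in latent-SD units); forward items move with the trait and
    reverse-keyed items against it, so the *scored total* shifts in the
    trait's direction.  Responses are integers in 1..4.
    """
    groups = list(groups)
    genders = list(genders)
    if len(groups) != len(genders):
        raise ValueError("groups and genders must have equal length")
    if not np.isfinite([group_effect, gender_effect]).all():
        raise ValueError("effect sizes must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(groups)

    out: dict[str, pd.DataFrame] = {}
    for instrument in ("SDS", "SAS"):
        reversed_items = scales.REVERSED[instrument]
        rows = np.empty((n, scales.N_ITEMS), dtype=int)
        for s in range(n):
            trait = (group_effect * (1 if groups[s] in (1, "lover") else 0)
                     + gender_effect * (1 if genders[s] in (1, "male") else 0)
                     + rng.normal())
            for i in range(1, scales.N_ITEMS + 1):
                sign = -1.0 if i in reversed_items else 1.0
                latent = 2.0 + 0.6 * sign * trait + 0.8 * rng.normal()
                rows[s, i - 1] = int(np.clip(np.rint(latent), 1, 4))
        df = pd.DataFrame(rows, columns=scales.ITEM_COLUMNS)
        df.insert(0, "gender", genders)
        df.insert(0, "group", groups)
        df.insert(0, "subject", [f"sub{s + 1:03d}" for s in range(n)])
        out[instrument] = df
    return out
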