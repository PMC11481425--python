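"""Run configuration: every stage parameter in one round-trippable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .difc import WindowSpec
from .preprocess import PreprocessConfig
from .synthdata import SynthConfig

__all__ = ["StatsConfig", "SvmConfig", "PipelineConfig"]


@dataclass
class StatsConfig:
    """Group-statistics knobs."""

    alpha: float = 0.05
    fdr_family: str = "global"  # or "per_pair"
    welch: bool = False
    fisher_z: bool = False


@dataclass
class SvmConfig:
    """Classifier knobs (grid of None means the built-in default grid)."""

    test_frac: float = 0.30
    cv_folds: int = 10
    paper_split: bool = False
    grid: list | None = None


@dataclass
class PipelineConfig:
    """Full end-to-end configuration (simulate -> preprocess -> dIFC ->
    stats -> classify)."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML round-trips
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj
        return clean(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = SynthConfig(**d.get("synth", {}))
        pp = d.get("preprocess", {})
        if "notch_freqs" in pp:
            pp = {**pp, "notch_freqs": tuple(pp["notch_freqs"])}
        if "band" in pp:
            pp = {**pp, "band": tuple(pp["band"])}
        preprocess = PreprocessConfig(**pp)
        window = WindowSpec(**d.get("window", {}))
        stats = StatsConfig(**d.get("stats", {}))
        svm = SvmConfig(**d.get("svm", {}))
        return cls(synth=synth, preprocess=preprocess, window=window,
                   stats=stats, svm=svm, seed=int(d.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(
            encoding="utf-8")) or {})
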