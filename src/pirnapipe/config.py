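"""Run configuration: one YAML file drives simulate -> process -> analyze.

Every constant of the analysis surfaces here as a named default: cleavage
offset 10, by-product length 16 (= guide 26 - offset 10), maximum sequencing
length 51, minimum read length 15, piRNA band 24-30, sharing thresholds
0.25 rpm / 3x, repeat filter 10 rpm, top-500 transcripts, normalizer length
23 nt.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .simulate import SimParams


@dataclass(frozen=True)
class LibrarySpec:
    """One simulated library: tag, genotype and its conversion efficiency."""

    tag: str
    genotype: str
    conversion_efficiency: float


def _default_libraries() -> tuple[LibrarySpec, ...]:
    return (
        LibrarySpec("control", "wild_type_like", 0.8),
        LibrarySpec("mutant", "mvh_mutant_like", 0.15),
    )


@dataclass(frozen=True)
class AnalysisParams:
    min_read_length: int = 15
    max_mm: int = 0
    pirna_min: int = 24
    pirna_max: int = 30
    trail_window: tuple[int, int] = (-10, 150)
    delta_range: tuple[int, int] = (-20, 30)
    sharing_min_rpm: float = 0.25
    sharing_fold: float = 3.0
    feature_min_rpm: float = 10.0
    top_n_transcripts: int = 500
    normalizer_length: int = 23
    genic_enrichment: float = 5.0
    trim_min_overlap: int = 3


@dataclass(frozen=True)
class RunConfig:
    sim: SimParams = field(default_factory=SimParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    libraries: tuple[LibrarySpec, ...] = field(default_factory=_default_libraries)
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, sim=self.sim.with_(seed=seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analysis"]["trail_window"] = list(self.analysis.trail_window)
        d["analysis"]["delta_range"] = list(self.analysis.delta_range)
        d["libraries"] = [asdict(lib) for lib in self.libraries]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = SimParams(**d.get("sim", {}))
        ana = d.get("analysis", {}).copy()
        for key in ("trail_window", "delta_range"):
            if key in ana:
                ana[key] = tuple(ana[key])
        analysis = AnalysisParams(**ana)
        libraries = tuple(
            LibrarySpec(**lib) for lib in d.get("libraries", [])
        ) or _default_libraries()
        return cls(
            sim=sim,
            analysis=analysis,
            libraries=libraries,
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
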