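"""The end-to-end classification chain and its configuration.

Stage order is fixed: per-sample windowed profile → per-sample GC fit →
correction → copy number → same-sex replicate combination → contig
classification. Both sexes are required: the method is a male/female depth
comparison and cannot run from one sex alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .io import Contig, DepthTrack
from .depth import profile_sample, WindowTable
from .gc_correction import fit_and_correct, GCModel
from .copy_number import (
    CopyNumberProfile,
    profile_copy_number,
    combine_replicates,
    DEFAULT_MIN_WINDOWS,
)
from .linkage import LinkageThresholds, classify_assembly
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "SampleResult", "classify_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one round-trippable record."""

    window_size: int = 100_000
    loess_span: float = 0.3
    loess_degree: int = 1
    two_pass_gc: bool = True  #: refit the GC model on near-diploid windows
    min_windows: int = DEFAULT_MIN_WINDOWS
    thresholds: LinkageThresholds = field(default_factory=LinkageThresholds)
    kmer_k: int = 21
    pairing_threshold: float = 0.6
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    output_dir: str = "sexdepth_out"

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["thresholds"]["ratio_x"] = list(self.thresholds.ratio_x)
        sim = raw["simulation"]
        sim["contig_length_range"] = list(self.simulation.contig_length_range)
        sim["gc_range"] = list(self.simulation.gc_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", {})
        thr["ratio_x"] = tuple(thr.get("ratio_x", (1.6, 2.4)))
        sim = raw.pop("simulation", {})
        for key in ("contig_length_range", "gc_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        return cls(
            thresholds=LinkageThresholds(**thr),
            simulation=SimulationConfig(**sim),
            **raw,
        )


@dataclass
class SampleResult:
    """Per-sample intermediates kept for inspection/serialization."""

    table: WindowTable
    model: GCModel
    profile: CopyNumberProfile


def classify_pipeline(
    assembly: Sequence[Contig],
    male_tracks: dict[str, DepthTrack],
    female_tracks: dict[str, DepthTrack],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, SampleResult]]:
    """Run profile → GC fit → correct → CN → combine → classify.

    ``male_tracks`` / ``female_tracks`` map sample id to a depth track; at
    least one track per sex is required. Returns ``(calls, summary,
    per_sample_results)``.
    """
    config = config or PipelineConfig()
    if not male_tracks or not female_tracks:
        raise ValueError("both sexes required: provide >=1 male and >=1 female track")

    results: dict[str, SampleResult] = {}
    consensus: dict[str, CopyNumberProfile] = {}
    for sex, tracks in (("male", male_tracks), ("female", female_tracks)):
        profiles = []
        for sample_id, track in tracks.items():
            table = profile_sample(
                assembly, track, config.window_size, sample_id, sex
            )
            corrected, model = fit_and_correct(
                table,
                span=config.loess_span,
                degree=config.loess_degree,
                two_pass=config.two_pass_gc,
            )
            profile = profile_copy_number(corrected, model, config.min_windows)
            results[sample_id] = SampleResult(corrected, model, profile)
            profiles.append(profile)
        consensus[sex] = combine_replicates(profiles, config.min_windows)

    lengths = {c.id: c.length for c in assembly}
    calls, summary = classify_assembly(
        consensus["male"], consensus["female"], lengths, config.thresholds
    )
    return calls, summary, results
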