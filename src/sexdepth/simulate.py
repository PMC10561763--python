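"""Synthetic diploid genomes with known sex-linked contigs, plus depth tracks.

The generator realizes the generative asymmetry the classifier relies on:
the female carries two X copies and no Y, the male one X and one Y, and
autosomes are diploid in both. Copy counts are derived from the class label,
never stored. Contigs are built from GC segments so that window GC varies on
the scale the correction operates at; depth is then simulated directly at
window resolution as

    expected = mean_depth * copy_count(sex, class) / 2 * b(gc)

where ``b`` is a multiplicative GC-bias curve with b(0.5) = 1 ("peaked":
b = exp(-2 s |gc - 0.5|), falling away from 0.5 on both sides, or
"monotone": b = exp(2 s (gc - 0.5))), and observed depth is drawn from the
configured noise law at read-count resolution. A read-level FASTQ emitter is
deliberately out of scope: the inference consumes only window depths.

All randomness flows from one seed through named substreams (genome,
depth-per-sample), so adding a sample never perturbs earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .io import Contig, write_fasta, write_depth_bedgraph, make_windows
from .depth import _base_counts

__all__ = [
    "SimulationConfig",
    "GenomeModel",
    "generate_genome",
    "gc_bias_factor",
    "simulate_depth",
    "simulate_tracks",
    "write_truth_table",
    "copy_count",
]

AUTOSOME, X, Y = "AUTOSOME", "X", "Y"

_COPY = {
    ("female", AUTOSOME): 2,
    ("female", X): 2,
    ("female", Y): 0,
    ("male", AUTOSOME): 2,
    ("male", X): 1,
    ("male", Y): 1,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def copy_count(sex: str, cls: str) -> int:
    """Copies per cell of a contig class in a given sex (diploid autosome = 2)."""
    try:
        return _COPY[(sex, cls)]
    except KeyError:
        raise ValueError(f"unknown sex/class combination ({sex!r}, {cls!r})") from None


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and its depth tracks.

    Defaults encode the replicate structure of three female and three male
    whole-genome libraries at ~30x diploid depth, 100-kb analysis windows,
    and mild exponential GC bias.
    """

    n_autosomes: int = 20
    n_x_contigs: int = 5
    n_y_contigs: int = 5
    contig_length_range: tuple[int, int] = (300_000, 1_000_000)
    gc_segment_length: int = 100_000
    gc_range: tuple[float, float] = (0.25, 0.65)
    window_size: int = 100_000
    mean_depth: float = 30.0  #: reads-per-base at a diploid locus
    gc_bias_strength: float = 0.5
    gc_bias_form: str = "peaked"  #: "peaked" | "monotone" (recorded in outputs)
    noise: str = "poisson"  #: "none" | "poisson" | "negative-binomial"
    nb_dispersion: float = 0.05
    read_length: int = 10_000  #: granularity of the count noise (long-read scale)
    n_male_samples: int = 3
    n_female_samples: int = 3
    duplicate_fraction: float = 0.0  #: fraction of contigs given an allelic copy
    duplicate_substitution_rate: float = 0.01
    duplicate_length_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autosomes + self.n_x_contigs + self.n_y_contigs < 1:
            raise ValueError("at least one contig required")
        if min(self.n_autosomes, self.n_x_contigs, self.n_y_contigs) < 0:
            raise ValueError("contig counts must be >= 0")
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be positive")
        if self.noise not in ("none", "poisson", "negative-binomial"):
            raise ValueError(f"unknown noise law {self.noise!r}")
        if self.gc_bias_form not in ("peaked", "monotone"):
            raise ValueError(f"unknown gc_bias_form {self.gc_bias_form!r}")
        lo, hi = self.contig_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid contig_length_range")

    def describe(self) -> dict:
        """Config dump including the exact bias-curve formula in force."""
        out = asdict(self)
        if self.gc_bias_form == "peaked":
            out["gc_bias_formula"] = "b(gc) = exp(-2 * strength * |gc - 0.5|)"
        else:
            out["gc_bias_formula"] = "b(gc) = exp(2 * strength * (gc - 0.5))"
        return out


@dataclass
class GenomeModel:
    """A synthetic assembly with per-contig truth labels.

    ``truth`` maps contig id to AUTOSOME/X/Y; allelic duplicates carry the
    class of their source contig and are listed in ``allelic_pairs`` as
    (primary_id, duplicate_id).
    """

    contigs: list[Contig]
    truth: dict[str, str]
    allelic_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs}

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self.contigs)


def _genome_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0]))


def _sample_rng(seed: int, sex: str, index: int) -> np.random.Generator:
    sex_code = 1 if sex == "male" else 2
    return np.random.default_rng(np.random.SeedSequence([seed, 1, sex_code, index]))


def _random_sequence(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    """Segment-wise GC: each segment's GC drawn uniformly from ``gc_range``."""
    chunks = []
    pos = 0
    while pos < length:
        seg = min(cfg.gc_segment_length, length - pos)
        gc = rng.uniform(*cfg.gc_range)
        # P(A), P(C), P(G), P(T) given the segment's target GC
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        idx = np.searchsorted(np.cumsum(p), rng.random(seg), side="right")
        chunks.append(_BASES[np.minimum(idx, 3)])
        pos += seg
    return np.concatenate(chunks).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit):
        # shift each hit base by 1-3 positions in ACGT, guaranteeing a change
        base_idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(base_idx + rng.integers(1, 4, size=len(hit))) % 4]
    return arr.tobytes().decode("ascii")


def generate_genome(cfg: SimulationConfig) -> GenomeModel:
    """Build the synthetic assembly: labeled contigs, optional allelic copies.

    Deterministic given ``cfg.seed``; two calls with the same config produce
    byte-identical sequences.
    """
    rng = _genome_rng(cfg.seed)
    plan = (
        [(f"aut_{i + 1:02d}", AUTOSOME) for i in range(cfg.n_autosomes)]
        + [(f"x_{i + 1:02d}", X) for i in range(cfg.n_x_contigs)]
        + [(f"y_{i + 1:02d}", Y) for i in range(cfg.n_y_contigs)]
    )
    lo, hi = cfg.contig_length_range
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    for cid, cls in plan:
        length = int(rng.integers(lo, hi + 1))
        contigs.append(Contig(cid, _random_sequence(rng, length, cfg)))
        truth[cid] = cls

    pairs: list[tuple[str, str]] = []
    n_dup = int(round(cfg.duplicate_fraction * len(plan)))
    if n_dup > 0:
        sources = rng.choice(len(contigs), size=n_dup, replace=False)
        for si in sorted(int(s) for s in sources):
            src = contigs[si]
            dup_len = int(round(cfg.duplicate_length_fraction * src.length))
            dup_seq = _mutate(
                rng, src.sequence[:dup_len], cfg.duplicate_substitution_rate
            )
            dup_id = f"{src.id}_alt"
            contigs.append(Contig(dup_id, dup_seq))
            truth[dup_id] = truth[src.id]
            pairs.append((src.id, dup_id))
    return GenomeModel(contigs=contigs, truth=truth, allelic_pairs=pairs)


def gc_bias_factor(
    gc: np.ndarray | float, strength: float, form: str = "peaked"
) -> np.ndarray:
    """Multiplicative depth bias b(gc), with b(0.5) = 1.

    "peaked" decays exponentially away from GC 0.5 on both sides; "monotone"
    rises exponentially with GC. Strength 0 gives b = 1 everywhere.
    """
    gc = np.asarray(gc, dtype=float)
    if form == "peaked":
        return np.exp(-2.0 * strength * np.abs(gc - 0.5))
    if form == "monotone":
        return np.exp(2.0 * strength * (gc - 0.5))
    raise ValueError(f"unknown gc_bias_form {form!r}")


def _window_records(
    genome: GenomeModel, cfg: SimulationConfig
) -> Iterator[tuple[str, int, int, float]]:
    """(contig, start, end, window_gc) for every tiling window."""
    for contig in genome.contigs:
        seq_bytes = np.frombuffer(contig.sequence.encode("ascii"), dtype=np.uint8)
        for start, end in make_windows(contig.length, cfg.window_size):
            gc_count, acgt = _base_counts(seq_bytes, start, end)
            gc = gc_count / acgt if acgt else 0.5
            yield contig.id, start, end, gc


def simulate_depth(
    genome: GenomeModel,
    sex: str,
    cfg: SimulationConfig,
    sample_index: int = 0,
) -> list[tuple[str, int, int, float]]:
    """One sample's windowed depth track as (contig, start, end, depth) records.

    Expected window depth is ``mean_depth * copy/2 * b(gc)``; under Poisson
    or negative-binomial noise the number of read equivalents per window is
    drawn at ``read_length`` granularity, so an absent sequence (female Y)
    yields exactly zero depth at any noise setting.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = _sample_rng(cfg.seed, sex, sample_index)
    records = []
    for cid, start, end, gc in _window_records(genome, cfg):
        copies = copy_count(sex, genome.truth[cid])
        bias = float(gc_bias_factor(gc, cfg.gc_bias_strength, cfg.gc_bias_form))
        expected = cfg.mean_depth * copies / 2.0 * bias
        width = end - start
        if cfg.noise == "none" or expected == 0.0:
            depth = expected
        else:
            mu = expected * width / cfg.read_length
            if cfg.noise == "poisson":
                n_reads = rng.poisson(mu)
            else:  # negative binomial via gamma-poisson mixture
                lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
                n_reads = rng.poisson(lam)
            depth = n_reads * cfg.read_length / width
        records.append((cid, start, end, float(depth)))
    return records


def simulate_tracks(
    genome: GenomeModel, cfg: SimulationConfig
) -> dict[str, tuple[str, list[tuple[str, int, int, float]]]]:
    """All samples' tracks: sample_id -> (sex, records)."""
    tracks = {}
    for i in range(cfg.n_male_samples):
        tracks[f"male_{i + 1}"] = ("male", simulate_depth(genome, "male", cfg, i))
    for i in range(cfg.n_female_samples):
        tracks[f"female_{i + 1}"] = ("female", simulate_depth(genome, "female", cfg, i))
    return tracks


def write_truth_table(genome: GenomeModel, path: str | Path) -> None:
    """TSV of contig_id, class, copy_male, copy_female for test harnesses."""
    with open(path, "w") as fh:
        fh.write("contig_id\tclass\tcopy_male\tcopy_female\n")
        for contig in genome.contigs:
            cls = genome.truth[contig.id]
            fh.write(
                f"{contig.id}\t{cls}\t{copy_count('male', cls)}"
                f"\t{copy_count('female', cls)}\n"
            )


def write_genome(genome: GenomeModel, cfg: SimulationConfig, outdir: str | Path) -> None:
    """Emit FASTA + per-sample bedgraphs + truth TSV into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.contigs, outdir / "genome.fasta")
    write_truth_table(genome, outdir / "truth.tsv")
    for sample_id, (_sex, records) in simulate_tracks(genome, cfg).items():
        write_depth_bedgraph(records, outdir / f"{sample_id}.bedgraph")
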