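"""Core domain types for DGR detection and analysis.

A diversity-generating retroelement (DGR) is a cassette of a reverse
transcriptase (RT) gene plus two near-identical repeats: an invariant
template repeat (TR) and a variable repeat (VR) embedded in a target gene.
Mutagenic retrohoming copies the TR through an error-prone cDNA into the VR
site, substituting bases specifically at TR-adenine positions.

All coordinates are 0-based, half-open internally.  Human-facing reports
convert to 1-based inclusive (GenBank style) at the output boundary only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CdsFeature:
    """A protein-coding feature on a region (0-based half-open interval).

    ``translation`` excludes the stop; for GenBank-style spans that include
    the stop codon the translation is one residue shorter than (end-start)/3.
    """

    start: int
    end: int
    strand: str
    product: str = ""
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"CDS end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class RegionRecord:
    """A genome or prophage region: sequence plus CDS annotations."""

    id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"region {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"region {self.id!r}: invalid bases {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.start < 0 or f.end > n:
                raise ValueError(
                    f"region {self.id!r}: feature {f.start}..{f.end} outside [0,{n})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "RegionRecord":
        n = len(self.sequence)
        feats = [
            CdsFeature(
                start=n - f.end,
                end=n - f.start,
                strand="-" if f.strand == "+" else "+",
                product=f.product,
                translation=f.translation,
            )
            for f in self.features
        ]
        return RegionRecord(
            id=self.id, sequence=revcomp(self.sequence), features=feats, source=self.source
        )


@dataclass
class RtHit:
    """A reverse-transcriptase call on one ORF of a region.

    ``source`` records provenance: 'domtbl' (HMMER PF00078 domain table) or
    'motif' (built-in catalytic-motif fallback).
    """

    region_id: str
    orf: CdsFeature
    score: float = 0.0
    source: str = "domtbl"


@dataclass
class RepeatPair:
    """A candidate repeat duplication: two equal-length gapless copies.

    ``mismatch_columns`` are 0-based offsets within the repeat where the two
    copies differ (columns with N in either copy never count).
    """

    region_id: str
    copy1_start: int
    copy1_end: int
    copy2_start: int
    copy2_end: int
    length: int
    mismatch_columns: list[int] = field(default_factory=list)
    orientation: str = "same"

    def __post_init__(self) -> None:
        if self.copy1_end - self.copy1_start != self.length:
            raise ValueError("copy1 span disagrees with length")
        if self.copy2_end - self.copy2_start != self.length:
            raise ValueError("copy2 span disagrees with length")
        lo, hi = sorted(
            [(self.copy1_start, self.copy1_end), (self.copy2_start, self.copy2_end)]
        )
        if lo[1] > hi[0]:
            raise ValueError("repeat copies overlap")

    def copy_seqs(self, region: RegionRecord) -> tuple[str, str]:
        return (
            region.sequence[self.copy1_start : self.copy1_end],
            region.sequence[self.copy2_start : self.copy2_end],
        )


@dataclass
class DgrCassette:
    """A repeat pair oriented into TR/VR with adenine-mismatch statistics.

    ``adenine_bias_fraction`` is adenine_mismatch_count / total_mismatch_count
    (None when total is zero); ``bias_pvalue`` is the one-sided binomial tail
    probability of seeing that many adenine mismatches under the TR's own
    adenine composition.
    """

    region_id: str
    repeat_pair: RepeatPair
    tr_span: tuple[int, int]
    vr_span: tuple[int, int]
    rt: RtHit
    tr_adenine_count: int
    adenine_mismatch_count: int
    total_mismatch_count: int
    adenine_bias_fraction: Optional[float]
    bias_pvalue: Optional[float]
    target_orf: Optional[CdsFeature] = None
    vr_residue_span: Optional[tuple[int, int]] = None
    ambiguity_flag: bool = False
    rank: int = 1

    def __post_init__(self) -> None:
        if self.adenine_mismatch_count > self.total_mismatch_count:
            raise ValueError("adenine mismatches cannot exceed total mismatches")
        spans = sorted([self.tr_span, self.vr_span])
        copies = sorted(
            [
                (self.repeat_pair.copy1_start, self.repeat_pair.copy1_end),
                (self.repeat_pair.copy2_start, self.repeat_pair.copy2_end),
            ]
        )
        if spans != copies:
            raise ValueError("tr_span/vr_span must be the two copies of repeat_pair")


@dataclass
class DetectionParams:
    """Tunable thresholds of the DGR scan.

    ``A_min`` (minimum adenines in the TR) and ``S_min`` (minimum adenine
    substitutions in the VR) are the DiGRef-style defaults; the coverage,
    identity and lifestyle-confidence thresholds mirror the published
    prophage-activity pipeline.
    """

    A_min: int = 10
    S_min: int = 7
    rt_window: int = 20_000
    seed_k: int = 11
    min_repeat_len: int = 40
    max_mismatch_fraction: float = 0.25
    max_copy_separation: int = 5_000
    coverage_threshold: float = 10.0
    identity_threshold: float = 0.97
    confidence_threshold: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if not 0 < self.max_mismatch_fraction <= 1:
            raise ValueError("max_mismatch_fraction must be in (0,1]")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0,1]")

    def replace(self, **kwargs) -> "DetectionParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CoverageProfile:
    """Per-base read depth over a region."""

    region_id: str
    depth: "list[int]"
    mean_fold: float
    breadth: float
    n_reads_used: int


@dataclass
class LifestyleScores:
    """Per-replicate temperate-probability scores for one phage."""

    phage_id: str
    replicate_scores: list[float]

    def __post_init__(self) -> None:
        for s in self.replicate_scores:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"replicate score {s} outside [0,1]")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_scores)


@dataclass
class VariantSet:
    """One DGR's TR consensus plus the VR of each tropic variant.

    ``reading_frame`` is (offset, strand): the 0/1/2 column offset of the
    first complete codon of the target ORF within the repeat, and the coding
    strand of the VR relative to the stored sequences.
    """

    dgr_id: str
    tr_consensus: str
    vrs: dict[str, str]
    reading_frame: Optional[tuple[int, str]] = None

    def __post_init__(self) -> None:
        n = len(self.tr_consensus)
        for vid, vr in self.vrs.items():
            if len(vr) != n:
                raise ValueError(
                    f"VR {vid!r} length {len(vr)} != TR length {n}"
                )


@dataclass
class DiversityReport:
    """Cross-variant diversification summary for one DGR."""

    n_variants: int
    variable_positions: list[int]
    adenine_specific: list[bool]
    asn_codon_fraction: Optional[float]
    identical_vr_pairs: list[tuple[str, str]]
    sequence_space: int

    @property
    def n_variable_positions(self) -> int:
        return len(self.variable_positions)


@dataclass
class AbundanceRecord:
    """Identity-filtered read recruitment of one phage in one sample."""

    sample_id: str
    recruited_reads: int
    total_reads: int
    fractional_abundance: float

    def __post_init__(self) -> None:
        if self.recruited_reads > self.total_reads:
            raise ValueError("recruited reads exceed total reads")


@dataclass
class GlobalEstimateParams:
    """Inputs to the global-virion back-of-envelope estimate."""

    prevalence: float
    virions_per_carrier: float
    population: float

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0,1]")
        if self.virions_per_carrier < 0 or self.population < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimParams:
    """Parameters of the mutagenic-retrohoming simulator.

    ``mutation_prob`` is the realized per-adenine mismatch probability: a
    mutated adenine is always replaced by one of the three other bases.
    """

    seed: int = 0
    genome_len: int = 10_000
    tr_len: int = 117
    tr_adenine_count: int = 30
    mutation_prob: float = 0.5
    n_variants: int = 1
    fold_coverage: float = 10.0
    read_len: int = 100
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.tr_adenine_count > self.tr_len:
            raise ValueError("tr_adenine_count cannot exceed tr_len")
        for name in ("mutation_prob", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
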