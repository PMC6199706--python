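"""Fractional abundance of a phage in a read set and the global-virion
back-of-envelope estimate.

Fractional abundance is the fraction of a sample's quality-filtered reads
recruited to the phage genome at a nucleotide-identity threshold (default
97%).  An optional per-kilobase normalization divides by reference length to
make abundances comparable across references of different size.
"""

from __future__ import annotations

import pysam

from .activity import alignment_identity
from .model import AbundanceRecord, GlobalEstimateParams


def fractional_abundance(
    sam_path: str,
    region_id: str,
    total_reads: int,
    identity_threshold: float = 0.97,
    sample_id: str = "sample",
    region_len: int | None = None,
    per_kb: bool = False,
) -> AbundanceRecord:
    """Count identity-filtered primary alignments and report their fraction
    of ``total_reads``.  With ``per_kb``, the fraction is further divided by
    the reference length in kb (requires ``region_len`` or an @SQ header)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    recruited = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        if region_len is None and region_id in (sam.references or ()):
            region_len = sam.lengths[sam.references.index(region_id)]
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != region_id:
                continue
            if identity_threshold is not None:
                if alignment_identity(read) < identity_threshold:
                    continue
            recruited += 1
    fraction = recruited / total_reads
    if per_kb:
        if not region_len:
            raise ValueError("per-kb normalization requires the reference length")
        fraction /= region_len / 1000.0
    return AbundanceRecord(
        sample_id=sample_id,
        recruited_reads=recruited,
        total_reads=total_reads,
        fractional_abundance=fraction,
    )


def global_virions(params: GlobalEstimateParams) -> float:
    """Global virion count: prevalence x virions per carrier x population."""
    return params.prevalence * params.virions_per_carrier * params.population
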