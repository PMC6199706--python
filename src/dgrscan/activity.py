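"""Coverage profiles from read alignments and the prophage-activity call.

A prophage region is classified "active" (capable of producing virions) when
virome reads recruit at strictly more than 10x mean fold coverage, optionally
after filtering alignments at a nucleotide-identity threshold.
"""

from __future__ import annotations

from typing import Optional

import pysam

from .model import CoverageProfile, RegionRecord, revcomp

# CIGAR operation codes that consume the reference
_REF_CONSUMING_ALIGNED = {0, 7, 8}  # M, =, X
_DELETION = 2  # D: consumes reference but is not covered by read bases


def alignment_identity(read: "pysam.AlignedSegment") -> float:
    """Nucleotide identity of an alignment: (aligned_cols - NM) / aligned_cols
    with aligned_cols the M/=/X span.  Requires the NM tag."""
    if not read.has_tag("NM"):
        raise ValueError(f"record {read.query_name!r}: NM tag required for identity filter")
    aligned = sum(l for op, l in read.cigartuples if op in _REF_CONSUMING_ALIGNED)
    if aligned == 0:
        return 0.0
    return (aligned - read.get_tag("NM")) / aligned


def coverage_from_sam(
    sam_path: str,
    region_id: str,
    region_len: Optional[int] = None,
    identity_threshold: Optional[float] = None,
) -> CoverageProfile:
    """Compute per-base depth for one region from a SAM text file.

    Depth is incremented over M/=/X CIGAR spans (deletions consume reference
    but add no depth).  Unmapped, secondary and supplementary records are
    excluded, as are records below ``identity_threshold`` when one is given
    (identity from the NM tag).
    """
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        if region_id not in (sam.references or ()):
            raise ValueError(f"{sam_path}: no @SQ header line for {region_id!r}")
        if region_len is None:
            region_len = sam.lengths[sam.references.index(region_id)]
        depth = [0] * region_len
        n_used = 0
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != region_id:
                continue
            if identity_threshold is not None:
                if alignment_identity(read) < identity_threshold:
                    continue
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in _REF_CONSUMING_ALIGNED:
                    for i in range(pos, min(pos + length, region_len)):
                        depth[i] += 1
                    pos += length
                elif op == _DELETION or op == 3:  # D, N skip reference
                    pos += length
            n_used += 1
    total = sum(depth)
    mean_fold = total / region_len
    breadth = sum(1 for d in depth if d > 0) / region_len
    return CoverageProfile(
        region_id=region_id,
        depth=depth,
        mean_fold=mean_fold,
        breadth=breadth,
        n_reads_used=n_used,
    )


def classify_active(profile: CoverageProfile, coverage_threshold: float = 10.0) -> str:
    """Activity verdict: 'active' iff mean fold coverage strictly exceeds the
    threshold (a region at exactly 10.0x is inactive)."""
    return "active" if profile.mean_fold > coverage_threshold else "inactive"


def naive_map(
    reads: list[tuple[str, str]],
    region: RegionRecord,
    k: int = 31,
) -> str:
    """Exact-k-mer read placement producing SAM text (test plumbing only; a
    deliberately simple stand-in for a production mapper).

    A read is placed at the unique position where its first k-mer matches the
    region exactly, forward or reverse complement; CIGAR is full-length M and
    NM is the direct Hamming distance at that placement.  Reads whose first
    k-mer is absent or multi-mapping are emitted unmapped.

    ``reads`` is a list of (name, sequence).
    """
    seq = region.sequence
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        index.setdefault(kmer, []).append(i)

    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{region.id}\tLN:{n}",
    ]
    for name, rseq in reads:
        if len(rseq) < k:
            lines.append(_sam_unmapped(name, rseq))
            continue
        placements = []
        for flag, oriented in ((0, rseq), (16, revcomp(rseq))):
            hits = index.get(oriented[:k], [])
            placements.extend(
                (flag, p, oriented) for p in hits if p + len(oriented) <= n
            )
        if len(placements) != 1:
            lines.append(_sam_unmapped(name, rseq))
            continue
        flag, pos, oriented = placements[0]
        nm = sum(1 for a, b in zip(oriented, seq[pos : pos + len(oriented)]) if a != b)
        lines.append(
            "\t".join(
                [
                    name,
                    str(flag),
                    region.id,
                    str(pos + 1),
                    "60",
                    f"{len(oriented)}M",
                    "*",
                    "0",
                    "0",
                    oriented,
                    "*",
                    f"NM:i:{nm}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _sam_unmapped(name: str, seq: str) -> str:
    return "\t".join([name, "4", "*", "0", "0", "*", "*", "0", "0", seq, "*"])
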