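"""Mutagenic-retrohoming simulator: planted DGR genomes and virome-like reads.

The generator emulates the anatomy of a phage DGR cassette — an RT ORF, an
invariant template repeat, and a variable repeat embedded in-frame near the
3' end of a target ORF, differing from the TR only at TR-adenine positions —
plus uniform-coverage shotgun reads for activity testing.  Every output is
reproducible bit-for-bit from an explicit seed; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import CdsFeature, RegionRecord, SimParams, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
# codons excluded from synthetic filler ORFs: stops, plus aspartate codons so
# that filler translations can never contain the RT catalytic x-DD motif
_FILLER_EXCLUDED = _STOPS | {"GAT", "GAC"}

# how many columns flanking each planted repeat copy are forced to disagree
# between the two loci ("clean flanks"): extension can then never creep past
# a planted boundary
_CLEAN_FLANK = 6


@dataclass
class PlantedTruth:
    """Ground-truth coordinates of a planted cassette (0-based half-open)."""

    tr_span: tuple[int, int]
    vr_span: tuple[int, int]
    rt_span: tuple[int, int]
    target_span: tuple[int, int]
    mismatch_columns: list[int] = field(default_factory=list)
    adenine_mismatches: int = 0


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=n))


def retrohome(
    tr: str, mutation_prob: float, rng: np.random.Generator
) -> str:
    """Produce a variable repeat from a template repeat by adenine-targeted
    mutagenesis: each TR adenine is independently replaced, with probability
    ``mutation_prob``, by a base drawn uniformly from {C,G,T}; every other
    position is copied verbatim."""
    out = list(tr)
    others = {"A": "CGT"}
    for i, base in enumerate(tr):
        if base == "A" and rng.random() < mutation_prob:
            out[i] = others["A"][rng.integers(3)]
    return "".join(out)


def _random_protein_dna(n_aa: int, rng: np.random.Generator,
                        motif_dna: Optional[str] = None) -> tuple[str, str]:
    """ATG + (n_aa-1) random non-stop, non-Asp codons + TAA; optionally a
    fixed DNA cassette (e.g. an RT catalytic-motif encoding) spliced into the
    middle, codon-aligned.  Returns (dna, translation)."""
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = random_dna(3, rng)
        if c not in _FILLER_EXCLUDED:
            codons.append(c)
    if motif_dna is not None:
        assert len(motif_dna) % 3 == 0
        mid = n_aa // 2
        k = len(motif_dna) // 3
        codons[mid : mid + k] = [motif_dna[i : i + 3] for i in range(0, len(motif_dna), 3)]
    dna = "".join(codons) + "TAA"
    translation = _translate(dna[:-3])
    return dna, translation


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def _translate(dna: str) -> str:
    return "".join(
        _CODON_TABLE.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


def _make_tr(tr_len: int, tr_adenine_count: int, rng: np.random.Generator) -> str:
    """Random TR with exactly ``tr_adenine_count`` adenines, no in-frame stop
    codon (frame 0), and no adenine in the final codon (reserved for the
    target ORF's stop when the repeat overhangs it)."""
    while True:
        non_a = [b for b in random_dna(tr_len * 2, rng) if b != "A"]
        seq = non_a[:tr_len]
        if len(seq) < tr_len:
            continue
        protected = set(range(tr_len - 3, tr_len))
        candidates = [i for i in range(tr_len) if i not in protected]
        a_pos = rng.choice(len(candidates), size=tr_adenine_count, replace=False)
        for i in a_pos:
            seq[candidates[i]] = "A"
        tr = "".join(seq)
        if all(tr[i : i + 3] not in _STOPS for i in range(0, tr_len - 2, 3)):
            return tr


def _mutate_tr(
    tr: str,
    rng: np.random.Generator,
    mutation_prob: float,
    force_mismatches: Optional[int],
) -> tuple[str, list[int]]:
    """Retrohome the TR, optionally forcing an exact mismatch count; rejects
    outcomes that create an in-frame stop codon or adjacent mismatches (so a
    planted repeat interior never resembles its random flanks)."""
    a_positions = [i for i, b in enumerate(tr) if b == "A"]
    for _ in range(1000):
        if force_mismatches is not None:
            if force_mismatches > len(a_positions):
                raise ValueError("not enough adenines to force that many mismatches")
            chosen = sorted(
                rng.choice(a_positions, size=force_mismatches, replace=False).tolist()
            )
            vr = list(tr)
            for i in chosen:
                vr[i] = "CGT"[rng.integers(3)]
            vr = "".join(vr)
        else:
            vr = retrohome(tr, mutation_prob, rng)
            chosen = [i for i, (a, b) in enumerate(zip(tr, vr)) if a != b]
        if any(b - a == 1 for a, b in zip(chosen, chosen[1:])):
            continue
        if not _clean_boundaries(chosen, len(tr)):
            continue
        if any(vr[i : i + 3] in _STOPS for i in range(0, len(vr) - 2, 3)):
            continue
        return vr, chosen
    raise RuntimeError("could not generate an acceptable VR in 1000 attempts")


def _clean_boundaries(mismatch_cols: list[int], length: int,
                      penalty: int = 3) -> bool:
    """True when every terminal prefix of the repeat has more matches than
    ``penalty`` x mismatches, i.e. mismatches sit far enough from both ends
    that maximal-scoring trimming keeps the full planted extent."""
    for cols in (mismatch_cols, [length - 1 - c for c in mismatch_cols]):
        score = 0
        prev = -1
        for c in sorted(cols):
            score += (c - prev - 1) - penalty
            if score <= 0:
                return False
            prev = c
    return True


# DNA encoding a canonical RT catalytic core fragment (…QGYMDD…), frame 0
_RT_MOTIF_DNA = "CAAGGCTACATGGATGAC"  # Q G Y M D D


def plant_cassette(
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    force_mismatches: Optional[int] = None,
    target_aa: int = 200,
    rt_aa: int = 300,
) -> tuple[RegionRecord, PlantedTruth]:
    """Generate a genome with one planted DGR cassette and its ground truth.

    Layout (left to right): background — target ORF with the VR in-frame at
    its 3' end — template repeat — RT ORF — background.  The VR is
    retrohome(TR); ``force_mismatches`` pins the exact adenine-mismatch count
    (e.g. S_min - 1 for below-threshold fixtures).  Flank columns around both
    repeat copies are forced to disagree, and backgrounds are rejection
    sampled against accidental long duplications, so the planted coordinates
    are exact detection truth.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L = params.genome_len
    tr_len = params.tr_len
    target_nt = 3 * target_aa + 3
    if target_nt - 3 < tr_len:
        raise ValueError("target ORF too short to host the VR")
    rt_nt = 3 * rt_aa + 3
    lead, gap1, gap2, tail = 400, 150, 100, 200
    needed = lead + target_nt + gap1 + tr_len + gap2 + rt_nt + tail
    if needed > L:
        raise ValueError(
            f"genome_len {L} too small for the planted layout ({needed} bp needed)"
        )

    for _ in range(200):
        tr = _make_tr(tr_len, params.tr_adenine_count, rng)
        vr, mism = _mutate_tr(tr, rng, params.mutation_prob, force_mismatches)
        target_dna, _ = _random_protein_dna(target_aa, rng)
        # splice the VR over the 3' end of the coding region, codon-aligned
        cut = target_nt - 3 - tr_len
        cut -= cut % 3
        target_dna = target_dna[:cut] + vr + target_dna[cut + tr_len :]
        target_translation = _translate(target_dna[:-3])
        if "*" not in target_translation and not _has_rt_motif(target_translation):
            break
    else:
        raise RuntimeError("could not build a stop-free target ORF")

    rt_dna, rt_translation = _random_protein_dna(rt_aa, rng, motif_dna=_RT_MOTIF_DNA)

    t0 = lead
    vr_start = t0 + cut
    vr_end = vr_start + tr_len
    tr_start = t0 + target_nt + gap1
    tr_end = tr_start + tr_len
    rt_start = tr_end + gap2
    rt_end = rt_start + rt_nt

    for _ in range(100):
        seq = list(random_dna(L, rng))
        seq[t0 : t0 + target_nt] = target_dna
        seq[tr_start:tr_end] = tr
        seq[rt_start:rt_end] = rt_dna
        _force_clean_flanks(seq, (vr_start, vr_end), (tr_start, tr_end), rng)
        genome = "".join(seq)
        if not _accidental_duplication(genome, (vr_start, vr_end), (tr_start, tr_end)):
            break
    else:
        raise RuntimeError("could not avoid accidental duplications")

    features = [
        CdsFeature(t0, t0 + target_nt, "+", product="hypothetical protein (DGR target)",
                   translation=target_translation),
        CdsFeature(rt_start, rt_end, "+", product="reverse transcriptase",
                   translation=rt_translation),
    ]
    region = RegionRecord(
        id=f"planted_seed{params.seed}", sequence=genome, features=features,
        source="simulator",
    )
    truth = PlantedTruth(
        tr_span=(tr_start, tr_end),
        vr_span=(vr_start, vr_end),
        rt_span=(rt_start, rt_end),
        target_span=(t0, t0 + target_nt),
        mismatch_columns=mism,
        adenine_mismatches=len(mism),
    )
    return region, truth


def _has_rt_motif(translation: str) -> bool:
    import re

    return re.search(r"[YFLIVM].DD", translation) is not None


def _force_clean_flanks(
    seq: list[str],
    vr_span: tuple[int, int],
    tr_span: tuple[int, int],
    rng: np.random.Generator,
) -> None:
    """Force the _CLEAN_FLANK columns on each side of the repeat pair to
    differ between the two loci, editing only the TR-side base (the TR sits
    in intergenic sequence, so edits never disturb a coding feature)."""
    n = len(seq)
    for j in range(1, _CLEAN_FLANK + 1):
        for v_idx, t_idx in (
            (vr_span[0] - j, tr_span[0] - j),
            (vr_span[1] - 1 + j, tr_span[1] - 1 + j),
        ):
            if 0 <= v_idx < n and 0 <= t_idx < n and seq[t_idx] == seq[v_idx]:
                choices = [b for b in "ACGT" if b != seq[v_idx]]
                seq[t_idx] = choices[rng.integers(len(choices))]


def _accidental_duplication(
    genome: str,
    vr_span: tuple[int, int],
    tr_span: tuple[int, int],
    k: int = 25,
) -> bool:
    """True if any k-mer occurs at two positions not explained by the planted
    repeat pair (a conservative proxy for an accidental long duplication)."""
    offset = tr_span[0] - vr_span[0]
    seen: dict[str, int] = {}
    for i in range(len(genome) - k + 1):
        kmer = genome[i : i + k]
        if kmer in seen:
            j = seen[kmer]
            planted = (
                vr_span[0] <= j and j + k <= vr_span[1] and i - j == offset
            )
            if not planted:
                return True
        else:
            seen[kmer] = i
    return False


def make_variant_set(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> "tuple[str, dict[str, str]]":
    """One TR plus ``n_variants`` independently retrohomed VRs (the
    multi-lysogen tropic-variant scenario).  Returns (tr, {variant_id: vr});
    wrap in a VariantSet with reading_frame (0, '+') — VR columns are
    codon-aligned frame 0 by construction."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    tr = _make_tr(params.tr_len, params.tr_adenine_count, rng)
    vrs = {
        f"variant{i:02d}": retrohome(tr, params.mutation_prob, rng)
        for i in range(params.n_variants)
    }
    return tr, vrs


def synth_reads(
    region: RegionRecord,
    fold_coverage: float,
    read_len: int,
    error_rate: float,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Uniform shotgun reads at the requested fold coverage.

    n = round(fold_coverage * region_len / read_len) reads at uniform random
    start positions and strands, with independent substitution errors at
    ``error_rate``.  Returns (name, sequence) pairs; use ``to_fastq`` for
    FASTQ text.
    """
    L = len(region.sequence)
    if read_len > L:
        raise ValueError("read_len exceeds region length")
    n = round(fold_coverage * L / read_len)
    reads = []
    for i in range(n):
        pos = int(rng.integers(0, L - read_len + 1))
        seq = region.sequence[pos : pos + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if error_rate > 0:
            seq = "".join(
                ("ACGT".replace(b, "")[rng.integers(3)]
                 if b != "N" and rng.random() < error_rate else b)
                for b in seq
            )
        reads.append((f"read{i:06d}", seq))
    return reads


def to_fastq(reads: list[tuple[str, str]], quality_char: str = "I") -> str:
    return "".join(
        f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n" for name, seq in reads
    )


def read_fastq(text: str) -> list[tuple[str, str]]:
    """Parse FASTQ text back into (name, sequence) pairs."""
    lines = text.strip().splitlines()
    if len(lines) % 4:
        raise ValueError("FASTQ record count is not a multiple of 4 lines")
    return [(lines[i][1:].split()[0], lines[i + 1]) for i in range(0, len(lines), 4)]
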