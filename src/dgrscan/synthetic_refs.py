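"""Synthetic stand-in reference genomes for the two published DGR exemplars.

These are *synthetic* constructions, generated deterministically at run time:
they reproduce the documented anatomy of the Bacteroides Hankyphage prophage
(42,831 bp genome, 45 CDS, a reverse transcriptase beside two 117 bp repeats
mismatched at 14 template-adenine positions, the variable repeat ending at
residue 2225 of a 2,225-residue target ORF) and of Bordetella phage BPP-1 (a
134 bp variable repeat inside the mtd tail-fiber gene), with all other
sequence content random.  They exercise exactly the code paths the real
GenBank records would and carry ground truth, but they are not the published
sequences.
"""

from __future__ import annotations

import numpy as np

from .model import CdsFeature, RegionRecord, VariantSet
from .simulate import (
    PlantedTruth,
    _accidental_duplication,
    _force_clean_flanks,
    _has_rt_motif,
    _make_tr,
    _mutate_tr,
    _random_protein_dna,
    _RT_MOTIF_DNA,
    _translate,
    random_dna,
)

HANKYPHAGE_LENGTH = 42_831
HANKYPHAGE_N_CDS = 45
_HANKY_SEED = 42_831
_BPP1_SEED = 5_357


def _assemble(
    genome_len: int,
    components: list[tuple[str, str, str, str | None]],
    rng: np.random.Generator,
) -> tuple[str, list[CdsFeature], dict[str, tuple[int, int]]]:
    """Lay out (kind, dna, product, translation) components left to right,
    spreading the leftover length as inter-component gaps of random sequence.
    ``kind`` is 'cds' or 'repeat'.  Returns sequence, features, and the span
    of each component by its product/name."""
    total = sum(len(dna) for _, dna, _, _ in components)
    n_gaps = len(components) + 1
    leftover = genome_len - total
    if leftover < n_gaps:
        raise ValueError("components do not fit in the genome")
    gap = leftover // n_gaps
    seq_parts: list[str] = []
    features: list[CdsFeature] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for kind, dna, name, translation in components:
        g = gap
        seq_parts.append(random_dna(g, rng))
        pos += g
        seq_parts.append(dna)
        spans[name] = (pos, pos + len(dna))
        if kind == "cds":
            features.append(
                CdsFeature(pos, pos + len(dna), "+", product=name,
                           translation=translation)
            )
        pos += len(dna)
    seq_parts.append(random_dna(genome_len - pos, rng))
    return "".join(seq_parts), features, spans


def synthetic_hankyphage() -> tuple[RegionRecord, PlantedTruth]:
    """Deterministic synthetic Hankyphage-like prophage genome.

    42,831 bp, 45 CDS.  Cassette anatomy: a 2,225-residue target ORF whose
    final 114 coding bases plus stop codon form the variable repeat (117 bp,
    residues 2188-2225), an identical-length template repeat downstream in
    intergenic sequence, a small accessory-variability-determinant-like ORF,
    and a reverse-transcriptase ORF.  The repeats differ at exactly 14
    positions, all adenine in the TR.
    """
    rng = np.random.default_rng(_HANKY_SEED)
    target_aa = 2225
    target_nt = 3 * target_aa + 3
    for _ in range(200):
        tr114 = _make_tr(114, 28, rng)
        vr114, mism = _mutate_tr(tr114, rng, 0.5, force_mismatches=14)
        tr = tr114 + "TAA"
        vr = vr114 + "TAA"
        cut = target_nt - len(vr)  # VR covers the last 114 coding nt + stop
        target_dna, _ = _random_protein_dna(target_aa, rng)
        target_dna = target_dna[:cut] + vr
        target_translation = _translate(target_dna[:-3])
        if "*" not in target_translation and not _has_rt_motif(target_translation):
            break
    else:
        raise RuntimeError("could not build the target ORF")

    avd_dna, avd_tr = _random_protein_dna(85, rng)
    rt_dna, rt_tr = _random_protein_dna(320, rng, motif_dna=_RT_MOTIF_DNA)

    filler_aa = rng.integers(120, 281, size=HANKYPHAGE_N_CDS - 3)
    fillers = [_random_protein_dna(int(a), rng) for a in filler_aa]

    components: list[tuple[str, str, str, str | None]] = []
    for i, (dna, trl) in enumerate(fillers[:20], 1):
        components.append(("cds", dna, f"hypothetical protein hp{i:02d}", trl))
    components.append(
        ("cds", target_dna, "DGR target protein (C-type lectin fold)",
         target_translation)
    )
    components.append(("repeat", tr, "template repeat", None))
    components.append(("cds", avd_dna, "accessory variability determinant", avd_tr))
    components.append(("cds", rt_dna, "reverse transcriptase", rt_tr))
    for i, (dna, trl) in enumerate(fillers[20:], 21):
        components.append(("cds", dna, f"hypothetical protein hp{i:02d}", trl))

    for _ in range(20):
        sequence, features, spans = _assemble(HANKYPHAGE_LENGTH, components, rng)
        t_span = spans["DGR target protein (C-type lectin fold)"]
        vr_span = (t_span[0] + cut, t_span[0] + cut + len(vr))
        tr_span = spans["template repeat"]
        seq_list = list(sequence)
        _force_clean_flanks(seq_list, vr_span, tr_span, rng)
        sequence = "".join(seq_list)
        if not _accidental_duplication(sequence, vr_span, tr_span):
            break
    else:
        raise RuntimeError("could not avoid accidental duplications")

    region = RegionRecord(
        id="synthetic_hankyphage",
        sequence=sequence,
        features=features,
        source="synthetic construction",
    )
    truth = PlantedTruth(
        tr_span=tr_span,
        vr_span=vr_span,
        rt_span=spans["reverse transcriptase"],
        target_span=t_span,
        mismatch_columns=mism,
        adenine_mismatches=len(mism),
    )
    assert len(region.sequence) == HANKYPHAGE_LENGTH
    assert len(region.features) == HANKYPHAGE_N_CDS
    return region, truth


def synthetic_bpp1() -> tuple[RegionRecord, PlantedTruth]:
    """Deterministic synthetic BPP-1-like genome segment.

    Carries the mtd tail-fiber gene with a 134 bp variable repeat near its
    3' end, the template repeat downstream, an accessory variability
    determinant and the brt reverse transcriptase.
    """
    rng = np.random.default_rng(_BPP1_SEED)
    vr_len = 134
    mtd_aa = 400
    mtd_nt = 3 * mtd_aa + 3
    for _ in range(200):
        tr = _make_tr(vr_len, 30, rng)
        vr, mism = _mutate_tr(tr, rng, 0.5, force_mismatches=14)
        # splice the VR so it ends 30 nt before the stop, codon-floor start
        cut = mtd_nt - 3 - 30 - vr_len
        cut -= cut % 3
        mtd_dna, _ = _random_protein_dna(mtd_aa, rng)
        mtd_dna = mtd_dna[:cut] + vr + mtd_dna[cut + vr_len :]
        mtd_translation = _translate(mtd_dna[:-3])
        if "*" not in mtd_translation and not _has_rt_motif(mtd_translation):
            break
    else:
        raise RuntimeError("could not build the mtd ORF")

    avd_dna, avd_tr = _random_protein_dna(120, rng)
    brt_dna, brt_tr = _random_protein_dna(320, rng, motif_dna=_RT_MOTIF_DNA)
    fillers = [_random_protein_dna(int(a), rng) for a in (180, 220, 150)]

    components: list[tuple[str, str, str, str | None]] = [
        ("cds", fillers[0][0], "hypothetical protein", fillers[0][1]),
        ("cds", mtd_dna, "major tropism determinant Mtd (tail fiber)",
         mtd_translation),
        ("repeat", tr, "template repeat", None),
        ("cds", avd_dna, "accessory variability determinant Avd", avd_tr),
        ("cds", brt_dna, "reverse transcriptase Brt", brt_tr),
        ("cds", fillers[1][0], "hypothetical protein 2", fillers[1][1]),
        ("cds", fillers[2][0], "hypothetical protein 3", fillers[2][1]),
    ]

    genome_len = 12_000
    for _ in range(20):
        sequence, features, spans = _assemble(genome_len, components, rng)
        mtd_span = spans["major tropism determinant Mtd (tail fiber)"]
        vr_span = (mtd_span[0] + cut, mtd_span[0] + cut + vr_len)
        tr_span = spans["template repeat"]
        seq_list = list(sequence)
        _force_clean_flanks(seq_list, vr_span, tr_span, rng)
        sequence = "".join(seq_list)
        if not _accidental_duplication(sequence, vr_span, tr_span):
            break
    else:
        raise RuntimeError("could not avoid accidental duplications")

    region = RegionRecord(
        id="synthetic_bpp1",
        sequence=sequence,
        features=features,
        source="synthetic construction",
    )
    truth = PlantedTruth(
        tr_span=tr_span,
        vr_span=vr_span,
        rt_span=spans["reverse transcriptase Brt"],
        target_span=mtd_span,
        mismatch_columns=mism,
        adenine_mismatches=len(mism),
    )
    return region, truth


def synthetic_hankyphage_variant_set(n_variants: int = 13) -> VariantSet:
    """Synthetic multi-lysogen variant set mirroring the published census:
    one invariant TR and ``n_variants`` distinct VRs whose union of variable
    positions is exactly 21 columns, every one adenine in the TR."""
    rng = np.random.default_rng(_HANKY_SEED + 1)
    region, truth = synthetic_hankyphage()
    tr = region.sequence[truth.tr_span[0] : truth.tr_span[1]]
    a_positions = [i for i, b in enumerate(tr[:114]) if b == "A"]
    target_positions = sorted(
        rng.choice(a_positions, size=21, replace=False).tolist()
    )
    for _ in range(1000):
        vrs: dict[str, str] = {}
        used: set[int] = set()
        for v in range(n_variants):
            chosen = [p for p in target_positions if rng.random() < 0.5]
            out = list(tr)
            for p in chosen:
                out[p] = "CGT"[rng.integers(3)]
            vrs[f"p{v:02d}"] = "".join(out)
            used.update(chosen)
        if used == set(target_positions) and len(set(vrs.values())) == n_variants:
            return VariantSet(
                dgr_id="synthetic_hankyphage_dgr",
                tr_consensus=tr,
                vrs=vrs,
                reading_frame=(0, "+"),
            )
    raise RuntimeError("could not cover all 21 positions with distinct variants")
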