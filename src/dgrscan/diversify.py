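"""Cross-variant diversification analysis of one DGR across many lysogens.

Given the invariant template repeat and the variable repeat extracted from
each tropic variant, this module censuses the variable positions, checks
their adenine specificity and codon context (DGR variation lands in AAT/AAC
asparagine codons of the template), and sizes the explorable sequence space
as an exact big integer 4^n over n variable nucleotide positions.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

from .model import DiversityReport, VariantSet, revcomp

_ASN_CODONS = {"AAT", "AAC"}


def check_tr_invariance(trs: list[str]) -> tuple[bool, list[int]]:
    """True iff all template-repeat copies are identical; otherwise the
    0-based columns at which any copy disagrees with the first."""
    if not trs:
        return True, []
    n = len(trs[0])
    for t in trs:
        if len(t) != n:
            raise ValueError("TR copies have unequal lengths")
    discordant = [
        i for i in range(n) if any(t[i] != trs[0][i] for t in trs[1:])
    ]
    return not discordant, discordant


def _coding_orientation(vs: VariantSet) -> tuple[str, dict[str, str], int]:
    """Return TR, VRs and frame offset on the target ORF's coding strand."""
    offset, strand = vs.reading_frame  # type: ignore[misc]
    if strand == "+":
        return vs.tr_consensus, vs.vrs, offset
    n = len(vs.tr_consensus)
    tr = revcomp(vs.tr_consensus)
    vrs = {k: revcomp(v) for k, v in vs.vrs.items()}
    # a codon starting at column c on the forward strand maps to one ending at
    # column n-1-c on the reverse; recompute the first full codon start
    off = (n - offset) % 3
    return tr, vrs, off


def diversity_report(vs: VariantSet) -> DiversityReport:
    """Column-wise census of VR variation against the TR consensus.

    Variable positions are the union over variants of columns differing from
    the TR; a column is adenine-specific when the TR base there is A.  The
    asparagine-codon fraction is computed over TR codons (in the target ORF's
    reading frame) containing at least one substituted column, and is None
    when no reading frame is given.  Sequence space is exactly
    4**n_variable_positions.
    """
    tr = vs.tr_consensus
    n = len(tr)
    variable = sorted(
        {
            i
            for vr in vs.vrs.values()
            for i in range(n)
            if vr[i] != tr[i] and tr[i] != "N" and vr[i] != "N"
        }
    )
    adenine_specific = [tr[i] == "A" for i in variable]

    asn_fraction: Optional[float] = None
    if vs.reading_frame is not None:
        ctr, cvrs, offset = _coding_orientation(vs)
        cvariable = {
            i
            for vr in cvrs.values()
            for i in range(n)
            if vr[i] != ctr[i] and ctr[i] != "N" and vr[i] != "N"
        }
        sub_codons = []
        for start in range(offset, n - 2, 3):
            if any(c in cvariable for c in (start, start + 1, start + 2)):
                sub_codons.append(ctr[start : start + 3])
        if sub_codons:
            asn_fraction = sum(1 for c in sub_codons if c in _ASN_CODONS) / len(
                sub_codons
            )

    identical = [
        (a, b)
        for a, b in combinations(sorted(vs.vrs), 2)
        if vs.vrs[a] == vs.vrs[b]
    ]
    return DiversityReport(
        n_variants=len(vs.vrs),
        variable_positions=variable,
        adenine_specific=adenine_specific,
        asn_codon_fraction=asn_fraction,
        identical_vr_pairs=identical,
        sequence_space=4 ** len(variable),
    )


def genome_pair_vr_only_diff(
    genome_a: str, genome_b: str, vr_span: tuple[int, int]
) -> bool:
    """True iff two pre-aligned equal-length genomes differ only at columns
    inside ``vr_span`` (0-based half-open)."""
    if len(genome_a) != len(genome_b):
        raise ValueError(
            "genomes must be pre-aligned to equal length for columnwise comparison"
        )
    lo, hi = vr_span
    return all(
        a == b
        for i, (a, b) in enumerate(zip(genome_a, genome_b))
        if not (lo <= i < hi)
    )


def render_alignment(vs: VariantSet, width: int = 60) -> str:
    """Columnar text rendering of TR and VRs with mismatches in lowercase."""
    lines = []
    ids = ["TR"] + sorted(vs.vrs)
    seqs = {"TR": vs.tr_consensus, **vs.vrs}
    label_w = max(len(i) for i in ids) + 2
    for block in range(0, len(vs.tr_consensus), width):
        for vid in ids:
            s = seqs[vid][block : block + width]
            if vid != "TR":
                s = "".join(
                    c.lower() if c != vs.tr_consensus[block + j] else c
                    for j, c in enumerate(s)
                )
            lines.append(f"{vid:<{label_w}}{s}")
        lines.append("")
    return "\n".join(lines)
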