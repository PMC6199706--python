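"""DGR cassette detection: repeat-pair discovery, TR/VR orientation, and
adenine-mismatch scoring.

The scan looks for direct (same-strand) imperfect repeat pairs near a
reverse-transcriptase locus using exact k-mer seeds extended greedily in both
directions, then orients the two copies into template (TR) and variable (VR)
repeat by asking which copy owns the adenines at the mismatched columns —
mutagenic retrohoming substitutes TR adenines, so the adenine-rich copy at
mismatch columns is the template.  A cassette is called when the TR carries at
least ``A_min`` adenines and at least ``S_min`` mismatch columns are adenine
in the TR.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Optional

from scipy.stats import binom

from .model import (
    CdsFeature,
    DetectionParams,
    DgrCassette,
    RegionRecord,
    RepeatPair,
    RtHit,
    revcomp,
)

# Greedy extension stops once the trailing window is mismatch-saturated;
# random flanking sequence mismatches ~3/4 of columns so extension halts
# within ~a window of a true repeat boundary, while a genuine repeat interior
# (mismatch fraction <= 0.25) essentially never saturates the window.
_STOP_WINDOW = 12
_STOP_WINDOW_MISMATCHES = 9
# Score-based trim of the extension: a terminal segment is kept only if its
# matches outweigh mismatches at this penalty, so termini are always matches.
_MISMATCH_PENALTY = 3

_RT_MOTIF = re.compile(r"[YFLIVM].DD")
_MIN_RT_ORF_AA = 200


def _extend_seed(
    seq: str,
    p1: int,
    p2: int,
    k: int,
    max_mismatch_fraction: float,
) -> Optional[tuple[int, int, int]]:
    """Extend an exact seed match at (p1, p1+k) / (p2, p2+k) in both
    directions.

    Returns (start_offset, end_offset, diagonal) as the final repeat placed
    at [p1+lo, p1+hi) / [p2+lo, p2+hi), or None if degenerate.  Extension
    adds columns while the trailing _STOP_WINDOW columns hold fewer than
    _STOP_WINDOW_MISMATCHES mismatches, the cumulative mismatch fraction
    stays within bounds, no N is hit, and the copies do not collide; the
    result is then trimmed back to the maximal-scoring extent on each side
    (match +1, mismatch -_MISMATCH_PENALTY), which also guarantees matching
    terminal columns.
    """
    n = len(seq)
    d = p2 - p1

    def _run(start: int, step: int) -> list[bool]:
        """Collect match flags walking outwards from the seed."""
        out: list[bool] = []
        mism = 0
        total = k
        i = start
        while True:
            a_idx = p1 + i
            b_idx = p2 + i
            if a_idx < 0 or b_idx < 0 or b_idx >= n or a_idx >= n:
                break
            # keep copies non-overlapping: copy1 must end before copy2 starts
            if step > 0 and a_idx >= p2:
                break
            if step < 0 and b_idx < p1 + k:
                break
            a, b = seq[a_idx], seq[b_idx]
            if a == "N" or b == "N":
                break
            match = a == b
            out.append(match)
            total += 1
            if not match:
                mism += 1
                window = out[-_STOP_WINDOW:]
                if window.count(False) >= _STOP_WINDOW_MISMATCHES:
                    break
                if mism / total > max_mismatch_fraction:
                    break
            i += step
        return out

    right = _run(k, +1)
    left = _run(-1, -1)

    def _best_cut(flags: list[bool]) -> int:
        """Length of the maximal-scoring prefix of the outward walk."""
        best, best_i, score = 0, 0, 0
        for i, m in enumerate(flags, 1):
            score += 1 if m else -_MISMATCH_PENALTY
            if score > best:
                best, best_i = score, i
        return best_i

    hi = k + _best_cut(right)
    lo = -_best_cut(left)
    # repeat copies must not overlap after extension
    if p1 + hi > p2 + lo:
        hi = min(hi, (p2 + lo) - p1)
        if hi <= lo:
            return None
    return lo, hi, d


def find_repeat_pairs(
    region: RegionRecord, anchor: RtHit, params: DetectionParams
) -> list[RepeatPair]:
    """Find maximal direct repeat pairs within ``rt_window`` of the RT ORF.

    Two-pass seeding: exact ``seed_k``-mers first; if nothing survives, a
    second pass with 7-mers catches heavily mutated repeats whose longest
    clean stretch is short (pigeonhole: 14 mismatches over 117 bp still leave
    a >= 7 bp exact run).  Overlapping seeds on one diagonal are merged into a
    single maximal pair.  Results are sorted by copy1_start, then length
    descending.
    """
    seq = region.sequence
    n = len(seq)
    orf = anchor.orf
    if orf.start < 0 or orf.end > n:
        raise ValueError(
            f"anchor ORF {orf.start}..{orf.end} outside region {region.id!r}"
        )
    w0 = max(0, orf.start - params.rt_window)
    w1 = min(n, orf.end + params.rt_window)
    if w1 - w0 < params.seed_k:
        return []

    for k in (params.seed_k, min(7, params.seed_k)):
        pairs = _scan_window(seq, w0, w1, k, params, region.id)
        if pairs:
            break
    pairs.sort(key=lambda p: (p.copy1_start, -p.length))
    return pairs


def _scan_window(
    seq: str, w0: int, w1: int, k: int, params: DetectionParams, region_id: str
) -> list[RepeatPair]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(w0, w1 - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)

    # max seed diagonal: copies at most max_copy_separation apart plus the
    # longest repeat we could plausibly extend to within the window
    max_diag = params.max_copy_separation + (w1 - w0)

    covered: dict[int, list[tuple[int, int]]] = defaultdict(list)
    found: dict[tuple[int, int, int], RepeatPair] = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > 100:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                p1, p2 = positions[ai], positions[bi]
                d = p2 - p1
                if d < k or d > max_diag:
                    continue
                if any(lo <= p1 < hi for lo, hi in covered[d]):
                    continue
                ext = _extend_seed(seq, p1, p2, k, params.max_mismatch_fraction)
                if ext is None:
                    continue
                lo, hi, _ = ext
                s1, e1 = p1 + lo, p1 + hi
                s2, e2 = p2 + lo, p2 + hi
                covered[d].append((s1, e1))
                length = e1 - s1
                if length < params.min_repeat_len:
                    continue
                if s2 - e1 > params.max_copy_separation:
                    continue
                c1, c2 = seq[s1:e1], seq[s2:e2]
                mism = [
                    i
                    for i, (a, b) in enumerate(zip(c1, c2))
                    if a != b and a != "N" and b != "N"
                ]
                if len(mism) / length > params.max_mismatch_fraction:
                    continue
                key = (s1, s2, length)
                if key not in found:
                    found[key] = RepeatPair(
                        region_id=region_id,
                        copy1_start=s1,
                        copy1_end=e1,
                        copy2_start=s2,
                        copy2_end=e2,
                        length=length,
                        mismatch_columns=mism,
                        orientation="same",
                    )
    return list(found.values())


def _orient_seqs(
    pair: RepeatPair, region: RegionRecord, c1: str, c2: str
) -> tuple[tuple[int, int], tuple[int, int], bool]:
    cols = [
        i for i, (a, b) in enumerate(zip(c1, c2)) if a != b and a != "N" and b != "N"
    ]
    a1 = sum(1 for i in cols if c1[i] == "A")
    a2 = sum(1 for i in cols if c2[i] == "A")
    span1 = (pair.copy1_start, pair.copy1_end)
    span2 = (pair.copy2_start, pair.copy2_end)
    if a1 > a2:
        return span1, span2, False
    if a2 > a1:
        return span2, span1, False
    in_cds1 = any(f.overlaps(*span1) for f in region.features)
    in_cds2 = any(f.overlaps(*span2) for f in region.features)
    if in_cds1 != in_cds2:
        # the CDS-embedded copy is the variable repeat
        return (span2, span1, False) if in_cds1 else (span1, span2, False)
    return span1, span2, True


def orient_tr_vr(
    pair: RepeatPair, region: RegionRecord
) -> tuple[tuple[int, int], tuple[int, int], bool]:
    """Assign the two copies of a repeat pair to template and variable repeat.

    The copy holding more adenines at the mismatched columns is the TR
    (retrohoming replaces TR adenines in the VR).  Ties fall back to CDS
    overlap — the copy inside an annotated ORF is the VR — and if that too is
    uninformative, copy1 is declared TR with the ambiguity flag raised.
    """
    if not pair.mismatch_columns:
        raise ValueError("identical repeats: orientation undefined")
    c1, c2 = pair.copy_seqs(region)
    return _orient_seqs(pair, region, c1, c2)


def _orient_both_strands(
    pair: RepeatPair, region: RegionRecord
) -> tuple[tuple[int, int], tuple[int, int], bool, str]:
    """Orient a repeat pair considering both polarities.

    Adenine specificity is strand-dependent (a TR adenine reads as thymine on
    the opposite strand), so the scan evaluates the pair as given and as its
    reverse complement and keeps the polarity with the stronger adenine
    ownership at mismatch columns.  Returns (tr_span, vr_span, ambiguity,
    strand) with spans always in region coordinates.
    """
    if not pair.mismatch_columns:
        raise ValueError("identical repeats: orientation undefined")
    c1, c2 = pair.copy_seqs(region)
    best = None
    for strand, (s1, s2) in (("+", (c1, c2)), ("-", (revcomp(c1), revcomp(c2)))):
        cols = [
            i for i, (a, b) in enumerate(zip(s1, s2)) if a != b and a != "N" and b != "N"
        ]
        owned = max(
            sum(1 for i in cols if s1[i] == "A"),
            sum(1 for i in cols if s2[i] == "A"),
        )
        tr_span, vr_span, flag = _orient_seqs(pair, region, s1, s2)
        if best is None or owned > best[0]:
            best = (owned, tr_span, vr_span, flag, strand)
    _, tr_span, vr_span, flag, strand = best
    return tr_span, vr_span, flag, strand


def adenine_bias(
    tr_seq: str, vr_seq: str
) -> tuple[int, int, Optional[float], Optional[float]]:
    """Count mismatches between TR and VR and score their adenine specificity.

    Returns (total_mismatches, adenine_mismatches, bias_fraction, bias_pvalue)
    where the p-value is the one-sided binomial tail P(X >= adenine | n=total,
    p=f_A) with f_A the adenine fraction of the TR.  Columns containing N are
    ignored.  Identical sequences give (0, 0, None, None).
    """
    if len(tr_seq) != len(vr_seq):
        raise ValueError(
            f"TR length {len(tr_seq)} != VR length {len(vr_seq)}"
        )
    total = 0
    adenine = 0
    for a, b in zip(tr_seq, vr_seq):
        if a == "N" or b == "N":
            continue
        if a != b:
            total += 1
            if a == "A":
                adenine += 1
    if total == 0:
        return 0, 0, None, None
    usable = sum(1 for a, b in zip(tr_seq, vr_seq) if a != "N" and b != "N")
    f_a = sum(
        1 for a, b in zip(tr_seq, vr_seq) if a == "A" and b != "N"
    ) / usable if usable else 0.0
    pvalue = float(binom.sf(adenine - 1, total, f_a))
    return total, adenine, adenine / total, pvalue


def _vr_residue_span(
    vr_span: tuple[int, int], orf: CdsFeature
) -> Optional[tuple[int, int]]:
    """1-based residue interval of the VR's overlap in the ORF translation.

    The CDS span is assumed to include the stop codon; residues past the
    translated length (the stop) are clamped off.
    """
    a = max(vr_span[0], orf.start)
    b = min(vr_span[1], orf.end)
    if b <= a:
        return None
    n_aa = len(orf.translation) if orf.translation else (orf.end - orf.start) // 3 - 1
    if orf.strand == "+":
        first = (a - orf.start) // 3 + 1
        last = (b - 1 - orf.start) // 3 + 1
    else:
        first = (orf.end - b) // 3 + 1
        last = (orf.end - 1 - a) // 3 + 1
    first = max(1, min(first, n_aa))
    last = max(1, min(last, n_aa))
    return (first, last)


def call_dgr(
    region: RegionRecord,
    rt_hits: list[RtHit],
    params: Optional[DetectionParams] = None,
) -> list[DgrCassette]:
    """Run the full DGR call for a region: repeats near each RT, oriented and
    filtered by the adenine criteria (TR adenines >= A_min, adenine mismatch
    columns >= S_min).

    All retained pairs are reported; within one RT, cassettes are ranked by
    proximity of the repeat pair to the RT ORF (rank 1 = closest, matching
    the convention that only the first TR/VR pair is headline-reported).
    """
    if params is None:
        params = DetectionParams()
    cassettes: list[DgrCassette] = []
    for rt in rt_hits:
        candidates = []
        for pair in find_repeat_pairs(region, rt, params):
            if not pair.mismatch_columns:
                continue
            tr_span, vr_span, ambiguous, strand = _orient_both_strands(pair, region)
            tr_seq = region.sequence[tr_span[0] : tr_span[1]]
            vr_seq = region.sequence[vr_span[0] : vr_span[1]]
            if strand == "-":
                tr_seq, vr_seq = revcomp(tr_seq), revcomp(vr_seq)
            total, adenine, fraction, pvalue = adenine_bias(tr_seq, vr_seq)
            tr_a = tr_seq.count("A")
            if tr_a < params.A_min or adenine < params.S_min:
                continue
            target = None
            best_overlap = 0
            for f in region.features:
                ov = min(vr_span[1], f.end) - max(vr_span[0], f.start)
                if ov > best_overlap:
                    best_overlap = ov
                    target = f
            res_span = _vr_residue_span(vr_span, target) if target else None
            dist = _pair_distance_to_orf(pair, rt.orf)
            candidates.append(
                (
                    dist,
                    DgrCassette(
                        region_id=region.id,
                        repeat_pair=pair,
                        tr_span=tr_span,
                        vr_span=vr_span,
                        rt=rt,
                        tr_adenine_count=tr_a,
                        adenine_mismatch_count=adenine,
                        total_mismatch_count=total,
                        adenine_bias_fraction=fraction,
                        bias_pvalue=pvalue,
                        target_orf=target,
                        vr_residue_span=res_span,
                        ambiguity_flag=ambiguous,
                    ),
                )
            )
        candidates.sort(key=lambda t: t[0])
        for rank, (_, cassette) in enumerate(candidates, 1):
            cassette.rank = rank
            cassettes.append(cassette)
    return cassettes


def _pair_distance_to_orf(pair: RepeatPair, orf: CdsFeature) -> int:
    def gap(s: int, e: int) -> int:
        if e <= orf.start:
            return orf.start - e
        if s >= orf.end:
            return s - orf.end
        return 0

    return min(
        gap(pair.copy1_start, pair.copy1_end), gap(pair.copy2_start, pair.copy2_end)
    )


def motif_rt_scan(region: RegionRecord) -> list[RtHit]:
    """Fallback RT screen: flag ORFs >= 200 aa whose translation carries the
    reverse-transcriptase catalytic motif (x-DD preceded by a hydrophobic or
    aromatic residue, e.g. YMDD / YADD / LVDD)."""
    hits = []
    for f in region.features:
        if not f.translation or len(f.translation) < _MIN_RT_ORF_AA:
            continue
        if _RT_MOTIF.search(f.translation):
            hits.append(RtHit(region_id=region.id, orf=f, score=0.0, source="motif"))
    return hits
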