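"""Repeat-pair discovery, TR/VR orientation, and adenine-mismatch scoring."""

from math import comb

import numpy as np
import pytest

from dgrscan import detect
from dgrscan.model import CdsFeature, DetectionParams, RegionRecord, RepeatPair, RtHit
from dgrscan.simulate import plant_cassette, random_dna
from dgrscan.model import SimParams


def _region_with_repeat(rng, length=1000, rep_len=117, separation=300, mismatches=()):
    """Random region with a planted direct repeat; returns (region, spans)."""
    seq = list(random_dna(length, rng))
    rep = random_dna(rep_len, rng)
    s1 = 200
    s2 = s1 + rep_len + separation
    seq[s1 : s1 + rep_len] = rep
    copy2 = list(rep)
    for i in mismatches:
        copy2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy2[i]]
    seq[s2 : s2 + rep_len] = copy2
    # clean flanks: force the 6 columns beyond each copy end to disagree
    for j in range(1, 7):
        for a, b in ((s1 - j, s2 - j), (s1 + rep_len - 1 + j, s2 + rep_len - 1 + j)):
            if seq[a] == seq[b]:
                seq[b] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[b]]
    region = RegionRecord(id="test", sequence="".join(seq))
    return region, (s1, s1 + rep_len), (s2, s2 + rep_len)


def _anchor(region):
    orf = CdsFeature(0, min(90, len(region.sequence)), "+")
    return RtHit(region_id=region.id, orf=orf)


def test_exact_planted_repeat_found(rng):
    region, span1, span2 = _region_with_repeat(rng)
    (pair,) = detect.find_repeat_pairs(region, _anchor(region), DetectionParams())
    assert (pair.copy1_start, pair.copy1_end) == span1
    assert (pair.copy2_start, pair.copy2_end) == span2
    assert pair.length == 117
    assert pair.mismatch_columns == []


def test_mismatched_planted_repeat_found_with_columns(rng):
    cols = [10, 25, 26, 40, 55, 60, 62, 70, 80, 88, 90, 99, 101, 110]
    region, span1, span2 = _region_with_repeat(rng, mismatches=cols)
    (pair,) = detect.find_repeat_pairs(region, _anchor(region), DetectionParams())
    assert (pair.copy1_start, pair.copy1_end) == span1
    assert (pair.copy2_start, pair.copy2_end) == span2
    assert pair.mismatch_columns == cols


def _brute_force_exact_repeats(seq, min_len):
    """O(n^2) oracle: does any exact duplicated substring >= min_len exist?"""
    seen = {}
    for i in range(len(seq) - min_len + 1):
        sub = seq[i : i + min_len]
        if sub in seen and i - seen[sub] >= min_len:
            return True
        seen.setdefault(sub, i)
    return False


def test_repeat_free_region_agrees_with_brute_force(rng):
    params = DetectionParams()
    for _ in range(5):
        seq = random_dna(2000, rng)
        region = RegionRecord(id="r", sequence=seq)
        pairs = detect.find_repeat_pairs(region, _anchor(region), params)
        exact = [p for p in pairs if not p.mismatch_columns]
        assert bool(exact) == _brute_force_exact_repeats(seq, params.min_repeat_len)
        assert pairs == []  # 2 kb of random sequence has no 40 bp near-repeat


def test_anchor_outside_region_is_an_error(rng):
    region = RegionRecord(id="r", sequence=random_dna(500, rng))
    bad = RtHit(region_id="r", orf=CdsFeature(400, 700, "+"))
    with pytest.raises(ValueError, match="outside region"):
        detect.find_repeat_pairs(region, bad, DetectionParams())


def _pair_on(region, s1, s2, length):
    c1 = region.sequence[s1 : s1 + length]
    c2 = region.sequence[s2 : s2 + length]
    cols = [i for i, (a, b) in enumerate(zip(c1, c2)) if a != b]
    return RepeatPair(
        region_id=region.id,
        copy1_start=s1,
        copy1_end=s1 + length,
        copy2_start=s2,
        copy2_end=s2 + length,
        length=length,
        mismatch_columns=cols,
    )


def test_orientation_by_adenine_ownership():
    # copy1 owns A at every mismatch column -> copy1 is the template repeat
    c1 = "AAAAAAAAAAAAAA" + "GCGCGC"
    c2 = "CCCCCCCCCCCCCC" + "GCGCGC"
    region = RegionRecord(id="r", sequence=c1 + "TTTTTTTTTT" + c2)
    pair = _pair_on(region, 0, 30, 20)
    tr, vr, flag = detect.orient_tr_vr(pair, region)
    assert tr == (0, 20) and vr == (30, 50) and flag is False


def test_orientation_tie_broken_by_cds_overlap():
    c1 = "AAAGGG" + "TCTCTCTCTC"
    c2 = "GGGAAA" + "TCTCTCTCTC"
    region = RegionRecord(
        id="r",
        sequence=c1 + "TTTTTTTTTT" + c2 + "TT",
        features=[CdsFeature(26, 44, "+")],  # covers copy2 only
    )
    pair = _pair_on(region, 0, 26, 16)
    tr, vr, flag = detect.orient_tr_vr(pair, region)
    assert tr == (0, 16) and vr == (26, 42) and flag is False


def test_orientation_tie_without_evidence_flags_ambiguity():
    c1 = "AAAGGG" + "TCTCTCTCTC"
    c2 = "GGGAAA" + "TCTCTCTCTC"
    region = RegionRecord(id="r", sequence=c1 + "TTTTTTTTTT" + c2 + "TT")
    pair = _pair_on(region, 0, 26, 16)
    tr, vr, flag = detect.orient_tr_vr(pair, region)
    assert tr == (0, 16) and flag is True


def test_orientation_undefined_for_identical_repeats():
    region = RegionRecord(id="r", sequence="ACGTACGTAC" * 6)
    pair = _pair_on(region, 0, 20, 10)
    assert pair.mismatch_columns == []
    with pytest.raises(ValueError, match="orientation undefined"):
        detect.orient_tr_vr(pair, region)


def test_orientation_symmetric_under_copy_relabeling(planted):
    region, truth = planted
    length = truth.tr_span[1] - truth.tr_span[0]
    fwd = _pair_on(region, truth.vr_span[0], truth.tr_span[0], length)
    # relabel: present the same duplication with the copies swapped
    swapped = RepeatPair(
        region_id=region.id,
        copy1_start=fwd.copy2_start,
        copy1_end=fwd.copy2_end,
        copy2_start=fwd.copy1_start,
        copy2_end=fwd.copy1_end,
        length=length,
        mismatch_columns=fwd.mismatch_columns,
    )
    assert detect.orient_tr_vr(fwd, region)[:2] == detect.orient_tr_vr(swapped, region)[:2]


class TestAdenineBias:
    def test_fully_adenine_specific(self):
        tr = "A" * 14 + "GCGCGC"
        vr = "C" * 14 + "GCGCGC"
        total, adenine, fraction, p = detect.adenine_bias(tr, vr)
        assert (total, adenine, fraction) == (14, 14, 1.0)

    def test_identical_sequences_null_result(self):
        assert detect.adenine_bias("ACGT", "ACGT") == (0, 0, None, None)

    def test_two_mismatch_example_matches_enumeration(self):
        tr = "AAAACCCC"
        vr = "AAAGGCCC"  # one adenine column and one cytosine column changed
        total, adenine, fraction, p = detect.adenine_bias(tr, vr)
        assert (total, adenine, fraction) == (2, 1, 0.5)
        # exact binomial tail with n=2, p=f_A=0.5: P(X>=1) = 0.75
        assert p == pytest.approx(0.75, abs=1e-12)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            detect.adenine_bias("ACGT", "ACG")

    def test_pvalue_matches_exact_enumeration_oracle(self, rng):
        """Binomial tail from scipy agrees with direct enumeration for all
        pairs with <= 12 mismatches."""
        for _ in range(30):
            n = int(rng.integers(60, 120))
            tr = random_dna(n, rng)
            k = int(rng.integers(1, 13))
            vr = list(tr)
            cols = rng.choice(n, size=k, replace=False)
            for c in cols:
                vr[c] = "ACGT".replace(tr[c], "")[rng.integers(3)]
            total, adenine, _, p = detect.adenine_bias(tr, "".join(vr))
            assert total == k
            f_a = tr.count("A") / n
            oracle = sum(
                comb(total, j) * f_a**j * (1 - f_a) ** (total - j)
                for j in range(adenine, total + 1)
            )
            assert p == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_full_bias_implies_adenine_only_divergence(self, planted):
        region, truth = planted
        tr = region.sequence[truth.tr_span[0] : truth.tr_span[1]]
        vr = region.sequence[truth.vr_span[0] : truth.vr_span[1]]
        total, adenine, fraction, _ = detect.adenine_bias(tr, vr)
        assert fraction == 1.0
        assert all(tr[i] == "A" for i in range(len(tr)) if tr[i] != vr[i])


class TestCallDgr:
    def test_planted_cassette_recovered_exactly(self, planted):
        region, truth = planted
        (cassette,) = detect.call_dgr(region, detect.motif_rt_scan(region))
        assert cassette.tr_span == truth.tr_span
        assert cassette.vr_span == truth.vr_span
        assert cassette.adenine_mismatch_count == truth.adenine_mismatches
        assert cassette.rank == 1
        assert cassette.target_orf.product.startswith("hypothetical protein (DGR")

    def test_below_threshold_cassette_rejected(self):
        region, _ = plant_cassette(SimParams(seed=5), force_mismatches=6)
        assert detect.call_dgr(region, detect.motif_rt_scan(region)) == []

    def test_no_rt_hits_returns_empty(self, planted):
        region, _ = planted
        assert detect.call_dgr(region, []) == []

    def test_strand_robustness(self, planted):
        """Scanning the reverse complement finds the same cassette after
        coordinate reflection."""
        region, truth = planted
        rc = region.reverse_complement()
        (cassette,) = detect.call_dgr(rc, detect.motif_rt_scan(rc))
        n = len(region.sequence)
        reflect = lambda span: (n - span[1], n - span[0])
        assert cassette.tr_span == reflect(truth.tr_span)
        assert cassette.vr_span == reflect(truth.vr_span)
        assert cassette.adenine_mismatch_count == truth.adenine_mismatches


class TestMotifRtScan:
    def _orf(self, translation, start=0):
        end = start + 3 * (len(translation) + 1)
        return CdsFeature(start, end, "+", translation=translation)

    def test_motif_bearing_long_orf_flagged(self, rng):
        prot = "M" + "".join(np.random.default_rng(1).choice(list("ACEFGHIKLNPQRSTVW"), 348)) + "QGYADD"
        region = RegionRecord(
            id="r", sequence=random_dna(3000, rng), features=[self._orf(prot)]
        )
        (hit,) = detect.motif_rt_scan(region)
        assert hit.source == "motif"

    def test_short_orf_with_motif_not_flagged(self, rng):
        region = RegionRecord(
            id="r", sequence=random_dna(1000, rng), features=[self._orf("M" * 94 + "QGYADD")]
        )
        assert detect.motif_rt_scan(region) == []

    def test_region_without_cds_empty(self, rng):
        region = RegionRecord(id="r", sequence=random_dna(100, rng))
        assert detect.motif_rt_scan(region) == []
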