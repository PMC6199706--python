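"""Coverage computation from SAM, the activity rule, and the naive mapper."""

import numpy as np
import pytest

from dgrscan.activity import classify_active, coverage_from_sam, naive_map
from dgrscan.model import CoverageProfile, RegionRecord, SimParams, revcomp
from dgrscan.simulate import plant_cassette, random_dna, synth_reads


def _sam(tmp_path, region_id, region_len, records):
    path = tmp_path / "in.sam"
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{region_id}\tLN:{region_len}"]
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def _rec(name, pos, seq, nm=0, flag=0, cigar=None):
    cigar = cigar or f"{len(seq)}M"
    return "\t".join(
        [name, str(flag), "reg", str(pos), "60", cigar, "*", "0", "0", seq, "*",
         f"NM:i:{nm}"]
    )


def test_uniform_tiling_mean_and_breadth(tmp_path):
    # 100 reads of length 100 tiled over a 1000 bp region: 10x everywhere
    records = [_rec(f"r{i}", (i % 10) * 100 + 1, "A" * 100) for i in range(100)]
    path = _sam(tmp_path, "reg", 1000, records)
    prof = coverage_from_sam(path, "reg", 1000)
    assert prof.mean_fold == pytest.approx(10.0)
    assert prof.breadth == 1.0
    assert prof.n_reads_used == 100


def test_empty_sam_zero_profile(tmp_path):
    path = _sam(tmp_path, "reg", 500, [])
    prof = coverage_from_sam(path, "reg", 500)
    assert prof.mean_fold == 0.0 and prof.breadth == 0.0 and prof.n_reads_used == 0


def test_identity_filter_boundary(tmp_path):
    # 100 bp read with NM=4 has identity 0.96
    path = _sam(tmp_path, "reg", 500, [_rec("r", 1, "A" * 100, nm=4)])
    assert coverage_from_sam(path, "reg", 500, identity_threshold=0.97).n_reads_used == 0
    assert coverage_from_sam(path, "reg", 500, identity_threshold=0.95).n_reads_used == 1


def test_deletion_spans_excluded_from_depth(tmp_path):
    # 10M5D10M: 20 aligned columns of depth over a 25-column reference span
    path = _sam(tmp_path, "reg", 100, [_rec("r", 1, "A" * 20, cigar="10M5D10M")])
    prof = coverage_from_sam(path, "reg", 100)
    assert sum(prof.depth) == 20
    assert prof.depth[:10] == [1] * 10 and prof.depth[10:15] == [0] * 5


def test_secondary_and_unmapped_excluded(tmp_path):
    records = [
        _rec("r1", 1, "A" * 50),
        _rec("r2", 1, "A" * 50, flag=256),  # secondary
        _rec("r3", 1, "A" * 50, flag=2048),  # supplementary
        "\t".join(["r4", "4", "*", "0", "0", "*", "*", "0", "0", "A" * 50, "*"]),
    ]
    prof = coverage_from_sam(_sam(tmp_path, "reg", 500, records), "reg", 500)
    assert prof.n_reads_used == 1


def test_missing_sq_header_is_error(tmp_path):
    path = tmp_path / "nosq.sam"
    path.write_text("@HD\tVN:1.6\n")
    with pytest.raises(ValueError, match="@SQ"):
        coverage_from_sam(str(path), "reg", 100)


def test_missing_nm_with_identity_filter_names_record(tmp_path):
    rec = "\t".join(
        ["badrec", "0", "reg", "1", "60", "50M", "*", "0", "0", "A" * 50, "*"]
    )
    path = _sam(tmp_path, "reg", 500, [rec])
    with pytest.raises(ValueError, match="badrec"):
        coverage_from_sam(path, "reg", 500, identity_threshold=0.97)


def test_activity_rule_strict_boundary_and_monotone():
    mk = lambda m: CoverageProfile("r", [], m, 1.0, 0)
    assert classify_active(mk(10.0)) == "inactive"
    assert classify_active(mk(10.0001)) == "active"
    assert classify_active(mk(229.0)) == "active"
    assert classify_active(mk(0.0)) == "inactive"
    verdicts = [classify_active(mk(m)) for m in np.linspace(0, 30, 40)]
    assert verdicts == sorted(verdicts, key=lambda v: v == "active")


class TestNaiveMap:
    def test_exact_read_placement(self, rng):
        region = RegionRecord(id="ref", sequence=random_dna(2000, rng))
        read = region.sequence[500:600]
        sam = naive_map([("r1", read)], region)
        fields = sam.strip().splitlines()[-1].split("\t")
        assert fields[1] == "0" and fields[3] == "501" and fields[11] == "NM:i:0"

    def test_substitutions_outside_seed_counted_in_nm(self, rng):
        region = RegionRecord(id="ref", sequence=random_dna(2000, rng))
        read = list(region.sequence[500:600])
        for i in (40, 70):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        sam = naive_map([("r1", "".join(read))], region)
        fields = sam.strip().splitlines()[-1].split("\t")
        assert fields[3] == "501" and fields[11] == "NM:i:2"

    def test_reverse_complement_read_mapped(self, rng):
        region = RegionRecord(id="ref", sequence=random_dna(2000, rng))
        read = revcomp(region.sequence[300:400])
        sam = naive_map([("r1", read)], region)
        fields = sam.strip().splitlines()[-1].split("\t")
        assert fields[1] == "16" and fields[3] == "301"

    def test_foreign_reads_unmapped(self, rng):
        """Reads from an unrelated sequence never seed on a 50 kb reference
        (expected 31-mer collisions ~ n_reads * 5e4 / 4^31 ~ 1e-13)."""
        region = RegionRecord(id="ref", sequence=random_dna(50_000, rng))
        foreign = [(f"f{i}", random_dna(100, rng)) for i in range(50)]
        sam = naive_map(foreign, region)
        body = [l for l in sam.splitlines() if not l.startswith("@")]
        assert all(l.split("\t")[1] == "4" for l in body)


def test_depth_conservation_and_fold_recovery(tmp_path, rng):
    """Reads generated at fold c and mapped naively conserve aligned columns
    exactly and recover the mean fold within 10% for c in {5, 10, 20}."""
    region, _ = plant_cassette(SimParams(seed=11))
    for fold in (5, 10, 20):
        reads = synth_reads(region, fold, 100, 0.0, rng)
        sam_text = naive_map(reads, region)
        path = tmp_path / f"c{fold}.sam"
        path.write_text(sam_text)
        prof = coverage_from_sam(str(path), region.id)
        mapped_cols = sum(
            len(l.split("\t")[9])
            for l in sam_text.splitlines()
            if not l.startswith("@") and l.split("\t")[1] != "4"
        )
        assert sum(prof.depth) == mapped_cols
        assert prof.mean_fold == pytest.approx(fold, rel=0.10)
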