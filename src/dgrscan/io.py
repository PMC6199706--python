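"""Readers and writers for the standard formats the toolkit touches.

FASTA and GenBank parsing go through Biopython; HMMER domtblout and the TSV /
GFF3 reports are simple columnar text handled here.  GenBank's 1-based
inclusive coordinates are converted to the internal 0-based half-open
convention on read and back on write.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import CdsFeature, DgrCassette, RegionRecord, RtHit

_NON_ACGTN = re.compile(r"[^ACGTN]")


def genbank_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_genbank(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    n_bad = len(_NON_ACGTN.findall(seq))
    if n_bad:
        warnings.warn(
            f"record {record_id!r}: {n_bad} non-ACGTN base(s) replaced with N",
            stacklevel=3,
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def read_fasta(path: str) -> list[RegionRecord]:
    """Read a (multi-)FASTA file into RegionRecords.

    Sequences are upper-cased, U is converted to T, and any other non-ACGTN
    character becomes N (with a warning).  Duplicate ids or an empty file are
    errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            RegionRecord(
                id=rec.id,
                sequence=_clean_sequence(str(rec.seq), rec.id),
                source=str(path),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _translation_from_qualifiers(feat) -> Optional[str]:
    tr = feat.qualifiers.get("translation")
    return tr[0] if tr else None


def read_genbank(path: str) -> RegionRecord:
    """Read a single-locus GenBank flatfile with its CDS features.

    join/complement locations are handled by Biopython; the feature interval
    stored is the envelope (min start, max end).  A CDS translation comes from
    the /translation qualifier when present, otherwise it is computed with the
    bacterial genetic code (table 11).
    """
    try:
        rec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: not a single-locus GenBank file ({exc})") from exc
    seq = _clean_sequence(str(rec.seq), rec.id)
    if not seq:
        raise ValueError(f"{path}: missing or empty ORIGIN sequence")
    features = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        if feat.location is None:
            warnings.warn(f"{path}: CDS without location skipped")
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        translation = _translation_from_qualifiers(feat)
        if translation is None:
            cds_seq = feat.location.extract(rec.seq)
            translation = str(Seq(cds_seq).translate(table=11, to_stop=True))
        product = feat.qualifiers.get("product", [""])[0]
        features.append(
            CdsFeature(
                start=start,
                end=end,
                strand=strand,
                product=product,
                translation=translation,
            )
        )
    features.sort(key=lambda f: (f.start, f.end))
    return RegionRecord(id=rec.id, sequence=seq, features=features, source=str(path))


def write_genbank(region: RegionRecord, path: str) -> None:
    """Write a RegionRecord as a minimal GenBank flatfile (test fixtures)."""
    rec = SeqRecord(
        Seq(region.sequence),
        id=region.id,
        name=region.id[:16],
        description="",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for f in region.features:
        qualifiers = {}
        if f.product:
            qualifiers["product"] = [f.product]
        if f.translation:
            qualifiers["translation"] = [f.translation]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    SeqIO.write(rec, path, "genbank")


# HMMER3 domtblout has 22 fixed whitespace-separated columns followed by a
# free-text description.
_DOMTBL_MIN_COLS = 22


def read_domtbl(
    path: str,
    region: Optional[RegionRecord] = None,
    accession: str = "PF00078",
) -> list[RtHit]:
    """Parse HMMER3 per-domain tabular output into reverse-transcriptase hits.

    Rows whose query or target accession matches ``accession`` (version suffix
    like ``.17`` ignored) are kept.  When ``region`` is given, hit names of the
    form ``<region_id>_<orf_index>`` (1-based, Prodigal style) are mapped onto
    the region's CDS features; unmapped names get a placeholder ORF spanning
    nothing and are dropped with a warning.
    """
    hits: list[RtHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            target_acc = cols[1].split(".")[0]
            query_acc = cols[4].split(".")[0]
            if accession not in (target_acc, query_acc):
                continue
            # domtblout layout: whichever of target/query is the sequence, the
            # other is the profile; the sequence name is the one that is not
            # the matching accession's companion name.
            seq_name = cols[0] if query_acc == accession else cols[3]
            score = float(cols[7])
            orf = None
            region_id = seq_name
            if region is not None:
                m = re.match(rf"^{re.escape(region.id)}_(\d+)$", seq_name)
                if m:
                    idx = int(m.group(1)) - 1
                    if 0 <= idx < len(region.features):
                        orf = region.features[idx]
                        region_id = region.id
                if orf is None:
                    warnings.warn(
                        f"{path}:{lineno}: hit {seq_name!r} does not map onto an "
                        f"ORF of region {region.id!r}; skipped"
                    )
                    continue
            else:
                orf = CdsFeature(start=0, end=3, strand="+")
            hits.append(RtHit(region_id=region_id, orf=orf, score=score, source="domtbl"))
    return hits


_TSV_COLUMNS = [
    "region_id",
    "rank",
    "rt_start",
    "rt_end",
    "rt_strand",
    "tr_start",
    "tr_end",
    "vr_start",
    "vr_end",
    "repeat_length",
    "tr_adenine_count",
    "adenine_mismatches",
    "total_mismatches",
    "adenine_bias_fraction",
    "bias_pvalue",
    "target_product",
    "vr_residue_start",
    "vr_residue_end",
    "ambiguous_orientation",
]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _cassette_row(c: DgrCassette) -> list[str]:
    rt1, rt2 = internal_to_genbank(c.rt.orf.start, c.rt.orf.end)
    tr1, tr2 = internal_to_genbank(*c.tr_span)
    vr1, vr2 = internal_to_genbank(*c.vr_span)
    res = c.vr_residue_span
    return [
        _fmt(v)
        for v in [
            c.region_id,
            c.rank,
            rt1,
            rt2,
            c.rt.orf.strand,
            tr1,
            tr2,
            vr1,
            vr2,
            c.repeat_pair.length,
            c.tr_adenine_count,
            c.adenine_mismatch_count,
            c.total_mismatch_count,
            c.adenine_bias_fraction,
            c.bias_pvalue,
            c.target_orf.product if c.target_orf else None,
            res[0] if res else None,
            res[1] if res else None,
            c.ambiguity_flag,
        ]
    ]


def write_cassette_report(
    cassettes: Iterable[DgrCassette], path: str, format: str = "tsv"
) -> None:
    """Write cassettes as a TSV table or linked GFF3 features.

    All coordinates in the output are 1-based inclusive.  Output is
    byte-stable for a fixed input order.
    """
    cassettes = list(cassettes)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for c in cassettes:
                fh.write("\t".join(_cassette_row(c)) + "\n")
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, c in enumerate(cassettes, 1):
                cid = f"dgr{i:03d}"
                rows = [
                    ("reverse_transcriptase", c.rt.orf.start, c.rt.orf.end,
                     c.rt.orf.strand, f"ID={cid}.RT;Parent={cid}"),
                    ("template_repeat", c.tr_span[0], c.tr_span[1], "+",
                     f"ID={cid}.TR;Parent={cid}"),
                    ("variable_repeat", c.vr_span[0], c.vr_span[1], "+",
                     f"ID={cid}.VR;Parent={cid};"
                     f"adenine_mismatches={c.adenine_mismatch_count}"),
                ]
                for ftype, s, e, strand, attrs in rows:
                    s1, e1 = internal_to_genbank(s, e)
                    fh.write(
                        "\t".join(
                            [c.region_id, "dgrscan", ftype, str(s1), str(e1),
                             ".", strand, ".", attrs]
                        )
                        + "\n"
                    )
    else:
        raise ValueError(f"unknown report format {format!r}")
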