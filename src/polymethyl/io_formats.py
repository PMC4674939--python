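"""Readers and writers for the pipeline's external formats.

Conventions: FASTA for references; SAM for alignments with the methylation
string in tag XM and the conversion state in tag XG (CT/GA; the full strand
product is mirrored in tag XP); TSV with headers for SNP catalogues,
expression and result tables; BED-like TSV (0-based half-open, class in
column 4, region id in column 5, linked gene in column 6) for region
annotations. SAM and TSV positions are 1-based on disk and converted to
0-based half-open exactly once on ingest; BED stays 0-based.

All writers are deterministic: stable row order, floats at 4 significant
digits, ``.`` for missing values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .extraction import classify_context
from .records import (
    CONTEXT_BY_SYMBOL,
    AllelicExpression,
    BisulfiteRead,
    HomoeologousSNP,
    RegionAnnotation,
    ANNOTATION_CLASSES,
)

logger = logging.getLogger(__name__)

_MISSING = "."
_PRODUCT_BY_XG = {"CT": "OT", "GA": "OB"}
_VALID_XM = set("ZzXxHhUu.")


def fmt(value) -> str:
    """4-significant-digit float formatting; '.' for missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return _MISSING
    if isinstance(value, float):
        return f"{value:.4g}"
    return str(value)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# SAM alignments


def write_alignments(reads: Iterable[BisulfiteRead], path,
                     reference: dict[str, str]) -> None:
    """Write reads as SAM. Sequences are stored on the forward reference
    strand for every product (flags stay 0); XG records the conversion
    state, XP the strand product."""
    names = list(reference)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": len(reference[n])} for n in names]}
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            a.reference_id = idx[read.contig]
            a.reference_start = read.pos
            a.mapping_quality = read.mapq
            a.query_sequence = read.seq
            a.cigarstring = f"{len(read.seq)}M"
            a.flag = 0
            a.set_tag("XM", read.xm, "Z")
            a.set_tag("XG", read.xg, "Z")
            a.set_tag("XP", read.strand_of_origin, "Z")
            out.write(a)


@dataclass
class AlignmentIngest:
    reads: list[BisulfiteRead] = field(default_factory=list)
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1
        logger.info("skipped alignment record: %s", reason)


def read_alignments(path, reference: dict[str, str],
                    validate: bool = True) -> AlignmentIngest:
    """Ingest SAM alignments, validating each record against the reference.

    Invalid records (missing/short methylation string, bad symbols, symbol
    context disagreeing with the reference) are skipped and counted per
    reason; a malformed header is fatal (raised by the SAM parser).
    """
    result = AlignmentIngest()
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        for a in fh:
            if a.is_unmapped or a.reference_name is None:
                result.skip("unmapped")
                continue
            if not a.has_tag("XM"):
                result.skip("missing_xm")
                continue
            xm = a.get_tag("XM")
            seq = a.query_sequence or ""
            if len(xm) != len(seq):
                result.skip("xm_length_mismatch")
                continue
            xg = a.get_tag("XG") if a.has_tag("XG") else "CT"
            if xg not in ("CT", "GA"):
                result.skip("bad_xg")
                continue
            product = (a.get_tag("XP") if a.has_tag("XP")
                       else _PRODUCT_BY_XG[xg])
            read = BisulfiteRead(
                read_id=a.query_name, contig=a.reference_name,
                pos=a.reference_start, mapq=a.mapping_quality,
                strand_of_origin=product, seq=seq, xm=xm)
            if validate and not _validate_read(read, reference, result):
                continue
            result.reads.append(read)
    return result


def _validate_read(read: BisulfiteRead, reference: dict[str, str],
                   result: AlignmentIngest) -> bool:
    if read.contig not in reference:
        result.skip("unknown_contig")
        return False
    seq = reference[read.contig]
    if read.pos + len(read) > len(seq):
        result.skip("out_of_bounds")
        return False
    strand = "+" if read.xg == "CT" else "-"
    for offset, sym in enumerate(read.xm):
        if sym not in _VALID_XM:
            result.skip("bad_symbol")
            return False
        if sym == _MISSING:
            continue
        ctx = CONTEXT_BY_SYMBOL[sym]
        pos = read.pos + offset
        base = seq[pos]
        expected = "C" if strand == "+" else "G"
        if base != expected:
            result.skip("symbol_at_non_cytosine")
            return False
        if ctx != "unknown" and classify_context(seq, pos, strand) != ctx:
            result.skip("context_mismatch")
            return False
    return True


# ---------------------------------------------------------------------------
# SNP catalogue TSV

_SNP_COLUMNS = ["contig", "pos_1based", "allele_A", "allele_B", "allele_D",
                "source"]


def write_snp_catalog(snps: Sequence[HomoeologousSNP], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SNP_COLUMNS) + "\n")
        for snp in sorted(snps, key=lambda s: (s.contig, s.pos)):
            fh.write("\t".join([snp.contig, str(snp.pos + 1), snp.allele_a,
                                snp.allele_b, snp.allele_d, snp.source]) + "\n")


def read_snp_catalog(path) -> list[HomoeologousSNP]:
    """Parse a SNP catalogue TSV (1-based positions on disk).

    Fatal errors name the offending line: alleles outside {A,C,G,T} and
    duplicate (contig, position) keys.
    """
    out: list[HomoeologousSNP] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != _SNP_COLUMNS[:5]:
            raise ValueError(f"unexpected SNP catalogue header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            contig, pos1, a, b, d = fields[:5]
            source = fields[5] if len(fields) > 5 else "progenitor"
            for allele in (a, b, d):
                if allele not in "ACGT" or len(allele) != 1:
                    raise ValueError(
                        f"{path}:{lineno}: allele {allele!r} not in A/C/G/T")
            key = (contig, int(pos1) - 1)
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate position {contig}:{pos1}")
            seen.add(key)
            out.append(HomoeologousSNP(contig, int(pos1) - 1, a, b, d, source))
    return out


# ---------------------------------------------------------------------------
# BED-like region annotations


def write_regions_bed(regions: Sequence[RegionAnnotation], path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.contig, r.start)):
            fh.write("\t".join([r.contig, str(r.start), str(r.end), r.cls,
                                r.region_id, r.gene_id or _MISSING]) + "\n")


def read_regions_bed(path) -> list[RegionAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            contig, start, end, cls = fields[:4]
            if cls not in ANNOTATION_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown class {cls!r}")
            region_id = fields[4] if len(fields) > 4 else f"{contig}:{start}-{end}"
            gene = fields[5] if len(fields) > 5 and fields[5] != _MISSING else None
            out.append(RegionAnnotation(region_id, contig, int(start), int(end),
                                        cls, gene))
    return out


# ---------------------------------------------------------------------------
# expression TSV

_EXPR_COLUMNS = ["region", "raw_A", "raw_B", "raw_D",
                 "pplr_A", "pplr_B", "pplr_D"]


def write_expression_table(expression: Sequence[AllelicExpression], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EXPR_COLUMNS) + "\n")
        for e in sorted(expression, key=lambda e: e.region_id):
            row = [e.region_id] + [fmt(float(v)) for v in e.raw] \
                + [fmt(v if v is None else float(v)) for v in e.pplr]
            fh.write("\t".join(row) + "\n")


def read_expression_table(path) -> list[AllelicExpression]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EXPR_COLUMNS:
            raise ValueError(f"unexpected expression header: {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            raw = tuple(float(v) for v in f[1:4])
            pplr = tuple(None if v == _MISSING else float(v) for v in f[4:7])
            out.append(AllelicExpression(f[0], raw, pplr))
    return out


# ---------------------------------------------------------------------------
# result tables


def write_table(df: pd.DataFrame, path, pos_columns: Sequence[str] = ()) -> None:
    """Write a result DataFrame as TSV: stable column order as given,
    1-based positions for the named columns, 4-significant-digit floats,
    '.' for missing."""
    df = df.copy()
    for col in pos_columns:
        if col in df:
            df[col] = df[col].astype(int) + 1
            df = df.rename(columns={col: f"{col.split('_')[0]}_1based"})
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(fmt(v) for v in row) + "\n")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING])
    for col in list(df.columns):
        if col.endswith("_1based"):
            base = col.replace("_1based", "")
            df[base] = df[col].astype(int) - 1
            df = df.drop(columns=[col])
    return df
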