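"""Alignment, annotation and SNP-mask parsing with read/base exclusion rules.

All coordinates are 0-based half-open internally.  SAM (1-based) and VCF
(1-based) are converted at parse time; BED passes through unchanged.

Mismatch extraction reconstructs the reference from the MD and CIGAR tags of
each aligned read, so no reference FASTA is needed to call edits.  Soft
clips consume no reference and are never inspected; bases involving ``N``
(read or reference) are never counted as mismatch or coverage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedReadRecord",
    "ReadFilterConfig",
    "MismatchObservation",
    "TranscriptModel",
    "MDConsistencyError",
    "stream_reads",
    "extract_mismatches",
    "iter_aligned_bases",
    "load_transcript_models",
    "load_snp_mask",
    "load_whitelist",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# SAM flag bits
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_QC_FAIL = 0x200
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

# value of the 10x ``xf`` tag marking the confidently mapped representative
# read of a UMI; reads without it are UMI duplicates in single-cell mode
XF_UMI_REPRESENTATIVE = 25


class MDConsistencyError(ValueError):
    """MD tag does not agree with the CIGAR/sequence of the read."""


@dataclass(frozen=True)
class ReadFilterConfig:
    """Read- and base-level exclusion thresholds.

    ``require_umi_rep_tag`` defaults to True for short-read single-cell
    mode (the ``xf:i:25`` convention of 10x alignments); long-read and bulk
    pipelines deduplicate upstream and should pass False.
    """

    min_mapq: int = 0
    min_base_qual: int = 20
    min_dist_from_end: int = 5
    require_umi_rep_tag: bool = True
    barcode_whitelist: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_base_qual, self.min_dist_from_end) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class AlignedReadRecord:
    """One aligned read with barcode/isoform tags and mismatch descriptors."""

    read_id: str
    contig: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    cigar: str
    md: str | None
    seq: str
    base_quals: list[int]
    mapq: int
    flags: int
    barcode: str | None = None
    isoform_id: str | None = None
    has_umi_rep_tag: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if len(self.seq) != len(self.base_quals):
            raise ValueError("seq and base_quals length mismatch")
        qlen = _cigar_query_length(self.cigar)
        if qlen != len(self.seq):
            raise ValueError(
                f"CIGAR consumes {qlen} query bases but seq has {len(self.seq)}"
            )

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedReadRecord":
        tags = dict(aln.get_tags())
        return cls(
            read_id=aln.query_name,
            contig=aln.reference_name,
            start=aln.reference_start,
            strand="-" if aln.is_reverse else "+",
            cigar=aln.cigarstring,
            md=tags.get("MD"),
            seq=aln.query_sequence or "",
            base_quals=list(aln.query_qualities or []),
            mapq=aln.mapping_quality,
            flags=aln.flag,
            barcode=tags.get("CB"),
            isoform_id=tags.get("IB") or tags.get("IS"),
            has_umi_rep_tag=tags.get("xf") == XF_UMI_REPRESENTATIVE,
        )

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + _cigar_reference_length(self.cigar)


@dataclass(frozen=True)
class MismatchObservation:
    """A single-base substitution observed on one read."""

    contig: str
    pos: int  # 0-based genomic
    ref_base: str
    alt_base: str
    read_strand: str
    barcode: str | None
    isoform_id: str | None
    base_qual: int
    dist_from_end: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")


@dataclass
class TranscriptModel:
    """Exon/CDS/UTR geometry of one transcript (0-based half-open)."""

    transcript_id: str
    gene_id: str
    biotype: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, _e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


# ----------------------------------------------------------------------
# CIGAR / MD machinery
# ----------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def _cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in _parse_cigar(cigar) if op in _QUERY_OPS)


def _cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in _parse_cigar(cigar) if op in _REF_OPS)


def _parse_md(md: str) -> list:
    """Tokenize an MD tag into ints (match runs), '^...' deletions and letters."""
    tokens: list = []
    consumed = 0
    for m in _MD_RE.finditer(md):
        consumed += len(m.group(0))
        if m.group(1) is not None:
            tokens.append(int(m.group(1)))
        elif m.group(2) is not None:
            tokens.append(m.group(2))
        else:
            tokens.append(m.group(3).upper())
    if consumed != len(md):
        raise MDConsistencyError(f"malformed MD tag: {md!r}")
    return tokens


def iter_aligned_bases(read: AlignedReadRecord) -> Iterator[tuple[int, int]]:
    """Yield (query_offset, reference_position) for every aligned base.

    Insertions and soft clips advance only the query; deletions and splice
    skips advance only the reference, so positions under them are not
    yielded.
    """
    q, r = 0, read.start
    for n, op in _parse_cigar(read.cigar):
        if op in "M=X":
            for i in range(n):
                yield q + i, r + i
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
        # H and P consume nothing


class _MDWalker:
    """Consumes MD tokens in step with reference-consuming CIGAR ops."""

    def __init__(self, md: str):
        self._tokens = _parse_md(md)
        self._i = 0
        self._match_credit = 0

    def step_aligned(self) -> str | None:
        """Advance one aligned (M/=/X) base; return ref base if mismatched."""
        while True:
            if self._match_credit > 0:
                self._match_credit -= 1
                return None
            if self._i >= len(self._tokens):
                raise MDConsistencyError("MD tag exhausted before CIGAR")
            tok = self._tokens[self._i]
            self._i += 1
            if isinstance(tok, int):
                self._match_credit = tok
                continue  # zero-length runs separate adjacent mismatches
            if tok.startswith("^"):
                raise MDConsistencyError("MD deletion where CIGAR aligns")
            return tok

    def step_deletion(self, length: int) -> None:
        # skip a zero match-run that may precede the deletion token
        while self._i < len(self._tokens) and self._tokens[self._i] == 0 and self._match_credit == 0:
            self._i += 1
        if self._match_credit:
            raise MDConsistencyError("MD match run spans a CIGAR deletion")
        if self._i >= len(self._tokens):
            raise MDConsistencyError("MD tag exhausted at deletion")
        tok = self._tokens[self._i]
        self._i += 1
        if not (isinstance(tok, str) and tok.startswith("^")):
            raise MDConsistencyError("CIGAR deletion without MD '^' token")
        if len(tok) - 1 != length:
            raise MDConsistencyError(
                f"MD deletion length {len(tok) - 1} != CIGAR {length}"
            )

    def finish(self) -> None:
        """Verify the MD tag is fully consumed once the CIGAR is exhausted."""
        if self._match_credit:
            raise MDConsistencyError("MD match run extends past the CIGAR")
        for tok in self._tokens[self._i:]:
            if tok != 0:
                raise MDConsistencyError("unconsumed MD tokens after CIGAR")


def extract_mismatches(
    read: AlignedReadRecord, config: ReadFilterConfig | None = None
) -> list[MismatchObservation]:
    """Reconstruct substituted reference positions from MD/CIGAR/sequence.

    Returns one observation per substituted aligned base that passes the
    base-quality and read-end-proximity filters.  Insertions contribute
    nothing (they consume no reference); deleted reference bases contribute
    nothing (no read base is present); ``N`` read or reference bases are
    ignored.
    """
    config = config or ReadFilterConfig()
    if read.md is None:
        raise MDConsistencyError(f"read {read.read_id} has no MD tag")
    walker = _MDWalker(read.md)
    out: list[MismatchObservation] = []
    q, r = 0, read.start
    qlen = len(read.seq)
    for n, op in _parse_cigar(read.cigar):
        if op in "M=X":
            for i in range(n):
                ref_base = walker.step_aligned()
                if ref_base is not None:
                    alt = read.seq[q + i].upper()
                    if ref_base == alt:
                        raise MDConsistencyError(
                            f"MD mismatch base equals read base at {read.contig}:{r + i}"
                        )
                    if ref_base == "N" or alt == "N":
                        continue
                    dist = min(q + i, qlen - 1 - (q + i))
                    qual = read.base_quals[q + i]
                    if qual < config.min_base_qual or dist < config.min_dist_from_end:
                        continue
                    out.append(
                        MismatchObservation(
                            contig=read.contig,
                            pos=r + i,
                            ref_base=ref_base,
                            alt_base=alt,
                            read_strand=read.strand,
                            barcode=read.barcode,
                            isoform_id=read.isoform_id,
                            base_qual=qual,
                            dist_from_end=dist,
                        )
                    )
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op == "D":
            walker.step_deletion(n)
            r += n
        elif op == "N":
            r += n
    walker.finish()
    return out


# ----------------------------------------------------------------------
# Read streaming
# ----------------------------------------------------------------------


def _read_passes(
    aln: pysam.AlignmentFile, rec: pysam.AlignedSegment, config: ReadFilterConfig
) -> bool:
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_qcfail:
        return False
    if rec.mapping_quality < config.min_mapq:
        return False
    if config.require_umi_rep_tag:
        try:
            if rec.get_tag("xf") != XF_UMI_REPRESENTATIVE:
                return False
        except KeyError:
            return False
    if config.barcode_whitelist is not None:
        try:
            bc = rec.get_tag("CB")
        except KeyError:
            return False
        if bc not in config.barcode_whitelist:
            return False
    return True


def stream_reads(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    config: ReadFilterConfig | None = None,
    counters: dict[str, int] | None = None,
) -> Iterator[AlignedReadRecord]:
    """Yield passing reads from a SAM/BAM file, optionally within a region.

    Excludes unmapped, secondary, supplementary and QC-fail reads, reads
    below ``min_mapq``, UMI duplicates (missing ``xf:i:25``) when
    configured, and reads whose barcode is absent from the whitelist.
    Malformed records are logged, counted and skipped.  Region queries use
    the index when present and fall back to a linear scan otherwise.
    """
    config = config or ReadFilterConfig()
    counters = counters if counters is not None else {}
    counters.setdefault("malformed_skipped", 0)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=True) as fh:
        if region is not None and fh.has_index():
            contig, start, end = region
            it: Iterable[pysam.AlignedSegment] = fh.fetch(contig, start, end)
        else:
            it = fh.fetch(until_eof=True)
        for rec in it:
            if not _read_passes(fh, rec, config):
                continue
            if region is not None:
                contig, start, end = region
                if rec.reference_name != contig:
                    continue
                if rec.reference_start >= end or (rec.reference_end or 0) <= start:
                    continue
            try:
                yield AlignedReadRecord.from_pysam(rec)
            except ValueError as exc:
                counters["malformed_skipped"] += 1
                logger.warning("skipping malformed record %s: %s", rec.query_name, exc)


# ----------------------------------------------------------------------
# Annotation / mask loading
# ----------------------------------------------------------------------


def _subtract_intervals(
    intervals: list[tuple[int, int]], window: tuple[int, int]
) -> list[tuple[int, int]]:
    """Intersect a sorted interval list with a half-open window."""
    lo, hi = window
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def load_transcript_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF into transcript models, deriving UTRs when absent.

    When the GTF carries no explicit UTR features, 5'/3' UTRs are derived
    from exon/CDS geometry: exonic sequence upstream of the CDS on the
    transcript strand is 5' UTR, downstream is 3' UTR.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path), as_df=True)
    if df.empty:
        return {}
    models: dict[str, TranscriptModel] = {}
    has_tx = "transcript_id" in df.columns
    if not has_tx:
        raise ValueError("GTF lacks transcript_id attributes")
    feat = df["Feature"].str.lower()
    utr5_names = {"five_prime_utr", "5utr", "five_prime_utr_variant"}
    utr3_names = {"three_prime_utr", "3utr"}
    for tid, sub in df[df["transcript_id"].notna()].groupby("transcript_id", sort=True):
        f = feat.loc[sub.index]
        exons = [
            (int(r.Start), int(r.End))
            for r in sub[f == "exon"].itertuples()
        ]
        if not exons:
            raise ValueError(f"transcript {tid} has no exon features")
        exons = sorted(exons)
        strand = sub["Strand"].iloc[0]
        contig = str(sub["Chromosome"].iloc[0])
        gene_id = sub["gene_id"].iloc[0]
        biotype = ""
        for col in ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type"):
            if col in sub.columns and sub[col].notna().any():
                biotype = str(sub[col].dropna().iloc[0])
                break
        cds_rows = sub[f == "cds"]
        cds = None
        if not cds_rows.empty:
            cds = (int(cds_rows["Start"].min()), int(cds_rows["End"].max()))
        utr5 = [
            (int(r.Start), int(r.End)) for r in sub[f.isin(utr5_names)].itertuples()
        ]
        utr3 = [
            (int(r.Start), int(r.End)) for r in sub[f.isin(utr3_names)].itertuples()
        ]
        # generic "UTR" features (e.g. Cell Ranger GTFs): classify by CDS side
        utr_generic = [
            (int(r.Start), int(r.End)) for r in sub[f == "utr"].itertuples()
        ]
        if utr_generic and cds is not None:
            for s, e in utr_generic:
                upstream = e <= cds[0]
                if (strand == "+" and upstream) or (strand == "-" and not upstream):
                    utr5.append((s, e))
                else:
                    utr3.append((s, e))
        if not utr5 and not utr3 and cds is not None:
            span = (exons[0][0], exons[-1][1])
            left = _subtract_intervals(exons, (span[0], cds[0]))
            right = _subtract_intervals(exons, (cds[1], span[1]))
            if strand == "+":
                utr5, utr3 = left, right
            else:
                utr5, utr3 = right, left
        models[str(tid)] = TranscriptModel(
            transcript_id=str(tid),
            gene_id=str(gene_id),
            biotype=biotype,
            contig=contig,
            strand=str(strand),
            exons=exons,
            cds=cds,
            utr5=sorted(utr5),
            utr3=sorted(utr3),
        )
    return models


def load_snp_mask(path: str | Path) -> set[tuple[str, int]]:
    """Load known-variant positions from a VCF or BED file as 0-based sites.

    VCF POS is converted from 1-based; multi-allelic records contribute
    their position once.  BED contributes every position in each interval.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    out: set[tuple[str, int]] = set()
    if ".vcf" in suffixes:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                out.add((rec.chrom, rec.pos - 1))
    elif ".bed" in suffixes:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    logger.warning("skipping malformed BED line %d", lineno)
                    continue
                try:
                    contig, start, end = parts[0], int(parts[1]), int(parts[2])
                except ValueError:
                    logger.warning("skipping malformed BED line %d", lineno)
                    continue
                for pos in range(start, end):
                    out.add((contig, pos))
    else:
        raise ValueError(f"unknown SNP mask format: {path.name}")
    return out


def load_whitelist(path: str | Path) -> frozenset[str]:
    """Load a one-barcode-per-line whitelist."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
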