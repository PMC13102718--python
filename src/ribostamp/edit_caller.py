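"""Barcode-aware edit calling: tabulation, coverage, site filters, matrices.

The caller partitions the genome into regions, tabulates every substitution
type at every non-reference position per cell barcode (or cell-isoform
combination) from MD/CIGAR information, computes per-barcode ref/alt
coverage at edited sites, applies the site-filter cascade (multi-edit-type,
SNP mask, minimum total edits, maximum edited fraction, antisense), and
aggregates kept sites into sparse cells x features matrices.

Mismatches are recorded in genomic forward-strand space and re-oriented to
the supporting-read strand before the target-conversion check, so a C-to-U
event on a minus-strand transcript (genomically G>A) is recognised as C>T.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from ribostamp.alignment_io import (
    AlignedReadRecord,
    ReadFilterConfig,
    TranscriptModel,
    extract_mismatches,
    iter_aligned_bases,
    stream_reads,
)
from ribostamp.matrix import CellFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSummary",
    "SiteFilterConfig",
    "GeneIndex",
    "partition_regions",
    "tabulate_edits",
    "build_sites",
    "compute_site_coverage",
    "apply_site_filters",
    "map_sites_to_genes",
    "aggregate_to_features",
    "aggregate_by_isoform",
    "filter_edit_table",
    "count_reads_per_gene",
    "count_reads_per_isoform",
    "call_edits",
    "call_edits_by_region",
    "write_sites_tsv",
    "write_bedgraph",
    "write_bed",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

FILTER_ORDER = (
    "multi_edit_type",
    "snp_mask",
    "min_total_edits",
    "max_edited_fraction",
    "antisense",
    "target_conversion",
)


@dataclass
class SiteSummary:
    """One candidate edit site with per-barcode edit and coverage counts."""

    contig: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    site_strand: str  # '+'/'-' inferred from supporting reads
    edit_counts: dict[str, int] = field(default_factory=dict)  # barcode -> edits
    coverage: dict[str, tuple[int, int]] = field(default_factory=dict)
    # barcode -> (ref_reads, alt_reads)
    pooled_ref_reads: int = 0  # over ALL passing reads, not only edited cells
    pooled_alt_reads: int = 0
    n_alt_types: int = 1  # distinct alt bases observed at this position

    @property
    def total_edits(self) -> int:
        return sum(self.edit_counts.values())

    @property
    def edited_fraction(self) -> float:
        """Pooled alt / (ref + alt) over all passing reads at the site."""
        total = self.pooled_ref_reads + self.pooled_alt_reads
        return self.pooled_alt_reads / total if total else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_base, self.alt_base)

    def oriented_conversion(self) -> tuple[str, str]:
        """(ref, alt) re-oriented to the supporting-read strand."""
        if self.site_strand == "-":
            return (_COMPLEMENT[self.ref_base], _COMPLEMENT[self.alt_base])
        return (self.ref_base, self.alt_base)


@dataclass(frozen=True)
class SiteFilterConfig:
    """The site-filter cascade thresholds (C>T APOBEC defaults)."""

    target_ref: str = "C"
    target_alt: str = "T"
    snp_mask: frozenset[tuple[str, int]] = frozenset()
    drop_multi_edit_type: bool = True
    min_total_edits: int = 3
    max_edited_fraction: float = 0.05
    require_sense_strand: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.max_edited_fraction <= 1):
            raise ValueError("max_edited_fraction must be in (0, 1]")


class GeneIndex:
    """Strand-aware interval index of gene spans for overlap queries."""

    def __init__(self, models: Mapping[str, TranscriptModel]):
        spans: dict[tuple[str, str, str], tuple[int, int]] = {}
        for m in models.values():
            key = (m.contig, m.gene_id, m.strand)
            s, e = m.span
            if key in spans:
                s0, e0 = spans[key]
                spans[key] = (min(s, s0), max(e, e0))
            else:
                spans[key] = (s, e)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for (contig, gene_id, strand), (s, e) in spans.items():
            self._trees[contig].addi(s, e, (gene_id, strand))

    def overlapping(self, contig: str, pos: int) -> list[tuple[str, str]]:
        """Genes (gene_id, strand) whose span contains ``pos``."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def overlapping_interval(
        self, contig: str, start: int, end: int
    ) -> list[tuple[str, str]]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))


# ----------------------------------------------------------------------
# Partitioning and tabulation
# ----------------------------------------------------------------------


def partition_regions(
    contig_lengths: Mapping[str, int], interval_size: int
) -> list[tuple[str, int, int]]:
    """Tile each contig with half-open intervals of ``interval_size``."""
    if interval_size <= 0:
        raise ValueError("interval_size must be > 0")
    regions = []
    for contig in contig_lengths:
        length = contig_lengths[contig]
        for start in range(0, length, interval_size):
            regions.append((contig, start, min(start + interval_size, length)))
    return regions


def tabulate_edits(
    reads: Iterable[AlignedReadRecord],
    group_by_isoform: bool = False,
    config: ReadFilterConfig | None = None,
    region: tuple[str, int, int] | None = None,
    counters: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate all substitution types per (site, alt, barcode[, isoform]).

    Counts every edit type (not only C>T) so the multi-edit-type filter can
    act downstream.  Returns a frame with columns ``contig, pos, ref, alt,
    strand, barcode[, isoform], count`` sorted deterministically.  When
    ``region`` is given, only observations with positions inside it count.
    """
    config = config or ReadFilterConfig()
    counters = counters if counters is not None else {}
    counters.setdefault("md_inconsistent_reads", 0)
    counts: Counter = Counter()
    for read in reads:
        try:
            obs_list = extract_mismatches(read, config)
        except ValueError as exc:
            counters["md_inconsistent_reads"] += 1
            logger.warning("skipping read %s: %s", read.read_id, exc)
            continue
        for obs in obs_list:
            if region is not None:
                contig, start, end = region
                if obs.contig != contig or not (start <= obs.pos < end):
                    continue
            key = [obs.contig, obs.pos, obs.ref_base, obs.alt_base, obs.read_strand,
                   obs.barcode or ""]
            if group_by_isoform:
                key.append(obs.isoform_id or "")
            counts[tuple(key)] += 1
    cols = ["contig", "pos", "ref", "alt", "strand", "barcode"]
    if group_by_isoform:
        cols.append("isoform")
    rows = [list(k) + [v] for k, v in counts.items()]
    df = pd.DataFrame(rows, columns=cols + ["count"])
    if df.empty:
        return pd.DataFrame(columns=cols + ["count"])
    return df.sort_values(cols, kind="mergesort").reset_index(drop=True)


def build_sites(edit_table: pd.DataFrame) -> list[SiteSummary]:
    """Collapse an edit table into per-(site, alt) summaries.

    The site strand is the read strand supported by the most edited reads
    (ties break to '+'); ``n_alt_types`` records how many distinct alt
    bases were seen at the position, for the multi-edit-type filter.
    """
    if edit_table.empty:
        return []
    alts_per_pos = (
        edit_table.groupby(["contig", "pos"])["alt"].nunique().to_dict()
    )
    sites: list[SiteSummary] = []
    for (contig, pos, ref, alt), sub in edit_table.groupby(
        ["contig", "pos", "ref", "alt"], sort=True
    ):
        strand_counts = sub.groupby("strand")["count"].sum()
        site_strand = strand_counts.sort_values(ascending=False).index[0]
        if len(strand_counts) > 1 and strand_counts.nunique() == 1:
            site_strand = "+"
        per_bc = sub.groupby("barcode")["count"].sum().to_dict()
        sites.append(
            SiteSummary(
                contig=contig,
                pos=int(pos),
                ref_base=ref,
                alt_base=alt,
                site_strand=site_strand,
                edit_counts={str(k): int(v) for k, v in sorted(per_bc.items())},
                n_alt_types=int(alts_per_pos[(contig, pos)]),
            )
        )
    return sites


# ----------------------------------------------------------------------
# Coverage
# ----------------------------------------------------------------------


def compute_site_coverage(
    reads: Iterable[AlignedReadRecord],
    sites: Sequence[SiteSummary],
    config: ReadFilterConfig | None = None,
    all_barcodes: bool = False,
) -> list[SiteSummary]:
    """Fill per-barcode (ref_reads, alt_reads) for each site.

    A read contributes to a site only where it aligns a base over the
    position (deletions and splice skips contribute nothing) and the base
    passes the same base-quality/read-end filters used for mismatch
    extraction, so edit and coverage tabulations agree.  By default only
    barcodes with at least one edit at the site are reported; pass
    ``all_barcodes=True`` for full pileups.
    """
    config = config or ReadFilterConfig()
    by_pos: dict[tuple[str, int], list[SiteSummary]] = defaultdict(list)
    for site in sites:
        by_pos[(site.contig, site.pos)].append(site)
    acc: dict[tuple[int, str], list[int]] = defaultdict(lambda: [0, 0])
    # key: (id(site)->index, barcode) -> [ref_reads, alt_reads]
    site_ids = {id(s): s for s in sites}
    for read in reads:
        qlen = len(read.seq)
        for q, r in iter_aligned_bases(read):
            targets = by_pos.get((read.contig, r))
            if not targets:
                continue
            base = read.seq[q].upper()
            if base == "N":
                continue
            dist = min(q, qlen - 1 - q)
            if read.base_quals[q] < config.min_base_qual or dist < config.min_dist_from_end:
                continue
            bc = read.barcode or ""
            for site in targets:
                if base == site.ref_base:
                    acc[(id(site), bc)][0] += 1
                elif base == site.alt_base:
                    acc[(id(site), bc)][1] += 1
    for (sid, bc), (ref_n, alt_n) in acc.items():
        site = site_ids[sid]
        site.pooled_ref_reads += ref_n
        site.pooled_alt_reads += alt_n
        if not all_barcodes and bc not in site.edit_counts:
            continue
        site.coverage[bc] = (ref_n, alt_n)
    for site in sites:
        site.coverage = dict(sorted(site.coverage.items()))
    return list(sites)


# ----------------------------------------------------------------------
# Site filter cascade
# ----------------------------------------------------------------------


def apply_site_filters(
    sites: Sequence[SiteSummary],
    cfg: SiteFilterConfig,
    gene_index: GeneIndex | None = None,
) -> tuple[list[SiteSummary], dict[str, int]]:
    """Apply the site-filter cascade in fixed order, returning drop counts.

    Order: (1) multi-edit-type, (2) SNP mask, (3) minimum total edits,
    (4) maximum pooled edited fraction, (5) antisense (supporting-read
    strand conflicts with every overlapping gene), (6) target conversion
    after re-orienting to the supporting-read strand.  Each dropped site is
    charged to the first rule that rejects it.
    """
    drops = {rule: 0 for rule in FILTER_ORDER}
    kept: list[SiteSummary] = []
    for site in sites:
        if cfg.drop_multi_edit_type and site.n_alt_types > 1:
            drops["multi_edit_type"] += 1
            continue
        if (site.contig, site.pos) in cfg.snp_mask:
            drops["snp_mask"] += 1
            continue
        if site.total_edits < cfg.min_total_edits:
            drops["min_total_edits"] += 1
            continue
        if site.edited_fraction > cfg.max_edited_fraction:
            drops["max_edited_fraction"] += 1
            continue
        if cfg.require_sense_strand:
            if gene_index is None:
                raise ValueError("require_sense_strand needs a gene index")
            genes = gene_index.overlapping(site.contig, site.pos)
            if genes and all(strand != site.site_strand for _, strand in genes):
                drops["antisense"] += 1
                continue
        if site.oriented_conversion() != (cfg.target_ref, cfg.target_alt):
            drops["target_conversion"] += 1
            continue
        kept.append(site)
    return kept, drops


# ----------------------------------------------------------------------
# Aggregation to features
# ----------------------------------------------------------------------


def map_sites_to_genes(
    sites: Sequence[SiteSummary],
    gene_index: GeneIndex,
    same_strand: bool = True,
) -> dict[tuple[str, int, str, str], list[str]]:
    """Map each site to the genes whose span contains it.

    With ``same_strand`` a gene must match the site's supporting-read
    strand; sites overlapping multiple matching genes map to each.
    """
    out = {}
    for site in sites:
        genes = gene_index.overlapping(site.contig, site.pos)
        if same_strand:
            genes = [(g, s) for g, s in genes if s == site.site_strand]
        out[site.key] = [g for g, _ in genes]
    return out


def aggregate_to_features(
    sites: Sequence[SiteSummary],
    feature_map: Mapping[tuple[str, int, str, str], list[str]],
    reads: pd.DataFrame,
) -> CellFeatureMatrix:
    """Sum per-barcode site edits into a cells x features matrix.

    ``reads`` is a cells x features frame of read counts (from an external
    MTX or counted from alignments); its labels define the matrix frame.
    A feature referenced by a site but absent from ``reads`` is an error.
    """
    features = list(reads.columns)
    fset = set(features)
    missing = sorted(
        {f for key in feature_map for f in feature_map[key]} - fset
    )
    if missing:
        raise ValueError(f"features absent from read matrix: {missing}")
    barcodes = list(reads.index)
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    f_idx = {f: i for i, f in enumerate(features)}
    edits = np.zeros((len(barcodes), len(features)))
    for site in sites:
        for feature in feature_map.get(site.key, []):
            j = f_idx[feature]
            for bc, n in site.edit_counts.items():
                i = bc_idx.get(bc)
                if i is not None:
                    edits[i, j] += n
    return CellFeatureMatrix.from_dense(barcodes, features, edits, reads.values)


def aggregate_by_isoform(
    edit_table: pd.DataFrame, reads: pd.DataFrame
) -> CellFeatureMatrix:
    """Sum isoform-grouped edit counts into a cells x isoforms matrix."""
    if "isoform" not in edit_table.columns:
        raise ValueError("edit table was not tabulated with group_by_isoform")
    barcodes = list(reads.index)
    features = list(reads.columns)
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    f_idx = {f: i for i, f in enumerate(features)}
    known = edit_table[edit_table["isoform"].isin(f_idx)]
    missing = sorted(set(edit_table["isoform"]) - set(features) - {""})
    if missing:
        raise ValueError(f"isoforms absent from read matrix: {missing}")
    edits = np.zeros((len(barcodes), len(features)))
    for row in known.itertuples():
        i = bc_idx.get(row.barcode)
        if i is not None:
            edits[i, f_idx[row.isoform]] += row.count
    return CellFeatureMatrix.from_dense(barcodes, features, edits, reads.values)


def filter_edit_table(
    table: pd.DataFrame,
    snp_mask: frozenset[tuple[str, int]] | set = frozenset(),
    target_ref: str = "C",
    target_alt: str = "T",
) -> pd.DataFrame:
    """Row-level SNP-mask and oriented target-conversion filter.

    Used by the long-read pipeline, where per-read edits are aggregated by
    isoform and only the SNP mask (not the site-count/fraction cascade)
    applies.  Each row's conversion is re-oriented to its read strand
    before comparison with the target, so minus-strand C>T events
    (genomic G>A) are retained.
    """
    if table.empty:
        return table
    masked = table.apply(
        lambda r: (r["contig"], r["pos"]) in snp_mask, axis=1
    )
    def oriented_ok(r) -> bool:
        ref, alt = r["ref"], r["alt"]
        if r["strand"] == "-":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        return (ref, alt) == (target_ref, target_alt)

    ok = table.apply(oriented_ok, axis=1)
    return table[~masked & ok].reset_index(drop=True)


def count_reads_per_gene(
    reads: Iterable[AlignedReadRecord],
    gene_index: GeneIndex,
    same_strand: bool = True,
) -> pd.DataFrame:
    """Count reads per (barcode, gene) by gene-span overlap."""
    counts: Counter = Counter()
    for read in reads:
        genes = gene_index.overlapping_interval(read.contig, read.start, read.end)
        if same_strand:
            genes = [(g, s) for g, s in genes if s == read.strand]
        for gene, _ in genes:
            counts[(read.barcode or "", gene)] += 1
    return _counts_to_frame(counts)


def count_reads_per_isoform(reads: Iterable[AlignedReadRecord]) -> pd.DataFrame:
    """Count reads per (barcode, isoform) from IB/IS tags."""
    counts: Counter = Counter()
    for read in reads:
        if read.isoform_id:
            counts[(read.barcode or "", read.isoform_id)] += 1
    return _counts_to_frame(counts)


def _counts_to_frame(counts: Counter) -> pd.DataFrame:
    if not counts:
        return pd.DataFrame()
    df = pd.Series(counts).rename_axis(["barcode", "feature"]).rename("count")
    return (
        df.reset_index()
        .pivot(index="barcode", columns="feature", values="count")
        .fillna(0)
        .astype(int)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )


# ----------------------------------------------------------------------
# End-to-end calling
# ----------------------------------------------------------------------


@dataclass
class CallResult:
    """Kept sites plus the audit trail of the filter cascade."""

    sites: list[SiteSummary]
    drop_counts: dict[str, int]
    edit_table: pd.DataFrame
    counters: dict[str, int]


def call_edits(
    alignment_path: str | Path,
    read_config: ReadFilterConfig | None = None,
    site_config: SiteFilterConfig | None = None,
    gene_index: GeneIndex | None = None,
    region: tuple[str, int, int] | None = None,
    group_by_isoform: bool = False,
    all_barcodes: bool = False,
) -> CallResult:
    """Run tabulation, coverage and the filter cascade over one region."""
    read_config = read_config or ReadFilterConfig()
    site_config = site_config or SiteFilterConfig()
    counters: dict[str, int] = {}
    reads = list(stream_reads(alignment_path, region, read_config, counters))
    edit_table = tabulate_edits(
        reads, group_by_isoform=group_by_isoform, config=read_config,
        region=region, counters=counters,
    )
    sites = build_sites(edit_table)
    compute_site_coverage(reads, sites, read_config, all_barcodes=all_barcodes)
    kept, drops = apply_site_filters(sites, site_config, gene_index)
    return CallResult(sites=kept, drop_counts=drops, edit_table=edit_table,
                      counters=counters)


def call_edits_by_region(
    alignment_path: str | Path,
    contig_lengths: Mapping[str, int],
    interval_size: int,
    read_config: ReadFilterConfig | None = None,
    site_config: SiteFilterConfig | None = None,
    gene_index: GeneIndex | None = None,
    group_by_isoform: bool = False,
    all_barcodes: bool = False,
) -> CallResult:
    """Region-partitioned calling whose merge equals a single-pass run.

    Each region tabulates only observations whose position falls inside it,
    so every site belongs to exactly one region and merging is pure
    concatenation followed by the shared filter cascade.
    """
    read_config = read_config or ReadFilterConfig()
    site_config = site_config or SiteFilterConfig()
    regions = partition_regions(contig_lengths, interval_size)
    all_sites: list[SiteSummary] = []
    tables = []
    counters: dict[str, int] = {}
    for region in regions:
        reads = list(stream_reads(alignment_path, region, read_config, counters))
        table = tabulate_edits(
            reads, group_by_isoform=group_by_isoform, config=read_config,
            region=region, counters=counters,
        )
        if table.empty:
            continue
        tables.append(table)
        sites = build_sites(table)
        compute_site_coverage(reads, sites, read_config, all_barcodes=all_barcodes)
        all_sites.extend(sites)
    all_sites.sort(key=lambda s: s.key)
    edit_table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["contig", "pos", "ref", "alt", "strand",
                                   "barcode", "count"])
    )
    sort_cols = [c for c in edit_table.columns if c != "count"]
    if not edit_table.empty:
        edit_table = edit_table.sort_values(
            sort_cols, kind="mergesort"
        ).reset_index(drop=True)
    kept, drops = apply_site_filters(all_sites, site_config, gene_index)
    return CallResult(sites=kept, drop_counts=drops, edit_table=edit_table,
                      counters=counters)


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------


def sites_to_frame(sites: Sequence[SiteSummary]) -> pd.DataFrame:
    rows = []
    for s in sorted(sites, key=lambda x: x.key):
        rows.append(
            {
                "contig": s.contig,
                "pos": s.pos,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "strand": s.site_strand,
                "total_edits": s.total_edits,
                "n_barcodes": len(s.edit_counts),
                "ref_reads": s.pooled_ref_reads,
                "alt_reads": s.pooled_alt_reads,
                "edited_fraction": s.edited_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "strand", "total_edits",
                 "n_barcodes", "ref_reads", "alt_reads", "edited_fraction"],
    )


def write_sites_tsv(sites: Sequence[SiteSummary], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(sites: Sequence[SiteSummary], path: str | Path) -> None:
    """Edited fraction per kept site as a bedgraph track."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: x.key):
            fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.edited_fraction:.6g}\n")


def write_bed(sites: Sequence[SiteSummary], path: str | Path) -> None:
    """Kept sites as a 6-column BED."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: x.key):
            name = f"{s.ref_base}>{s.alt_base}"
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{name}\t{s.total_edits}\t{s.site_strand}\n"
            )
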