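"""Seeded synthetic data: references, alignments with planted edits, matrices.

Every generator is deterministic given its seed and returns a
machine-readable truth table alongside the files or matrices, so the edit
caller and the downstream statistics can be validated against planted
ground truth.  The alignment simulator emulates 10x-style short reads
(90 bp, CB barcode tags, ``xf:i:25`` UMI-representative tags) and
full-transcript long reads with IB isoform tags; planted C-to-U edits are
placed on sense-strand cytosines (genomic C on plus-strand genes, genomic
G on minus-strand genes) with per-cell-type rates.

Decoy sites exercise every rule of the site-filter cascade:

* multi-alt sites carry two different alt bases;
* low-count sites carry exactly two edits (below the three-edit minimum);
* high-fraction sites are edited in well over 5% of covering reads;
* SNP sites are edited in 100% of reads and listed in the VCF mask;
* antisense sites are edited only on reads opposing the gene strand, with
  enough unedited antisense coverage to stay under the 5% fraction cap so
  that the strand rule, not the fraction rule, removes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ribostamp.matrix import CellFeatureMatrix

__all__ = [
    "AlignmentSimSpec",
    "SimulatedAlignments",
    "simulate_alignments",
    "MatrixSimSpec",
    "SimulatedMatrices",
    "simulate_matrices",
    "mixture_values",
    "simulate_differential_replicates",
    "simulate_editsc_dataset",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


# ======================================================================
# Alignment simulation
# ======================================================================


@dataclass(frozen=True)
class AlignmentSimSpec:
    """Study conditions for the alignment simulator.

    Coverage is deep enough that a kept site (>= 3 edits at <= 5% edited
    fraction) is attainable: with ~360 reads per gene a mid-gene position
    is covered by roughly 100 reads, so a 3% per-read edit rate yields ~3
    edits at ~3% fraction.
    """

    n_contigs: int = 2
    contig_len: int = 10_000
    n_genes: int = 8
    gene_len: int = 400
    n_cells: int = 12
    cell_types: tuple[str, ...] = ("typeA", "typeB")
    edit_rate: dict = field(default_factory=lambda: {"typeA": 0.02, "typeB": 0.04})
    n_edit_sites_per_gene: int = 3
    reads_mean: float = 30.0
    reads_dispersion: float = 10.0
    read_len: int = 90
    frac_insertion: float = 0.05
    frac_deletion: float = 0.05
    n_snp_sites: int = 2
    n_multi_alt: int = 2
    n_low_count: int = 2
    n_high_fraction: int = 2
    n_antisense: int = 2
    n_antisense_reads: int = 60
    n_decoy_reads: int = 3  # non-whitelist / no-xf / secondary / qcfail each
    long_read: bool = False
    long_read_edit_rate_per_c: dict = field(
        default_factory=lambda: {"typeA": 0.004, "typeB": 0.012}
    )
    long_reads_mean: float = 6.0
    seed: int = 0


@dataclass
class SimulatedAlignments:
    """Paths to generated files plus the truth tables."""

    out_dir: Path
    fasta: Path
    gtf: Path
    vcf: Path
    whitelist: Path
    sam: Path
    contig_lengths: dict[str, int]
    sites: pd.DataFrame  # planted sites: contig,pos,ref,alt,gene,site_strand,kind
    read_edits: pd.DataFrame  # read_id,barcode,contig,pos,ref,alt
    cells: pd.DataFrame  # barcode,cell_type,state,stamp_level
    genes: pd.DataFrame  # gene_id,contig,start,end,strand

    def truth_site_counts(self) -> pd.DataFrame:
        """Planted edits aggregated per (site, alt, barcode)."""
        if self.read_edits.empty:
            return pd.DataFrame(
                columns=["contig", "pos", "ref", "alt", "barcode", "count"]
            )
        return (
            self.read_edits.groupby(["contig", "pos", "ref", "alt", "barcode"])
            .size()
            .rename("count")
            .reset_index()
            .sort_values(["contig", "pos", "ref", "alt", "barcode"])
            .reset_index(drop=True)
        )


class _ReadBuilder:
    """Builds one aligned read from the reference plus planted substitutions."""

    def __init__(self, contig: str, contig_seq: str, start: int,
                 cigar_ops: list[tuple[str, int]], rng: np.random.Generator):
        self.contig = contig
        self.start = start
        self.ops = cigar_ops
        # aligned (query_offset, ref_pos) pairs
        self.pairs: list[tuple[int, int]] = []
        q, r = 0, start
        query = []
        self.del_refs: dict[int, str] = {}  # query gap order -> deleted ref bases
        for op, n in cigar_ops:
            if op == "M":
                for i in range(n):
                    self.pairs.append((q + i, r + i))
                    query.append(contig_seq[r + i])
                q += n
                r += n
            elif op == "I":
                for _ in range(n):
                    query.append(_BASES[rng.integers(4)])
                q += n
            elif op in "DN":
                if op == "D":
                    self.del_refs[len(self.pairs)] = contig_seq[r : r + n]
                r += n
        self.seq = list(query)
        self.ref_end = r
        self.subs: dict[int, tuple[str, str]] = {}  # ref pos -> (ref, alt)

    def covers(self, pos: int) -> bool:
        return any(r == pos for _, r in self.pairs)

    def well_covers(self, pos: int, margin: int = 5) -> bool:
        """Covers ``pos`` with the aligned base at least ``margin`` from both ends."""
        n = len(self.seq)
        return any(
            r == pos and min(q, n - 1 - q) >= margin for q, r in self.pairs
        )

    def plant(self, pos: int, alt: str) -> str:
        """Substitute the aligned base at ``pos``; returns the ref base."""
        for q, r in self.pairs:
            if r == pos:
                ref = self.seq[q]
                self.seq[q] = alt
                self.subs[pos] = (ref, alt)
                return ref
        raise ValueError(f"read does not cover {pos}")

    def cigarstring(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


def _build_md(contig_seq: str, start: int, ops: list[tuple[str, int]],
              seq: list[str]) -> str:
    """MD tag from CIGAR + final read sequence versus the reference."""
    md: list[str] = []
    run = 0
    q, r = 0, start
    for op, n in ops:
        if op == "M":
            for i in range(n):
                if seq[q + i] == contig_seq[r + i]:
                    run += 1
                else:
                    md.append(str(run))
                    md.append(contig_seq[r + i])
                    run = 0
            q += n
            r += n
        elif op == "I":
            q += n
        elif op == "D":
            md.append(str(run))
            run = 0
            md.append("^" + contig_seq[r : r + n])
            r += n
        elif op == "N":
            r += n
    md.append(str(run))
    return "".join(md)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_alignments(
    spec: AlignmentSimSpec, out_dir: str | Path
) -> SimulatedAlignments:
    """Write FASTA/GTF/VCF/whitelist/SAM with planted edits and truth tables."""
    if spec.long_read:
        return _simulate_long_reads(spec, out_dir)
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    contigs = {f"chr{i + 1}": None for i in range(spec.n_contigs)}
    seqs = {
        name: "".join(_BASES[b] for b in rng.integers(0, 4, spec.contig_len))
        for name in contigs
    }

    # --- genes: evenly spaced, alternating strand, single exon
    genes = []
    per_contig = math.ceil(spec.n_genes / spec.n_contigs)
    gap = spec.contig_len // (per_contig + 1)
    g = 0
    for ci, contig in enumerate(seqs):
        for k in range(per_contig):
            if g >= spec.n_genes:
                break
            start = gap * (k + 1) - spec.gene_len // 2
            genes.append(
                {
                    "gene_id": f"gene{g + 1}",
                    "contig": contig,
                    "start": start,
                    "end": start + spec.gene_len,
                    "strand": "+" if g % 2 == 0 else "-",
                }
            )
            g += 1
    genes_df = pd.DataFrame(genes)

    # --- cells
    barcodes = [f"CELL_{i:03d}" for i in range(spec.n_cells)]
    types = [spec.cell_types[i % len(spec.cell_types)] for i in range(spec.n_cells)]
    stamp = rng.poisson(5.0, spec.n_cells) + 1
    cells_df = pd.DataFrame(
        {"barcode": barcodes, "cell_type": types, "state": "low",
         "stamp_level": stamp}
    )

    # --- choose planted site positions per gene (sense-strand cytosines)
    def sense_positions(gene) -> list[int]:
        base = "C" if gene["strand"] == "+" else "G"
        lo = gene["start"] + spec.read_len // 2
        hi = gene["end"] - spec.read_len // 2
        return [p for p in range(lo, hi) if seqs[gene["contig"]][p] == base]

    def antisense_positions(gene) -> list[int]:
        base = "G" if gene["strand"] == "+" else "C"
        lo = gene["start"] + spec.read_len // 2
        hi = gene["end"] - spec.read_len // 2
        return [p for p in range(lo, hi) if seqs[gene["contig"]][p] == base]

    site_rows = []
    used: set[tuple[str, int]] = set()

    def take(gene, pool, kind, alt_of=None):
        pool = [p for p in pool if (gene["contig"], p) not in used]
        pos = int(pool[rng.integers(len(pool))])
        used.add((gene["contig"], pos))
        ref = seqs[gene["contig"]][pos]
        return pos, ref

    decoy_plan = (
        [("snp",)] * spec.n_snp_sites
        + [("multi_alt",)] * spec.n_multi_alt
        + [("low_count",)] * spec.n_low_count
        + [("high_fraction",)] * spec.n_high_fraction
        + [("antisense",)] * spec.n_antisense
    )
    for gi, gene in enumerate(genes):
        pool = sense_positions(gene)
        for _ in range(spec.n_edit_sites_per_gene):
            pos, ref = take(gene, pool, "edit")
            alt = "T" if ref == "C" else "A"  # C>T sense == G>A genomic on '-'
            site_rows.append(
                {"contig": gene["contig"], "pos": pos, "ref": ref, "alt": alt,
                 "gene": gene["gene_id"], "site_strand": gene["strand"],
                 "kind": "edit"}
            )
    # spread decoys round-robin over genes
    for di, (kind,) in enumerate(decoy_plan):
        gene = genes[di % len(genes)]
        if kind == "antisense":
            pos, ref = take(gene, antisense_positions(gene), kind)
            strand = "-" if gene["strand"] == "+" else "+"
        else:
            pos, ref = take(gene, sense_positions(gene), kind)
            strand = gene["strand"]
        alt = "T" if ref == "C" else "A"
        site_rows.append(
            {"contig": gene["contig"], "pos": pos, "ref": ref, "alt": alt,
             "gene": gene["gene_id"], "site_strand": strand, "kind": kind}
        )
        if kind == "multi_alt":
            second = "G" if ref == "C" else "T"
            if second == ref:
                second = "A"
            site_rows.append(
                {"contig": gene["contig"], "pos": pos, "ref": ref, "alt": second,
                 "gene": gene["gene_id"], "site_strand": strand,
                 "kind": "multi_alt_secondary"}
            )
    sites_df = pd.DataFrame(site_rows)

    # --- generate reads gene by gene
    reads: list[dict] = []
    read_edit_rows: list[dict] = []
    read_serial = 0

    def new_read(gene, barcode, strand, has_xf=True, flags_extra=0,
                 antisense=False) -> dict:
        nonlocal read_serial
        contig = gene["contig"]
        u = rng.random()
        if u < spec.frac_insertion:
            a = int(rng.integers(20, spec.read_len - 20))
            ops = [("M", a), ("I", 1), ("M", spec.read_len - 1 - a)]
        elif u < spec.frac_insertion + spec.frac_deletion:
            a = int(rng.integers(20, spec.read_len - 20))
            ops = [("M", a), ("D", 1), ("M", spec.read_len - a)]
        else:
            ops = [("M", spec.read_len)]
        ref_span = sum(n for op, n in ops if op in "MDN")
        start = int(rng.integers(gene["start"], gene["end"] - ref_span))
        rb = _ReadBuilder(contig, seqs[contig], start, ops, rng)
        read_serial += 1
        return {
            "builder": rb,
            "read_id": f"read{read_serial:06d}",
            "barcode": barcode,
            "gene": gene,
            "strand": strand,
            "has_xf": has_xf,
            "flags_extra": flags_extra,
        }

    site_by_gene = sites_df.groupby("gene")
    for gene in genes:
        gid = gene["gene_id"]
        gsites = site_by_gene.get_group(gid) if gid in site_by_gene.groups else None
        gene_reads = []
        for bc, ctype in zip(barcodes, types):
            n = _nb_draw(rng, spec.reads_mean, spec.reads_dispersion)
            rate = spec.edit_rate[ctype] if isinstance(spec.edit_rate, dict) else spec.edit_rate
            for _ in range(n):
                rd = new_read(gene, bc, gene["strand"])
                if gsites is not None:
                    for srow in gsites.itertuples():
                        if srow.kind not in ("edit", "snp"):
                            continue
                        if not rd["builder"].covers(srow.pos):
                            continue
                        hit = srow.kind == "snp" or rng.random() < rate
                        if hit:
                            rd["builder"].plant(srow.pos, srow.alt)
                            if srow.kind == "edit":
                                read_edit_rows.append(
                                    {"read_id": rd["read_id"], "barcode": bc,
                                     "contig": srow.contig, "pos": srow.pos,
                                     "ref": srow.ref, "alt": srow.alt}
                                )
                gene_reads.append(rd)
        # deterministic decoy planting on plain-M covering reads
        if gsites is not None:
            for srow in gsites.itertuples():
                if srow.kind in ("edit", "snp", "multi_alt_secondary", "antisense"):
                    continue
                covering = [
                    rd for rd in gene_reads
                    if len(rd["builder"].ops) == 1
                    and rd["builder"].well_covers(srow.pos)
                ]
                if srow.kind == "multi_alt":
                    second = gsites[
                        (gsites["pos"] == srow.pos)
                        & (gsites["kind"] == "multi_alt_secondary")
                    ]["alt"].iloc[0]
                    for rd in covering[:3]:
                        rd["builder"].plant(srow.pos, srow.alt)
                    for rd in covering[3:5]:
                        rd["builder"].plant(srow.pos, second)
                elif srow.kind == "low_count":
                    for rd in covering[:2]:
                        rd["builder"].plant(srow.pos, srow.alt)
                elif srow.kind == "high_fraction":
                    k = max(3, math.ceil(0.3 * len(covering)))
                    for rd in covering[:k]:
                        rd["builder"].plant(srow.pos, srow.alt)
            # dedicated antisense coverage
            for srow in gsites.itertuples():
                if srow.kind != "antisense":
                    continue
                anti_strand = "-" if gene["strand"] == "+" else "+"
                planted = 0
                margin = 5
                for j in range(spec.n_antisense_reads):
                    bc = barcodes[j % len(barcodes)]
                    rd = new_read(gene, bc, anti_strand)
                    # force plain-M reads whose aligned base at the site sits
                    # clear of the read-end exclusion margin
                    ops = [("M", spec.read_len)]
                    lo = max(gene["start"], srow.pos - (spec.read_len - 1 - margin))
                    hi = min(gene["end"] - spec.read_len, srow.pos - margin)
                    start = int(rng.integers(lo, hi + 1))
                    rd["builder"] = _ReadBuilder(
                        gene["contig"], seqs[gene["contig"]], start, ops, rng
                    )
                    if planted < 3:
                        rd["builder"].plant(srow.pos, srow.alt)
                        planted += 1
                    gene_reads.append(rd)
        reads.extend(gene_reads)

    # --- decoy reads exercising the read-level filters
    wl_gene = genes[0]
    first_site = sites_df[sites_df["gene"] == wl_gene["gene_id"]].iloc[0]
    for i in range(spec.n_decoy_reads):
        rd = new_read(wl_gene, "NOT_IN_WHITELIST", wl_gene["strand"])
        if rd["builder"].covers(int(first_site["pos"])):
            rd["builder"].plant(int(first_site["pos"]), str(first_site["alt"]))
        reads.append(rd)
    for i in range(spec.n_decoy_reads):
        rd = new_read(wl_gene, barcodes[0], wl_gene["strand"], has_xf=False)
        reads.append(rd)
    for i in range(spec.n_decoy_reads):
        rd = new_read(wl_gene, barcodes[0], wl_gene["strand"],
                      flags_extra=0x100)  # secondary
        reads.append(rd)
    for i in range(spec.n_decoy_reads):
        rd = new_read(wl_gene, barcodes[0], wl_gene["strand"],
                      flags_extra=0x200)  # QC fail
        reads.append(rd)

    # --- SNPs are germline: every covering read carries the alt base
    snp_rows = sites_df[sites_df["kind"] == "snp"]
    for srow in snp_rows.itertuples():
        for rd in reads:
            rb = rd["builder"]
            if rb.contig == srow.contig and srow.pos not in rb.subs \
                    and rb.covers(srow.pos):
                rb.plant(srow.pos, srow.alt)

    # --- write outputs
    contig_lengths = {name: spec.contig_len for name in seqs}
    paths = _write_reference_files(out, seqs, genes_df, sites_df, barcodes)
    sam_path = out / "alignments.sam"
    _write_sam(sam_path, contig_lengths, reads, seqs, unmapped=spec.n_decoy_reads)

    read_edits_df = pd.DataFrame(
        read_edit_rows,
        columns=["read_id", "barcode", "contig", "pos", "ref", "alt"],
    )
    return SimulatedAlignments(
        out_dir=out, fasta=paths["fasta"], gtf=paths["gtf"], vcf=paths["vcf"],
        whitelist=paths["whitelist"], sam=sam_path,
        contig_lengths=contig_lengths, sites=sites_df,
        read_edits=read_edits_df, cells=cells_df, genes=genes_df,
    )


def _write_fasta(out: Path, seqs) -> Path:
    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return fasta


def _write_vcf(out: Path, seqs, snp_sites: pd.DataFrame) -> Path:
    vcf = out / "snps.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in seqs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snp_sites.sort_values(["contig", "pos"]).itertuples():
            fh.write(f"{s.contig}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\n")
    return vcf


def _write_whitelist(out: Path, barcodes) -> Path:
    whitelist = out / "whitelist.txt"
    with open(whitelist, "w") as fh:
        fh.write("\n".join(barcodes) + "\n")
    return whitelist


def _write_reference_files(out: Path, seqs, genes_df, sites_df, barcodes):
    fasta = _write_fasta(out, seqs)
    gtf = out / "annotation.gtf"
    with open(gtf, "w") as fh:
        for g in genes_df.itertuples():
            attrs_g = f'gene_id "{g.gene_id}"; gene_biotype "protein_coding";'
            tid = f"{g.gene_id}.t1"
            attrs_t = (
                f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                f'transcript_biotype "protein_coding";'
            )
            start1, end1 = g.start + 1, g.end  # GTF is 1-based inclusive
            fh.write(f"{g.contig}\tsim\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs_g}\n")
            fh.write(f"{g.contig}\tsim\ttranscript\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs_t}\n")
            fh.write(f"{g.contig}\tsim\texon\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs_t}\n")
            cds_s = g.start + 60 + 1
            cds_e = g.end - 60
            fh.write(f"{g.contig}\tsim\tCDS\t{cds_s}\t{cds_e}\t.\t{g.strand}\t.\t{attrs_t}\n")
    vcf = _write_vcf(out, seqs, sites_df[sites_df["kind"] == "snp"])
    whitelist = _write_whitelist(out, barcodes)
    return {"fasta": fasta, "gtf": gtf, "vcf": vcf, "whitelist": whitelist}


def _write_sam(path: Path, contig_lengths, reads, seqs, unmapped: int = 0):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    order = {name: i for i, name in enumerate(contig_lengths)}
    mapped = sorted(
        reads, key=lambda rd: (order[rd["builder"].contig], rd["builder"].start,
                               rd["read_id"])
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rd in mapped:
            rb = rd["builder"]
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rd["read_id"]
            a.query_sequence = "".join(rb.seq)
            a.reference_id = order[rb.contig]
            a.reference_start = rb.start
            a.cigarstring = rb.cigarstring()
            a.mapping_quality = 255
            flag = rd["flags_extra"]
            if rd["strand"] == "-":
                flag |= 0x10
            a.flag = flag
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rb.seq))
            tags = [("MD", _build_md(seqs[rb.contig], rb.start, rb.ops, rb.seq)),
                    ("CB", rd["barcode"])]
            if rd["has_xf"]:
                tags.append(("xf", 25))
            if rd.get("isoform"):
                tags.append(("IB", rd["isoform"]))
            a.set_tags(tags)
            fh.write(a)
        for i in range(unmapped):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"unmapped{i:03d}"
            a.query_sequence = "A" * 30
            a.flag = 0x4
            a.reference_id = -1
            a.reference_start = -1
            a.mapping_quality = 0
            a.query_qualities = pysam.qualitystring_to_array("I" * 30)
            a.set_tags([("CB", "CELL_000")])
            fh.write(a)


# ----------------------------------------------------------------------
# Long-read simulation
# ----------------------------------------------------------------------


def _simulate_long_reads(spec: AlignmentSimSpec, out_dir: str | Path) -> SimulatedAlignments:
    """Full-transcript reads with IB isoform tags and per-C Bernoulli edits.

    Genes carry two isoforms with offset spans; every read covers its whole
    isoform, so EditsC truth is exact from the per-read edit lists.
    """
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = [f"chr{i + 1}" for i in range(spec.n_contigs)]
    seqs = {
        name: "".join(_BASES[b] for b in rng.integers(0, 4, spec.contig_len))
        for name in contigs
    }
    genes, tx_rows = [], []
    per_contig = math.ceil(spec.n_genes / spec.n_contigs)
    gap = spec.contig_len // (per_contig + 1)
    g = 0
    isoforms = []
    for contig in contigs:
        for k in range(per_contig):
            if g >= spec.n_genes:
                break
            start = gap * (k + 1) - spec.gene_len // 2
            strand = "+" if g % 2 == 0 else "-"
            gid = f"gene{g + 1}"
            genes.append({"gene_id": gid, "contig": contig, "start": start,
                          "end": start + spec.gene_len, "strand": strand})
            off = spec.gene_len // 8
            isoforms.append({"transcript_id": f"{gid}.t1", "gene_id": gid,
                             "contig": contig, "start": start,
                             "end": start + spec.gene_len - off, "strand": strand})
            isoforms.append({"transcript_id": f"{gid}.t2", "gene_id": gid,
                             "contig": contig, "start": start + off,
                             "end": start + spec.gene_len, "strand": strand})
            g += 1
    genes_df = pd.DataFrame(genes)
    barcodes = [f"CELL_{i:03d}" for i in range(spec.n_cells)]
    types = [spec.cell_types[i % len(spec.cell_types)] for i in range(spec.n_cells)]
    cells_df = pd.DataFrame({"barcode": barcodes, "cell_type": types,
                             "state": "low",
                             "stamp_level": rng.poisson(5.0, spec.n_cells) + 1})

    # SNP decoys on isoform 1 of the first genes
    site_rows = []
    for i in range(spec.n_snp_sites):
        iso = isoforms[(2 * i) % len(isoforms)]
        base = "C" if iso["strand"] == "+" else "G"
        pool = [p for p in range(iso["start"], iso["end"])
                if seqs[iso["contig"]][p] == base]
        pos = int(pool[rng.integers(len(pool))])
        ref = seqs[iso["contig"]][pos]
        site_rows.append({"contig": iso["contig"], "pos": pos, "ref": ref,
                          "alt": "T" if ref == "C" else "A",
                          "gene": iso["gene_id"], "site_strand": iso["strand"],
                          "kind": "snp"})
    snp_by_contig: dict[str, set[int]] = {}
    for s in site_rows:
        snp_by_contig.setdefault(s["contig"], set()).add(s["pos"])

    reads = []
    read_edit_rows = []
    serial = 0
    for iso in isoforms:
        contig = iso["contig"]
        length = iso["end"] - iso["start"]
        base = "C" if iso["strand"] == "+" else "G"
        c_positions = [p for p in range(iso["start"], iso["end"])
                       if seqs[contig][p] == base]
        for bc, ctype in zip(barcodes, types):
            rate = spec.long_read_edit_rate_per_c[ctype]
            n = 1 + rng.poisson(spec.long_reads_mean - 1)
            for _ in range(n):
                serial += 1
                rb = _ReadBuilder(contig, seqs[contig], iso["start"],
                                  [("M", length)], rng)
                rd = {"builder": rb, "read_id": f"lread{serial:06d}",
                      "barcode": bc, "gene": iso, "strand": iso["strand"],
                      "has_xf": False, "flags_extra": 0,
                      "isoform": iso["transcript_id"]}
                for pos in c_positions:
                    is_snp = pos in snp_by_contig.get(contig, set())
                    if is_snp or rng.random() < rate:
                        ref = seqs[contig][pos]
                        alt = "T" if ref == "C" else "A"
                        rb.plant(pos, alt)
                        if not is_snp:
                            read_edit_rows.append(
                                {"read_id": rd["read_id"], "barcode": bc,
                                 "contig": contig, "pos": pos, "ref": ref,
                                 "alt": alt,
                                 "isoform": iso["transcript_id"]}
                            )
                reads.append(rd)

    contig_lengths = {name: spec.contig_len for name in seqs}
    # GTF with isoform models
    gtf = out / "annotation.gtf"
    with open(gtf, "w") as fh:
        for gr in genes_df.itertuples():
            attrs_g = f'gene_id "{gr.gene_id}"; gene_biotype "protein_coding";'
            fh.write(f"{gr.contig}\tsim\tgene\t{gr.start + 1}\t{gr.end}\t.\t{gr.strand}\t.\t{attrs_g}\n")
        for iso in isoforms:
            attrs_t = (
                f'gene_id "{iso["gene_id"]}"; transcript_id "{iso["transcript_id"]}"; '
                f'transcript_biotype "protein_coding";'
            )
            fh.write(f"{iso['contig']}\tsim\ttranscript\t{iso['start'] + 1}\t{iso['end']}\t.\t{iso['strand']}\t.\t{attrs_t}\n")
            fh.write(f"{iso['contig']}\tsim\texon\t{iso['start'] + 1}\t{iso['end']}\t.\t{iso['strand']}\t.\t{attrs_t}\n")
    sites_df = pd.DataFrame(
        site_rows, columns=["contig", "pos", "ref", "alt", "gene",
                            "site_strand", "kind"]
    )
    fasta = _write_fasta(out, seqs)
    vcf = _write_vcf(out, seqs, sites_df[sites_df["kind"] == "snp"])
    whitelist = _write_whitelist(out, barcodes)
    sam_path = out / "alignments.sam"
    _write_sam(sam_path, contig_lengths, reads, seqs)
    read_edits_df = pd.DataFrame(
        read_edit_rows,
        columns=["read_id", "barcode", "contig", "pos", "ref", "alt", "isoform"],
    )
    return SimulatedAlignments(
        out_dir=out, fasta=fasta, gtf=gtf, vcf=vcf, whitelist=whitelist,
        sam=sam_path, contig_lengths=contig_lengths, sites=sites_df,
        read_edits=read_edits_df, cells=cells_df, genes=genes_df,
    )


# ======================================================================
# Matrix simulation
# ======================================================================


@dataclass(frozen=True)
class MatrixSimSpec:
    """Statistical structure for edit/read/RNA matrix simulation.

    Per-cell mean EPR follows log(mean EPR + 1) = A x log(Stamp CPM + 1)
    + b + noise; per-gene edit counts are Poisson around the cell's rate
    times the gene's read depth, so a read may carry several edits and the
    per-gene EPR is unbounded above, as with real multi-site editing.
    Library sizes are fixed at one million so Stamp CPM equals the Stamp
    count exactly.
    """

    n_cells: int = 2000
    n_genes: int = 300
    stamp_slope: float = 0.5
    stamp_intercept: float = 0.1
    noise_sd: float = 0.05
    stamp_max_count: int = 12
    reads_mean: float = 30.0
    reads_dispersion: float = 10.0
    high_state_fraction: float = 0.0
    high_state_log_offset: float = 0.0
    rna_mean: float = 5.0
    seed: int = 0


@dataclass
class SimulatedMatrices:
    """Edit/read/RNA matrices with per-cell truth labels."""

    matrix: CellFeatureMatrix
    rna: pd.DataFrame  # cells x genes raw counts
    cells: pd.DataFrame  # barcode, stamp_count, total, target_mean_epr, state
    spec: MatrixSimSpec

    @property
    def stamp_counts(self) -> pd.Series:
        return self.cells.set_index("barcode")["stamp_count"]

    @property
    def totals(self) -> pd.Series:
        return self.cells.set_index("barcode")["total"]


def simulate_matrices(spec: MatrixSimSpec) -> SimulatedMatrices:
    rng = np.random.default_rng(spec.seed)
    barcodes = [f"CELL_{i:05d}" for i in range(spec.n_cells)]
    genes = [f"gene{j + 1}" for j in range(spec.n_genes)]
    stamp = rng.integers(0, spec.stamp_max_count + 1, spec.n_cells)
    total = np.full(spec.n_cells, 1_000_000)
    state = np.where(rng.random(spec.n_cells) < spec.high_state_fraction,
                     "high", "low")
    x = np.log1p(stamp.astype(float))
    y = (
        spec.stamp_slope * x
        + spec.stamp_intercept
        + np.where(state == "high", spec.high_state_log_offset, 0.0)
        + rng.normal(0.0, spec.noise_sd, spec.n_cells)
    )
    target = np.expm1(np.maximum(y, 0.0))
    p = spec.reads_dispersion / (spec.reads_dispersion + spec.reads_mean)
    reads = rng.negative_binomial(spec.reads_dispersion, p,
                                  (spec.n_cells, spec.n_genes))
    edits = rng.poisson(target[:, None] * reads)
    rna = pd.DataFrame(rng.poisson(spec.rna_mean, (spec.n_cells, spec.n_genes)),
                       index=barcodes, columns=genes)
    cells = pd.DataFrame(
        {"barcode": barcodes, "stamp_count": stamp, "total": total,
         "target_mean_epr": target, "state": state}
    )
    matrix = CellFeatureMatrix.from_dense(barcodes, genes, edits, reads)
    return SimulatedMatrices(matrix=matrix, rna=rna, cells=cells, spec=spec)


def mixture_values(
    n: int,
    means: tuple[float, float] = (1.0, 5.0),
    sds: tuple[float, float] = (0.1, 0.1),
    weights: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Draw per-cell rates from a two-component Gaussian mixture.

    Returns (values, labels) with labels 'low'/'high' by generating
    component; draws are truncated at zero to stay valid as rates.
    """
    rng = np.random.default_rng(seed)
    comp = (rng.random(n) < weights[1] / (weights[0] + weights[1])).astype(int)
    vals = rng.normal(np.take(means, comp), np.take(sds, comp))
    vals = np.maximum(vals, 0.0)
    idx = pd.RangeIndex(n)
    labels = pd.Series(np.where(comp == 1, "high", "low"), index=idx)
    return pd.Series(vals, index=idx), labels


def simulate_differential_replicates(
    n_features: int = 2000,
    n_reps: int = 3,
    base: float = 1.0,
    sigma: float = 0.1,
    effects: pd.Series | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-replicate pseudobulk EPR for two groups with planted shifts.

    ``effects`` holds the planted mean shift per feature in units of
    ``sigma`` for group A over group B (0 = null).  Values are truncated
    at a small positive floor so every replicate has nonzero EPR, matching
    the retention rule of the bootstrap pipeline.
    """
    rng = np.random.default_rng(seed)
    features = [f"gene{j + 1}" for j in range(n_features)]
    if effects is None:
        effects = pd.Series(0.0, index=features)
    eff = effects.reindex(features).fillna(0.0).to_numpy(float)
    a = rng.normal(base + eff[:, None] * sigma, sigma, (n_features, n_reps))
    b = rng.normal(base, sigma, (n_features, n_reps))
    floor = 1e-9
    va = pd.DataFrame(np.maximum(a, floor), index=features,
                      columns=[f"rep{r + 1}" for r in range(n_reps)])
    vb = pd.DataFrame(np.maximum(b, floor), index=features,
                      columns=[f"rep{r + 1}" for r in range(n_reps)])
    return va, vb, effects.reindex(features).fillna(0.0)


def simulate_editsc_dataset(
    n_discordant: int = 6,
    n_concordant: int = 6,
    n_single: int = 6,
    n_null: int = 4,
    n_samples: int = 3,
    base_rate: float = 1e-3,
    fold: float = 4.0,
    c_content_mean: int = 500,
    reads_mean: int = 150,
    seed: int = 0,
):
    """Per-sample EditsC tables for two cell types with planted discordance.

    Genes come in four flavours: discordant (two isoforms shifted in
    opposite directions between the cell types), concordant (both isoforms
    shifted the same way), single (one shifted isoform plus a gene with
    only that isoform), and null (no shift).  Shifts are ``fold``-times
    rate changes, far beyond sampling noise, so Welch p-values identify
    exactly the planted significant isoforms.

    Returns a dict with per-sample EditsC frames ``values_a``/``values_b``
    (isoforms x samples), integer ``edits_a/reads_a/edits_b/reads_b``
    frames, ``c_content``, ``gene_map``, ``total_reads`` and the planted
    ``discordant_genes`` set.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_i = 0
    for _ in range(n_discordant):
        gene_i += 1
        g = f"gene{gene_i}"
        rows.append((g, f"{g}.t1", fold, 1.0))
        rows.append((g, f"{g}.t2", 1.0, fold))
    for _ in range(n_concordant):
        gene_i += 1
        g = f"gene{gene_i}"
        rows.append((g, f"{g}.t1", fold, 1.0))
        rows.append((g, f"{g}.t2", fold, 1.0))
    for _ in range(n_single):
        gene_i += 1
        g = f"gene{gene_i}"
        rows.append((g, f"{g}.t1", fold, 1.0))
    for _ in range(n_null):
        gene_i += 1
        g = f"gene{gene_i}"
        rows.append((g, f"{g}.t1", 1.0, 1.0))
        rows.append((g, f"{g}.t2", 1.0, 1.0))
    transcripts = [t for _, t, _, _ in rows]
    gene_map = pd.Series({t: g for g, t, _, _ in rows})
    mult_a = np.array([ma for _, _, ma, _ in rows])
    mult_b = np.array([mb for _, _, _, mb in rows])
    c_content = pd.Series(
        rng.integers(c_content_mean // 2, c_content_mean * 2, len(rows)),
        index=transcripts, name="c_content",
    )
    samples = [f"s{k + 1}" for k in range(n_samples)]

    def draw(mult):
        reads = pd.DataFrame(
            rng.poisson(reads_mean, (len(rows), n_samples)) + 1,
            index=transcripts, columns=samples,
        )
        lam = (base_rate * mult)[:, None] * c_content.to_numpy()[:, None] * reads.values
        edits = pd.DataFrame(rng.poisson(lam), index=transcripts, columns=samples)
        editsc = edits / (reads.mul(c_content, axis=0))
        return reads, edits, editsc

    reads_a, edits_a, values_a = draw(mult_a)
    reads_b, edits_b, values_b = draw(mult_b)
    discordant = {
        f"gene{i + 1}" for i in range(n_discordant)
    }
    return {
        "values_a": values_a, "values_b": values_b,
        "edits_a": edits_a, "reads_a": reads_a,
        "edits_b": edits_b, "reads_b": reads_b,
        "c_content": c_content, "gene_map": gene_map,
        "total_reads": (reads_a.sum(axis=1) + reads_b.sum(axis=1)),
        "discordant_genes": discordant,
    }
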