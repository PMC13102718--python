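"""Transcript sequence and interval feature statistics.

UTR/CDS lengths, GC content, binding-site overlap counts (miRNA target
regions, RBP eCLIP peaks) and rank-sum comparisons between transcript
groups.  Interval inputs follow BED semantics (0-based half-open); overlap
counting requires a minimum of 1 bp and counts each site interval once per
transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ribostamp.alignment_io import TranscriptModel

__all__ = [
    "FeatureProfile",
    "gc_content",
    "region_lengths",
    "count_overlaps",
    "rank_sum_compare",
    "feature_profiles",
    "has_top_motif",
    "spliced_sequence",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PYRIMIDINES = set("CT")


@dataclass
class FeatureProfile:
    """Per-transcript feature summary row."""

    transcript_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    gc5: float
    gc_cds: float
    gc3: float
    mirna_sites: int = 0
    rbp_sites: int = 0
    noncoding: bool = False


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T); N excluded from the denominator.

    Returns NaN when no unambiguous base remains.  Characters outside
    {A, C, G, T, N} are an error.
    """
    seq = sequence.upper()
    if set(seq) - _VALID:
        raise ValueError(f"illegal characters: {sorted(set(seq) - _VALID)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / denom


def region_lengths(model: TranscriptModel) -> tuple[int, int, int]:
    """Spliced (intron-free) lengths of the 5' UTR, CDS and 3' UTR."""
    utr5 = sum(e - s for s, e in model.utr5)
    utr3 = sum(e - s for s, e in model.utr3)
    if model.cds is None:
        cds = 0
    else:
        lo, hi = model.cds
        cds = sum(max(0, min(e, hi) - max(s, lo)) for s, e in model.exons)
    return utr5, cds, utr3


def count_overlaps(
    regions: Mapping[str, Sequence[tuple]],
    sites: Iterable[tuple],
    strand_aware: bool = False,
    region_strands: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Count site intervals intersecting each transcript's region set.

    ``regions`` maps transcript id to intervals ``(contig, start, end)``;
    ``sites`` are ``(contig, start, end)`` or ``(contig, start, end,
    strand)`` tuples.  Intersection is half-open with a 1 bp minimum; a
    site overlapping several intervals of the same transcript counts once.
    With ``strand_aware`` a site must match the transcript strand given in
    ``region_strands``.
    """
    trees: dict[str, IntervalTree] = {}
    site_list = []
    for i, site in enumerate(sites):
        contig, start, end = site[0], int(site[1]), int(site[2])
        strand = site[3] if len(site) > 3 else None
        if start >= end:
            continue
        trees.setdefault(contig, IntervalTree()).addi(start, end, (i, strand))
        site_list.append(site)
    out: dict[str, int] = {}
    for tid, intervals in regions.items():
        hit: set[int] = set()
        t_strand = (region_strands or {}).get(tid)
        for contig, start, end in intervals:
            tree = trees.get(contig)
            if tree is None:
                continue
            for iv in tree.overlap(int(start), int(end)):
                site_id, s_strand = iv.data
                if strand_aware and t_strand and s_strand and s_strand != t_strand:
                    continue
                hit.add(site_id)
        out[tid] = len(hit)
    return out


def rank_sum_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both groups have at most 8 observations
    and there are no ties, and the tie-corrected normal approximation
    otherwise.  Returns (U statistic for the first group, two-sided p).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spliced_sequence(model: TranscriptModel, fasta) -> str:
    """mRNA-sense spliced sequence of a transcript from a genome FASTA."""
    from pyfaidx import Fasta

    if not isinstance(fasta, Fasta):
        fasta = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    parts = [str(fasta[model.contig][s:e]) for s, e in model.exons]
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def _region_seq(model: TranscriptModel, intervals, fasta) -> str:
    from pyfaidx import Fasta

    if not isinstance(fasta, Fasta):
        fasta = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    parts = [str(fasta[model.contig][s:e]) for s, e in sorted(intervals)]
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def has_top_motif(mrna_seq: str, min_pyrimidines: int = 4) -> bool:
    """Heuristic 5' terminal oligopyrimidine (5'TOP) scan.

    True when the transcript starts with C followed by at least
    ``min_pyrimidines`` further pyrimidines.  This is a heuristic stand-in
    for curated 5'TOP lists, which can be supplied directly instead.
    """
    seq = mrna_seq.upper()
    if not seq.startswith("C"):
        return False
    run = 0
    for base in seq[1:]:
        if base in _PYRIMIDINES:
            run += 1
        else:
            break
    return run >= min_pyrimidines


def feature_profiles(
    models: Mapping[str, TranscriptModel],
    fasta_path,
    mirna_sites: Iterable[tuple] = (),
    rbp_sites: Iterable[tuple] = (),
    strand_aware: bool = True,
) -> pd.DataFrame:
    """FeatureProfile rows for every transcript.

    GC content is computed per region on the mRNA sense strand; miRNA and
    RBP site counts intersect the 3' UTR coordinates, matching how target
    scans and eCLIP peaks are annotated.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    utr3_regions = {
        tid: [(m.contig, s, e) for s, e in m.utr3] for tid, m in models.items()
    }
    strands = {tid: m.strand for tid, m in models.items()}
    mirna_counts = count_overlaps(
        utr3_regions, mirna_sites, strand_aware=strand_aware, region_strands=strands
    )
    rbp_counts = count_overlaps(
        utr3_regions, rbp_sites, strand_aware=strand_aware, region_strands=strands
    )
    rows = []
    for tid, m in sorted(models.items()):
        u5, cds, u3 = region_lengths(m)
        cds_intervals = []
        if m.cds is not None:
            lo, hi = m.cds
            cds_intervals = [
                (max(s, lo), min(e, hi)) for s, e in m.exons if min(e, hi) > max(s, lo)
            ]
        rows.append(
            FeatureProfile(
                transcript_id=tid,
                utr5_len=u5,
                cds_len=cds,
                utr3_len=u3,
                gc5=gc_content(_region_seq(m, m.utr5, fa)) if m.utr5 else float("nan"),
                gc_cds=gc_content(_region_seq(m, cds_intervals, fa))
                if cds_intervals else float("nan"),
                gc3=gc_content(_region_seq(m, m.utr3, fa)) if m.utr3 else float("nan"),
                mirna_sites=mirna_counts.get(tid, 0),
                rbp_sites=rbp_counts.get(tid, 0),
                noncoding=m.cds is None,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("transcript_id")
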