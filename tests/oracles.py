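"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's own MD/CIGAR walking and
filter cascade: mismatches come from pysam's ``get_aligned_pairs`` (which
reconstructs reference bases from the MD tag independently), pileups from a
naive per-position scan, and the filter cascade from a literal re-statement
of the rules over the oracle-derived counts.
"""

from collections import Counter, defaultdict

import pysam

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def passing_reads(sam_path, config):
    """Reads surviving the read-level exclusions, via plain pysam."""
    out = []
    with pysam.AlignmentFile(str(sam_path)) as fh:
        for rec in fh.fetch(until_eof=True):
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or rec.is_qcfail):
                continue
            if rec.mapping_quality < config.min_mapq:
                continue
            if config.require_umi_rep_tag:
                try:
                    if rec.get_tag("xf") != 25:
                        continue
                except KeyError:
                    continue
            if config.barcode_whitelist is not None:
                try:
                    if rec.get_tag("CB") not in config.barcode_whitelist:
                        continue
                except KeyError:
                    continue
            out.append(rec)
    return out


def _passes_base_filters(rec, q, config):
    n = len(rec.query_sequence)
    if rec.query_qualities[q] < config.min_base_qual:
        return False
    if min(q, n - 1 - q) < config.min_dist_from_end:
        return False
    return True


def mismatch_counts(sam_path, config):
    """(contig, pos, ref, alt, strand, barcode) -> count via get_aligned_pairs."""
    counts = Counter()
    for rec in passing_reads(sam_path, config):
        seq = rec.query_sequence
        for q, r, refb in rec.get_aligned_pairs(with_seq=True, matches_only=True):
            refb = refb.upper()
            alt = seq[q].upper()
            if refb == alt or refb == "N" or alt == "N":
                continue
            if not _passes_base_filters(rec, q, config):
                continue
            strand = "-" if rec.is_reverse else "+"
            bc = dict(rec.get_tags()).get("CB", "")
            counts[(rec.reference_name, r, refb, alt, strand, bc)] += 1
    return counts


def pileup_at(sam_path, config, positions):
    """Naive per-position base pileup: (contig, pos) -> {(barcode, base): n}."""
    wanted = set(positions)
    piles = defaultdict(Counter)
    for rec in passing_reads(sam_path, config):
        seq = rec.query_sequence
        for q, r in rec.get_aligned_pairs(matches_only=True):
            key = (rec.reference_name, r)
            if key not in wanted:
                continue
            base = seq[q].upper()
            if base == "N":
                continue
            if not _passes_base_filters(rec, q, config):
                continue
            bc = dict(rec.get_tags()).get("CB", "")
            piles[key][(bc, base)] += 1
    return piles


def oracle_sites(sam_path, config):
    """Site summaries rebuilt from the oracle counts and pileups.

    Returns a dict keyed (contig, pos, ref, alt) with per-barcode edit
    counts, the majority read strand, pooled ref/alt coverage and the
    per-barcode ref/alt coverage restricted to edited barcodes.
    """
    counts = mismatch_counts(sam_path, config)
    sites = {}
    alts_at_pos = defaultdict(set)
    for (contig, pos, ref, alt, strand, bc), n in counts.items():
        key = (contig, pos, ref, alt)
        site = sites.setdefault(
            key, {"edit_counts": Counter(), "strand_counts": Counter()}
        )
        site["edit_counts"][bc] += n
        site["strand_counts"][strand] += n
        alts_at_pos[(contig, pos)].add(alt)
    piles = pileup_at(sam_path, config, {(c, p) for c, p, _, _ in sites})
    for (contig, pos, ref, alt), site in sites.items():
        pile = piles[(contig, pos)]
        site["n_alt_types"] = len(alts_at_pos[(contig, pos)])
        site["strand"] = max(
            sorted(site["strand_counts"]),
            key=lambda s: (site["strand_counts"][s], s == "+"),
        )
        site["pooled_ref"] = sum(n for (bc, b), n in pile.items() if b == ref)
        site["pooled_alt"] = sum(n for (bc, b), n in pile.items() if b == alt)
        site["coverage"] = {
            bc: (
                sum(n for (b2, b), n in pile.items() if b2 == bc and b == ref),
                sum(n for (b2, b), n in pile.items() if b2 == bc and b == alt),
            )
            for bc in site["edit_counts"]
        }
    return sites


def oracle_filter_cascade(sites, snp_mask, gene_lookup, min_total_edits=3,
                          max_edited_fraction=0.05, require_sense_strand=True,
                          target=("C", "T")):
    """Literal re-statement of the site-filter cascade over oracle sites.

    ``gene_lookup(contig, pos)`` returns [(gene_id, strand), ...].
    Returns (kept keys, drop counts per rule).
    """
    drops = Counter()
    kept = []
    for key in sorted(sites):
        contig, pos, ref, alt = key
        s = sites[key]
        if s["n_alt_types"] > 1:
            drops["multi_edit_type"] += 1
            continue
        if (contig, pos) in snp_mask:
            drops["snp_mask"] += 1
            continue
        if sum(s["edit_counts"].values()) < min_total_edits:
            drops["min_total_edits"] += 1
            continue
        total = s["pooled_ref"] + s["pooled_alt"]
        frac = s["pooled_alt"] / total if total else 0.0
        if frac > max_edited_fraction:
            drops["max_edited_fraction"] += 1
            continue
        if require_sense_strand:
            genes = gene_lookup(contig, pos)
            if genes and all(strand != s["strand"] for _, strand in genes):
                drops["antisense"] += 1
                continue
        ref_o, alt_o = ref, alt
        if s["strand"] == "-":
            ref_o, alt_o = COMPLEMENT[ref], COMPLEMENT[alt]
        if (ref_o, alt_o) != target:
            drops["target_conversion"] += 1
            continue
        kept.append(key)
    return kept, dict(drops)


def welch_oracle(a, b):
    """Textbook Welch statistic and two-sided p via the t distribution."""
    import numpy as np
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / se2 ** 0.5
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def mannwhitney_exact_oracle(a, b):
    """Exhaustive enumeration of all group assignments (no ties, small n)."""
    from itertools import combinations

    import numpy as np

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + \
            0.5 * sum(1 for x in group_a for y in group_b if x == y)

    u_obs = u_stat(a, b)
    n_total = len(pooled)
    m = na * (n_total - na)
    dev_obs = abs(u_obs - m / 2)
    count = 0
    total = 0
    for idx in combinations(range(n_total), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n_total) if i not in idx]
        if abs(u_stat(ga, gb) - m / 2) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def spearman_oracle(x, y):
    """Spearman rho via the classic rank-difference formula (no ties)."""
    import numpy as np

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = x.argsort().argsort()
    ry = y.argsort().argsort()
    n = len(x)
    d2 = ((rx - ry) ** 2).sum()
    return 1 - 6 * d2 / (n * (n ** 2 - 1))
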