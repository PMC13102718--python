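"""Edit tabulation, coverage, the site-filter cascade and aggregation."""

import numpy as np
import pandas as pd
import pytest

import oracles
from ribostamp.alignment_io import ReadFilterConfig, stream_reads
from ribostamp.edit_caller import (
    SiteFilterConfig,
    SiteSummary,
    aggregate_to_features,
    apply_site_filters,
    build_sites,
    call_edits,
    call_edits_by_region,
    compute_site_coverage,
    filter_edit_table,
    partition_regions,
    sites_to_frame,
    tabulate_edits,
    write_sites_tsv,
)


class TestPartitionRegions:
    def test_even_tiling_with_remainder(self):
        assert partition_regions({"chr1": 10000}, 4000) == [
            ("chr1", 0, 4000), ("chr1", 4000, 8000), ("chr1", 8000, 10000)
        ]

    def test_contig_shorter_than_interval(self):
        assert partition_regions({"chr1": 100}, 4000) == [("chr1", 0, 100)]

    def test_partitions_never_span_contigs(self):
        regions = partition_regions({"chr1": 5000, "chr2": 3000}, 2000)
        for contig, start, end in regions:
            assert 0 <= start < end <= (5000 if contig == "chr1" else 3000)

    def test_exact_cover_no_overlap(self):
        regions = partition_regions({"c": 9999}, 1234)
        covered = []
        for _, s, e in regions:
            covered.extend(range(s, e))
        assert covered == list(range(9999))

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            partition_regions({"c": 10}, 0)


class TestTabulation:
    def test_reference_identical_reads_empty(self, tmp_path):
        import pysam

        path = tmp_path / "clean.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = "r0"
            a.query_sequence = "ACGT" * 10
            a.reference_id = 0
            a.reference_start = 0
            a.cigarstring = "40M"
            a.mapping_quality = 60
            a.query_qualities = pysam.qualitystring_to_array("I" * 40)
            a.set_tags([("MD", "40"), ("CB", "BC1"), ("xf", 25)])
            fh.write(a)
        cfg = ReadFilterConfig()
        table = tabulate_edits(stream_reads(path, None, cfg), config=cfg)
        assert table.empty

    def test_counts_match_brute_force_oracle(self, sim_bundle, read_config):
        table = tabulate_edits(
            stream_reads(sim_bundle.sam, None, read_config), config=read_config
        )
        mine = {
            (r.contig, r.pos, r.ref, r.alt, r.strand, r.barcode): r.count
            for r in table.itertuples()
        }
        oracle = oracles.mismatch_counts(sim_bundle.sam, read_config)
        assert mine == dict(oracle)

    def test_same_site_two_barcodes_two_rows(self, sim_bundle):
        table = pd.DataFrame({
            "contig": ["chr1"] * 2, "pos": [5, 5], "ref": ["C", "C"],
            "alt": ["T", "T"], "strand": ["+", "+"],
            "barcode": ["b1", "b2"], "count": [2, 3],
        })
        (site,) = build_sites(table)
        assert site.edit_counts == {"b1": 2, "b2": 3}
        assert site.total_edits == 5


class TestCoverage:
    def test_pileup_matches_naive_oracle(self, sim_bundle, read_config):
        reads = list(stream_reads(sim_bundle.sam, None, read_config))
        table = tabulate_edits(reads, config=read_config)
        sites = build_sites(table)
        compute_site_coverage(reads, sites, read_config)
        oracle = oracles.oracle_sites(sim_bundle.sam, read_config)
        assert len(sites) == len(oracle)
        for site in sites:
            o = oracle[site.key]
            assert site.edit_counts == dict(o["edit_counts"])
            assert site.coverage == o["coverage"]
            assert (site.pooled_ref_reads, site.pooled_alt_reads) == (
                o["pooled_ref"], o["pooled_alt"])

    def test_deletion_read_contributes_nothing(self):
        from test_alignment_io import make_read

        # deletion spans position 102
        read = make_read("AAAA", "2M2D2M", "2^CG2", start=100)
        site = SiteSummary(contig="chr1", pos=102, ref_base="C", alt_base="T",
                           site_strand="+", edit_counts={"BC1": 1})
        cfg = ReadFilterConfig(min_base_qual=0, min_dist_from_end=0,
                               require_umi_rep_tag=False)
        compute_site_coverage([read], [site], cfg)
        assert site.coverage == {}
        assert (site.pooled_ref_reads, site.pooled_alt_reads) == (0, 0)

    def test_barcode_without_reads_absent(self):
        from test_alignment_io import make_read

        read = make_read("AATAA", "5M", "2C2", start=100, barcode="BC1")
        site = SiteSummary(contig="chr1", pos=102, ref_base="C", alt_base="T",
                           site_strand="+", edit_counts={"BC1": 1, "BC2": 1})
        cfg = ReadFilterConfig(min_base_qual=0, min_dist_from_end=0,
                               require_umi_rep_tag=False)
        compute_site_coverage([read], [site], cfg)
        assert "BC2" not in site.coverage


def _site(ref="C", alt="T", strand="+", edits=None, pooled=(40, 2),
          n_alt_types=1, contig="chr1", pos=500):
    return SiteSummary(
        contig=contig, pos=pos, ref_base=ref, alt_base=alt, site_strand=strand,
        edit_counts=edits or {"b1": 2, "b2": 1},
        pooled_ref_reads=pooled[0], pooled_alt_reads=pooled[1],
        n_alt_types=n_alt_types,
    )


class TestFilterCascade:
    CFG = SiteFilterConfig()

    def test_multi_edit_type_dropped(self):
        kept, drops = apply_site_filters([_site(n_alt_types=2)], self.CFG)
        assert not kept and drops["multi_edit_type"] == 1

    def test_two_edit_site_dropped(self):
        site = _site(edits={"b1": 2})
        kept, drops = apply_site_filters([site], self.CFG)
        assert not kept and drops["min_total_edits"] == 1

    def test_fraction_above_five_percent_dropped(self):
        site = _site(edits={"b1": 3}, pooled=(37, 3))  # 3/40 = 7.5%
        kept, drops = apply_site_filters([site], self.CFG)
        assert not kept and drops["max_edited_fraction"] == 1

    def test_snp_masked_site_dropped(self):
        cfg = SiteFilterConfig(snp_mask=frozenset({("chr1", 500)}))
        kept, drops = apply_site_filters([_site()], cfg)
        assert not kept and drops["snp_mask"] == 1

    def test_minus_strand_c_to_u_is_genomic_g_to_a(self):
        site = _site(ref="G", alt="A", strand="-", pooled=(60, 3))
        kept, _ = apply_site_filters([site], self.CFG)
        assert kept
        wrong = _site(ref="G", alt="A", strand="+", pooled=(60, 3))
        kept, drops = apply_site_filters([wrong], self.CFG)
        assert not kept and drops["target_conversion"] == 1

    def test_antisense_conflict_dropped(self, gene_index, sim_bundle):
        gene = sim_bundle.genes.iloc[0]
        anti = "-" if gene["strand"] == "+" else "+"
        ref, alt = ("C", "T") if anti == "+" else ("G", "A")
        site = _site(ref=ref, alt=alt, strand=anti, contig=gene["contig"],
                     pos=int(gene["start"]) + 50, pooled=(80, 3))
        cfg = SiteFilterConfig(require_sense_strand=True)
        kept, drops = apply_site_filters([site], cfg, gene_index)
        assert not kept and drops["antisense"] == 1

    def test_decoys_removed_by_their_intended_rule(
        self, sim_bundle, read_config, site_config, gene_index
    ):
        """Every planted decoy falls to the rule it was built to exercise."""
        reads = list(stream_reads(sim_bundle.sam, None, read_config))
        table = tabulate_edits(reads, config=read_config)
        sites = build_sites(table)
        compute_site_coverage(reads, sites, read_config)
        truth = sim_bundle.sites
        expected_rule = {
            "snp": "snp_mask", "multi_alt": "multi_edit_type",
            "multi_alt_secondary": "multi_edit_type",
            "low_count": "min_total_edits",
            "high_fraction": "max_edited_fraction", "antisense": "antisense",
        }
        kind_at = {(r.contig, r.pos): r.kind for r in truth.itertuples()
                   if r.kind != "multi_alt_secondary"}
        for site in sites:
            kind = kind_at.get((site.contig, site.pos))
            if kind not in expected_rule:
                continue
            kept, drops = apply_site_filters([site], site_config, gene_index)
            assert not kept
            (rule,) = [r for r, c in drops.items() if c]
            assert rule == expected_rule[kind], (site.key, kind, rule)

    def test_drop_counts_match_oracle_cascade(
        self, sim_bundle, read_config, site_config, gene_index
    ):
        result = call_edits(sim_bundle.sam, read_config, site_config,
                            gene_index=gene_index)
        oracle = oracles.oracle_sites(sim_bundle.sam, read_config)
        kept, drops = oracles.oracle_filter_cascade(
            oracle, site_config.snp_mask, gene_index.overlapping
        )
        assert sorted(s.key for s in result.sites) == kept
        assert {r: c for r, c in result.drop_counts.items() if c} == drops


class TestAggregation:
    def test_sum_over_sites_in_gene(self):
        s1 = _site(edits={"b1": 3}, pos=10)
        s2 = _site(edits={"b1": 1}, pos=20)
        fmap = {s1.key: ["g1"], s2.key: ["g1"]}
        reads = pd.DataFrame({"g1": [10]}, index=["b1"])
        m = aggregate_to_features([s1, s2], fmap, reads)
        assert m.edits_df().loc["b1", "g1"] == 4

    def test_fanout_to_overlapping_genes(self):
        s = _site(edits={"b1": 2}, pos=10)
        fmap = {s.key: ["g1", "g2"]}
        reads = pd.DataFrame({"g1": [5], "g2": [5]}, index=["b1"])
        m = aggregate_to_features([s], fmap, reads)
        assert m.edits_df().loc["b1"].tolist() == [2, 2]

    def test_missing_feature_is_error(self):
        s = _site(edits={"b1": 2}, pos=10)
        with pytest.raises(ValueError, match="g_missing"):
            aggregate_to_features(
                [s], {s.key: ["g_missing"]},
                pd.DataFrame({"g1": [5]}, index=["b1"]),
            )

    def test_matrix_matches_truth_aggregation(
        self, sim_bundle, read_config, site_config, gene_index
    ):
        from ribostamp.edit_caller import count_reads_per_gene, map_sites_to_genes

        result = call_edits(sim_bundle.sam, read_config, site_config,
                            gene_index=gene_index)
        reads = list(stream_reads(sim_bundle.sam, None, read_config))
        read_counts = count_reads_per_gene(reads, gene_index)
        fmap = map_sites_to_genes(result.sites, gene_index)
        m = aggregate_to_features(result.sites, fmap, read_counts)
        # conservation: matrix total equals kept-site totals (all sites map)
        mapped_total = sum(
            s.total_edits for s in result.sites if fmap.get(s.key)
        )
        assert m.edits.sum() == mapped_total

    def test_isoform_edit_table_filtering(self):
        table = pd.DataFrame({
            "contig": ["chr1"] * 3, "pos": [5, 9, 12],
            "ref": ["C", "G", "A"], "alt": ["T", "A", "G"],
            "strand": ["+", "-", "+"], "barcode": ["b"] * 3,
            "isoform": ["t1"] * 3, "count": [1, 1, 1],
        })
        out = filter_edit_table(table, snp_mask={("chr1", 5)})
        # SNP site removed; minus-strand G>A kept (C>T on transcript);
        # A>G is not the target conversion
        assert out[["pos"]].values.tolist() == [[9]]


class TestRegionParallelDeterminism:
    def test_merged_equals_single_pass(self, sim_bundle, read_config,
                                       site_config, gene_index):
        single = call_edits(sim_bundle.sam, read_config, site_config,
                            gene_index=gene_index)
        merged = call_edits_by_region(
            sim_bundle.sam, sim_bundle.contig_lengths, 1700,
            read_config, site_config, gene_index,
        )
        assert sites_to_frame(single.sites).equals(sites_to_frame(merged.sites))
        assert single.edit_table.equals(merged.edit_table)
        assert single.drop_counts == merged.drop_counts

    def test_site_tsv_byte_identical_across_runs(self, sim_bundle, read_config,
                                                 site_config, gene_index,
                                                 tmp_path):
        paths = []
        for i in range(2):
            res = call_edits(sim_bundle.sam, read_config, site_config,
                             gene_index=gene_index)
            p = tmp_path / f"sites{i}.tsv"
            write_sites_tsv(res.sites, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
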