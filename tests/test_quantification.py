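"""EPR/EditsC formulas, Stamp normalization, pseudobulk and pseudocells."""

import numpy as np
import pandas as pd
import pytest

from ribostamp.matrix import CellFeatureMatrix
from ribostamp.quantification import (
    apply_stamp_normalization,
    compute_editsc,
    compute_epr,
    cpm_log_normalize,
    filter_cells,
    fit_stamp_normalization,
    make_pseudocells,
    mean_epr,
    pseudobulk_epr,
    transcript_c_content,
)
from ribostamp.simulate import MatrixSimSpec, simulate_matrices


def mat(edits, reads, barcodes=None, genes=None):
    edits = np.atleast_2d(np.asarray(edits, float))
    reads = np.atleast_2d(np.asarray(reads, float))
    barcodes = barcodes or [f"c{i}" for i in range(edits.shape[0])]
    genes = genes or [f"g{j}" for j in range(edits.shape[1])]
    return CellFeatureMatrix.from_dense(barcodes, genes, edits, reads)


class TestComputeEpr:
    def test_formula(self):
        m = compute_epr(mat([[4]], [[20]]))
        assert m.rate_df().iloc[0, 0] == pytest.approx(0.2)

    def test_read_depth_mask_zeroes_rate_and_edits(self):
        m = compute_epr(mat([[2]], [[4]]), min_reads=5)
        assert m.rate_df().iloc[0, 0] == 0
        assert m.edits_df().iloc[0, 0] == 0

    def test_zero_edits(self):
        m = compute_epr(mat([[0]], [[100]]))
        assert m.rate_df().iloc[0, 0] == 0

    def test_rate_times_reads_recovers_edits(self):
        rng = np.random.default_rng(0)
        edits = rng.integers(0, 10, (20, 30))
        reads = rng.integers(0, 40, (20, 30))
        m = compute_epr(mat(edits, reads), min_reads=5)
        rate = m.rate_df().values
        r = m.reads_df().values
        e = m.edits_df().values
        mask = r >= 5
        assert np.abs(rate[mask] * r[mask] - e[mask]).max() < 1e-9


class TestFilterCells:
    @pytest.mark.parametrize(
        "n_edited,mode,kept",
        [(4, "short", False), (5, "short", True), (6, "short", True),
         (4, "long", False), (5, "long", False), (6, "long", True)],
    )
    def test_retention_rules(self, n_edited, mode, kept):
        edits = np.zeros((1, 8))
        edits[0, :n_edited] = 1
        m = filter_cells(mat(edits, np.full((1, 8), 10.0)), mode=mode)
        assert (len(m.barcodes) == 1) is kept


class TestMeanEpr:
    def test_edited_gene_definition(self):
        # gene0: edited with enough reads; gene1: edited but <3 reads;
        # gene2: unedited -> mean over gene0 only
        m = mat([[2, 1, 0]], [[10, 2, 50]])
        assert mean_epr(m, min_reads=3).iloc[0] == pytest.approx(0.2)

    def test_no_qualifying_gene_is_nan(self):
        m = mat([[0, 0]], [[10, 10]])
        assert np.isnan(mean_epr(m).iloc[0])


class TestStampNormalization:
    def _simulated(self, n_cells=2000, seed=0, **kw):
        sm = simulate_matrices(MatrixSimSpec(n_cells=n_cells, seed=seed, **kw))
        me = mean_epr(sm.matrix, min_reads=3)
        return sm, me

    def test_slope_recovery_matches_ols_oracle(self):
        sm, me = self._simulated()
        fit = fit_stamp_normalization(me, sm.stamp_counts, sm.totals)
        # independent closed-form OLS oracle on the same pairs
        cpm = sm.stamp_counts / sm.totals * 1e6
        sel = (sm.stamp_counts > 0) & me.notna()
        x = np.log1p(cpm[sel].to_numpy())
        y = np.log1p(me[sel].to_numpy())
        slope_oracle, intercept_oracle = np.polyfit(x, y, 1)
        assert fit.A == pytest.approx(slope_oracle, abs=1e-10)
        assert fit.b == pytest.approx(intercept_oracle, abs=1e-10)
        assert abs(fit.A - 0.5) < 0.03

    def test_collinear_noise_free_residuals_zero(self):
        idx = [f"c{i}" for i in range(10)]
        stamp = pd.Series(np.arange(1, 11), index=idx)
        totals = pd.Series(1e6, index=idx)
        me = pd.Series(np.expm1(0.4 * np.log1p(stamp.values) + 0.2), index=idx)
        fit = fit_stamp_normalization(me, stamp, totals)
        assert fit.A == pytest.approx(0.4, abs=1e-9)
        lo, hi = fit.residual_range
        assert hi - lo < 1e-9
        # degenerate residual range -> all factors 1
        assert np.allclose(fit.factors.values, 1.0)

    def test_all_zero_stamp_factors_one(self):
        idx = [f"c{i}" for i in range(5)]
        fit = fit_stamp_normalization(
            pd.Series(0.1, index=idx), pd.Series(0, index=idx),
            pd.Series(1e6, index=idx))
        assert fit.degenerate
        assert (fit.factors == 1.0).all()

    def test_corrected_range_matches_original(self):
        sm, me = self._simulated(n_cells=500, seed=3)
        fit = fit_stamp_normalization(me, sm.stamp_counts, sm.totals)
        orig = me[fit.fitted_cells]
        corrected = fit.factors[fit.fitted_cells] * orig
        assert corrected.min() == pytest.approx(orig.min(), abs=1e-9)
        assert corrected.max() == pytest.approx(orig.max(), abs=1e-9)

    def test_factor_one_leaves_row_unchanged(self):
        m = mat([[4, 2]], [[10, 10]])
        fit = fit_stamp_normalization(
            pd.Series(0.1, index=["c0"]), pd.Series(0, index=["c0"]),
            pd.Series(1e6, index=["c0"]))
        out = apply_stamp_normalization(m, fit, min_reads=5)
        assert np.allclose(out.edits_df().values, m.edits_df().values)

    def test_decorrelation_on_confounded_data(self):
        from scipy.stats import spearmanr

        sm, me = self._simulated(n_cells=5000, seed=4)
        fit = fit_stamp_normalization(me, sm.stamp_counts, sm.totals)
        out = apply_stamp_normalization(sm.matrix, fit, min_reads=5)
        me2 = mean_epr(out, min_reads=3)
        cpm = (sm.stamp_counts / sm.totals * 1e6)[fit.fitted_cells]
        rho = spearmanr(me2[fit.fitted_cells], cpm).statistic
        assert abs(rho) < 0.05

    def test_final_rate_is_scaled_edits_over_unadjusted_reads(self):
        sm, me = self._simulated(n_cells=300, seed=5)
        fit = fit_stamp_normalization(me, sm.stamp_counts, sm.totals)
        out = apply_stamp_normalization(sm.matrix, fit, min_reads=5)
        e, r, rate = (out.edits_df().values, out.reads_df().values,
                      out.rate_df().values)
        mask = r >= 5
        assert np.abs(rate[mask] * r[mask] - e[mask]).max() < 1e-9
        assert (rate[~mask] == 0).all()


class TestPseudobulk:
    def _groups(self, barcodes, group, sample):
        return pd.DataFrame({"group": group, "sample": sample}, index=barcodes)

    def test_pooled_ratio_not_mean_of_ratios(self):
        m = mat([[2], [3]], [[10], [40]])
        g = self._groups(m.barcodes, ["A", "A"], ["s1", "s1"])
        t = pseudobulk_epr(m, g, min_reads=0, min_edits=0, min_cells=0)
        assert t.total_epr.loc["g0", ("A", "s1")] == pytest.approx(5 / 50)
        # asymmetric fixture: mean of ratios would be (0.2 + 0.075)/2 = 0.1375
        assert t.total_epr.loc["g0", ("A", "s1")] != pytest.approx(0.1375)

    def test_low_edit_feature_dropped_in_every_group(self):
        # 4 edits in one sample of the only group -> fails min_edits=5
        m = mat([[4], [0]], [[10], [10]])
        g = self._groups(m.barcodes, ["A", "A"], ["s1", "s2"])
        t = pseudobulk_epr(m, g, min_reads=5, min_edits=5, min_cells=1)
        assert "g0" not in t.total_epr.index
        assert not t.passed.loc["g0"]

    def test_zero_thresholds_keep_everything(self):
        m = mat([[1, 0], [0, 0]], [[5, 5], [5, 5]])
        g = self._groups(m.barcodes, ["A", "A"], ["s1", "s2"])
        t = pseudobulk_epr(m, g, min_reads=0, min_edits=0, min_cells=0)
        assert list(t.total_epr.index) == ["g0", "g1"]

    def test_pass_requires_all_samples_of_one_group(self):
        # group A passes in s1 only; group B passes in both samples
        edits = [[9], [0], [9], [9]]
        reads = [[20], [20], [20], [20]]
        m = mat(edits, reads)
        g = self._groups(m.barcodes, ["A", "A", "B", "B"],
                         ["s1", "s2", "s1", "s2"])
        t = pseudobulk_epr(m, g, min_reads=5, min_edits=5, min_cells=1)
        assert t.passed.loc["g0"]
        g_all_a = self._groups(m.barcodes, ["A", "A", "A", "A"],
                               ["s1", "s2", "s3", "s4"])
        t2 = pseudobulk_epr(mat([[9], [0], [9], [9]], reads), g_all_a,
                            min_reads=5, min_edits=5, min_cells=1)
        assert not t2.passed.loc["g0"]

    def test_rna_summaries(self):
        m = mat([[1], [1]], [[10], [10]])
        g = self._groups(m.barcodes, ["A", "A"], ["s1", "s1"])
        rna = cpm_log_normalize(pd.DataFrame({"g0": [100, 300]},
                                             index=m.barcodes))
        t = pseudobulk_epr(m, g, min_reads=0, min_edits=0, min_cells=0,
                           rna_normalized=rna)
        assert t.total_rna.loc["g0", "A"] == pytest.approx(rna["g0"].sum())
        assert t.mean_rna.loc["g0", "A"] == pytest.approx(rna["g0"].mean())


class TestPseudocells:
    def _matrix(self, n=30, g=4, seed=0):
        rng = np.random.default_rng(seed)
        return mat(rng.integers(0, 5, (n, g)), rng.integers(5, 30, (n, g)))

    def test_chunk_count(self):
        m = self._matrix(30)
        types = pd.Series("t1", index=m.barcodes)
        (pc,) = make_pseudocells(m, types, size=10, n_repeats=1, seed=0)
        assert pc.shape[0] == 3

    def test_size_one_is_identity_up_to_order(self):
        m = self._matrix(10)
        types = pd.Series("t1", index=m.barcodes)
        (pc,) = make_pseudocells(m, types, size=1, n_repeats=1, seed=0)
        got = np.sort(pc.edits_df().values, axis=0)
        want = np.sort(m.edits_df().values, axis=0)
        assert np.array_equal(got, want)

    def test_reads_conserved(self):
        m = self._matrix(25)
        types = pd.Series(["t1"] * 20 + ["t2"] * 5, index=m.barcodes)
        (pc,) = make_pseudocells(m, types, size=5, n_repeats=1, seed=1)
        # all cells used: 20 = 4 chunks of 5, 5 = 1 chunk
        assert pc.reads.sum() == m.reads.sum()

    def test_remainder_dropped_and_small_types_skipped(self):
        m = self._matrix(12)
        types = pd.Series(["t1"] * 9 + ["t2"] * 3, index=m.barcodes)
        (pc,) = make_pseudocells(m, types, size=5, n_repeats=1, seed=1)
        labels = pc.barcodes
        assert sum(l.startswith("t1") for l in labels) == 1
        assert not any(l.startswith("t2") for l in labels)

    def test_seed_reproducibility(self):
        m = self._matrix(30)
        types = pd.Series("t1", index=m.barcodes)
        a = make_pseudocells(m, types, size=5, n_repeats=3, seed=7)
        b = make_pseudocells(m, types, size=5, n_repeats=3, seed=7)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.edits.toarray(), mb.edits.toarray())
        c = make_pseudocells(m, types, size=5, n_repeats=3, seed=8)
        assert any(
            not np.array_equal(ma.edits.toarray(), mc.edits.toarray())
            for ma, mc in zip(a, c)
        )


class TestEditsC:
    def test_formula(self):
        m = mat([[2]], [[4]])
        out = compute_editsc(m, pd.Series({"g0": 100}),
                             min_edit_positive_cells=1)
        assert out.rate_df().iloc[0, 0] == pytest.approx(2 / (100 * 4))

    def test_transcript_exclusion_rule(self):
        # g0 edited in 5 cells (excluded), g1 in 6 cells (kept)
        edits = np.zeros((8, 2))
        edits[:5, 0] = 1
        edits[:6, 1] = 1
        m = mat(edits, np.full((8, 2), 10.0))
        out = compute_editsc(m, pd.Series({"g0": 50, "g1": 50}))
        assert out.features == ["g1"]

    def test_missing_c_content_is_error(self):
        m = mat([[1]], [[4]])
        with pytest.raises(ValueError, match="g0"):
            compute_editsc(m, pd.Series(dtype=float))

    def test_c_content_counts_sense_strand(self, sim_long_bundle):
        from pyfaidx import Fasta

        from ribostamp.alignment_io import load_transcript_models

        models = load_transcript_models(sim_long_bundle.gtf)
        cc = transcript_c_content(models, sim_long_bundle.fasta)
        fa = Fasta(str(sim_long_bundle.fasta), as_raw=True,
                   sequence_always_upper=True)
        for tid, model in models.items():
            s, e = model.span
            seq = str(fa[model.contig][s:e])
            base = "C" if model.strand == "+" else "G"
            assert cc[tid] == seq.count(base)
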