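"""EPR and EditsC quantification, Stamp normalization, aggregation.

EPR (edits per read) is the per cell-gene translational metric: total
C-to-U edits divided by total reads, masked below a minimum read depth.
EditsC is the isoform-level analogue for long reads: edited cytosines
divided by (total exonic cytosines x reads).

Stamp normalization removes the dependence of a cell's mean EPR on how
much editor construct the cell expresses: ordinary least squares of
log(mean EPR + 1) on log(Stamp CPM + 1), with exponentiated residuals
rescaled onto the original dynamic range; the ratio of corrected to
original mean EPR becomes a per-cell factor applied to the edit counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ribostamp.alignment_io import TranscriptModel
from ribostamp.matrix import CellFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationFit",
    "PseudobulkTable",
    "compute_epr",
    "filter_cells",
    "mean_epr",
    "fit_stamp_normalization",
    "apply_stamp_normalization",
    "pseudobulk_epr",
    "make_pseudocells",
    "compute_editsc",
    "transcript_c_content",
    "cpm_log_normalize",
]


@dataclass
class NormalizationFit:
    """Stamp-expression regression parameters and per-cell factors."""

    A: float
    b: float
    residual_range: tuple[float, float]
    target_range: tuple[float, float]
    factors: pd.Series  # barcode -> corrected/original mean-EPR ratio
    fitted_cells: list[str] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class PseudobulkTable:
    """Per-(feature, group, sample) pooled EPR plus filter flags.

    ``total_epr`` columns are (group, sample) MultiIndexed; ``group_mean``
    is the across-sample mean per group; ``passed`` marks features that
    satisfy all three retention conditions in at least one group.
    """

    total_epr: pd.DataFrame
    group_mean: pd.DataFrame
    passed: pd.Series
    total_rna: pd.DataFrame | None = None
    mean_rna: pd.DataFrame | None = None


# ----------------------------------------------------------------------
# EPR
# ----------------------------------------------------------------------


def compute_epr(
    matrix: CellFeatureMatrix, min_reads: int = 5
) -> CellFeatureMatrix:
    """EPR = edits / reads where reads >= ``min_reads``, else 0.

    Entries below the read-depth mask have both rate and edits zeroed, so
    downstream sums only ever see well-covered gene-cell pairs.
    """
    edits = matrix.edits.toarray().astype(float)
    reads = matrix.reads.toarray().astype(float)
    if edits.shape != reads.shape:
        raise ValueError("edits/reads shape mismatch")
    mask = reads >= min_reads
    edits = np.where(mask, edits, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(mask & (reads > 0), edits / np.where(reads > 0, reads, 1), 0.0)
    return CellFeatureMatrix.from_dense(
        matrix.barcodes, matrix.features, edits, matrix.reads.toarray(), rate
    )


def filter_cells(
    matrix: CellFeatureMatrix,
    min_edited_genes: int = 5,
    mode: str = "short",
) -> CellFeatureMatrix:
    """Drop cells with too few edited features.

    Short-read mode retains cells with at least ``min_edited_genes`` edited
    features; long-read mode drops cells with that many or fewer (strictly
    greater required), matching the two stated retention rules.
    """
    edited = (matrix.edits.toarray() > 0).sum(axis=1)
    if mode == "short":
        keep = edited >= min_edited_genes
    elif mode == "long":
        keep = edited > min_edited_genes
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        logger.warning("no cells pass the edited-feature filter")
    kept = [b for b, k in zip(matrix.barcodes, keep) if k]
    return matrix.subset_cells(kept)


def mean_epr(matrix: CellFeatureMatrix, min_reads: int = 3) -> pd.Series:
    """Per-cell mean EPR over edited genes.

    The mean is taken over genes with more than zero edits and at least
    ``min_reads`` reads (sum of per-gene EPR divided by the number of such
    genes); cells with no qualifying gene get NaN.
    """
    edits = matrix.edits.toarray().astype(float)
    reads = matrix.reads.toarray().astype(float)
    sel = (edits > 0) & (reads >= min_reads)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sel, edits / np.where(reads > 0, reads, 1), 0.0)
    n = sel.sum(axis=1)
    total = ratio.sum(axis=1)
    out = np.divide(total, n, out=np.full(len(total), np.nan), where=n > 0)
    return pd.Series(out, index=matrix.barcodes, name="mean_epr")


# ----------------------------------------------------------------------
# Stamp normalization
# ----------------------------------------------------------------------


def fit_stamp_normalization(
    mean_epr_values: pd.Series,
    stamp_counts: pd.Series,
    totals: pd.Series,
) -> NormalizationFit:
    """OLS of log1p(mean EPR) on log1p(Stamp CPM) over nonzero-Stamp cells.

    Residuals are exponentiated and min-max rescaled onto the range of the
    uncorrected mean EPR; the per-cell factor is corrected/original mean
    EPR.  Cells with zero Stamp expression (or undefined mean EPR) keep
    factor 1.  A constant predictor yields a degenerate fit with A=0 and
    all factors 1.
    """
    idx = mean_epr_values.index
    stamp_counts = stamp_counts.reindex(idx)
    totals = totals.reindex(idx)
    cpm = stamp_counts / totals.replace(0, np.nan) * 1e6
    sel = (stamp_counts > 0) & mean_epr_values.notna() & cpm.notna()
    factors = pd.Series(1.0, index=idx)
    if sel.sum() < 3:
        return NormalizationFit(
            A=0.0, b=0.0, residual_range=(1.0, 1.0), target_range=(0.0, 0.0),
            factors=factors, fitted_cells=[], degenerate=True,
        )
    x = np.log1p(cpm[sel].to_numpy(float))
    y = np.log1p(mean_epr_values[sel].to_numpy(float))
    vx = x.var()
    if vx == 0:
        logger.warning("constant Stamp CPM predictor; degenerate fit")
        return NormalizationFit(
            A=0.0, b=float(y.mean()), residual_range=(1.0, 1.0),
            target_range=(float(mean_epr_values[sel].min()),
                          float(mean_epr_values[sel].max())),
            factors=factors, fitted_cells=list(idx[sel]), degenerate=True,
        )
    A = float(np.cov(x, y, bias=True)[0, 1] / vx)
    b = float(y.mean() - A * x.mean())
    resid = y - (A * x + b)
    r_exp = np.exp(resid)
    r_min, r_max = float(r_exp.min()), float(r_exp.max())
    original = mean_epr_values[sel].to_numpy(float)
    t_min, t_max = float(original.min()), float(original.max())
    # a residual spread at float-noise level must not be stretched onto the
    # full target range; treat it as degenerate (factors 1)
    if (r_max - r_min) <= 1e-12 * max(r_max, 1.0) or t_max - t_min <= 0:
        corrected = original.copy()
        degenerate = True
    else:
        corrected = (r_exp - r_min) / (r_max - r_min) * (t_max - t_min) + t_min
        degenerate = False
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(original > 0, corrected / original, 1.0)
    factors.loc[idx[sel]] = f
    return NormalizationFit(
        A=A, b=b, residual_range=(r_min, r_max), target_range=(t_min, t_max),
        factors=factors, fitted_cells=list(idx[sel]), degenerate=degenerate,
    )


def apply_stamp_normalization(
    matrix: CellFeatureMatrix,
    fit: NormalizationFit,
    min_reads: int = 5,
) -> CellFeatureMatrix:
    """Scale each cell's edit counts by its factor and recompute EPR.

    The adjusted (fractional) edit matrix is re-masked at ``min_reads`` and
    the final rate is normalized edits over unadjusted read counts.
    """
    factors = fit.factors.reindex(matrix.barcodes).fillna(1.0).to_numpy(float)
    edits = matrix.edits.toarray().astype(float) * factors[:, None]
    reads = matrix.reads.toarray().astype(float)
    mask = reads >= min_reads
    edits = np.where(mask, edits, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(mask & (reads > 0), edits / np.where(reads > 0, reads, 1), 0.0)
    return CellFeatureMatrix.from_dense(
        matrix.barcodes, matrix.features, edits, reads, rate
    )


# ----------------------------------------------------------------------
# Pseudobulk / pseudocells
# ----------------------------------------------------------------------


def cpm_log_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """CPM per cell followed by log1p (natural log)."""
    totals = counts.sum(axis=1).replace(0, np.nan)
    return np.log1p(counts.div(totals, axis=0) * 1e6).fillna(0.0)


def pseudobulk_epr(
    matrix: CellFeatureMatrix,
    groups: pd.DataFrame,
    min_reads: int = 5,
    min_edits: int = 5,
    min_cells: int = 1,
    rna_normalized: pd.DataFrame | None = None,
) -> PseudobulkTable:
    """Pooled EPR per (feature, group, sample) with the retention filter.

    ``groups`` maps each barcode (index) to ``group`` and ``sample``
    columns.  Cell-feature observations below ``min_reads`` are masked
    before pooling.  Total EPR is the pooled ratio sum(edits)/sum(reads),
    not the mean of per-cell ratios.  A feature passes when, in at least
    one group, every sample has total reads >= ``min_reads``, total edits
    >= ``min_edits`` and at least ``min_cells`` cells over the read
    threshold.
    """
    missing = set(matrix.barcodes) - set(groups.index)
    if missing:
        raise ValueError(f"unmapped cells: {sorted(missing)[:5]}...")
    edits = matrix.edits_df()
    reads = matrix.reads_df()
    mask = reads >= min_reads
    edits = edits.where(mask, 0.0)
    reads_m = reads.where(mask, 0)
    g = groups.loc[matrix.barcodes]
    keys = pd.MultiIndex.from_arrays(
        [g["group"].to_numpy(), g["sample"].to_numpy()], names=["group", "sample"]
    )
    lv = ["group", "sample"]
    sum_edits = edits.set_axis(keys).groupby(level=lv).sum().T
    sum_reads = reads_m.set_axis(keys).groupby(level=lv).sum().T
    n_cells = mask.astype(int).set_axis(keys).groupby(level=lv).sum().T
    with np.errstate(divide="ignore", invalid="ignore"):
        total_epr = (sum_edits / sum_reads.replace(0, np.nan)).fillna(0.0)
    cond = (
        (sum_reads >= min_reads)
        & (sum_edits >= min_edits)
        & (n_cells >= min_cells)
    )
    # all samples within a group must pass, in at least one group
    passed = cond.T.groupby(level="group").all().T.any(axis=1)
    total_epr = total_epr.loc[passed[passed].index]
    group_mean = total_epr.T.groupby(level="group").mean().T
    total_rna = mean_rna = None
    if rna_normalized is not None:
        rna = rna_normalized.loc[matrix.barcodes]
        total_rna_s = rna.set_axis(keys).groupby(level=lv).sum().T
        mean_rna_s = rna.set_axis(keys).groupby(level=lv).mean().T
        total_rna = total_rna_s.T.groupby(level="group").mean().T
        mean_rna = mean_rna_s.T.groupby(level="group").mean().T
    return PseudobulkTable(
        total_epr=total_epr, group_mean=group_mean, passed=passed,
        total_rna=total_rna, mean_rna=mean_rna,
    )


def make_pseudocells(
    matrix: CellFeatureMatrix,
    cell_types: pd.Series,
    size: int,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[CellFeatureMatrix]:
    """Randomly group same-type cells into pseudocells, summing counts.

    Within each cell type, cells are shuffled by a seeded generator and
    chunked into floor(n/size) groups (the remainder is dropped, keeping
    pseudocell size homogeneous); edits and reads are summed per chunk and
    EPR recomputed as the pooled ratio.  One matrix per repeat, each with a
    distinct seed derived from ``seed``.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_repeats)
    edits = matrix.edits_df()
    reads = matrix.reads_df()
    types = cell_types.reindex(matrix.barcodes)
    out = []
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        rows_e, rows_r, labels = [], [], []
        for ctype in sorted(types.dropna().unique()):
            cells = [b for b in matrix.barcodes if types[b] == ctype]
            if len(cells) < size:
                logger.warning("cell type %s has fewer than %d cells; skipped",
                               ctype, size)
                continue
            order = list(rng.permutation(cells))
            n_chunks = len(order) // size
            for i in range(n_chunks):
                chunk = order[i * size : (i + 1) * size]
                rows_e.append(edits.loc[chunk].sum())
                rows_r.append(reads.loc[chunk].sum())
                labels.append(f"{ctype}|rep{rep}|{i}")
        e = pd.DataFrame(rows_e, index=labels)
        r = pd.DataFrame(rows_r, index=labels)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = (e / r.replace(0, np.nan)).fillna(0.0)
        out.append(
            CellFeatureMatrix.from_dense(
                labels, matrix.features, e.values, r.values, rate.values
            )
        )
    return out


# ----------------------------------------------------------------------
# EditsC
# ----------------------------------------------------------------------


def compute_editsc(
    matrix: CellFeatureMatrix,
    c_content: Mapping[str, int] | pd.Series,
    min_edit_positive_cells: int = 6,
) -> CellFeatureMatrix:
    """EditsC = edits / (exonic C count x reads) per cell and isoform.

    Transcripts observed with edits in fewer than
    ``min_edit_positive_cells`` cells are removed (the default drops
    transcripts with five or fewer edit-positive cells).  Every isoform in
    the matrix must have a positive C content.
    """
    c = pd.Series(c_content).reindex(matrix.features)
    missing = sorted(c[c.isna() | (c <= 0)].index)
    if missing:
        raise ValueError(f"isoforms without positive C content: {missing}")
    edits = matrix.edits.toarray().astype(float)
    reads = matrix.reads.toarray().astype(float)
    denom = c.to_numpy(float)[None, :] * reads
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(reads > 0, edits / np.where(denom > 0, denom, 1), 0.0)
    full = CellFeatureMatrix.from_dense(
        matrix.barcodes, matrix.features, edits, reads, rate
    )
    positive = (edits > 0).sum(axis=0)
    keep = [f for f, n in zip(matrix.features, positive)
            if n >= min_edit_positive_cells]
    return full.subset_features(keep)


def transcript_c_content(
    models: Mapping[str, TranscriptModel], fasta_path
) -> pd.Series:
    """Count cytosines on the mRNA sense strand over each transcript's exons.

    On plus-strand genes this counts genomic C within exons; on minus-strand
    genes the spliced mRNA's C corresponds to genomic G.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    out = {}
    for tid, m in models.items():
        base = "C" if m.strand == "+" else "G"
        n = 0
        for s, e in m.exons:
            n += str(fa[m.contig][s:e]).count(base)
        out[tid] = n
    return pd.Series(out, name="c_content")
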