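"""Translational states, bootstrap/Welch differential tests, stratification.

A two-component univariate Gaussian mixture splits cells into high/low
translational states by their total editing rate (total edits / total
reads); the higher-mean component is the "high" state.  Differential
translation between two cell types is tested either by vectorized
bootstrap resampling of per-replicate pseudobulk EPR (empirical p) or by
Welch's unequal-variance t-test on per-sample EditsC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureFit",
    "fit_translation_states",
    "total_edit_rate",
    "quantile_band_filter",
    "bootstrap_differential",
    "welch_differential",
    "find_discordant_isoforms",
    "stratify_extremes",
    "isoform_pair_correlations",
    "benjamini_hochberg",
]


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit over per-cell editing rates."""

    means: np.ndarray  # sorted ascending: [low, high]
    variances: np.ndarray
    weights: np.ndarray
    posterior_high: pd.Series  # P(high component) per cell
    assignment: pd.Series  # 'high' / 'low' per cell
    converged: bool
    n_iter: int
    degenerate: bool = False


def total_edit_rate(edits: pd.DataFrame, reads: pd.DataFrame) -> pd.Series:
    """Per-cell total editing rate: sum(edits) / sum(reads)."""
    se = edits.sum(axis=1)
    sr = reads.sum(axis=1)
    return (se / sr.replace(0, np.nan)).fillna(0.0).rename("total_edit_rate")


def fit_translation_states(
    values: pd.Series | np.ndarray,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> MixtureFit:
    """EM fit of a 1-D two-component Gaussian mixture with high/low labels.

    Components are initialized at the 25th/75th percentiles with pooled
    variance (deterministic; ``seed`` is accepted for interface parity and
    unused by the closed-form initialization).  Convergence is declared
    when the log-likelihood improves by less than ``tol``.  Cells are
    assigned by maximum posterior probability and the component with the
    larger mean is labelled "high".  Zero-variance input yields a flagged
    degenerate fit with every cell "low".
    """
    if isinstance(values, pd.Series):
        index = values.index
        x = values.to_numpy(float)
    else:
        x = np.asarray(values, float)
        index = pd.RangeIndex(len(x))
    if len(x) < 4:
        raise ValueError("need at least 4 cells")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("values must be finite and non-negative")
    if np.ptp(x) == 0:
        return MixtureFit(
            means=np.array([x[0], x[0]]),
            variances=np.array([0.0, 0.0]),
            weights=np.array([1.0, 0.0]),
            posterior_high=pd.Series(0.0, index=index),
            assignment=pd.Series("low", index=index),
            converged=False, n_iter=0, degenerate=True,
        )
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:
        mu[1] = mu[0] + np.ptp(x) * 0.1
    var = np.full(2, max(x.var(), 1e-12))
    w = np.array([0.5, 0.5])
    floor = max(x.var() * 1e-8, 1e-300)
    ll_old = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E step
        log_pdf = stats.norm.logpdf(x[:, None], mu[None, :], np.sqrt(var)[None, :])
        log_r = np.log(w)[None, :] + log_pdf
        log_norm = np.logaddexp(log_r[:, 0], log_r[:, 1])
        resp = np.exp(log_r - log_norm[:, None])
        ll = float(log_norm.sum())
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, floor)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
    order = np.argsort(mu)
    mu, var, w = mu[order], var[order], w[order]
    resp = resp[:, order]
    posterior_high = pd.Series(resp[:, 1], index=index)
    assignment = pd.Series(
        np.where(resp[:, 1] > resp[:, 0], "high", "low"), index=index
    )
    if mu[1] == mu[0]:
        logger.warning("mixture components collapsed to one mean")
    return MixtureFit(
        means=mu, variances=var, weights=w,
        posterior_high=posterior_high, assignment=assignment,
        converged=converged, n_iter=n_iter,
    )


def quantile_band_filter(
    values: pd.Series, low: float = 0.65, high: float = 0.80
) -> pd.Index:
    """Cells whose value lies between two quantiles of the distribution.

    Used to retain cells inside a quantile window of editor-construct RNA
    counts before state analysis.
    """
    lo, hi = values.quantile([low, high])
    return values[(values >= lo) & (values <= hi)].index


# ----------------------------------------------------------------------
# Differential tests
# ----------------------------------------------------------------------


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    out = np.full(len(mean_a), np.nan)
    ok = (mean_a > 0) & (mean_b > 0)
    out[ok] = np.log2(mean_a[ok] / mean_b[ok])
    return out


def bootstrap_differential(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    two_sided: bool = True,
    smooth: bool = False,
    chunk_size: int = 256,
) -> pd.DataFrame:
    """Per-feature bootstrap test of group mean difference, empirical p.

    Rows are features, columns replicates.  Per iteration the pooled
    replicate values of a feature are resampled with replacement and
    reassigned to the two groups at their original sizes; the statistic is
    the group mean difference (absolute for the two-sided default).  The
    empirical p-value is the fraction of bootstrap statistics greater than
    or equal to the observed one; with ``smooth`` it becomes
    (1 + k) / (1 + n_boot) to avoid exact zeros.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if not values_a.index.equals(values_b.index):
        raise ValueError("feature indices differ between groups")
    a = values_a.to_numpy(float)
    b = values_b.to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    pooled = np.concatenate([a, b], axis=1)
    obs = a.mean(axis=1) - b.mean(axis=1)
    obs_stat = np.abs(obs) if two_sided else obs
    rng = np.random.default_rng(seed)
    count = np.zeros(len(pooled))
    for start in range(0, len(pooled), chunk_size):
        block = pooled[start : start + chunk_size]
        idx = rng.integers(0, n, size=(len(block), n_boot, n))
        res = np.take_along_axis(block[:, None, :], idx, axis=2)
        diff = res[:, :, :na].mean(axis=2) - res[:, :, na:].mean(axis=2)
        stat = np.abs(diff) if two_sided else diff
        count[start : start + chunk_size] = (
            stat >= obs_stat[start : start + chunk_size, None]
        ).sum(axis=1)
    if smooth:
        p = (1.0 + count) / (1.0 + n_boot)
    else:
        p = count / n_boot
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": _log2fc(mean_a, mean_b),
            "p": p,
            "test": "bootstrap",
            "n_boot": n_boot,
        },
        index=values_a.index,
    )


def bootstrap_retention_mask(
    epr_per_replicate: pd.DataFrame,
) -> pd.Series:
    """Features with non-zero pooled EPR in every replicate of both groups."""
    return (epr_per_replicate > 0).all(axis=1)


def welch_differential(
    values_a: pd.DataFrame, values_b: pd.DataFrame
) -> pd.DataFrame:
    """Two-sample unequal-variance (Welch) t-test per feature.

    Rows are features, columns samples; at least two samples per group.
    Features with zero variance in both groups and equal means get t=0,
    p=1 rather than NaN.
    """
    if values_a.shape[1] < 2 or values_b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    if not values_a.index.equals(values_b.index):
        raise ValueError("feature indices differ between groups")
    a = values_a.to_numpy(float)
    b = values_b.to_numpy(float)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # near-identical rows trip scipy's precision warning; the
        # zero-variance case is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal = zero_var & (mean_a == mean_b)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": _log2fc(mean_a, mean_b),
            "t": t,
            "p": p,
            "test": "welch",
        },
        index=values_a.index,
    )


def find_discordant_isoforms(
    results: pd.DataFrame,
    gene_map: pd.Series,
    alpha: float = 0.05,
) -> dict[str, tuple[list[str], list[str]]]:
    """Genes with significant isoforms changing in opposite directions.

    Keeps transcripts with p < ``alpha``, groups them by gene, and reports
    only genes having at least one significant isoform with positive
    log2FC and one with negative log2FC, as (up, down) transcript lists.
    """
    sig = results[(results["p"] < alpha) & results["log2fc"].notna()]
    out: dict[str, tuple[list[str], list[str]]] = {}
    genes = gene_map.reindex(sig.index)
    for gene, sub_idx in sig.groupby(genes).groups.items():
        sub = sig.loc[sub_idx]
        up = sorted(sub.index[sub["log2fc"] > 0])
        down = sorted(sub.index[sub["log2fc"] < 0])
        if up and down:
            out[str(gene)] = (up, down)
    return out


# ----------------------------------------------------------------------
# Stratification and isoform correlations
# ----------------------------------------------------------------------


def stratify_extremes(
    values: pd.Series,
    mode: str = "quartiles",
    gene_map: pd.Series | None = None,
    total_reads: pd.Series | None = None,
    min_total_reads: int = 20,
):
    """Quartile labels or per-gene highest/lowest isoform pairs.

    Quartile mode rank-cuts ``values`` into Q1 (lowest) to Q4 (highest)
    with near-equal bin sizes; ties break by rank with stable ordering on
    feature id.  Extremes mode keeps transcripts whose gene has at least
    two isoforms after the total-read filter (strictly greater than
    ``min_total_reads`` summed across samples) and returns a frame of
    (gene, high isoform, low isoform).
    """
    if mode == "quartiles":
        if len(values) < 4:
            raise ValueError("need at least 4 transcripts for quartiles")
        order = values.to_frame("v").assign(fid=values.index).sort_values(
            ["v", "fid"], kind="mergesort"
        )
        ranks = np.arange(len(order))
        labels = pd.Series(
            [f"Q{r * 4 // len(order) + 1}" for r in ranks], index=order.index
        )
        return labels.reindex(values.index)
    if mode == "extremes":
        if gene_map is None:
            raise ValueError("extremes mode needs a gene map")
        keep = values.index
        if total_reads is not None:
            keep = keep[total_reads.reindex(keep) > min_total_reads]
        vals = values.loc[keep]
        genes = gene_map.reindex(keep)
        rows = []
        for gene, sub_idx in vals.groupby(genes).groups.items():
            sub = vals.loc[sub_idx]
            if len(sub) < 2:
                continue
            rows.append(
                {"gene": gene, "high": sub.idxmax(), "low": sub.idxmin()}
            )
        return pd.DataFrame(rows, columns=["gene", "high", "low"])
    raise ValueError(f"unknown mode {mode!r}")


def isoform_pair_correlations(
    values: pd.DataFrame, gene_map: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Spearman rho for every unordered isoform pair within each gene.

    ``values`` is features x cell types (mean pseudobulk values); needs at
    least 3 cell types.  Pairs where either profile is constant are skipped
    and counted.  Returns the pair table (gene, iso_a, iso_b, rho) and the
    skipped-pair count; the fraction of pairs with rho <= 0 is a column
    consumer one-liner: ``(table.rho <= 0).mean()``.
    """
    if values.shape[1] < 3:
        raise ValueError("need at least 3 cell types")
    genes = gene_map.reindex(values.index)
    rows = []
    skipped = 0
    for gene, sub_idx in values.groupby(genes).groups.items():
        isoforms = sorted(sub_idx)
        for iso_a, iso_b in combinations(isoforms, 2):
            va = values.loc[iso_a].to_numpy(float)
            vb = values.loc[iso_b].to_numpy(float)
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                skipped += 1
                continue
            rho = stats.spearmanr(va, vb).statistic
            rows.append({"gene": gene, "iso_a": iso_a, "iso_b": iso_b, "rho": rho})
    return pd.DataFrame(rows, columns=["gene", "iso_a", "iso_b", "rho"]), skipped


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional utility)."""
    p_arr = p.to_numpy(float)
    n = len(p_arr)
    order = np.argsort(p_arr)
    ranked = p_arr[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return pd.Series(out, index=p.index, name="p_adj")
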