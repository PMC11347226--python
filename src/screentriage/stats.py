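"""Differential-abundance statistics for pooled screen counts.

Per-construct treated-vs-control testing uses a simplified
negative-binomial Wald scheme: median-of-ratios size factors, a
method-of-moments dispersion with trend shrinkage, a pseudocounted
log2 fold change of normalized group means, and a delta-method standard
error.  Gene-level calls aggregate the constructs of a gene by their
median log2FC; the non-targeting controls are randomly partitioned into
pseudo-genes of matching size to provide an empirical null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quant import NTC_GENE, CountTable, LibraryDesign

__all__ = [
    "estimate_size_factors",
    "estimate_dispersion",
    "test_constructs",
    "bin_ntcs",
    "aggregate_genes",
    "NtcBinning",
]

#: pseudocount added to normalized group means in the log2FC
LFC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every construct with all-positive counts, each sample's count is
    divided by the construct's geometric mean across samples; the sample
    size factor is the median of those ratios.  If no construct is
    positive everywhere, the geometric means are computed over each
    construct's positive samples instead (with a warning).
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        log = np.log(arr)
    if all_pos.any():
        log_gm = log[all_pos].mean(axis=1)
        ratios = arr[all_pos] / np.exp(log_gm)[:, None]
    else:
        warnings.warn(
            "no construct detected in every sample; size factors fall back to "
            "positive-subset geometric means",
            RuntimeWarning,
            stacklevel=2,
        )
        any_pos = (arr > 0).any(axis=1)
        if not any_pos.any():
            raise ValueError("all-zero count matrix")
        masked = np.where(arr > 0, log, np.nan)
        log_gm = np.nanmean(masked[any_pos], axis=1)
        ratios = np.where(arr[any_pos] > 0, arr[any_pos] / np.exp(log_gm)[:, None], np.nan)
    sf = np.nanmedian(ratios, axis=0)
    sf = sf / np.exp(np.log(sf).mean())  # geometric mean 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _group_arrays(counts: pd.DataFrame, size_factors: pd.Series, groups: pd.Series):
    norm = counts / size_factors
    return {g: norm.loc[:, groups.index[groups == g]].to_numpy(dtype=float) for g in groups.unique()}


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series,
    n_bins: int = 20,
    prior_df: float = 24.0,
) -> pd.Series:
    """Per-construct NB dispersion (variance = mu + alpha * mu^2).

    Method-of-moments on size-factor-normalized counts, pooled across the
    replicate groups, then shrunk toward the mean raw estimate of
    constructs of similar abundance (``n_bins`` equal-occupancy abundance
    bins).  The raw estimate's weight grows with its residual degrees of
    freedom, df / (df + prior_df): at 3-vs-3 the trend dominates (the
    zero-truncated per-construct estimate is far too noisy there and
    makes downstream Wald tests anticonservative), while at tens of
    replicates the per-construct value takes over.  Designs with a
    single replicate per group take the dispersion entirely from the
    trend of whatever groups have replication; with no replicated group
    at all an error is raised.
    """
    by_group = _group_arrays(counts, size_factors, groups)
    n_constructs = counts.shape[0]
    ss = np.zeros(n_constructs)
    df = 0
    mu_sum = np.zeros(n_constructs)
    n_tot = 0
    for arr in by_group.values():
        n_g = arr.shape[1]
        mu_sum += arr.sum(axis=1)
        n_tot += n_g
        if n_g >= 2:
            gm = arr.mean(axis=1)
            ss += ((arr - gm[:, None]) ** 2).sum(axis=1)
            df += n_g - 1
    mu = mu_sum / n_tot
    if df == 0:
        raise ValueError("dispersion estimation needs at least one group with >=2 replicates")
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)
    # abundance-trend shrinkage: mean raw estimate within abundance bins
    order = np.argsort(np.argsort(mu))
    bins = np.minimum((order * n_bins) // n_constructs, n_bins - 1)
    trend = np.empty(n_constructs)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            trend[mask] = raw[mask].mean()
    w_raw = df / (df + prior_df)
    alpha = w_raw * raw + (1 - w_raw) * trend
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def test_constructs(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series,
    groups: pd.Series,
    treated: str = "treated",
    control: str = "vehicle",
) -> pd.DataFrame:
    """Per-construct Wald test of treated vs control abundance.

    log2FC = log2((m_T + c0) / (m_C + c0)) on normalized group means with
    pseudocount c0 = 0.5.  The standard error comes from the delta method
    under the NB variance function evaluated at the group means; p is the
    two-sided normal tail of log2FC / SE, and padj the BH adjustment over
    all constructs.  Constructs with zero counts in both groups are
    flagged untestable (log2FC 0, p 1).
    """
    for g in (treated, control):
        if (groups == g).sum() == 0:
            raise ValueError(f"no samples in group {g!r}")
    by_group = _group_arrays(counts, size_factors, groups)
    arr_t, arr_c = by_group[treated], by_group[control]
    n_t, n_c = arr_t.shape[1], arr_c.shape[1]
    m_t, m_c = arr_t.mean(axis=1), arr_c.mean(axis=1)
    alpha = dispersion.reindex(counts.index).to_numpy()

    lfc = np.log2((m_t + LFC_PSEUDOCOUNT) / (m_c + LFC_PSEUDOCOUNT))
    mt = np.maximum(m_t, LFC_PSEUDOCOUNT)
    mc = np.maximum(m_c, LFC_PSEUDOCOUNT)
    var_log = (1 / n_t) * (1 / mt + alpha) + (1 / n_c) * (1 / mc + alpha)
    se = np.sqrt(var_log) / np.log(2)
    untestable = (m_t == 0) & (m_c == 0)
    lfc[untestable] = 0.0
    z = np.where(se > 0, lfc / se, 0.0)
    p = 2 * sps.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[untestable] = 1.0
    z[untestable] = 0.0
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2FC": lfc,
            "SE": se,
            "wald_z": z,
            "p": p,
            "padj": padj,
            "untestable": untestable,
        },
        index=counts.index,
    )


@dataclass(frozen=True)
class NtcBinning:
    """Partition of NTC constructs into pseudo-genes (NTC1, NTC2, ...)."""

    assignment: pd.Series  # construct_id -> pseudo-gene label
    seed: int

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.assignment.value_counts().sort_index().to_dict()


def bin_ntcs(ntc_ids: list[str], seed: int, sizes: tuple[int, ...] | None = None) -> NtcBinning:
    """Randomly partition NTC constructs into pseudo-genes.

    With the standard 18 controls the sizes are (5, 5, 4, 4), matching
    the 4-5 guide groups of targeting genes; for other counts an explicit
    ``sizes`` tuple summing to ``len(ntc_ids)`` must be given.
    """
    n = len(ntc_ids)
    if sizes is None:
        if n != 18:
            raise ValueError(f"{n} NTCs: pseudo-gene sizes must be supplied explicitly")
        sizes = (5, 5, 4, 4)
    if sum(sizes) != n:
        raise ValueError(f"sizes {sizes} do not sum to {n}")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(ntc_ids, dtype=object)[rng.permutation(n)])
    labels: dict[str, str] = {}
    start = 0
    for i, size in enumerate(sizes, start=1):
        for cid in shuffled[start : start + size]:
            labels[cid] = f"NTC{i}"
        start += size
    return NtcBinning(pd.Series(labels).sort_index(), seed)


def aggregate_genes(
    construct_stats: pd.DataFrame,
    design: LibraryDesign,
    ntc_binning: NtcBinning | None = None,
    lfc_threshold: float = -1.0,
    p_threshold: float = 0.05,
    min_sig_constructs: int = 2,
) -> pd.DataFrame:
    """Gene-level summary: median log2FC, SEM, and the essentiality call.

    A gene is essential iff its median construct log2FC is below
    ``lfc_threshold`` (default -1, i.e. at least twofold dropout) and at
    least ``min_sig_constructs`` of its constructs are individually
    depleted (log2FC < threshold and p < ``p_threshold``).  NTC
    constructs are aggregated into the pseudo-genes of ``ntc_binning``.
    """
    gene_map = design.gene_of().copy()
    if ntc_binning is not None:
        gene_map.loc[ntc_binning.assignment.index] = ntc_binning.assignment
    stats = construct_stats.copy()
    stats["gene"] = gene_map.reindex(stats.index)

    testable = stats[~stats["untestable"]] if "untestable" in stats else stats
    dropped = set(stats["gene"].dropna()) - set(testable["gene"].dropna())
    if dropped:
        warnings.warn(
            f"genes with no testable construct excluded: {sorted(dropped)}",
            RuntimeWarning,
            stacklevel=2,
        )

    rows = []
    for gene, sub in testable.groupby("gene", sort=True):
        lfc = sub["log2FC"].to_numpy()
        n_sig = int(((lfc < lfc_threshold) & (sub["p"].to_numpy() < p_threshold)).sum())
        median = float(np.median(lfc))
        sem = float(sps.sem(lfc, ddof=1)) if len(lfc) > 1 else 0.0
        rows.append(
            {
                "gene": gene,
                "median_log2FC": median,
                "sem": sem,
                "n_constructs": len(lfc),
                "n_sig_constructs": n_sig,
                "essential": bool(median < lfc_threshold and n_sig >= min_sig_constructs),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def screen_gene_stats(
    table: CountTable,
    design: LibraryDesign,
    context: str,
    ntc_seed: int = 0,
    treated: str = "treated",
    control: str = "vehicle",
    **aggregate_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience pipeline for one screen context.

    Selects the context's treated and control samples, runs size-factor
    normalization, dispersion estimation and per-construct Wald tests,
    and aggregates to gene level with NTC pseudo-genes.  Returns
    (construct table, gene table).
    """
    sub = table.select(context=context)
    keep = sub.sample_meta["treatment"].isin([treated, control])
    sub = CountTable(sub.counts.loc[:, keep.index[keep]], sub.sample_meta.loc[keep.index[keep]])
    groups = sub.sample_meta["treatment"]
    sf = estimate_size_factors(sub.counts)
    disp = estimate_dispersion(sub.counts, sf, groups)
    cstats = test_constructs(sub.counts, sf, disp, groups, treated=treated, control=control)
    ntcs = design.ntc_ids
    binning = bin_ntcs(ntcs, ntc_seed) if len(ntcs) == 18 else None
    gstats = aggregate_genes(cstats, design, ntc_binning=binning, **aggregate_kwargs)
    return cstats, gstats
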