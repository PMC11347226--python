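"""Spike-in-normalized chromatin occupancy at promoters and its linkage
to gene regulation.

Samples sequenced together with a fixed amount of foreign-species
spike-in chromatin are rescaled so their spike-in read totals agree;
global losses of experimental signal then survive normalization instead
of being washed out.  Promoter occupancy is the (scaled) count of read
starts in the strand-aware TSS +/- 3 kb window; regulation-occupancy
relationships are summarized by equal-width or equal-count bin plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

__all__ = [
    "GenomeAnnotation",
    "OccupancySet",
    "spike_scaling",
    "promoter_signal",
    "feature_distribution",
    "random_intervals",
    "regulation_occupancy_binplot",
    "rank_binplot",
    "promoter_correlation",
]

PROMOTER_HALF_WINDOW = 3000
DOWNSTREAM_EXTENT = 2000


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene coordinate table: gene, chrom, strand, tss, tes.

    Coordinates are 0-based half-open; ``tss`` is the strand-aware
    5' end (for minus-strand genes the genomically larger coordinate),
    ``tes`` the 3' end.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "strand", "tss", "tes"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be + or -")
        plus = self.table["strand"] == "+"
        if (self.table.loc[plus, "tes"] <= self.table.loc[plus, "tss"]).any():
            raise ValueError("plus-strand genes require tes > tss")
        if (self.table.loc[~plus, "tes"] >= self.table.loc[~plus, "tss"]).any():
            raise ValueError("minus-strand genes require tes < tss")
        if (self.table[["tss", "tes"]].to_numpy() < 0).any():
            raise ValueError("negative coordinates")

    def promoter_windows(self) -> pd.DataFrame:
        """Genomic promoter windows [tss-3kb, tss+3kb), truncated at 0."""
        tss = self.table["tss"].to_numpy()
        start = tss - PROMOTER_HALF_WINDOW
        if (start < 0).any():
            warnings.warn("promoter window truncated at chromosome start", RuntimeWarning)
        return pd.DataFrame(
            {
                "gene": self.table["gene"],
                "chrom": self.table["chrom"],
                "start": np.maximum(start, 0),
                "end": tss + PROMOTER_HALF_WINDOW,
            }
        )

    @classmethod
    def from_tsv(cls, path) -> "GenomeAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class OccupancySet:
    """Per-promoter occupancy for a vehicle/treated sample pair.

    ``raw`` and ``normalized`` are promoters x samples read-count
    matrices; ``spike`` holds per-sample experimental / spike-in read
    totals and the scaling factor; ``regulation`` is the per-gene
    expression log2FC linked to each promoter.
    """

    raw: pd.DataFrame
    spike: pd.DataFrame
    normalized: pd.DataFrame
    regulation: pd.Series


def spike_scaling(spike_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample scaling factor f = median(n_spike) / n_spike.

    ``spike_counts`` needs columns ``n_exp`` and ``n_spike`` indexed by
    sample.  Multiplying each sample's signal by its f equalizes
    spike-in totals across samples exactly.
    """
    n_spike = spike_counts["n_spike"].to_numpy(dtype=float)
    if (n_spike <= 0).any():
        raise ValueError("spike-in read counts must be positive")
    f = np.median(n_spike) / n_spike
    out = spike_counts.copy()
    out["f"] = f
    return out


def promoter_signal(
    reads: dict[str, pd.DataFrame],
    annotation: GenomeAnnotation,
    scaling: pd.DataFrame,
) -> pd.DataFrame:
    """Spike-scaled promoter occupancy: read starts in TSS +/- 3 kb.

    ``reads`` maps sample name to a BED-like frame (chrom, start, end)
    of read placements; a read is in the window iff its start coordinate
    falls in the half-open genomic interval.  Each count is multiplied
    by the sample's scaling factor ``f`` from ``scaling``.
    """
    windows = annotation.promoter_windows()
    out = {}
    for sample, bed in reads.items():
        f = float(scaling.loc[sample, "f"])
        signal = np.zeros(len(windows))
        for chrom, grp in bed.groupby("chrom"):
            starts = np.sort(grp["start"].to_numpy())
            mask = windows["chrom"] == chrom
            lo = np.searchsorted(starts, windows.loc[mask, "start"].to_numpy(), side="left")
            hi = np.searchsorted(starts, windows.loc[mask, "end"].to_numpy(), side="left")
            signal[np.flatnonzero(mask)] = hi - lo
        out[sample] = signal * f
    return pd.DataFrame(out, index=windows["gene"].to_numpy())


_FEATURES = ("promoter", "gene_body", "downstream", "intergenic")


def _feature_trees(annotation: GenomeAnnotation) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {f: {} for f in _FEATURES[:3]}

    def add(feature: str, chrom: str, start: int, end: int) -> None:
        start = max(int(start), 0)
        end = int(end)
        if end > start:
            trees[feature].setdefault(chrom, IntervalTree()).addi(start, end)

    for row in annotation.table.itertuples(index=False):
        tss, tes = int(row.tss), int(row.tes)
        add("promoter", row.chrom, tss - PROMOTER_HALF_WINDOW, tss + PROMOTER_HALF_WINDOW)
        if row.strand == "+":
            add("gene_body", row.chrom, tss + PROMOTER_HALF_WINDOW, tes)
            add("downstream", row.chrom, tes, tes + DOWNSTREAM_EXTENT)
        else:
            add("gene_body", row.chrom, tes, tss - PROMOTER_HALF_WINDOW)
            add("downstream", row.chrom, tes - DOWNSTREAM_EXTENT, tes)
    return trees


def feature_distribution(
    intervals: pd.DataFrame,
    annotation: GenomeAnnotation,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.Series:
    """Classify intervals by midpoint into promoter / gene body /
    downstream / intergenic and return the fraction in each class.

    Overlapping annotations are resolved by precedence
    promoter > gene body > downstream, making the classes a partition:
    the four fractions always sum to 1.
    """
    if chrom_sizes is not None:
        for row in intervals.itertuples(index=False):
            size = chrom_sizes.get(row.chrom)
            if size is None or row.end > size or row.start < 0:
                raise ValueError(f"interval off chromosome: {row}")
    trees = _feature_trees(annotation)
    mids = ((intervals["start"] + intervals["end"]) // 2).to_numpy()
    chroms = intervals["chrom"].to_numpy()
    counts = dict.fromkeys(_FEATURES, 0)
    for chrom, mid in zip(chroms, mids):
        for feature in _FEATURES[:3]:
            tree = trees[feature].get(chrom)
            if tree is not None and tree.overlaps_point(int(mid)):
                counts[feature] += 1
                break
        else:
            counts["intergenic"] += 1
    total = len(intervals)
    if total == 0:
        raise ValueError("no intervals to classify")
    return pd.Series({k: v / total for k, v in counts.items()}, name="fraction")


def random_intervals(
    chrom_sizes: dict[str, int],
    n: int = 100_000,
    length: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded random fixed-length intervals, chromosomes weighted by
    placeable length — the null reference for feature_distribution."""
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    room = np.array([max(chrom_sizes[c] - length, 0) for c in chroms], dtype=float)
    if room.sum() <= 0:
        raise ValueError("no chromosome can hold an interval of this length")
    probs = room / room.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    starts = (rng.random(n) * room[which]).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[which],
            "start": starts,
            "end": starts + length,
        }
    )


def _bin_frame(x: np.ndarray, y: np.ndarray, membership: np.ndarray, n_bins: int) -> pd.DataFrame:
    rows = []
    for b in range(n_bins):
        mask = membership == b
        n = int(mask.sum())
        rows.append(
            {
                "bin": b,
                "n": n,
                "mean_x": float(x[mask].mean()) if n else np.nan,
                "mean_y": float(y[mask].mean()) if n else np.nan,
                "sem_y": float(sps.sem(y[mask], ddof=1)) if n > 1 else 0.0 if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def regulation_occupancy_binplot(
    regulation: pd.Series,
    occupancy: pd.Series,
    n_bins: int = 8,
) -> tuple[pd.DataFrame, float, float]:
    """Equal-width binning of gene regulation against mean occupancy.

    Genes are split into ``n_bins`` equally distant bins spanning
    [min, max] of regulation; per bin the mean regulation, mean
    occupancy and SEM are reported, and Pearson r / p are computed on
    the non-empty bin means.
    """
    common = regulation.index.intersection(occupancy.index)
    if len(common) < n_bins:
        raise ValueError("fewer genes than bins")
    x = regulation.loc[common].to_numpy(dtype=float)
    y = occupancy.loc[common].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.min() == x.max():
        raise ValueError("all regulation values identical: equal-width binning undefined")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    membership = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    summary = _bin_frame(x, y, membership, n_bins)
    filled = summary.dropna(subset=["mean_x"])
    r, p = sps.pearsonr(filled["mean_x"], filled["mean_y"])
    return summary, float(r), float(p)


def rank_binplot(
    delta: pd.Series,
    covariate: pd.Series,
    n_bins: int = 15,
) -> pd.DataFrame:
    """Equal-count binning: promoters sorted by ``delta`` (most negative
    first, i.e. strongest decrease leading) and split into ``n_bins``
    equal-size bins, remainder spread over the leading bins; per bin the
    mean delta and mean covariate are reported."""
    common = delta.index.intersection(covariate.index)
    if len(common) < n_bins:
        raise ValueError("fewer promoters than bins")
    order = delta.loc[common].sort_values(kind="mergesort").index
    x = delta.loc[order].to_numpy(dtype=float)
    y = covariate.loc[order].to_numpy(dtype=float)
    membership = np.concatenate(
        [np.full(len(chunk), b) for b, chunk in enumerate(np.array_split(np.arange(len(x)), n_bins))]
    )
    return _bin_frame(x, y, membership, n_bins)


def promoter_correlation(signal_a: pd.Series, signal_b: pd.Series) -> tuple[float, float]:
    """Pearson r and t-test p between two occupancy signals over the
    shared promoter universe."""
    common = signal_a.index.intersection(signal_b.index)
    if len(common) < 4:
        raise ValueError("need at least 4 shared promoters")
    x = signal_a.loc[common].to_numpy(dtype=float)
    y = signal_b.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
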