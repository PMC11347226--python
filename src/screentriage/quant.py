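"""Guide quantification: library parsing, exact-match read counting and
library-representation QC for pooled shRNA screens.

Reads are assigned to constructs by exact string identity of the guide
region (no mismatches tolerated, mirroring ``bowtie -v 0``).  Library
representation is judged by two rules: every construct must be detected,
and more than 80% of constructs must lie within 10-fold of the median
non-zero abundance.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

NTC_GENE = "NTC"

__all__ = [
    "NTC_GENE",
    "LibraryDesign",
    "CountTable",
    "RepresentationReport",
    "read_library",
    "read_fastq",
    "count_reads",
    "representation_qc",
]


class LibraryValidationError(ValueError):
    """Raised when a library design violates its invariants."""


@dataclass(frozen=True)
class LibraryDesign:
    """The screen's construct universe.

    ``table`` has columns ``construct_id``, ``gene``, ``guide_seq`` and
    optionally ``full_oligo``.  Non-targeting controls carry the gene
    label :data:`NTC_GENE`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"construct_id", "gene", "guide_seq"}
        missing = required - set(self.table.columns)
        if missing:
            raise LibraryValidationError(f"library table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise LibraryValidationError("library design is empty")
        ids = self.table["construct_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise LibraryValidationError(f"duplicate construct ids: {dupes}")
        guides = self.table["guide_seq"]
        if guides.duplicated().any():
            raise LibraryValidationError("duplicate guide sequences in library")
        lengths = guides.str.len().unique()
        if len(lengths) != 1:
            raise LibraryValidationError(f"guide sequences have mixed lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def construct_ids(self) -> pd.Index:
        return pd.Index(self.table["construct_id"])

    @property
    def guide_length(self) -> int:
        return int(self.table["guide_seq"].str.len().iloc[0])

    @property
    def is_ntc(self) -> pd.Series:
        return (self.table["gene"] == NTC_GENE).set_axis(self.construct_ids)

    @property
    def ntc_ids(self) -> list[str]:
        return self.table.loc[self.table["gene"] == NTC_GENE, "construct_id"].tolist()

    @property
    def targeting_genes(self) -> list[str]:
        genes = self.table.loc[self.table["gene"] != NTC_GENE, "gene"]
        return sorted(genes.unique())

    def gene_of(self) -> pd.Series:
        """construct_id -> gene mapping as a Series."""
        return self.table.set_index("construct_id")["gene"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CountTable:
    """Integer construct x sample count matrix with per-sample metadata.

    ``sample_meta`` is indexed by sample name with columns ``context``,
    ``treatment`` (vehicle / treated / input) and ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.sample_meta.index):
            if set(self.counts.columns) != set(self.sample_meta.index):
                raise ValueError("count columns and sample metadata disagree")
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(arr.dtype, np.integer) and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def select(self, context: str | None = None, treatment: str | None = None) -> "CountTable":
        meta = self.sample_meta
        keep = pd.Series(True, index=meta.index)
        if context is not None:
            keep &= meta["context"] == context
        if treatment is not None:
            keep &= meta["treatment"] == treatment
        cols = meta.index[keep]
        return CountTable(self.counts[cols], meta.loc[cols])

    def to_tsv(self, counts_path, meta_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="construct_id")
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="construct_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
        return cls(counts, meta)


@dataclass(frozen=True)
class RepresentationReport:
    """Outcome of the library-uniformity QC on one sample."""

    n_detected: int
    library_size: int
    fraction_within_10fold: float
    uniform: bool = field(default=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def read_library(path) -> LibraryDesign:
    """Parse a library design TSV (construct_id, gene, guide_seq[, full_oligo])."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise LibraryValidationError(f"empty library file: {path}") from exc
    for i, row in enumerate(table.itertuples(index=False), start=2):
        for value in (row.construct_id, row.gene, row.guide_seq):
            if not isinstance(value, str) or value == "":
                raise LibraryValidationError(f"{path}: malformed row at line {i}: {row}")
    bad = ~table["guide_seq"].str.fullmatch("[ACGT]+")
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise LibraryValidationError(f"{path}: non-ACGT guide sequence at line {line}")
    return LibraryDesign(table)


def read_fastq(path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzip)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip().upper()


_REVCOMP = str.maketrans("ACGT", "TGCA")


def count_reads(
    reads: Iterable[str],
    design: LibraryDesign,
    offset: int = 0,
    reverse_complement: bool = False,
) -> tuple[pd.Series, int]:
    """Count reads per construct by exact guide matching.

    A read increments exactly one construct iff its guide-region substring
    equals that construct's guide with no mismatches.  The expected guide
    ``offset`` within the read is probed first; failing that, every
    substring position is scanned and the first hit wins.  Returns the
    per-construct counts (indexed by construct_id) and the number of
    unmatched reads; matched + unmatched always equals the read total.
    """
    k = design.guide_length
    lookup = dict(zip(design.table["guide_seq"], design.table["construct_id"]))
    counts = {cid: 0 for cid in design.construct_ids}
    unmatched = 0
    for read in reads:
        if reverse_complement:
            read = read.translate(_REVCOMP)[::-1]
        hit = None
        if len(read) >= offset + k:
            hit = lookup.get(read[offset : offset + k])
        if hit is None and len(read) >= k:
            for pos in range(len(read) - k + 1):
                if pos == offset:
                    continue
                cand = lookup.get(read[pos : pos + k])
                if cand is not None:
                    hit = cand
                    break
        if hit is None:
            unmatched += 1
        else:
            counts[hit] += 1
    return pd.Series(counts, name="count"), unmatched


def representation_qc(counts: pd.Series, design: LibraryDesign) -> RepresentationReport:
    """Apply the two-part library-uniformity rule to one sample's counts.

    The sample is uniform iff all constructs are detected and more than
    80% of constructs lie strictly within 10-fold of the median non-zero
    abundance.
    """
    counts = counts.reindex(design.construct_ids, fill_value=0)
    values = counts.to_numpy(dtype=float)
    n_detected = int((values > 0).sum())
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return RepresentationReport(0, len(design), 0.0, False)
    m = float(np.median(nonzero))
    with np.errstate(divide="ignore"):
        ratio = np.where(values > 0, np.maximum(values / m, m / values), np.inf)
    frac = float((ratio < 10.0).mean())
    uniform = (n_detected == len(design)) and (frac > 0.8)
    return RepresentationReport(n_detected, len(design), frac, uniform)
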