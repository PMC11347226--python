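"""Candidate triage: combine per-context screen results, dependency-
reference essentiality scores and expression-based filters into a ranked
shortlist of tumour-selective targets.

A gene advances when it (1) drops out in the in vivo screen
(median log2FC < -1), (2) is more essential in tumour cells than in
fibroblasts (delta log2FC < 0), (3) co-expresses with the oncogenic
activity score (Pearson r > 0.5) and (4) is overexpressed in tumours
versus normal tissue (log2FC > 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DependencyMatrix",
    "essentiality_score",
    "compare_screens",
    "rank_candidates",
    "TriageThresholds",
]


@dataclass(frozen=True)
class DependencyMatrix:
    """Binary genes x cell-lines matrix; 1 marks the gene essential in
    that line (DepMap-style CRISPR dependency calls)."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy()
        if arr.shape[1] == 0:
            raise ValueError("dependency matrix has no cell lines")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("dependency matrix entries must be 0/1")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "DependencyMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def essentiality_score(dep: DependencyMatrix, gene: str | None = None) -> pd.DataFrame:
    """Percentage of reference cell lines in which each gene is essential.

    Genes with a score >= 50% are classified common essential.  If
    ``gene`` is given, only that row is returned; an unknown gene raises
    KeyError.
    """
    mat = dep.matrix
    if gene is not None:
        if gene not in mat.index:
            raise KeyError(f"gene {gene!r} not in dependency matrix")
        mat = mat.loc[[gene]]
    score = 100.0 * mat.sum(axis=1) / dep.n_lines
    return pd.DataFrame({"score": score, "common_essential": score >= 50.0})


def compare_screens(
    gene_stats: dict[str, pd.DataFrame],
    context_a: str = "invitro",
    context_b: str = "invivo",
    lfc_threshold: float = -1.0,
) -> pd.DataFrame:
    """Join gene-level median log2FC across two screen contexts and label
    each gene's dependence class.

    Classes (threshold log2FC < -1 per context):
    ``dispensable_both``, ``essential_{a}_only``, ``essential_{b}_only``,
    ``essential_both``; genes missing either context are labelled
    ``incomplete`` and excluded from the four quadrants.
    """
    a = gene_stats[context_a]["median_log2FC"].rename(context_a)
    b = gene_stats[context_b]["median_log2FC"].rename(context_b)
    joined = pd.concat([a, b], axis=1)
    ess_a = joined[context_a] < lfc_threshold
    ess_b = joined[context_b] < lfc_threshold
    label = np.select(
        [
            joined.isna().any(axis=1),
            ess_a & ess_b,
            ess_a & ~ess_b,
            ~ess_a & ess_b,
        ],
        [
            "incomplete",
            "essential_both",
            f"essential_{context_a}_only",
            f"essential_{context_b}_only",
        ],
        default="dispensable_both",
    )
    joined["class"] = label
    return joined


@dataclass(frozen=True)
class TriageThresholds:
    """The four filter thresholds of the candidate triage."""

    essential_lfc: float = -1.0
    delta_lfc: float = 0.0
    coexpression_r: float = 0.5
    overexpression_lfc: float = 0.3


def rank_candidates(
    gene_stats: dict[str, pd.DataFrame],
    coexpression_r: pd.Series,
    overexpression_lfc: pd.Series,
    essentiality: pd.DataFrame | None = None,
    tumour_context: str = "invivo",
    fibroblast_context: str = "fibroblast",
    thresholds: TriageThresholds = TriageThresholds(),
) -> pd.DataFrame:
    """Apply the four triage filters and rank the survivors.

    Filters: in vivo essential (median log2FC < essential_lfc),
    tumour-selective (log2FC(tumour) - log2FC(fibroblast) < delta_lfc),
    co-expressed with the activity score (r > coexpression_r) and
    overexpressed in tumours (log2FC > overexpression_lfc).  Passing
    genes are ranked by descending r, ties broken by ascending in vivo
    log2FC.  The returned table carries every gene with its filter
    booleans; non-passing genes get rank NA.
    """
    tumour = gene_stats[tumour_context]["median_log2FC"].rename("lfc_tumour")
    fibro = gene_stats[fibroblast_context]["median_log2FC"].rename("lfc_fibroblast")
    table = pd.concat(
        [
            tumour,
            fibro,
            coexpression_r.rename("r_coexpr"),
            overexpression_lfc.rename("lfc_tumour_vs_normal"),
        ],
        axis=1,
    )
    table["delta_lfc"] = table["lfc_tumour"] - table["lfc_fibroblast"]
    table["pass_essential_invivo"] = table["lfc_tumour"] < thresholds.essential_lfc
    table["pass_tumour_selective"] = table["delta_lfc"] < thresholds.delta_lfc
    table["pass_coexpression"] = table["r_coexpr"] > thresholds.coexpression_r
    table["pass_overexpression"] = table["lfc_tumour_vs_normal"] > thresholds.overexpression_lfc
    filter_cols = [c for c in table.columns if c.startswith("pass_")]
    table["pass_all"] = table[filter_cols].fillna(False).all(axis=1)
    if essentiality is not None:
        table = table.join(essentiality.add_prefix("depmap_"))

    passing = table[table["pass_all"]].sort_values(
        ["r_coexpr", "lfc_tumour"], ascending=[False, True]
    )
    table["rank"] = pd.Series(
        np.arange(1, len(passing) + 1), index=passing.index, dtype="float"
    ).reindex(table.index)
    table.attrs["filter_fail_counts"] = {
        c: int((~table[c].fillna(False)).sum()) for c in filter_cols
    }
    return table.sort_values(["rank", "r_coexpr"], na_position="last")
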