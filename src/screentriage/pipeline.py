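"""End-to-end orchestration: synthetic inputs -> counting/QC ->
per-context screen statistics -> triage -> expression/survival ->
occupancy, with a run manifest and plot-ready report tables."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .occupancy import rank_binplot, regulation_occupancy_binplot
from .quant import LibraryDesign, representation_qc
from .simulate import (
    CohortSimParams,
    OccupancySimParams,
    ScreenSimParams,
    simulate_cohort,
    simulate_dependency_matrix,
    simulate_library,
    simulate_occupancy,
    simulate_screen_counts,
)
from .stats import screen_gene_stats
from .survival import (
    correlate_candidate,
    geneset_score,
    scale_expression,
    stratify_and_logrank,
    tumour_vs_normal_lfc,
)
from .triage import DependencyMatrix, TriageThresholds, essentiality_score, compare_screens, rank_candidates

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Single-file configuration of a full (synthetic) pipeline run.

    Every published-threshold default is surfaced: essential dropout
    log2FC -1 at p 0.05, common-essential score 50%, co-expression
    r 0.5, tumour overexpression log2FC 0.3.
    """

    seed: int = 0
    # synthetic screen
    n_genes: int = 92
    guides_per_gene: int = 5
    n_ntc: int = 18
    replicates_per_context: int = 3
    depth: float = 1000.0
    dispersion: float = 0.05
    bottleneck_cells: int | None = None
    planted_effects: dict = field(default_factory=dict)
    planted_candidate: str | None = None
    # cohort
    n_patients: int = 159
    geneset_size: int = 50
    planted_r: float = 0.7
    tumour_overexpression_lfc: float = 0.5
    survival_hazard_ratio: float = 3.0
    censoring_rate: float = 0.2
    # dependency reference
    n_cell_lines: int = 1086
    dependency_fractions: dict = field(default_factory=dict)
    # occupancy
    n_promoters: int = 2000
    spike_fraction: float = 0.06
    global_depletion: float = 0.2
    regulation_slope: float = -0.5
    # thresholds (published defaults)
    essential_lfc: float = -1.0
    p_threshold: float = 0.05
    min_sig_constructs: int = 2
    essentiality_cutoff: float = 50.0
    coexpression_r: float = 0.5
    overexpression_lfc: float = 0.3
    # mode flags for documented design decisions
    survival_mode: str = "intersection"
    restrict_most_aggressive: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage on synthetic inputs and write the run directory.

    Stages: simulate -> representation QC -> per-context construct and
    gene statistics -> cross-screen comparison -> dependency scores ->
    cohort expression/survival -> candidate triage -> occupancy bin
    plots.  Reruns with the same config are identical; the manifest
    records the config hash and per-stage row counts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_digest": config.digest(), "stages": {}}
    config.to_yaml(out / "config.yaml")

    # --- simulate screen -------------------------------------------------
    sp = ScreenSimParams(
        n_genes=config.n_genes,
        guides_per_gene=config.guides_per_gene,
        n_ntc=config.n_ntc,
        replicates_per_context=config.replicates_per_context,
        depth=config.depth,
        dispersion=config.dispersion,
        planted_effects=config.planted_effects,
        bottleneck_cells=config.bottleneck_cells,
        seed=config.seed,
    )
    design = simulate_library(sp)
    design.to_tsv(out / "library.tsv")
    table = simulate_screen_counts(design, sp)
    table.to_tsv(out / "counts.tsv", out / "samples.tsv")
    manifest["stages"]["simulate"] = {"constructs": len(design), "samples": len(table.samples)}

    # --- representation QC on each context's input sample ----------------
    qc = {}
    for ctx in sp.contexts:
        sample = f"{ctx}_input_r0"
        report = representation_qc(table.counts[sample], design)
        qc[sample] = {
            "n_detected": report.n_detected,
            "fraction_within_10fold": report.fraction_within_10fold,
            "uniform": report.uniform,
        }
    (out / "qc.json").write_text(json.dumps(qc, indent=2))
    manifest["stages"]["qc"] = qc

    # --- per-context differential abundance ------------------------------
    gene_stats: dict[str, pd.DataFrame] = {}
    construct_stats: dict[str, pd.DataFrame] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ctx in sp.contexts:
            cstats, gstats = screen_gene_stats(
                table,
                design,
                ctx,
                ntc_seed=config.seed,
                lfc_threshold=config.essential_lfc,
                p_threshold=config.p_threshold,
                min_sig_constructs=config.min_sig_constructs,
            )
            cstats.to_csv(out / f"constructs_{ctx}.tsv", sep="\t", index_label="construct_id")
            gstats.to_csv(out / f"genes_{ctx}.tsv", sep="\t")
            gene_stats[ctx] = gstats
            construct_stats[ctx] = cstats
    manifest["stages"]["test"] = {ctx: len(v) for ctx, v in construct_stats.items()}

    comparison = compare_screens(gene_stats, "invitro", "invivo", config.essential_lfc)
    comparison.to_csv(out / "screen_comparison.tsv", sep="\t", index_label="gene")

    # --- dependency reference --------------------------------------------
    genes = sp.gene_names
    fractions = {g: config.dependency_fractions.get(g, 0.0) for g in genes}
    dep = simulate_dependency_matrix(genes, config.n_cell_lines, fractions, seed=config.seed + 7)
    dep.to_tsv(out / "dependency.tsv")
    scores = essentiality_score(dep)
    scores.to_csv(out / "essentiality.tsv", sep="\t", index_label="gene")

    # --- expression cohort -------------------------------------------------
    candidate = config.planted_candidate or genes[0]
    background = tuple(g for g in genes if g != candidate)
    cp = CohortSimParams(
        n_patients=config.n_patients,
        n_genes=config.geneset_size + 1 + len(background),
        geneset_size=config.geneset_size,
        planted_r=config.planted_r,
        tumour_overexpression_lfc=config.tumour_overexpression_lfc,
        survival_hazard_ratio=config.survival_hazard_ratio,
        censoring_rate=config.censoring_rate,
        candidate_name=candidate,
        background_names=background,
        seed=config.seed + 13,
    )
    cohort = simulate_cohort(cp)
    cohort.fpkm.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index_label="sample")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = scale_expression(cohort.fpkm[cohort.tumour_samples])
    score = geneset_score(z, cohort.geneset)
    corr_rows = []
    for gene in genes:
        if gene in z.index and z.loc[gene].std() > 0:
            r, p = correlate_candidate(z.loc[gene], score)
            lfc, se = tumour_vs_normal_lfc(cohort.fpkm, cohort.sample_class, gene)
            corr_rows.append({"gene": gene, "r": r, "p": p, "lfc_tumour_vs_normal": lfc, "se": se})
    expr = pd.DataFrame(corr_rows).set_index("gene")
    expr.to_csv(out / "expression_filters.tsv", sep="\t")

    candidate_z = z.loc[candidate]
    surv = stratify_and_logrank(
        candidate_z,
        score,
        cohort.clinical,
        mode=config.survival_mode,
        restrict_most_aggressive=config.restrict_most_aggressive,
    )
    surv.km_curves.to_csv(out / "km_curves.tsv", sep="\t", index=False)
    manifest["stages"]["survival"] = {
        "logrank_chi2": surv.logrank_chi2,
        "p": surv.p,
        "n_high": surv.n_high,
        "n_low": surv.n_low,
    }

    # --- triage -----------------------------------------------------------
    candidates = rank_candidates(
        gene_stats,
        expr["r"],
        expr["lfc_tumour_vs_normal"],
        essentiality=scores,
        thresholds=TriageThresholds(
            essential_lfc=config.essential_lfc,
            coexpression_r=config.coexpression_r,
            overexpression_lfc=config.overexpression_lfc,
        ),
    )
    candidates.to_csv(out / "candidates.tsv", sep="\t", index_label="gene")
    manifest["stages"]["triage"] = {
        "n_passing": int(candidates["pass_all"].sum()),
        "filter_fail_counts": candidates.attrs["filter_fail_counts"],
        "top_candidate": str(candidates.index[0]) if candidates["pass_all"].any() else None,
    }

    # --- occupancy --------------------------------------------------------
    op = OccupancySimParams(
        n_promoters=config.n_promoters,
        spike_fraction=config.spike_fraction,
        global_depletion=config.global_depletion,
        regulation_slope=config.regulation_slope,
        seed=config.seed + 29,
    )
    occ = simulate_occupancy(op)
    occ.normalized.to_csv(out / "promoter_signal.tsv", sep="\t", index_label="promoter")
    occ.spike.to_csv(out / "spike_scaling.tsv", sep="\t")
    summary, r_bins, p_bins = regulation_occupancy_binplot(occ.regulation, occ.normalized["vehicle"])
    summary.to_csv(out / "binplot_regulation.tsv", sep="\t", index=False)
    delta = np.log2((occ.normalized["treated"] + 1) / (occ.normalized["vehicle"] + 1))
    rank_bins = rank_binplot(delta, occ.normalized["vehicle"])
    rank_bins.to_csv(out / "binplot_rank.tsv", sep="\t", index=False)
    manifest["stages"]["occupancy"] = {
        "binplot_r": r_bins,
        "binplot_p": p_bins,
        "global_signal_ratio": float(occ.normalized["treated"].sum() / occ.normalized["vehicle"].sum()),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def make_report(run_dir) -> Path:
    """Emit plot-ready summary tables from a completed run directory.

    Writes, per context: a waterfall table (genes sorted by ascending
    median log2FC) and a volcano table (construct log2FC vs -log10 p,
    NTC rows flagged); plus the cross-screen scatter table.  Raises if
    required stage outputs are missing.
    """
    run = Path(run_dir)
    required = ["library.tsv", "screen_comparison.tsv", "essentiality.tsv"]
    contexts = sorted(
        p.stem.replace("genes_", "") for p in run.glob("genes_*.tsv")
    )
    missing = [f for f in required if not (run / f).exists()]
    if not contexts:
        missing.append("genes_<context>.tsv")
    if missing:
        raise FileNotFoundError(f"incomplete run at {run}: missing {missing}")
    report = run / "report"
    report.mkdir(exist_ok=True)

    library = pd.read_csv(run / "library.tsv", sep="\t")
    gene_of = library.set_index("construct_id")["gene"]
    for ctx in contexts:
        genes = pd.read_csv(run / f"genes_{ctx}.tsv", sep="\t", index_col="gene")
        waterfall = genes.sort_values("median_log2FC")[["median_log2FC", "sem", "essential"]]
        waterfall.to_csv(report / f"waterfall_{ctx}.tsv", sep="\t", index_label="gene")
        constructs = pd.read_csv(run / f"constructs_{ctx}.tsv", sep="\t", index_col="construct_id")
        volcano = pd.DataFrame(
            {
                "log2FC": constructs["log2FC"],
                "neg_log10_p": -np.log10(constructs["p"]),
                "is_ntc": gene_of.reindex(constructs.index).eq("NTC"),
            }
        )
        volcano.to_csv(report / f"volcano_{ctx}.tsv", sep="\t", index_label="construct_id")

    comparison = pd.read_csv(run / "screen_comparison.tsv", sep="\t", index_col="gene")
    scores = pd.read_csv(run / "essentiality.tsv", sep="\t", index_col="gene")
    scatter = comparison.join(scores["score"].rename("essentiality_score"))
    scatter.to_csv(report / "scatter_invitro_invivo.tsv", sep="\t", index_label="gene")
    for name in ("binplot_regulation.tsv", "binplot_rank.tsv"):
        if (run / name).exists():
            pd.read_csv(run / name, sep="\t").to_csv(report / name, sep="\t", index=False)
    return report
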