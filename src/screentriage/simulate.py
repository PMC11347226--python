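"""Synthetic data with the statistical structure the pipeline assumes.

Every downstream stage can be exercised without external downloads:

* a pooled shRNA library (five guides per gene, 18 non-targeting
  controls by default) with negative-binomially distributed counts,
  planted dropout effects per context, and an optional engraftment
  bottleneck modelled as multinomial subsampling;
* a binary gene x cell-line dependency matrix with planted essential
  fractions;
* an expression pseudo-cohort with a latent activity factor driving a
  gene set, a candidate gene correlated with it at a planted Pearson r,
  tumour-vs-normal overexpression, and exponential survival times whose
  hazard differs between activity tertiles;
* a vehicle/treated ChIP sample pair with constant spike-in material,
  a planted global depletion of experimental signal, and per-gene
  regulation values linked to promoter occupancy.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy import OccupancySet, spike_scaling
from .quant import NTC_GENE, CountTable, LibraryDesign
from .survival import ExpressionCohort
from .triage import DependencyMatrix

__all__ = [
    "ScreenSimParams",
    "CohortSimParams",
    "OccupancySimParams",
    "simulate_library",
    "simulate_screen_counts",
    "simulate_dependency_matrix",
    "simulate_cohort",
    "simulate_occupancy",
]

GUIDE_LENGTH = 22
#: sigma of the log-normal baseline construct abundances; non-uniform
#: enough to make the 10-fold representation rule non-trivial
BASELINE_SIGMA = 0.25


@dataclass(frozen=True)
class ScreenSimParams:
    """Design of a simulated pooled dropout screen.

    Defaults mirror the published library: 92 targeted genes (the 91
    binding partners plus the oncogene itself) x 5 guides + 18
    non-targeting controls = 478 constructs.
    """

    n_genes: int = 92
    guides_per_gene: int = 5
    n_ntc: int = 18
    contexts: tuple[str, ...] = ("invitro", "invivo", "fibroblast")
    replicates_per_context: int = 3
    depth: float = 1000.0
    dispersion: float = 0.05
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    bottleneck_cells: int | None = None
    bottleneck_contexts: tuple[str, ...] = ("invivo",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_ntc < 0:
            raise ValueError("counts must be non-negative")
        if self.n_genes + self.n_ntc == 0:
            raise ValueError("library would be empty")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for gene, by_ctx in self.planted_effects.items():
            for ctx, lfc in by_ctx.items():
                if not np.isfinite(lfc):
                    raise ValueError(f"non-finite planted effect for {gene}/{ctx}")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def _random_guides(rng: np.random.Generator, n: int, length: int = GUIDE_LENGTH) -> list[str]:
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    guides: list[str] = []
    while len(guides) < n:
        seq = "".join(alphabet[rng.integers(0, 4, size=length)])
        if seq not in seen:
            seen.add(seq)
            guides.append(seq)
    return guides


def simulate_library(params: ScreenSimParams) -> LibraryDesign:
    """Build the construct table: guides_per_gene constructs per target
    gene plus n_ntc non-targeting controls, unique random 22-nt guides."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for gene in params.gene_names:
        for g in range(params.guides_per_gene):
            rows.append({"construct_id": f"{gene}_sh{g + 1}", "gene": gene})
    for i in range(params.n_ntc):
        rows.append({"construct_id": f"NTC_sh{i + 1}", "gene": NTC_GENE})
    table = pd.DataFrame(rows)
    table["guide_seq"] = _random_guides(rng, len(table))
    return LibraryDesign(table)


def simulate_screen_counts(design: LibraryDesign, params: ScreenSimParams) -> CountTable:
    """Draw NB counts per construct for every context/replicate pair.

    Expected count = depth * baseline_i * 2^(planted lfc) for treated
    samples (lfc 0 for vehicle/input); variance mu + alpha mu^2.
    Baselines are log-normal (sigma 0.25), shared across samples.  For
    bottleneck contexts each replicate first passes the library through
    a multinomial draw of ``bottleneck_cells`` cells, so low-abundance
    constructs can drop out of the engrafted population before any
    treatment effect applies.
    """
    genes = set(design.gene_of())
    for gene in params.planted_effects:
        if gene not in genes:
            raise ValueError(f"planted effect references unknown gene {gene!r}")
    rng = np.random.default_rng(params.seed + 1)
    n = len(design)
    baseline = rng.lognormal(mean=-(BASELINE_SIGMA**2) / 2, sigma=BASELINE_SIGMA, size=n)
    gene_of = design.gene_of().to_numpy()

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        if params.dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / params.dispersion
        return rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for ctx in params.contexts:
        lfc = np.array(
            [params.planted_effects.get(g, {}).get(ctx, 0.0) for g in gene_of]
        )
        for rep in range(1, params.replicates_per_context + 1):
            rel = baseline
            if params.bottleneck_cells is not None and ctx in params.bottleneck_contexts:
                cells = rng.multinomial(params.bottleneck_cells, baseline / baseline.sum())
                rel = cells / cells.mean() if cells.sum() else cells.astype(float)
            for treatment, effect in (("vehicle", 0.0), ("treated", 1.0)):
                mu = params.depth * rel * 2.0 ** (lfc * effect)
                name = f"{ctx}_{treatment}_r{rep}"
                columns[name] = nb_draw(mu)
                meta_rows.append(
                    {"sample": name, "context": ctx, "treatment": treatment, "replicate": rep}
                )
        # one pre-engraftment input sample per context for QC contrasts
        name = f"{ctx}_input_r0"
        columns[name] = nb_draw(params.depth * baseline)
        meta_rows.append({"sample": name, "context": ctx, "treatment": "input", "replicate": 0})
    counts = pd.DataFrame(columns, index=design.construct_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountTable(counts, meta)


def simulate_dependency_matrix(
    n_genes: int | list[str],
    n_lines: int,
    planted_fractions: dict[str, float] | float,
    seed: int = 0,
) -> DependencyMatrix:
    """Binary dependency matrix: each gene essential in
    round(fraction * n_lines) seeded-random cell lines."""
    genes = [f"G{i + 1:04d}" for i in range(n_genes)] if isinstance(n_genes, int) else list(n_genes)
    if isinstance(planted_fractions, (int, float)):
        planted_fractions = {g: float(planted_fractions) for g in genes}
    rng = np.random.default_rng(seed)
    mat = np.zeros((len(genes), n_lines), dtype=int)
    for i, gene in enumerate(genes):
        frac = planted_fractions.get(gene, 0.0)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for {gene} outside [0, 1]: {frac}")
        k = round(frac * n_lines)
        mat[i, rng.choice(n_lines, size=k, replace=False)] = 1
    matrix = pd.DataFrame(mat, index=genes, columns=[f"line{j + 1}" for j in range(n_lines)])
    return DependencyMatrix(matrix)


@dataclass(frozen=True)
class CohortSimParams:
    """Design of the expression pseudo-cohort."""

    n_patients: int = 159
    n_genes: int = 200
    geneset_size: int = 50
    n_normals: int = 4
    planted_r: float = 0.7
    tumour_overexpression_lfc: float = 0.5
    survival_hazard_ratio: float = 3.0
    censoring_rate: float = 0.2
    noise_sd: float = 0.3
    median_survival_days: float = 600.0
    candidate_name: str = "CAND"
    background_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.planted_r) > 1:
            raise ValueError("|planted_r| must be <= 1")
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if self.geneset_size + 1 > self.n_genes:
            raise ValueError("geneset_size (+ candidate) exceeds n_genes")
        if (
            self.background_names is not None
            and len(self.background_names) != self.n_genes - self.geneset_size - 1
        ):
            raise ValueError("background_names length must equal n_genes - geneset_size - 1")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")


def simulate_cohort(params: CohortSimParams) -> ExpressionCohort:
    """Expression pseudo-cohort with a planted activity factor.

    A latent activity ``a ~ N(0,1)`` per tumour patient drives the gene
    set members (FPKM linear in ``a`` plus noise_sd Gaussian noise) and,
    at correlation ``planted_r``, the candidate gene.  Normal-tissue
    samples express the candidate at 2^(-tumour_overexpression_lfc) of
    the tumour mean.  Event times are exponential; the hazard of the top
    activity tertile exceeds the bottom tertile's by
    ``survival_hazard_ratio`` (middle tertile at the geometric mean),
    with independent exponential censoring calibrated to
    ``censoring_rate``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    tumour_samples = [f"T{i + 1:03d}" for i in range(p.n_patients)]
    normal_samples = [f"N{i + 1:02d}" for i in range(p.n_normals)]
    a = rng.standard_normal(p.n_patients)

    geneset = [f"MS{i + 1:03d}" for i in range(p.geneset_size)]
    candidate = p.candidate_name
    n_bg = p.n_genes - p.geneset_size - 1
    if p.background_names is not None:
        background = list(p.background_names)
    else:
        background = [f"BG{i + 1:03d}" for i in range(n_bg)]

    base = rng.uniform(8.0, 20.0, size=p.n_genes)
    rows = {}
    for i, g in enumerate(geneset):
        rows[g] = base[i] + a + p.noise_sd * rng.standard_normal(p.n_patients)
    eta = rng.standard_normal(p.n_patients)
    cand_latent = p.planted_r * a + np.sqrt(max(0.0, 1 - p.planted_r**2)) * eta
    cand_base = base[p.geneset_size]
    rows[candidate] = cand_base + cand_latent
    for i, g in enumerate(background):
        rows[g] = base[p.geneset_size + 1 + i] + rng.standard_normal(p.n_patients)
    fpkm_t = pd.DataFrame(rows, index=tumour_samples).T

    # normals: same baselines, no activity; candidate mean scaled down
    rows_n = {}
    for i, g in enumerate(geneset):
        rows_n[g] = base[i] + p.noise_sd * rng.standard_normal(p.n_normals)
    rows_n[candidate] = cand_base * 2.0 ** (-p.tumour_overexpression_lfc) + 0.2 * rng.standard_normal(
        p.n_normals
    )
    for i, g in enumerate(background):
        rows_n[g] = base[p.geneset_size + 1 + i] + rng.standard_normal(p.n_normals)
    fpkm_n = pd.DataFrame(rows_n, index=normal_samples).T

    fpkm = pd.concat([fpkm_t, fpkm_n], axis=1).clip(lower=0.0)
    sample_class = pd.Series(
        ["tumour"] * p.n_patients + ["normal"] * p.n_normals, index=fpkm.columns
    )

    # survival: hazard by tertile of the true activity factor
    lo, hi = np.quantile(a, [1 / 3, 2 / 3])
    lam_base = np.log(2) / p.median_survival_days
    hr = np.where(a >= hi, p.survival_hazard_ratio, np.where(a <= lo, 1.0, np.sqrt(p.survival_hazard_ratio)))
    lam = lam_base * hr
    event_time = rng.exponential(1.0 / lam)
    if p.censoring_rate > 0:
        # P(censored) = mu / (lam + mu) for independent exponentials
        mu = lam * p.censoring_rate / (1 - p.censoring_rate)
        censor_time = rng.exponential(1.0 / mu)
    else:
        censor_time = np.full(p.n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    clinical = pd.DataFrame(
        {"time": np.maximum(time, 1e-6), "event": event}, index=tumour_samples
    )
    cohort = ExpressionCohort(
        fpkm=fpkm,
        sample_class=sample_class,
        clinical=clinical,
        geneset=geneset,
        candidate=candidate,
    )
    cohort.fpkm.attrs["activity_factor"] = pd.Series(a, index=tumour_samples)
    return cohort


@dataclass(frozen=True)
class OccupancySimParams:
    """Design of the vehicle/treated spike-in ChIP pair."""

    n_promoters: int = 2000
    spike_fraction: float = 0.06
    global_depletion: float = 0.2
    regulation_slope: float = -0.5
    noise_sd: float = 5.0
    regulation_noise_sd: float = 0.3
    total_reads: int = 200_000
    baseline_mean: float = 100.0
    sample_reads: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.global_depletion < 0:
            raise ValueError("global_depletion must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_occupancy(params: OccupancySimParams) -> OccupancySet:
    """Vehicle/treated ChIP pair with constant spike-in material.

    Per-promoter experimental material is log-normal baseline plus
    Gaussian noise; the treated sample's experimental material is scaled
    by ``global_depletion`` while the spike-in material stays constant,
    so the treated sample's spike-in read share rises as signal is lost.
    Reads are allocated multinomially over promoters + the spike-in
    compartment at fixed total depth (expected allocations when
    ``sample_reads`` is off), then spike-scaled back.  Regulation values
    are ``regulation_slope`` times the standardized true occupancy plus
    noise.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    promoters = [f"P{i + 1:05d}" for i in range(p.n_promoters)]
    baseline = rng.lognormal(mean=np.log(p.baseline_mean) - 0.125, sigma=0.5, size=p.n_promoters)
    material = {
        "vehicle": np.maximum(baseline + p.noise_sd * rng.standard_normal(p.n_promoters), 0.0),
        "treated": np.maximum(
            p.global_depletion * baseline + p.noise_sd * rng.standard_normal(p.n_promoters), 0.0
        ),
    }
    spike_material = p.spike_fraction / (1 - p.spike_fraction) * material["vehicle"].sum()

    raw = {}
    spike_rows = []
    for sample, m in material.items():
        pool = np.append(m, spike_material)
        probs = pool / pool.sum()
        if p.sample_reads:
            alloc = rng.multinomial(p.total_reads, probs).astype(float)
        else:
            alloc = p.total_reads * probs
        raw[sample] = alloc[:-1]
        spike_rows.append(
            {"sample": sample, "n_exp": float(alloc[:-1].sum()), "n_spike": float(alloc[-1])}
        )
    raw_df = pd.DataFrame(raw, index=promoters)
    spike = spike_scaling(pd.DataFrame(spike_rows).set_index("sample"))
    normalized = raw_df * spike["f"]

    z = (baseline - baseline.mean()) / baseline.std()
    regulation = pd.Series(
        p.regulation_slope * z + p.regulation_noise_sd * rng.standard_normal(p.n_promoters),
        index=promoters,
        name="regulation_log2FC",
    )
    return OccupancySet(raw=raw_df, spike=spike, normalized=normalized, regulation=regulation)
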