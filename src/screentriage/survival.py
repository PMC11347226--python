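"""Expression-cohort analyses: gene-set activity scoring, candidate
co-expression, tumour-vs-normal overexpression, and survival
stratification.

The activity score of a gene set is the per-sample mean of z-scaled
expression of its member genes, computed across the cohort — a simple
proxy for the transcriptional output of an oncogenic programme.  For
survival, samples are stratified into high (top third of both scores)
and low (bottom third of both) groups and compared by log-rank test on
Kaplan-Meier curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

__all__ = [
    "ExpressionCohort",
    "SurvivalResult",
    "scale_expression",
    "geneset_score",
    "correlate_candidate",
    "tumour_vs_normal_lfc",
    "stratify_and_logrank",
]

OVEREXPRESSION_PSEUDOCOUNT = 0.1


@dataclass
class ExpressionCohort:
    """FPKM expression matrix (genes x samples) with clinical follow-up.

    ``sample_class`` labels each column tumour or normal; ``clinical``
    is indexed by tumour sample with columns ``time`` (days) and
    ``event`` (bool).  ``geneset`` and ``candidate`` name the activity
    proxy and the gene under triage when the cohort is synthetic.
    """

    fpkm: pd.DataFrame
    sample_class: pd.Series
    clinical: pd.DataFrame
    geneset: list[str] = field(default_factory=list)
    candidate: str | None = None

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        if not set(self.clinical.index) <= set(self.tumour_samples):
            raise ValueError("clinical rows must be keyed to tumour samples")
        if (self.clinical["time"].to_numpy() <= 0).any():
            raise ValueError("non-positive survival times")

    @property
    def tumour_samples(self) -> pd.Index:
        return self.sample_class.index[self.sample_class == "tumour"]

    @property
    def normal_samples(self) -> pd.Index:
        return self.sample_class.index[self.sample_class == "normal"]


def scale_expression(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Z-scale each gene across samples (sample sd, n-1 denominator).

    Genes with zero variance are set to all-zero with a warning.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("scaling needs at least two samples")
    mean = fpkm.mean(axis=1)
    sd = fpkm.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s) set to all-zero",
            RuntimeWarning,
            stacklevel=2,
        )
    z = fpkm.sub(mean, axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z[degenerate] = 0.0
    return z


def geneset_score(z: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Per-sample mean z-score over the gene set's members found in the
    matrix.  Missing members are reported in ``.attrs['missing']``."""
    members = [g for g in gene_set if g in z.index]
    missing = [g for g in gene_set if g not in z.index]
    if not members:
        raise ValueError("gene set has no overlap with the expression matrix")
    score = z.loc[members].mean(axis=0)
    score.name = "activity_score"
    score.attrs["found"] = members
    score.attrs["missing"] = missing
    return score


def correlate_candidate(candidate_z: pd.Series, score: pd.Series) -> tuple[float, float]:
    """Pearson correlation of a candidate's z-row with the activity
    score; p from the t transform t = r sqrt((n-2)/(1-r^2)), two-sided."""
    x = candidate_z.to_numpy(dtype=float)
    y = score.reindex(candidate_z.index).to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("correlation needs at least 4 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def tumour_vs_normal_lfc(
    fpkm: pd.DataFrame,
    sample_class: pd.Series,
    gene: str,
    pseudocount: float = OVEREXPRESSION_PSEUDOCOUNT,
) -> tuple[float, float]:
    """Tumour-vs-normal log2 fold change of mean FPKM with a delta-method
    SE on the log scale; pseudocount c0 = 0.1 guards low expression."""
    if gene not in fpkm.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    tum = fpkm.loc[gene, sample_class.index[sample_class == "tumour"]].to_numpy(dtype=float)
    nor = fpkm.loc[gene, sample_class.index[sample_class == "normal"]].to_numpy(dtype=float)
    if len(tum) == 0 or len(nor) == 0:
        raise ValueError("both tumour and normal samples are required")
    m_t, m_n = tum.mean() + pseudocount, nor.mean() + pseudocount
    lfc = float(np.log2(m_t / m_n))
    var_t = tum.var(ddof=1) / len(tum) if len(tum) > 1 else 0.0
    var_n = nor.var(ddof=1) / len(nor) if len(nor) > 1 else 0.0
    se = float(np.sqrt(var_t / m_t**2 + var_n / m_n**2) / np.log(2))
    return lfc, se


@dataclass(frozen=True)
class SurvivalResult:
    """High-vs-low stratification outcome: KM curves and log-rank test."""

    groups: pd.Series  # sample -> 'high' / 'low' (stratified samples only)
    km_curves: pd.DataFrame  # columns: group, time, survival, at_risk
    logrank_chi2: float
    p: float

    @property
    def n_high(self) -> int:
        return int((self.groups == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.groups == "low").sum())


def _tertile_mask(score: pd.Series) -> tuple[pd.Series, pd.Series]:
    lo, hi = score.quantile([1 / 3, 2 / 3])
    return score <= lo, score >= hi


def stratify_and_logrank(
    score_a: pd.Series,
    score_b: pd.Series,
    clinical: pd.DataFrame,
    mode: str = "intersection",
    restrict_most_aggressive: bool = False,
) -> SurvivalResult:
    """Stratify tumour samples by two expression scores and compare
    survival of the strata by log-rank test.

    ``mode='intersection'`` (default): high = top third of BOTH scores,
    low = bottom third of both.  ``mode='combined'``: thirds of the sum
    of the two scores.  ``restrict_most_aggressive`` first drops the
    half of the cohort with the lowest combined score, an optional
    reading of plotting only the more aggressive diseases.
    """
    samples = clinical.index
    a = score_a.reindex(samples)
    b = score_b.reindex(samples)
    if restrict_most_aggressive:
        combined = a + b
        keep = combined >= combined.median()
        samples = samples[keep]
        a, b = a[keep], b[keep]
    if mode == "intersection":
        lo_a, hi_a = _tertile_mask(a)
        lo_b, hi_b = _tertile_mask(b)
        high = hi_a & hi_b
        low = lo_a & lo_b
    elif mode == "combined":
        low, high = _tertile_mask(a + b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for name, mask in (("high", high), ("low", low)):
        if int(mask.sum()) == 0:
            raise ValueError(f"stratum {name!r} is empty")
    groups = pd.Series(
        np.where(high, "high", np.where(low, "low", "mid")), index=samples
    )
    groups = groups[groups != "mid"]
    clin = clinical.loc[groups.index]
    t = clin["time"].to_numpy(dtype=float)
    e = clin["event"].to_numpy(dtype=bool)
    if int(e.sum()) < 2:
        raise ValueError("log-rank needs at least two events")
    is_high = (groups == "high").to_numpy()

    result = logrank_test(t[is_high], t[~is_high], e[is_high], e[~is_high])
    curves = []
    for name, mask in (("high", is_high), ("low", ~is_high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        table = kmf.event_table
        surv = kmf.survival_function_[name]
        curves.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": surv.index.to_numpy(),
                    "survival": surv.to_numpy(),
                    "at_risk": table["at_risk"].reindex(surv.index).to_numpy(),
                }
            )
        )
    return SurvivalResult(
        groups=groups,
        km_curves=pd.concat(curves, ignore_index=True),
        logrank_chi2=float(result.test_statistic),
        p=float(result.p_value),
    )
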