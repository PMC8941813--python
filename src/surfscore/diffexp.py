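"""Two-group differential expression and the upregulation filter.

Provides the pooled-variance two-sample t (equivalent to one-way ANOVA
with two groups), an empirical-Bayes moderated t whose per-gene variance
is shrunk toward a prior, Benjamini-Hochberg adjustment, and the
selection rule p < p_max AND log2FC > lfc_min (downregulated genes are
always excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from surfscore.errors import ValidationError
from surfscore.preprocess import ExpressionMatrix

_D0_CAP = 1e6  # stands in for an infinite prior df


@dataclass
class ModerationParams:
    """Hyperparameters of the moderated t: prior df d0 and prior variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq: prior variance must be > 0")
        if self.d0 < 0:
            raise ValidationError("d0: prior degrees of freedom must be >= 0")


@dataclass
class DEResult:
    """Per-gene differential-expression table for one dataset."""

    gene_ids: list[str]
    lfc: np.ndarray
    t_stat: np.ndarray
    df: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    dataset_id: str = ""

    @property
    def upregulated(self) -> np.ndarray:
        return self.lfc > 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "lfc": self.lfc,
                "t": self.t_stat,
                "df": self.df,
                "p": self.p,
                "q": self.q if self.q is not None else np.full(len(self.gene_ids), np.nan),
                "upregulated": self.upregulated,
            }
        )
        return frame

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _group_split(matrix: ExpressionMatrix, min_per_group: int = 1):
    tumor = matrix.values[:, matrix.group_mask("tumor")]
    normal = matrix.values[:, matrix.group_mask("normal")]
    if tumor.shape[1] < min_per_group or normal.shape[1] < min_per_group:
        raise ValidationError(
            f"groups: need >= {min_per_group} samples per group, "
            f"found tumor={tumor.shape[1]}, normal={normal.shape[1]}"
        )
    return tumor, normal


def log_fold_change(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene log2 fold change: mean(tumor) - mean(normal).

    Assumes values are already on the log2 scale.
    """
    tumor, normal = _group_split(matrix, min_per_group=1)
    return tumor.mean(axis=1) - normal.mean(axis=1)


def _pooled_stats(matrix: ExpressionMatrix):
    tumor, normal = _group_split(matrix, min_per_group=2)
    n1, n2 = tumor.shape[1], normal.shape[1]
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)
    ss1 = tumor.var(axis=1, ddof=1) * (n1 - 1)
    ss2 = normal.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    scale = 1.0 / n1 + 1.0 / n2
    return lfc, s2, df, scale


def ordinary_t(matrix: ExpressionMatrix) -> DEResult:
    """Pooled-variance two-sided t-test per gene (df = n1 + n2 - 2).

    Genes with zero pooled variance are reported as t=0, p=1.
    """
    lfc, s2, df, scale = _pooled_stats(matrix)
    se = np.sqrt(s2 * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return DEResult(
        gene_ids=list(matrix.gene_ids),
        lfc=lfc,
        t_stat=t,
        df=np.full(len(lfc), float(df)),
        p=p,
        dataset_id=matrix.dataset_id,
    )


def _trigamma_inverse(y: float) -> float:
    # Newton solve of trigamma(x) = y; trigamma is convex decreasing on
    # (0, inf) so this converges from the asymptotic start x ~ 1/y.
    if y <= 0:
        return _D0_CAP
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation_params(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of (d0, s0_sq) from per-gene sample variances.

    Matches the mean and variance of log s2 against the scaled-F moments
    implied by the hierarchical variance model. Returns d0 capped at 1e6
    when the observed spread of log variances is at or below the
    within-gene chi-square expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValidationError("s2: need >= 2 positive sample variances to estimate priors")
    z = np.log(positive)
    half_d = df / 2.0
    e_gene = special.digamma(half_d) - math.log(half_d)
    mean_z = float(z.mean())
    var_z = float(z.var(ddof=1))
    excess = var_z - float(special.polygamma(1, half_d))
    if excess > 0:
        half_d0 = _trigamma_inverse(excess)
        d0 = min(2.0 * half_d0, _D0_CAP)
    else:
        d0 = _D0_CAP
    half_d0 = d0 / 2.0
    e_prior = special.digamma(half_d0) - math.log(half_d0)
    s0_sq = math.exp(mean_z - e_gene + e_prior)
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    matrix: ExpressionMatrix, params: ModerationParams | None = None
) -> DEResult:
    """Empirical-Bayes moderated t.

    Posterior variance per gene: (d0*s0_sq + df*s2) / (d0 + df); the
    statistic uses this in place of the pooled variance and gains d0
    degrees of freedom. ``params=None`` estimates (d0, s0_sq) by method
    of moments on the log sample variances.
    """
    lfc, s2, df, scale = _pooled_stats(matrix)
    if params is None:
        params = estimate_moderation_params(s2, df)
    d0, s0_sq = params.d0, params.s0_sq
    if d0 == 0:
        return ordinary_t(matrix)
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    df_total = min(d0 + df, _D0_CAP)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df_total), 1.0)
    return DEResult(
        gene_ids=list(matrix.gene_ids),
        lfc=lfc,
        t_stat=t,
        df=np.full(len(lfc), float(df_total)),
        p=p,
        dataset_id=matrix.dataset_id,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p: expected a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p: p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def select_upregulated(
    result: DEResult,
    p_max: float = 0.05,
    lfc_min: float = 1.5,
    use_adjusted: bool = False,
    log2_threshold: bool = True,
) -> set[str]:
    """Genes with p < p_max and log2FC > lfc_min (strict inequalities).

    Genes with lfc <= 0 are always excluded. ``use_adjusted`` switches
    the p criterion to BH-adjusted values (computed on the fly when the
    result has none). ``log2_threshold=False`` reads ``lfc_min`` as a
    plain fold change and converts it to log2.
    """
    if p_max <= 0 or lfc_min <= 0:
        raise ValidationError("thresholds: p_max and lfc_min must be positive")
    threshold = lfc_min if log2_threshold else math.log2(lfc_min)
    pvals = result.p
    if use_adjusted:
        pvals = result.q if result.q is not None else bh_adjust(result.p)
    keep = (pvals < p_max) & (result.lfc > threshold) & (result.lfc > 0)
    return {g for g, k in zip(result.gene_ids, keep) if k}
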