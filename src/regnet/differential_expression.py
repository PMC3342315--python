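"""Single-array differential expression with an empirical normal null.

With only one array per condition no within-group variance exists, so the
per-gene log2 fold change itself is the test statistic.  The null
distribution of that statistic is taken to be normal, with mean and
standard deviation estimated from log-ratios between control arrays — the
same quantity the statistic measures, formed where no biological effect is
present.  Two-sided p-values are Benjamini-Hochberg adjusted and genes are
classified up / down / unchanged at an FDR cutoff (0.01 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats_core


class DegenerateNullError(ValueError):
    """Control arrays are (numerically) identical; no noise scale exists."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of positive linear-scale intensities.

    ``condition`` maps each sample id to "control" or "knockdown".
    Intensities are assumed already normalized across arrays.
    """

    values: pd.DataFrame
    condition: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        missing = set(self.values.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")
        bad = set(self.condition.values()) - {"control", "knockdown"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]


@dataclass(frozen=True)
class NullModel:
    mu: float
    sigma: float
    n_genes_used: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateNullError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    lfc: float
    p: float
    fdr: float
    reg_class: str  # down | up | unchanged


def compute_lfc(m: ExpressionMatrix) -> pd.Series:
    """Per-gene log2 of (mean knockdown / mean control) linear intensity.

    Genes with a missing value in any sample are dropped.
    """
    kd, ctrl = m.samples("knockdown"), m.samples("control")
    if not kd or not ctrl:
        raise ValueError("need at least one knockdown and one control sample")
    values = m.values.dropna(axis=0)
    kd_mean = values[kd].mean(axis=1)
    ctrl_mean = values[ctrl].mean(axis=1)
    if (kd_mean <= 0).any() or (ctrl_mean <= 0).any():
        raise ValueError("nonpositive mean intensity; intensities must be linear-scale positive")
    return np.log2(kd_mean / ctrl_mean)


def estimate_null(m: ExpressionMatrix) -> NullModel:
    """Fit the normal null from between-control-array log2 ratios.

    Per-gene log2 ratios are pooled over all ordered pairs of distinct
    control arrays (so the pool is antisymmetric and its mean is ~0 by
    construction); mu and sigma are the pooled mean and standard deviation.
    """
    ctrl = m.samples("control")
    if len(ctrl) < 2:
        raise ValueError("need >= 2 control arrays to estimate the null")
    values = m.values[ctrl].dropna(axis=0)
    if (values <= 0).any().any():
        raise ValueError("nonpositive control intensity")
    pooled = np.concatenate(
        [np.log2(values[a] / values[b]).to_numpy() for a, b in permutations(ctrl, 2)]
    )
    sigma = float(pooled.std(ddof=1))
    if sigma <= 0 or not np.isfinite(sigma):
        raise DegenerateNullError("control arrays are identical; null sigma is zero")
    return NullModel(mu=float(pooled.mean()), sigma=sigma, n_genes_used=len(values))


def de_test(
    lfc: pd.Series, null: NullModel, fdr_cutoff: float = 0.01
) -> list[DEResult]:
    """Two-sided normal p per gene, BH adjustment, and regulation classes.

    A gene is "down" when its FDR beats the cutoff and its log fold change
    sits below the null mean, "up" when above, else "unchanged".
    """
    if not 0.0 < fdr_cutoff < 1.0:
        raise ValueError("fdr_cutoff must be in (0, 1)")
    pvals = [stats_core.normal_two_sided_p(x, null.mu, null.sigma) for x in lfc]
    fdrs = stats_core.bh_adjust(pvals).adjusted
    results = []
    for gene_id, x, p, fdr in zip(lfc.index, lfc, pvals, fdrs):
        if fdr < fdr_cutoff and x < null.mu:
            reg = "down"
        elif fdr < fdr_cutoff and x > null.mu:
            reg = "up"
        else:
            reg = "unchanged"
        results.append(DEResult(gene_id=str(gene_id), lfc=float(x), p=p, fdr=fdr, reg_class=reg))
    return results


def statistic_null(m: ExpressionMatrix, pairwise_null: NullModel) -> NullModel:
    """Rescale the pairwise-ratio null to the fold-change statistic's design.

    The pooled control-vs-control log-ratio has variance 2 sigma_array^2,
    while log2(mean of n_kd knockdowns / mean of n_ctrl controls) has
    variance sigma_array^2 (1/n_kd + 1/n_ctrl); the pairwise sigma is
    scaled by sqrt((1/n_kd + 1/n_ctrl) / 2) so that null p-values for the
    statistic are calibrated.  For the one-versus-one design the scale is 1
    and the pairwise null is used as-is.
    """
    n_kd = max(len(m.samples("knockdown")), 1)
    n_ctrl = len(m.samples("control"))
    scale = float(np.sqrt((1.0 / n_kd + 1.0 / n_ctrl) / 2.0))
    return NullModel(
        mu=pairwise_null.mu,
        sigma=pairwise_null.sigma * scale,
        n_genes_used=pairwise_null.n_genes_used,
    )


def run_de(m: ExpressionMatrix, fdr_cutoff: float = 0.01) -> list[DEResult]:
    """Full stage: fold changes, empirical null (design-scaled), test, classes."""
    null = statistic_null(m, estimate_null(m))
    return de_test(compute_lfc(m), null, fdr_cutoff)


def significant_genes(results: Sequence[DEResult]) -> set[str]:
    return {r.gene_id for r in results if r.reg_class != "unchanged"}


def median_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Optional per-array median scaling to a common median (off by default)."""
    medians = values.median(axis=0)
    return values * (medians.mean() / medians)


# ---------------------------------------------------------------------------
# I/O


def read_matrix(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a two-column sample/condition design TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    condition = design.iloc[:, 0].to_dict()
    return ExpressionMatrix(values=values, condition=condition)


def write_results(results: Sequence[DEResult], path: str | Path) -> None:
    pd.DataFrame(results).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[DEResult]:
    df = pd.read_csv(path, sep="\t")
    return [DEResult(**row) for row in df.to_dict("records")]
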