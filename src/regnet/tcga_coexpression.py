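"""Tumor-cohort co-upregulation of an anchor factor with its target genes.

Expression Z-scores (gene x tumor, standardized against a diploid reference
population) are binarized at Z > 1.65, the top ~5% of a normal.  For every
gene a 2x2 table against the anchor over tumors gives an odds ratio and a
one-sided Fisher p; a gene "co-upregulates" when OR > 1.5 and p < 0.05.
The target set's hit rate is then compared with the genome-wide background
rate by Pearson's chi-square.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .integration import GeneSet, normalize_gene_id
from .stats_core import Table2x2

Z_THRESHOLD = 1.65
OR_THRESHOLD = 1.5
ALPHA = 0.05


@dataclass(frozen=True)
class ZScoreMatrix:
    """Genes x tumors matrix of expression Z-scores."""

    z: pd.DataFrame

    def __post_init__(self) -> None:
        if self.z.index.has_duplicates or self.z.columns.has_duplicates:
            raise ValueError("duplicate gene or tumor ids")
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("non-finite Z-scores")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def n_tumors(self) -> int:
        return self.z.shape[1]


@dataclass(frozen=True)
class CoexpResult:
    gene_id: str
    table: Table2x2
    or_value: float
    p: float
    co_up_flag: bool  # OR above threshold
    significant_flag: bool  # Fisher p below alpha

    @property
    def hit(self) -> bool:
        return self.co_up_flag and self.significant_flag


@dataclass(frozen=True)
class SetEnrichmentReport:
    target_tested: int
    target_hits: int
    background_tested: int
    background_hits: int
    chi2: float
    p: float

    @property
    def target_hit_pct(self) -> float:
        return 100.0 * self.target_hits / self.target_tested

    @property
    def background_hit_pct(self) -> float:
        return 100.0 * self.background_hits / self.background_tested

    def summary(self) -> str:
        return (
            f"{self.target_hits} of {self.target_tested} target genes "
            f"({self.target_hit_pct:.1f}%) vs {self.background_hits} of "
            f"{self.background_tested} background genes "
            f"({self.background_hit_pct:.1f}%) co-upregulated; "
            f"chi-square p = {self.p:.3g}"
        )


def binarize(zm: ZScoreMatrix, z_threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Boolean over-expression calls: strictly Z > threshold (ties are not over)."""
    if not np.isfinite(z_threshold):
        raise ValueError("threshold must be finite")
    return zm.z > z_threshold


def pairwise_co_up(
    anchor: np.ndarray,
    gene: np.ndarray,
    gene_id: str = "gene",
    or_threshold: float = OR_THRESHOLD,
    alpha: float = ALPHA,
) -> CoexpResult:
    """Odds ratio and one-sided Fisher p for co-over-expression over tumors.

    The 2x2 cells: a = both over-expressed, b = anchor only, c = gene only,
    d = neither.  Zero cells fall back to the Haldane-corrected odds ratio;
    a gene never over-expressed together with the anchor (a = 0) is not
    called co-upregulated regardless of the corrected ratio.
    """
    anchor = np.asarray(anchor, dtype=bool)
    gene = np.asarray(gene, dtype=bool)
    if anchor.shape != gene.shape:
        raise ValueError("anchor and gene vectors differ in length")
    a = int(np.sum(anchor & gene))
    b = int(np.sum(anchor & ~gene))
    c = int(np.sum(~anchor & gene))
    d = int(np.sum(~anchor & ~gene))
    table = Table2x2(a=a, b=b, c=c, d=d)
    or_value, _ = stats_core.odds_ratio(table, zero_cell_policy="haldane")
    p = stats_core.fisher_one_sided(table)
    return CoexpResult(
        gene_id=gene_id,
        table=table,
        or_value=or_value,
        p=p,
        co_up_flag=or_value > or_threshold and a > 0,
        significant_flag=p < alpha,
    )


def score_target_set(
    zm: ZScoreMatrix,
    anchor_gene: str,
    target_genes: GeneSet,
    z_threshold: float = Z_THRESHOLD,
    or_threshold: float = OR_THRESHOLD,
    alpha: float = ALPHA,
    disjoint_background: bool = True,
    chi2_continuity: bool = False,
) -> tuple[list[CoexpResult], SetEnrichmentReport]:
    """Per-gene co-upregulation with the anchor, plus a set-level chi-square.

    Every gene in the matrix (except the anchor) receives a CoexpResult; a
    gene is a hit when its odds ratio exceeds ``or_threshold`` AND its
    Fisher p is below ``alpha``.  The report compares the hit rate among
    the target genes with the background — by default the disjoint
    non-target remainder, or with ``disjoint_background=False`` all tested
    genes.
    """
    anchor_gene = normalize_gene_id(anchor_gene)
    gene_index = {normalize_gene_id(g): g for g in zm.gene_ids}
    if anchor_gene not in gene_index:
        raise KeyError(f"anchor gene {anchor_gene!r} absent from Z-score matrix")
    targets = {g for g in target_genes.genes if g in gene_index} - {anchor_gene}
    if not targets:
        raise ValueError("no target genes present in the Z-score matrix")
    binary = binarize(zm, z_threshold).to_numpy()
    rows = {normalize_gene_id(g): i for i, g in enumerate(zm.gene_ids)}
    anchor_vec = binary[rows[anchor_gene]]
    results = []
    for gene_norm, gene_raw in gene_index.items():
        if gene_norm == anchor_gene:
            continue
        results.append(
            pairwise_co_up(
                anchor_vec, binary[rows[gene_norm]], gene_id=gene_raw,
                or_threshold=or_threshold, alpha=alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.gene_id))
    t_tested = t_hits = b_tested = b_hits = 0
    for r in results:
        is_target = normalize_gene_id(r.gene_id) in targets
        if is_target:
            t_tested += 1
            t_hits += r.hit
        if not is_target or not disjoint_background:
            b_tested += 1
            b_hits += r.hit
    table = Table2x2(a=t_hits, b=t_tested - t_hits, c=b_hits, d=b_tested - b_hits)
    try:
        chi2, p = stats_core.pearson_chi2_2x2(table, continuity=chi2_continuity)
    except stats_core.DegenerateTableError:
        chi2, p = 0.0, 1.0
    report = SetEnrichmentReport(
        target_tested=t_tested, target_hits=t_hits,
        background_tested=b_tested, background_hits=b_hits,
        chi2=chi2, p=p,
    )
    return results, report


def hit_rate_report(
    target_hits: int, target_tested: int, background_hits: int, background_tested: int
) -> SetEnrichmentReport:
    """Build a set-level report directly from printed counts."""
    table = Table2x2(
        a=target_hits, b=target_tested - target_hits,
        c=background_hits, d=background_tested - background_hits,
    )
    chi2, p = stats_core.pearson_chi2_2x2(table)
    return SetEnrichmentReport(
        target_tested=target_tested, target_hits=target_hits,
        background_tested=background_tested, background_hits=background_hits,
        chi2=chi2, p=p,
    )


# ---------------------------------------------------------------------------
# I/O


def read_zscores(path: str | Path) -> ZScoreMatrix:
    """Read a genes-in-rows, tumors-in-columns Z-score TSV."""
    return ZScoreMatrix(z=pd.read_csv(path, sep="\t", index_col=0))


def write_zscores(zm: ZScoreMatrix, path: str | Path) -> None:
    zm.z.to_csv(path, sep="\t", float_format="%.4f")


def write_results(
    results: Sequence[CoexpResult], report: SetEnrichmentReport,
    results_path: str | Path, report_path: str | Path,
) -> None:
    records = [
        {
            "gene_id": r.gene_id, "a": r.table.a, "b": r.table.b,
            "c": r.table.c, "d": r.table.d, "odds_ratio": r.or_value,
            "p": r.p, "co_up": r.co_up_flag, "significant": r.significant_flag,
            "hit": r.hit,
        }
        for r in results
    ]
    pd.DataFrame(records).to_csv(results_path, sep="\t", index=False)
    Path(report_path).write_text(json.dumps(asdict(report), indent=2) + "\n")
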