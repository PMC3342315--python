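"""Thin orchestration of the analysis stages over one dataset."""

from __future__ import annotations

from dataclasses import dataclass

from . import differential_expression as de
from . import integration, peak_analysis
from .integration import GeneSet
from .synthetic_data import TARGET_FACTOR, SimulatedDataset


@dataclass
class PipelineResult:
    chip_genes: GeneSet
    de_results: list[de.DEResult]
    direct_targets: GeneSet


def chip_target_genes(
    ds: SimulatedDataset, max_fdr: float = 0.2, factor: str = TARGET_FACTOR
) -> GeneSet:
    """FDR screen + IgG subtraction + promoter assignment for one factor."""
    positive = peak_analysis.positive_peaks(ds.peaks[factor], ds.peaks["IgG"], max_fdr)
    assignment = peak_analysis.assign_to_promoters(positive, ds.promoters)
    return GeneSet(
        label=f"{factor}_chip",
        genes=frozenset(assignment),
        universe_size=ds.cfg.n_genes,
    )


def run_direct_target_discovery(
    ds: SimulatedDataset, max_fdr: float = 0.2, de_fdr: float = 0.01
) -> PipelineResult:
    """Peak screening and differential expression joined into direct targets."""
    chip = chip_target_genes(ds, max_fdr)
    de_results = de.run_de(ds.expression, fdr_cutoff=de_fdr)
    return PipelineResult(
        chip_genes=chip,
        de_results=de_results,
        direct_targets=integration.direct_targets(chip, de_results),
    )
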