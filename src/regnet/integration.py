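"""Cross-dataset synthesis of binding, expression and chromatin-mark results.

Four summaries: a hypergeometric co-occurrence matrix between binding gene
sets, the intersection of ChIP targets with the knockdown-regulated
transcriptome (the direct-target set), enrichment of ChIP targets within
each regulation class, and the fraction of target promoters carrying each
histone mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats_core
from .differential_expression import DEResult

#: Universe sizes used by the overlap tests: genes represented on the
#: promoter binding array vs on the expression array.
DEFAULT_BINDING_UNIVERSE = 18_511
DEFAULT_EXPRESSION_UNIVERSE = 30_500


def normalize_gene_id(gene_id: str) -> str:
    return gene_id.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(normalize_gene_id(g) for g in self.genes))
        if len(self.genes) > self.universe_size:
            raise ValueError(
                f"set {self.label!r} has {len(self.genes)} genes, "
                f"more than universe {self.universe_size}"
            )


@dataclass(frozen=True)
class CooccurrenceMatrix:
    labels: tuple[str, ...]
    p_values: np.ndarray  # symmetric; diagonal is NaN (not reported)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class OverlayReport:
    target_count: int
    per_mark: Mapping[str, tuple[int, float]] = field(default_factory=dict)


def cooccurrence_matrix(sets: Sequence[GeneSet], universe_N: int) -> CooccurrenceMatrix:
    """Pairwise overlap significance between gene sets in a shared universe.

    Entry (i, j) is the hypergeometric upper-tail probability of observing
    the same number or more shared genes when sampling both sets at random
    from the universe.  The matrix is symmetric; the diagonal is NaN.
    """
    for s in sets:
        if len(s.genes) > universe_N:
            raise ValueError(f"set {s.label!r} larger than universe {universe_N}")
    m = len(sets)
    p = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            k = len(sets[i].genes & sets[j].genes)
            q = stats_core.OverlapQuery(
                overlap_k=k,
                set_a_size_K=len(sets[i].genes),
                set_b_size_n=len(sets[j].genes),
                universe_N=universe_N,
            )
            p[i, j] = p[j, i] = stats_core.hypergeom_upper_tail(q)
    return CooccurrenceMatrix(labels=tuple(s.label for s in sets), p_values=p)


def direct_targets(chip_genes: GeneSet, de: Sequence[DEResult]) -> GeneSet:
    """Genes both bound at the promoter and significantly regulated.

    The intersection of the ChIP target set with genes classified up or
    down by the differential-expression stage — the candidate direct
    targets of the factor.
    """
    regulated = {
        normalize_gene_id(r.gene_id) for r in de if r.reg_class in ("down", "up")
    }
    return GeneSet(
        label=f"{chip_genes.label}_direct_targets",
        genes=frozenset(chip_genes.genes & regulated),
        universe_size=chip_genes.universe_size,
    )


def category_enrichment(
    chip_genes: GeneSet, de: Sequence[DEResult], universe_N: int
) -> dict[str, float]:
    """Hypergeometric enrichment of ChIP targets in each regulation class.

    For each class (down / up / unchanged) the p-value is the upper tail of
    the overlap between the ChIP target set and that class, against the
    given universe.  Only genes tested by the DE stage enter the class
    sets; an empty class yields p = 1.
    """
    classes: dict[str, set[str]] = {"down": set(), "up": set(), "unchanged": set()}
    for r in de:
        classes[r.reg_class].add(normalize_gene_id(r.gene_id))
    chip = chip_genes.genes
    out = {}
    for label, genes in classes.items():
        if not genes:
            out[label] = 1.0
            continue
        q = stats_core.OverlapQuery(
            overlap_k=len(chip & genes),
            set_a_size_K=min(len(chip), universe_N),
            set_b_size_n=min(len(genes), universe_N),
            universe_N=universe_N,
        )
        out[label] = stats_core.hypergeom_upper_tail(q)
    return out


def histone_overlay(targets: GeneSet, marks: Mapping[str, GeneSet]) -> OverlayReport:
    """Count and fraction of target promoters carried in each mark's gene set."""
    n = len(targets.genes)
    per_mark = {}
    for label, mark in marks.items():
        count = len(targets.genes & mark.genes)
        per_mark[label] = (count, count / n if n else 0.0)
    return OverlayReport(target_count=n, per_mark=per_mark)


# ---------------------------------------------------------------------------
# I/O


def read_gene_set(path: str | Path, label: str | None = None,
                  universe_size: int = DEFAULT_BINDING_UNIVERSE) -> GeneSet:
    """Read a one-column gene list TSV (ignores lines starting with '#')."""
    path = Path(path)
    genes = [
        line.split("\t")[0]
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet(label=label or path.stem, genes=frozenset(genes), universe_size=universe_size)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
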