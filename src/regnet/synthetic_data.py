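"""Synthetic inputs with known ground truth for every pipeline stage.

The generator fabricates a promoter annotation with window sequences, scored
peak sets for a target transcription factor, RNA polymerase II, H3K4me3 and
H3K27me3 plus an IgG control (with shared-artifact peaks copied into the
IgG set), knockdown/control expression arrays with planted regulatory
effects, and a latent-factor tumor Z-score cohort in which the factor and
its direct targets co-upregulate.  Everything is a pure function of
(config, seed), and the planted truth is serialized alongside so recovery
can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .differential_expression import ExpressionMatrix
from .motif_enrichment import PWM, pwm_from_consensus, reverse_complement
from .peak_analysis import (
    PromoterRegion,
    ScoredPeak,
    write_peaks,
    write_promoters,
)
from .tcga_coexpression import ZScoreMatrix

TARGET_FACTOR = "TF"
FACTORS = (TARGET_FACTOR, "PolII", "H3K4me3", "H3K27me3")

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Binding fractions mirror a promoter-array screen where ~12% of genes
    carry factor binding; the tumor cohort matches the 316-sample Z-score
    panel with over-expression defined at the top 5% of expression.
    Knockdown effects are scale-free, expressed in units of the null
    standard deviation of the log fold-change statistic.
    """

    n_genes: int = 2000
    promoter_upstream: int = 2200
    promoter_downstream: int = 500
    # binding structure
    bound_fraction: float = 0.12
    direct_rate: float = 0.3  # fraction of bound genes whose expression depends on the factor
    regulated_fraction: float = 0.07  # overall regulated fraction, direct targets included
    decoy_fraction: float = 0.1  # unbound genes receiving sub-threshold (FDR > 0.2) peaks
    artifact_fraction: float = 0.1  # fraction of true factor peaks duplicated into IgG
    peak_halfwidth: int = 150
    peak_jitter_sd: float = 200.0
    # motif planting
    motif_consensus: str = "TGATTGAT"
    motif_plant_rate: float = 0.6
    motif_jitter_sd: float = 75.0
    # expression arrays
    noise_sd: float = 0.2  # per-array technical noise, log2 scale
    n_control_arrays: int = 3
    n_knockdown_arrays: int = 1
    direct_effect: float = -5.5  # knockdown lowers direct targets; null-sigma units
    indirect_effect_magnitude: float = 5.0
    # tumor cohort
    n_tumors: int = 316
    background_overexp_rate: float = 0.05
    coexp_active_fraction: float = 0.25
    coexp_penetrance: float = 0.6
    coexp_shift: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "bound_fraction", "direct_rate", "regulated_fraction", "decoy_fraction",
            "artifact_fraction", "motif_plant_rate", "background_overexp_rate",
            "coexp_active_fraction", "coexp_penetrance",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_control_arrays < 2:
            raise ValueError("need >= 2 control arrays to estimate the null")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def window_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    @property
    def statistic_noise_sd(self) -> float:
        """Null sd of the log2 fold-change statistic (the effect-size unit)."""
        return self.noise_sd * np.sqrt(
            1.0 / self.n_knockdown_arrays + 1.0 / self.n_control_arrays
        )


@dataclass
class SimulationTruth:
    """Planted ground truth, fully determined by (config, seed)."""

    bound_genes: dict[str, set[str]]
    regulated_genes: dict[str, float]  # gene -> signed effect, null-sigma units
    artifact_genes: set[str]
    motif_planted_regions: dict[str, float]  # region -> motif offset from peak center
    coexp_active_tumors: set[str]
    coexp_target_genes: set[str]
    penetrance: float
    anchor_gene: str
    seed: int

    def direct_targets(self) -> set[str]:
        return self.bound_genes[TARGET_FACTOR] & set(self.regulated_genes)

    def recoverable_direct_targets(self) -> set[str]:
        """Direct targets whose binding evidence survives artifact removal."""
        return self.direct_targets() - self.artifact_genes

    def to_json(self) -> str:
        payload = {
            "bound_genes": {f: sorted(g) for f, g in self.bound_genes.items()},
            "regulated_genes": self.regulated_genes,
            "artifact_genes": sorted(self.artifact_genes),
            "motif_planted_regions": self.motif_planted_regions,
            "coexp_active_tumors": sorted(self.coexp_active_tumors),
            "coexp_target_genes": sorted(self.coexp_target_genes),
            "penetrance": self.penetrance,
            "anchor_gene": self.anchor_gene,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            bound_genes={f: set(g) for f, g in d["bound_genes"].items()},
            regulated_genes=d["regulated_genes"],
            artifact_genes=set(d["artifact_genes"]),
            motif_planted_regions=d["motif_planted_regions"],
            coexp_active_tumors=set(d["coexp_active_tumors"]),
            coexp_target_genes=set(d["coexp_target_genes"]),
            penetrance=d["penetrance"],
            anchor_gene=d["anchor_gene"],
            seed=d["seed"],
        )


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    truth: SimulationTruth
    promoters: list[PromoterRegion]
    sequences: dict[str, str]  # gene -> promoter window sequence (genomic orientation)
    peaks: dict[str, list[ScoredPeak]]  # factor (and "IgG") -> peak list
    expression: ExpressionMatrix
    zscores: ZScoreMatrix


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_truth(cfg: SimConfig, seed: int) -> SimulationTruth:
    """Draw the planted regulatory structure.

    The factor binds ``bound_fraction`` of genes; of those, ``direct_rate``
    are transcriptionally dependent on it (knockdown lowers them).  Extra
    indirectly regulated genes (mixed signs) are drawn from the unbound
    remainder up to ``regulated_fraction`` overall.  PolII and H3K4me3 are
    planted to co-occur with factor binding, H3K27me3 to avoid H3K4me3
    entirely.  A latent tumor subset co-activates the factor gene and its
    direct targets.
    """
    rng = _rng(seed, 1)
    genes = np.array(_gene_ids(cfg.n_genes))
    n_bound = round(cfg.bound_fraction * cfg.n_genes)
    bound_tf = rng.choice(genes, size=n_bound, replace=False)
    n_direct = round(cfg.direct_rate * n_bound)
    direct = rng.choice(bound_tf, size=n_direct, replace=False)
    unbound = np.setdiff1d(genes, bound_tf)
    n_indirect = max(0, round(cfg.regulated_fraction * cfg.n_genes) - n_direct)
    indirect = rng.choice(unbound, size=min(n_indirect, unbound.size), replace=False)

    regulated: dict[str, float] = {g: cfg.direct_effect for g in direct}
    signs = rng.choice([-1.0, 1.0], size=indirect.size)
    for g, s in zip(indirect, signs):
        regulated[g] = s * cfg.indirect_effect_magnitude

    bound_tf_set = set(bound_tf)
    polii, k4, k27 = set(), set(), set()
    for g in genes:
        is_tf = g in bound_tf_set
        if rng.random() < (0.8 if is_tf else 0.35):
            polii.add(g)
        in_k4 = rng.random() < (0.7 if is_tf else 0.45)
        if in_k4:
            k4.add(g)
        # H3K27me3 planted strictly outside H3K4me3 promoters; the
        # conditional rate keeps ~2% of factor-bound genes K27-marked
        elif rng.random() < ((0.02 / 0.3) if is_tf else 0.3):
            k27.add(g)

    n_artifact = round(cfg.artifact_fraction * n_bound)
    artifact = set(rng.choice(bound_tf, size=n_artifact, replace=False))

    tumors = [f"T{i:03d}" for i in range(cfg.n_tumors)]
    active = {t for t in tumors if rng.random() < cfg.coexp_active_fraction}
    anchor = "ANCHOR_TF"
    direct_set = set(direct)
    return SimulationTruth(
        bound_genes={TARGET_FACTOR: bound_tf_set, "PolII": polii, "H3K4me3": k4, "H3K27me3": k27},
        regulated_genes=regulated,
        artifact_genes=artifact,
        motif_planted_regions={},
        coexp_active_tumors=active,
        coexp_target_genes=direct_set,
        penetrance=cfg.coexp_penetrance,
        anchor_gene=anchor,
        seed=seed,
    )


def make_annotation(
    cfg: SimConfig, seed: int
) -> tuple[list[PromoterRegion], dict[str, str]]:
    """Non-overlapping promoter windows on synthetic chromosomes, with sequences.

    Windows span ``promoter_upstream`` bases 5' and ``promoter_downstream``
    bases 3' of the TSS, mixed strands, ~200 genes per chromosome.  Window
    sequences are uniform-random ACGT stored in genomic orientation.
    """
    rng = _rng(seed, 2)
    genes = _gene_ids(cfg.n_genes)
    L = cfg.window_length
    per_chrom = 200
    spacing = L + 500
    promoters = []
    sequences = {}
    for i, gene in enumerate(genes):
        chrom = f"chr{1 + i // per_chrom}"
        start = 10_000 + (i % per_chrom) * spacing
        end = start + L
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start + cfg.promoter_upstream if strand == "+" else end - 1 - cfg.promoter_upstream
        promoters.append(
            PromoterRegion(
                gene_id=gene, chrom=chrom, window_start=start,
                window_end=end, tss=tss, strand=strand,
            )
        )
        seq_codes = rng.integers(0, 4, size=L, dtype=np.uint8)
        sequences[gene] = _BASE_BYTES[seq_codes].tobytes().decode()
    return promoters, sequences


def make_peaksets(
    truth: SimulationTruth,
    cfg: SimConfig,
    seed: int,
    promoters: Sequence[PromoterRegion],
) -> dict[str, list[ScoredPeak]]:
    """Scored peak lists per factor plus the IgG control.

    Bound genes receive a peak near the TSS with FDR <= 0.2; a fraction of
    unbound genes receive decoy peaks with FDR > 0.2.  For the target
    factor, the peaks of ``truth.artifact_genes`` are duplicated verbatim
    into the IgG list (shared artifacts), and IgG additionally carries
    non-specific peaks at unbound promoters.
    """
    rng = _rng(seed, 3)
    by_gene = {p.gene_id: p for p in promoters}
    missing = set().union(*truth.bound_genes.values()) - set(by_gene)
    if missing:
        raise ValueError(f"truth refers to genes absent from annotation: {sorted(missing)[:5]}")
    half = cfg.peak_halfwidth
    margin = half  # keep peaks inside the promoter window; scan windows shift inward

    def true_peak(factor: str, gene: str) -> ScoredPeak:
        prom = by_gene[gene]
        center = int(round(prom.tss + rng.normal(0.0, cfg.peak_jitter_sd)))
        center = min(max(center, prom.window_start + margin), prom.window_end - margin)
        return ScoredPeak(
            chrom=prom.chrom, start=center - half, end=center + half,
            score=float(rng.uniform(2.0, 10.0)), fdr=float(rng.uniform(0.0, 0.2)),
            name=f"{factor}:{gene}",
        )

    peaksets: dict[str, list[ScoredPeak]] = {}
    for factor, bound in truth.bound_genes.items():
        peaksets[factor] = [true_peak(factor, g) for g in sorted(bound)]

    tf_bound = truth.bound_genes[TARGET_FACTOR]
    unbound = sorted(set(by_gene) - tf_bound)
    n_decoy = round(cfg.decoy_fraction * len(unbound))
    decoy_genes = rng.choice(unbound, size=n_decoy, replace=False)
    for g in decoy_genes:
        prom = by_gene[g]
        center = int(round(prom.tss + rng.normal(0.0, cfg.peak_jitter_sd)))
        center = min(max(center, prom.window_start + margin), prom.window_end - margin)
        peaksets[TARGET_FACTOR].append(
            ScoredPeak(
                chrom=prom.chrom, start=center - half, end=center + half,
                score=float(rng.uniform(1.0, 3.0)),
                fdr=float(rng.uniform(0.2 + 1e-9, 1.0)),
                name=f"decoy:{g}",
            )
        )

    igg: list[ScoredPeak] = []
    tf_true = {p.name.split(":", 1)[1]: p for p in peaksets[TARGET_FACTOR] if p.name.startswith(f"{TARGET_FACTOR}:")}
    for g in sorted(truth.artifact_genes):
        p = tf_true[g]
        igg.append(ScoredPeak(chrom=p.chrom, start=p.start, end=p.end,
                              score=p.score, fdr=float(rng.uniform(0.0, 1.0)),
                              name=f"IgG:{g}"))
    # non-specific IgG peaks at promoters without factor binding; these can
    # only collide with decoys, which the FDR screen removes anyway
    igg_extra = rng.choice(unbound, size=round(0.05 * len(unbound)), replace=False)
    for g in igg_extra:
        prom = by_gene[g]
        center = int(rng.integers(prom.window_start + half, prom.window_end - half))
        igg.append(
            ScoredPeak(chrom=prom.chrom, start=center - half, end=center + half,
                       score=float(rng.uniform(1.0, 4.0)), fdr=float(rng.uniform(0.0, 1.0)),
                       name=f"IgG:{g}")
        )
    peaksets["IgG"] = igg
    return peaksets


def plant_motifs(
    sequences: Mapping[str, str],
    promoters: Sequence[PromoterRegion],
    tf_peaks: Sequence[ScoredPeak],
    cfg: SimConfig,
    seed: int,
) -> tuple[dict[str, str], dict[str, float]]:
    """Write motif consensus instances near factor peak centers.

    Each true factor peak receives, with probability ``motif_plant_rate``,
    one consensus instance (random strand) centered at the peak midpoint
    plus Gaussian jitter.  Returns the edited sequences and the realized
    center offsets keyed by peak name.
    """
    rng = _rng(seed, 4)
    by_gene = {p.gene_id: p for p in promoters}
    consensus = cfg.motif_consensus.upper()
    w = len(consensus)
    edited = dict(sequences)
    offsets: dict[str, float] = {}
    for peak in tf_peaks:
        if not peak.name.startswith(f"{TARGET_FACTOR}:"):
            continue
        if rng.random() >= cfg.motif_plant_rate:
            continue
        gene = peak.name.split(":", 1)[1]
        prom = by_gene[gene]
        seq = edited[gene]
        jitter = rng.normal(0.0, cfg.motif_jitter_sd)
        motif_center = int(round(peak.midpoint + jitter))
        pos = motif_center - prom.window_start - w // 2
        pos = min(max(pos, 0), len(seq) - w)
        instance = consensus if rng.random() < 0.5 else reverse_complement(consensus)
        edited[gene] = seq[:pos] + instance + seq[pos + w:]
        offsets[peak.name] = (pos + w / 2.0) + prom.window_start - peak.midpoint
    return edited, offsets


def extract_peak_windows(
    peaks: Sequence[ScoredPeak],
    promoters: Sequence[PromoterRegion],
    sequences: Mapping[str, str],
    width: int = 600,
) -> dict[str, str]:
    """Slice fixed-width sequence windows centered on peak midpoints.

    Peaks are matched to promoters by the gene encoded in their name; the
    window is shifted inward when the peak sits near a promoter edge.
    """
    by_gene = {p.gene_id: p for p in promoters}
    half = width // 2
    windows = {}
    for peak in peaks:
        gene = peak.name.split(":", 1)[1] if ":" in peak.name else None
        prom = by_gene.get(gene)
        if prom is None:
            continue
        seq = sequences[gene]
        center = peak.midpoint - prom.window_start
        center = min(max(center, half), len(seq) - half)
        windows[peak.name] = seq[center - half : center + half]
    return windows


def make_expression(
    truth: SimulationTruth, cfg: SimConfig, seed: int
) -> ExpressionMatrix:
    """Control and knockdown arrays with planted regulatory effects.

    Per-gene baselines are log-uniform; every array adds independent
    N(0, noise_sd) log2 technical noise.  Regulated genes are shifted in
    the knockdown arrays by effect x (null sd of the fold-change statistic),
    so effect sizes are scale-free z-shifts.
    """
    rng = _rng(seed, 5)
    genes = _gene_ids(cfg.n_genes)
    base = rng.uniform(6.0, 12.0, size=cfg.n_genes)
    shift_unit = cfg.statistic_noise_sd
    effect = np.array([truth.regulated_genes.get(g, 0.0) for g in genes]) * shift_unit
    columns = {}
    condition = {}
    for i in range(cfg.n_control_arrays):
        name = f"ctrl_{i + 1}"
        columns[name] = base + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        condition[name] = "control"
    for i in range(cfg.n_knockdown_arrays):
        name = f"kd_{i + 1}"
        columns[name] = base + effect + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        condition[name] = "knockdown"
    values = pd.DataFrame({k: np.exp2(v) for k, v in columns.items()}, index=genes)
    return ExpressionMatrix(values=values, condition=condition)


def make_zscores(truth: SimulationTruth, cfg: SimConfig, seed: int) -> ZScoreMatrix:
    """Latent-factor tumor Z-score cohort.

    Background entries are centered normal, scaled so the nominal
    over-expression rate at the Z > 1.65 threshold equals
    ``background_overexp_rate`` (a standard normal to within 0.4% at the
    default 5%).  In the latent-active tumor subset the anchor gene is
    always over-expressed and each co-regulated target independently with
    probability ``penetrance``; activated cells take
    ``coexp_shift + |background noise|``, so activation always clears the
    default 1.65 threshold (penetrant activation is deterministic).
    """
    from scipy.stats import norm

    rng = _rng(seed, 6)
    genes = [truth.anchor_gene] + _gene_ids(cfg.n_genes)
    tumors = [f"T{i:03d}" for i in range(cfg.n_tumors)]
    bg_sd = 1.65 / norm.isf(cfg.background_overexp_rate)
    z = rng.normal(0.0, bg_sd, size=(len(genes), cfg.n_tumors))
    active_mask = np.array([t in truth.coexp_active_tumors for t in tumors])
    gene_pos = {g: i for i, g in enumerate(genes)}
    anchor_row = gene_pos[truth.anchor_gene]
    z[anchor_row, active_mask] = cfg.coexp_shift + np.abs(z[anchor_row, active_mask])
    for g in sorted(truth.coexp_target_genes):
        fires = active_mask & (rng.random(cfg.n_tumors) < truth.penetrance)
        z[gene_pos[g], fires] = cfg.coexp_shift + np.abs(z[gene_pos[g], fires])
    return ZScoreMatrix(z=pd.DataFrame(z, index=genes, columns=tumors))


def simulate(cfg: SimConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate the full study: truth, annotation, peaks, motifs, arrays, cohort."""
    cfg = cfg or SimConfig()
    truth = make_truth(cfg, seed)
    promoters, sequences = make_annotation(cfg, seed)
    peaks = make_peaksets(truth, cfg, seed, promoters)
    sequences, offsets = plant_motifs(
        sequences, promoters, peaks[TARGET_FACTOR], cfg, seed
    )
    truth.motif_planted_regions = offsets
    expression = make_expression(truth, cfg, seed)
    zscores = make_zscores(truth, cfg, seed)
    return SimulatedDataset(
        cfg=cfg, truth=truth, promoters=promoters, sequences=sequences,
        peaks=peaks, expression=expression, zscores=zscores,
    )


def default_pwm(cfg: SimConfig | None = None) -> PWM:
    cfg = cfg or SimConfig()
    return pwm_from_consensus("PLANTED", cfg.motif_consensus)


def make_library(
    n_motifs: int, seed: int, cfg: SimConfig | None = None,
    width_range: tuple[int, int] = (8, 12),
) -> list[PWM]:
    """The planted motif plus random-consensus competitor PWMs."""
    cfg = cfg or SimConfig()
    rng = _rng(seed, 7)
    library = [default_pwm(cfg)]
    for i in range(n_motifs - 1):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, size=w))
        library.append(pwm_from_consensus(f"RAND{i:02d}", consensus))
    return library


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write every input file the pipeline reads, plus the truth record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_promoters(ds.promoters, out / "promoters.bed")
    for factor, peaks in ds.peaks.items():
        write_peaks(peaks, out / f"peaks_{factor}.bed")
    with open(out / "promoter_windows.fa", "w") as fh:
        for gene, seq in ds.sequences.items():
            fh.write(f">{gene}\n{seq}\n")
    ds.expression.values.to_csv(out / "expression.tsv", sep="\t", float_format="%.4f")
    pd.Series(dict(ds.expression.condition), name="condition").rename_axis("sample").to_frame().to_csv(
        out / "design.tsv", sep="\t"
    )
    with open(out / "design.yaml", "w") as fh:
        yaml.safe_dump({"condition": dict(ds.expression.condition)}, fh)
    ds.zscores.z.to_csv(out / "zscores.tsv", sep="\t", float_format="%.4f")
    (out / "truth.json").write_text(ds.truth.to_json() + "\n")
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(ds.cfg)))


def load_truth(path: str | Path) -> SimulationTruth:
    return SimulationTruth.from_json(Path(path).read_text())
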