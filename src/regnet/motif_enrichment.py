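"""PWM scanning of peak-flanking windows and motif enrichment ranking.

Fixed-width windows (600 bp by default) centered on ChIP peaks are scanned
on both strands with a library of position weight matrices.  Each motif is
then scored by how many peak windows carry at least one hit, compared with
a background window set (user-supplied, or dinucleotide-preserving shuffles
of the peak windows) through a binomial upper-tail test.  Peak-to-motif
distances summarize where hits fall relative to peak centers.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PWM:
    """Position frequency matrix with background model and pseudocount.

    ``counts`` is 4 x w with rows in A, C, G, T order; columns are motif
    positions.  The log-odds transform uses background-proportional
    pseudocounts.
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", bg)
        if counts.shape[0] != 4 or counts.shape[1] < 4:
            raise ValueError("counts must be 4 x w with w >= 4")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: float  # hit center minus window center, bp
    strand: str
    log_odds: float


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    hit_regions: int
    total_regions: int
    background_rate: float
    p_value: float
    enriched: bool


def pwm_log_odds(pwm: PWM) -> np.ndarray:
    """4 x w log2-odds matrix with background-proportional pseudocounts.

    entry(b, j) = log2( (counts_bj + pc * bg_b) / (colsum_j + pc) / bg_b ).
    """
    col_totals = pwm.counts.sum(axis=0)
    if pwm.pseudocount == 0 and np.any(col_totals == 0):
        raise ValueError("zero column total with zero pseudocount")
    probs = (pwm.counts + pwm.pseudocount * pwm.background[:, None]) / (
        col_totals + pwm.pseudocount
    )
    return np.log2(probs / pwm.background[:, None])


def max_score(pwm: PWM) -> float:
    """Maximum achievable log-odds score (column-wise best base)."""
    return float(pwm_log_odds(pwm).max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence contains symbols outside ACGTN")
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _strand_scores(encoded: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; -inf where the window hits an N."""
    w = lom.shape[1]
    # row 4 (N) maps to -inf so N-containing windows can never pass threshold
    padded = np.vstack([lom, np.full((1, w), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    return padded[windows, np.arange(w)].sum(axis=1)


def scan_window(
    seq: str,
    pwm: PWM,
    threshold_fraction: float = 0.8,
    region_id: str = "region",
) -> list[MotifHit]:
    """Scan one window on both strands; report hits above a score threshold.

    A hit is any placement whose log-odds score is at least
    ``threshold_fraction`` times the motif's maximum achievable score.
    Reverse-strand hits are reported in forward coordinates, so scanning a
    sequence and its reverse complement yields mirrored hit sets.  Windows
    overlapping an N are skipped.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    w = pwm.width
    if len(seq) < w:
        return []
    lom = pwm_log_odds(pwm)
    threshold = threshold_fraction * max_score(pwm)
    L = len(seq)
    center = L / 2.0
    fwd = _encode(seq)
    rev = _encode(reverse_complement(seq))
    hits = []
    for strand, scores in (("+", _strand_scores(fwd, lom)), ("-", _strand_scores(rev, lom))):
        for pos in np.nonzero(scores >= threshold)[0]:
            start = int(pos) if strand == "+" else L - w - int(pos)
            hits.append(
                MotifHit(
                    region_id=region_id,
                    offset=start + w / 2.0 - center,
                    strand=strand,
                    log_odds=float(scores[pos]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(
    windows: Mapping[str, str], pwm: PWM, threshold_fraction: float = 0.8
) -> list[MotifHit]:
    """Scan every named window with one PWM."""
    out: list[MotifHit] = []
    for region_id, seq in windows.items():
        out.extend(scan_window(seq, pwm, threshold_fraction, region_id=region_id))
    return out


def _region_hit_count(windows: Mapping[str, str], pwm: PWM, threshold_fraction: float) -> int:
    return sum(
        1 for seq in windows.values() if scan_window(seq, pwm, threshold_fraction)
    )


def enrich_motifs(
    peak_windows: Mapping[str, str],
    pwm_library: Sequence[PWM],
    background: Mapping[str, str] | None = None,
    threshold_fraction: float = 0.8,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[MotifEnrichment]:
    """Rank motifs by over-representation in peak windows vs background.

    For each motif the background rate is the fraction of background windows
    containing at least one hit (clamped away from 0 and 1 by half a count so
    the binomial tail stays in (0, 1]); the p-value is the binomial upper
    tail of the number of hit-carrying peak windows at that rate.  When no
    background is given, dinucleotide-preserving shuffles of the peak
    windows are used (seeded).
    """
    if not pwm_library:
        raise ValueError("empty PWM library")
    if not peak_windows:
        raise ValueError("empty peak window set")
    if background is None:
        rng = np.random.default_rng(seed)
        background = {
            f"shuf_{rid}": dinucleotide_shuffle(seq, rng)
            for rid, seq in peak_windows.items()
        }
    n_peak = len(peak_windows)
    n_bg = len(background)
    results = []
    for pwm in pwm_library:
        hits = _region_hit_count(peak_windows, pwm, threshold_fraction)
        bg_hits = _region_hit_count(background, pwm, threshold_fraction)
        rate = min(max(bg_hits / n_bg, 0.5 / n_bg), 1.0 - 0.5 / n_bg)
        p = float(stats.binom.sf(hits - 1, n_peak, rate))
        results.append(
            MotifEnrichment(
                motif_id=pwm.motif_id,
                hit_regions=hits,
                total_regions=n_peak,
                background_rate=rate,
                p_value=min(p, 1.0),
                enriched=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.motif_id))
    return results


def peak_motif_distances(hits: Iterable[MotifHit]) -> list[float]:
    """One signed distance per region with hits: the closest hit's center offset."""
    by_region: dict[str, list[MotifHit]] = defaultdict(list)
    for h in hits:
        by_region[h.region_id].append(h)
    return [
        min(region_hits, key=lambda h: (abs(h.offset), h.offset)).offset
        for _, region_hits in sorted(by_region.items())
    ]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving exact dinucleotide counts.

    Altschul-Erickson: pick a random set of terminal edges forming a tree
    into the final character, shuffle the remaining edges per vertex, and
    walk the resulting Eulerian path.
    """
    seq = seq.upper()
    if len(seq) < 3 or len(set(seq)) < 2:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    while True:  # rejection-sample terminal edges until they form a tree into `last`
        terminal = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        if all(_reaches(v, last, terminal) for v in vertices):
            break
    shuffled: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in terminal:
            pool.remove(terminal[v])
        rng.shuffle(pool)
        shuffled[v] = pool + ([terminal[v]] if v in terminal else [])
    out = [seq[0]]
    cursors: dict[str, int] = defaultdict(int)
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[v][cursors[v]]
        cursors[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def _reaches(v: str, last: str, terminal: Mapping[str, str]) -> bool:
    seen = set()
    while v != last:
        if v in seen or v not in terminal:
            return False
        seen.add(v)
        v = terminal[v]
    return True


# ---------------------------------------------------------------------------
# Motif library I/O


def parse_transfac(text: str) -> list[PWM]:
    """Parse a minimal TRANSFAC-style library (ID / P0 / numbered rows / //)."""
    motifs = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        tag = line.split()[0]
        if tag == "ID":
            motif_id = line.split(None, 1)[1].strip()
            rows = []
        elif tag in ("P0", "PO", "XX"):
            continue
        elif tag == "//":
            if motif_id is not None and rows:
                motifs.append(PWM(motif_id=motif_id, counts=np.array(rows).T))
            motif_id, rows = None, []
        elif re.fullmatch(r"\d+", tag):
            vals = line.split()[1:5]
            rows.append([float(v) for v in vals])
    if motif_id is not None and rows:
        motifs.append(PWM(motif_id=motif_id, counts=np.array(rows).T))
    if not motifs:
        raise ValueError("no motifs parsed from TRANSFAC text")
    return motifs


def parse_pfm_tsv(text: str) -> list[PWM]:
    """Parse a plain PFM library: '>motif_id' header then w rows of 4 counts."""
    motifs = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if motif_id is not None and rows:
                motifs.append(PWM(motif_id=motif_id, counts=np.array(rows).T))
            motif_id = line[1:].strip() or None
            rows = []
        elif line:
            rows.append([float(v) for v in line.split("\t" if "\t" in line else None)])
    if not motifs:
        raise ValueError("no motifs parsed from PFM text")
    return motifs


def load_motif_library(path: str | Path) -> list[PWM]:
    """Load motifs from a TRANSFAC-style or '>'-delimited PFM TSV file."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        return parse_pfm_tsv(text)
    return parse_transfac(text)


def pwm_from_consensus(motif_id: str, consensus: str, weight: float = 10.0) -> PWM:
    """Build a sharply-peaked PWM from a consensus string (1 count off-consensus)."""
    counts = np.ones((4, len(consensus)))
    for j, base in enumerate(consensus.upper()):
        counts[_BASE_INDEX[base], j] = weight
    return PWM(motif_id=motif_id, counts=counts)
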