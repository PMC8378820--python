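"""Promoter motif scanning with a position weight matrix (PWM).

Counts in JASPAR plain-text format (e.g. the androgen-responsive element,
ARE) are converted to probabilities with a background-proportional
pseudocount, and promoter windows (-1000..+100 bp around the TSS in
transcription orientation, by default) are scanned on both strands with a
log2-odds score. The headline statistic is the fraction of a gene list whose
promoter contains at least one hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PWM:
    """Position probability matrix with its background model.

    ``probs`` has shape (length, 4) in A, C, G, T order; each row sums to 1.
    Scores are log2 odds against ``background`` (bits).
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("PWM must be positions x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1], self.background[::-1])


def pwm_from_counts(counts: np.ndarray, motif_id: str = "pwm",
                    pseudocount: float = 0.2,
                    background=None) -> PWM:
    """Counts -> probabilities with a background-proportional pseudocount.

    Each cell receives ``pseudocount * 4 * background[base]`` added mass
    (exactly ``pseudocount`` per cell at uniform background) before column
    normalization.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be positions x 4 (A, C, G, T)")
    if counts.min() < 0:
        raise ValueError("negative counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    padded = counts + pseudocount * 4.0 * bg
    row_sums = padded.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("a PWM position has zero total mass; use a positive pseudocount")
    return PWM(motif_id, padded / row_sums, bg)


def load_pwm(source, pseudocount: float = 0.2, background=None) -> PWM:
    """Parse one JASPAR plain-text record (path, handle, or string).

    Accepts both bracketed (``A [ 3 1 0 ]``) and bare matrix layouts, with an
    optional ``>MA0007.2 AR`` header. Requires exactly the four rows A, C, G,
    T of equal length with nonnegative counts.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith(">"):
            with open(text) as fh:
                text = fh.read()
    motif_id = "pwm"
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if line[1:].split() else "pwm"
            continue
        m = re.match(r"^([A-Za-z])\s*[:\[]?\s*([-0-9eE.+\s]*?)\s*\]?$", line)
        if not m:
            raise ValueError(f"unparseable PWM line: {line!r}")
        base = m.group(1).upper()
        if base not in _BASE_INDEX:
            raise ValueError(f"unknown row label {base!r} (expected A/C/G/T)")
        if base in rows:
            raise ValueError(f"duplicate row for base {base!r}")
        values = [float(v) for v in m.group(2).split()]
        if any(v < 0 for v in values):
            raise ValueError("negative counts in PWM record")
        rows[base] = values
    if set(rows) != set(ALPHABET):
        raise ValueError(f"PWM record must have rows A, C, G, T; got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1 or lengths == {0}:
        raise ValueError("PWM rows must be nonempty and of equal length")
    counts = np.column_stack([rows[b] for b in ALPHABET])
    return pwm_from_counts(counts, motif_id, pseudocount, background)


@dataclass(frozen=True)
class PromoterRegion:
    """0-based half-open genomic window around a TSS."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int


def define_promoters(tss_table: pd.DataFrame, upstream: int = 1000,
                     downstream: int = 100,
                     contig_lengths: dict[str, int] | None = None) -> list[PromoterRegion]:
    """Promoter windows covering -upstream..+downstream in transcription
    orientation.

    *tss_table* needs columns ``gene``, ``chrom``, ``strand``, ``tss`` (0-based
    TSS position). Windows are truncated at contig boundaries; a TSS beyond
    the contig length is an error.
    """
    regions = []
    for row in tss_table.itertuples(index=False):
        strand = row.strand
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {strand!r}")
        tss = int(row.tss)
        if tss < 0:
            raise ValueError(f"negative TSS for {row.gene}")
        limit = contig_lengths.get(row.chrom) if contig_lengths else None
        if limit is not None and tss >= limit:
            raise ValueError(f"TSS {tss} beyond contig {row.chrom} length {limit}")
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start = max(start, 0)
        if limit is not None:
            end = min(end, limit)
        regions.append(PromoterRegion(row.gene, row.chrom, strand, start, end))
    return regions


def extract_promoters(regions, contigs: dict[str, str]) -> dict[str, str]:
    """Promoter sequences in transcription orientation, keyed by gene id."""
    out = {}
    for r in regions:
        seq = contigs[r.chrom][r.start:r.end].upper()
        if r.strand == "-":
            seq = reverse_complement(seq)
        out[r.gene_id] = seq
    return out


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    offset: int
    strand: str
    score: float


def scan_sequence(seq: str, pwm: PWM, threshold: float,
                  gene_id: str = "") -> list[MotifHit]:
    """Log2-odds scan of both strands; windows containing N are skipped.

    *threshold* is in bits. Hits are sorted by offset (offset of the window
    start on the given sequence, for either strand), then strand.
    """
    seq = seq.upper()
    if not set(seq) <= set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    L, W = len(seq), len(pwm)
    hits: list[MotifHit] = []
    if L < W:
        return hits
    idx = np.fromiter((_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int64, count=L)
    windows = np.lib.stride_tricks.sliding_window_view(idx, W)
    valid = (windows >= 0).all(axis=1)
    pos_range = np.arange(W)
    for strand, matrix in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        safe = np.where(windows >= 0, windows, 0)
        scores = matrix[pos_range, safe].sum(axis=1)
        for off in np.nonzero(valid & (scores >= threshold))[0]:
            hits.append(MotifHit(gene_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(promoters: dict[str, str], pwm: PWM,
                   rel_threshold: float = 0.8,
                   abs_threshold: float | None = None) -> pd.DataFrame:
    """Scan every promoter; threshold defaults to 80% of the maximum score.

    Returns a long DataFrame (gene_id, offset, strand, score); genes without
    hits are absent.
    """
    threshold = abs_threshold if abs_threshold is not None else rel_threshold * pwm.max_score()
    rows = []
    for gene, seq in promoters.items():
        rows.extend(scan_sequence(seq, pwm, threshold, gene_id=gene))
    return pd.DataFrame([h.__dict__ for h in rows],
                        columns=["gene_id", "offset", "strand", "score"])


def are_fraction(gene_list, hits: pd.DataFrame, available=None) -> dict:
    """Fraction of listed genes whose (available) promoter has >= 1 hit."""
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        raise ValueError("empty gene list")
    if available is None:
        usable = genes
        missing = []
    else:
        available = set(available)
        usable = [g for g in genes if g in available]
        missing = [g for g in genes if g not in available]
    hit_genes = set(hits["gene_id"]) if len(hits) else set()
    n_hit = sum(g in hit_genes for g in usable)
    return {
        "n_genes": len(genes),
        "n_with_promoter": len(usable),
        "n_missing_promoter": len(missing),
        "n_with_hit": n_hit,
        "fraction": n_hit / len(usable) if usable else float("nan"),
    }


def hits_to_bed(hits: pd.DataFrame, regions: list[PromoterRegion],
                motif_id: str, motif_length: int, path) -> None:
    """Write hits as BED6 in genome coordinates (chrom start end name score strand).

    Offsets from :func:`scan_promoters` are in transcription orientation, so
    for minus-strand promoters both the coordinate and the hit strand are
    mirrored back to the reference.
    """
    by_gene = {r.gene_id: r for r in regions}
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            r = by_gene[row.gene_id]
            if r.strand == "+":
                start = r.start + row.offset
                strand = row.strand
            else:
                start = r.end - row.offset - motif_length
                strand = "+" if row.strand == "-" else "-"
            fh.write(f"{r.chrom}\t{start}\t{start + motif_length}\t"
                     f"{row.gene_id}:{motif_id}\t{row.score:.3f}\t{strand}\n")
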