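"""ChIP-seq track processing: fragment length, extension, background, occupancy.

Implements the standard single-end ChIP pipeline over a joint reference of
genome chromosomes plus one integrated-plasmid contig:

1. fragment-length estimation by the +/− strand cross-correlation shift,
2. extension of read starts to fragment-length coverage,
3. depth normalization to 1,000,000 reads, genome-wide mean-background
   subtraction and clipping of negatives,
4. promoter-averaged binding per gene signal region (TSS−500 bp .. TTS,
   strand-aware), and
5. plasmid occupancy as the raw-read fraction on the plasmid contig.

Coordinates are 0-based, half-open.  A − strand read start is stored at the
5′ end of the reverse read, i.e. the rightmost covered base: a fragment
[s, s+L) registers a + start at s or a − start at s+L−1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReadStartTrack",
    "CoverageTrack",
    "RegionSet",
    "estimate_fragment_length",
    "extend_reads",
    "normalize_subtract",
    "promoter_binding",
    "paired_binding",
    "plasmid_occupancy",
]

STRANDS = ("+", "-")


@dataclass
class ReadStartTrack:
    """Per-contig, per-strand integer arrays of read-start counts."""

    starts: dict  # contig -> {"+": np.ndarray, "-": np.ndarray}
    plasmid_contig: str | None = "plasmid"

    def __post_init__(self) -> None:
        for contig, by_strand in self.starts.items():
            for s in STRANDS:
                if s not in by_strand:
                    raise ValueError(f"contig {contig} missing strand {s}")
            if len(by_strand["+"]) != len(by_strand["-"]):
                raise ValueError(f"contig {contig}: strand arrays differ in length")

    @property
    def contigs(self) -> list:
        return list(self.starts)

    @property
    def genome_contigs(self) -> list:
        return [c for c in self.starts if c != self.plasmid_contig]

    def length(self, contig: str) -> int:
        return len(self.starts[contig]["+"])

    def strand_total(self, strand: str) -> int:
        return int(sum(by[strand].sum() for by in self.starts.values()))

    def total_reads(self) -> int:
        return self.strand_total("+") + self.strand_total("-")


@dataclass
class CoverageTrack:
    """Strandless real-valued coverage after read extension."""

    coverage: dict  # contig -> np.ndarray
    total_reads: int
    plasmid_contig: str | None = "plasmid"

    @property
    def genome_contigs(self) -> list:
        return [c for c in self.coverage if c != self.plasmid_contig]


@dataclass
class RegionSet:
    """Signal/background partition of the genome.

    Signal is the union of per-gene intervals from 500 bp upstream of the
    TSS (strand-aware) to the TTS; background is the genomic complement.
    The plasmid contig belongs to neither (its coverage is still
    background-subtracted, but never contributes to the background mean).
    """

    intervals: pd.DataFrame  # columns: gene_id, contig, start, end
    contig_lengths: dict
    plasmid_contig: str | None = "plasmid"
    _masks: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_catalog(cls, catalog: pd.DataFrame, contig_lengths: dict,
                     genome_contig: str = "chrI", upstream: int = 500,
                     plasmid_contig: str | None = "plasmid") -> "RegionSet":
        """Build gene signal regions from a catalog with tss/tts/strand.

        ``tss``/``tts`` are stored promoter-to-terminator, so a − strand
        gene has tss > tts; the upstream extension is applied on the
        promoter side in genomic coordinates.
        """
        rows = []
        length = contig_lengths[genome_contig]
        for gene in catalog.itertuples():
            lo, hi = sorted((int(gene.tss), int(gene.tts)))
            if gene.strand == "+":
                start, end = max(lo - upstream, 0), hi
            else:
                start, end = lo, min(hi + upstream, length)
            rows.append({"gene_id": gene.gene_id, "contig": genome_contig,
                         "start": start, "end": end})
        return cls(pd.DataFrame(rows), dict(contig_lengths), plasmid_contig)

    def signal_mask(self, contig: str) -> np.ndarray:
        if contig not in self._masks:
            mask = np.zeros(self.contig_lengths[contig], dtype=bool)
            sub = self.intervals[self.intervals["contig"] == contig]
            for iv in sub.itertuples():
                mask[iv.start:iv.end] = True
            self._masks[contig] = mask
        return self._masks[contig]

    @property
    def genome_contigs(self) -> list:
        return [c for c in self.contig_lengths if c != self.plasmid_contig]


def estimate_fragment_length(track: ReadStartTrack,
                             shift_range=range(50, 301)) -> int:
    """Fragment length from the best-aligning +/− strand shift.

    Maximizes, over shifts ``s``, the cross-correlation between + strand
    starts and − strand starts moved upstream by ``s`` (summed over all
    contigs); ties resolve to the smallest shift.
    """
    shifts = np.asarray(list(shift_range), dtype=int)
    if shifts.size == 0:
        raise ValueError("empty shift_range")
    if track.strand_total("+") == 0 or track.strand_total("-") == 0:
        raise ValueError("both strands must contain reads")
    scores = np.zeros(shifts.size)
    for by_strand in track.starts.values():
        plus = by_strand["+"].astype(float)
        minus = by_strand["-"].astype(float)
        n = plus.size
        for j, s in enumerate(shifts):
            if s >= n:
                continue
            if s == 0:
                scores[j] += float(plus @ minus)
            else:
                scores[j] += float(plus[:-s] @ minus[s:])
    return int(shifts[int(np.argmax(scores))])


def extend_reads(track: ReadStartTrack, frag_len: int) -> CoverageTrack:
    """Extend single-end read starts to fragment-length coverage.

    A + start at ``p`` covers ``[p, p+frag_len)``; a − start at ``p``
    (the 5′ end of the reverse read) covers ``[p-frag_len+1, p+1)``.
    Fragments running off a contig end are truncated (counted in the log).
    """
    if frag_len < 1:
        raise ValueError("frag_len must be >= 1")
    coverage = {}
    truncated = 0
    for contig, by_strand in track.starts.items():
        n = len(by_strand["+"])
        delta = np.zeros(n + 1)
        pos = np.arange(n)

        plus = by_strand["+"].astype(float)
        delta[:n] += plus
        ends = np.minimum(pos + frag_len, n)
        np.add.at(delta, ends, -plus)
        truncated += int(plus[pos + frag_len > n].sum())

        minus = by_strand["-"].astype(float)
        starts = np.maximum(pos - frag_len + 1, 0)
        np.add.at(delta, starts, minus)
        np.add.at(delta, pos + 1, -minus)
        truncated += int(minus[pos - frag_len + 1 < 0].sum())

        coverage[contig] = np.cumsum(delta[:n])
    if truncated:
        logger.info("extend_reads: %d fragments truncated at contig boundaries",
                    truncated)
    return CoverageTrack(coverage, track.total_reads(), track.plasmid_contig)


def normalize_subtract(coverage: CoverageTrack, regions: RegionSet) -> CoverageTrack:
    """Depth-normalize, subtract the mean background, clip negatives.

    Coverage is scaled to a depth of 1,000,000 reads; the mean over all
    genomic background positions (signal complement, plasmid excluded) is
    subtracted from every position of every contig; negatives become 0.
    """
    if coverage.total_reads <= 0:
        raise ValueError("track has no reads")
    scale = 1_000_000.0 / coverage.total_reads
    bg_sum, bg_n = 0.0, 0
    for contig in regions.genome_contigs:
        mask = regions.signal_mask(contig)
        vals = coverage.coverage[contig][~mask]
        bg_sum += float(vals.sum())
        bg_n += vals.size
    if bg_n == 0:
        raise ValueError("background region is empty")
    bg_mean = scale * bg_sum / bg_n
    out = {c: np.clip(v * scale - bg_mean, 0.0, None)
           for c, v in coverage.coverage.items()}
    return CoverageTrack(out, coverage.total_reads, coverage.plasmid_contig)


def promoter_binding(coverage: CoverageTrack, regions: RegionSet) -> pd.Series:
    """Mean processed coverage over each gene's signal region."""
    means = {}
    for iv in regions.intervals.itertuples():
        if iv.end <= iv.start:
            raise ValueError(f"zero-length region for {iv.gene_id}")
        means[iv.gene_id] = float(coverage.coverage[iv.contig][iv.start:iv.end].mean())
    return pd.Series(means, name="binding")


def paired_binding(cov_a: CoverageTrack, cov_b: CoverageTrack,
                   regions: RegionSet) -> tuple[pd.DataFrame, float]:
    """Per-gene binding in two samples plus their Pearson correlation."""
    a = promoter_binding(cov_a, regions)
    b = promoter_binding(cov_b, regions)
    table = pd.DataFrame({"sample_a": a, "sample_b": b})
    r = float(stats.pearsonr(table["sample_a"], table["sample_b"])[0])
    return table, r


def plasmid_occupancy(track: ReadStartTrack,
                      plasmid_contig: str | None = None) -> float:
    """Fraction of raw reads on the plasmid contig (pre-normalization)."""
    contig = plasmid_contig or track.plasmid_contig
    if contig not in track.starts:
        raise ValueError(f"plasmid contig {contig!r} not in track")
    total = track.total_reads()
    if total == 0:
        raise ValueError("track has no reads")
    by = track.starts[contig]
    return float((by["+"].sum() + by["-"].sum()) / total)
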