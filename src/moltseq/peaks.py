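"""Consensus peaks, functional-region annotation and TSS signal profiles.

Peaks called per sample are merged into a consensus set by single-linkage
overlap (any shared base joins two peaks), carrying per-sample
fold-enrichment forward.  Each consensus peak is then assigned exactly one
functional region by a fixed priority order::

    promoter-TSS > 5'UTR > 3'UTR > exon > intron > downstream > distal intergenic

so a peak that could be an exon of one gene and an intron of another is
annotated to the exon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, promoter_of, tts_of

__all__ = [
    "PeakRecord",
    "REGION_CATEGORIES",
    "GenomeRegions",
    "read_narrowpeak",
    "write_consensus_tsv",
    "read_consensus_tsv",
    "merge_sample_peaks",
    "categorize_peak",
    "region_distribution",
    "tss_profile",
]

REGION_CATEGORIES = (
    "promoter_tss",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)


@dataclass
class PeakRecord:
    """A genomic interval with optional summit and per-sample FoldEnrich."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int | None = None
    fold_enrich: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.peak_id}: start must be < end")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.peak_id}: summit outside interval")
        for s, v in self.fold_enrich.items():
            if v < 0:
                raise ValueError(f"peak {self.peak_id}: negative FoldEnrich for {s}")

    @property
    def anchor(self) -> int:
        """Summit if present, else interval midpoint (floor)."""
        return self.summit if self.summit is not None else (self.start + self.end) // 2


def read_narrowpeak(path: str | Path, sample_id: str | None = None) -> list[PeakRecord]:
    """Read a 10-column narrowPeak file (0-based half-open).

    Column 7 is signalValue (fold-enrichment), column 10 the summit offset
    from the peak start (-1 = no summit).  When ``sample_id`` is given the
    fold-enrichment is stored under that key; otherwise under the file
    stem.
    """
    sample = sample_id if sample_id is not None else Path(path).stem
    peaks: list[PeakRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 10:
            raise ValueError(f"{path}:{lineno}: expected 10 narrowPeak columns")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        fe = float(parts[6])
        offset = int(parts[9])
        summit = start + offset if offset >= 0 else None
        peaks.append(
            PeakRecord(name, chrom, start, end, summit=summit, fold_enrich={sample: fe})
        )
    return peaks


def merge_sample_peaks(
    per_sample_peaks: Mapping[str, Sequence[PeakRecord]],
    known_chroms: Iterable[str] | None = None,
) -> list[PeakRecord]:
    """Merge per-sample peak calls into consensus peaks.

    Peaks from any samples that overlap by >= 1 bp are unioned
    (single-linkage, so a chain of pairwise overlaps forms one consensus
    peak).  Each sample's fold-enrichment on the consensus peak is the
    maximum over its constituent peaks; the summit is taken from the
    constituent peak with the highest fold-enrichment.  Idempotent:
    merging an already merged set returns it unchanged.
    """
    flat: list[tuple[str, int, int, int | None, str, float]] = []
    known = set(known_chroms) if known_chroms is not None else None
    for sample, peaks in per_sample_peaks.items():
        for p in peaks:
            if known is not None and p.chrom not in known:
                warnings.warn(f"peak {p.peak_id} on unknown chromosome {p.chrom}; retained")
            if p.fold_enrich:
                # already-merged records carry several samples; keep each
                for s, v in p.fold_enrich.items():
                    flat.append((p.chrom, p.start, p.end, p.summit, s, v))
            else:
                flat.append((p.chrom, p.start, p.end, p.summit, sample, 0.0))

    flat.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[PeakRecord] = []
    cluster: list[tuple[str, int, int, int | None, str, float]] = []

    def _flush() -> None:
        if not cluster:
            return
        chrom = cluster[0][0]
        start = min(c[1] for c in cluster)
        end = max(c[2] for c in cluster)
        fe: dict[str, float] = {}
        for _, _, _, _, sample, v in cluster:
            fe[sample] = max(fe.get(sample, 0.0), v)
        best = max(cluster, key=lambda c: c[5])
        summit = best[3]
        if summit is not None and not (start <= summit < end):
            summit = None
        merged.append(
            PeakRecord(f"consensus_{len(merged) + 1}", chrom, start, end,
                       summit=summit, fold_enrich=fe)
        )

    cur_chrom, cur_end = None, -1
    for rec in flat:
        chrom, start, end = rec[0], rec[1], rec[2]
        if chrom != cur_chrom or start >= cur_end:
            _flush()
            cluster = [rec]
            cur_chrom, cur_end = chrom, end
        else:
            cluster.append(rec)
            cur_end = max(cur_end, end)
    _flush()
    return merged


class GenomeRegions:
    """Per-chromosome interval indexes for the seven functional categories.

    Built once from a gene set; ``promoter_flank`` and ``downstream_extent``
    follow the definitions used throughout the pipeline (promoter = TSS
    +/- 2 kb; downstream = the ``downstream_extent`` bases past the TTS on
    the gene's strand).
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_flank: int = 2000,
        downstream_extent: int = 3000,
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.genes = list(genes)
        self.promoter_flank = promoter_flank
        self.downstream_extent = downstream_extent
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {}
        self.trees: dict[str, dict[str, IntervalTree]] = {
            cat: {} for cat in REGION_CATEGORIES if cat != "distal_intergenic"
        }
        self.promoters = []
        for g in genes:
            size = self.chrom_sizes.get(g.chrom)
            prom = promoter_of(g, promoter_flank, size)
            self.promoters.append(prom)
            self._add("promoter_tss", g.chrom, prom.start, prom.end)
            for s, e in g.utr5:
                self._add("utr5", g.chrom, s, e)
            for s, e in g.utr3:
                self._add("utr3", g.chrom, s, e)
            for s, e in g.exons:
                self._add("exon", g.chrom, s, e)
            # introns: gene body minus exons
            prev = g.start
            for s, e in g.exons:
                if s > prev:
                    self._add("intron", g.chrom, prev, s)
                prev = max(prev, e)
            if g.end > prev:
                self._add("intron", g.chrom, prev, g.end)
            tts = tts_of(g)
            if g.strand == "+":
                ds_start, ds_end = tts + 1, tts + 1 + downstream_extent
            else:
                ds_start, ds_end = tts - downstream_extent, tts
            ds_start = max(0, ds_start)
            if size is not None:
                ds_end = min(ds_end, size)
            if ds_start < ds_end:
                self._add("downstream", g.chrom, ds_start, ds_end)

    def _add(self, cat: str, chrom: str, start: int, end: int) -> None:
        if end <= start:
            return
        self.trees[cat].setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, cat: str, chrom: str, start: int, end: int) -> bool:
        tree = self.trees[cat].get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False


def categorize_peak(peak: PeakRecord, regions: GenomeRegions) -> str:
    """Assign the peak's functional region by the fixed priority order.

    The full peak interval is tested against each category's region set in
    order; the first category with >= 1 bp of overlap wins, and a peak
    overlapping nothing is distal intergenic.
    """
    for cat in REGION_CATEGORIES[:-1]:
        if regions.overlaps(cat, peak.chrom, peak.start, peak.end):
            return cat
    return "distal_intergenic"


def region_distribution(
    peaks: Sequence[PeakRecord], regions: GenomeRegions
) -> pd.DataFrame:
    """Count and fraction of peaks per functional category.

    Returns a DataFrame indexed by category with ``count`` and
    ``fraction`` columns; fractions sum to 1.
    """
    if not peaks:
        raise ValueError("region_distribution requires at least one peak")
    counts = {cat: 0 for cat in REGION_CATEGORIES}
    for p in peaks:
        counts[categorize_peak(p, regions)] += 1
    df = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)},
        index=list(REGION_CATEGORIES),
    )
    df["fraction"] = df["count"] / len(peaks)
    return df


def tss_profile(
    signal_positions: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
    flank: int = 3000,
    bin_size: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signal counts in bins across ``[tss - flank, tss + flank)`` per gene.

    ``signal_positions`` maps chromosome -> array of positions (e.g. Tn5
    insertion sites).  Rows of reverse-strand genes are flipped so bin 0
    is always the 5'/upstream side.  Windows that run off the chromosome
    start keep zero-filled bins and the gene is flagged truncated.

    Returns ``(matrix, mean_profile, truncated_mask)`` where ``matrix`` is
    genes x bins and ``mean_profile`` its column mean.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    mat = np.zeros((len(genes), n_bins), dtype=float)
    truncated = np.zeros(len(genes), dtype=bool)
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in signal_positions.items()}
    for i, g in enumerate(genes):
        pos = sorted_pos.get(g.chrom)
        tss = g.tss
        # reverse-strand windows shift by one base so that, after the
        # orientation flip, a signal d bases downstream of the TSS lands
        # in the same oriented bin on either strand
        win_start = tss - flank if g.strand == "+" else tss - flank + 1
        if win_start < 0:
            truncated[i] = True
        if pos is None or len(pos) == 0:
            continue
        edges = win_start + bin_size * np.arange(n_bins + 1)
        idx = np.searchsorted(pos, edges)
        row = np.diff(idx).astype(float)
        if g.strand == "-":
            row = row[::-1]
        mat[i] = row
    return mat, mat.mean(axis=0), truncated


_CONSENSUS_COLS = ["peak_id", "chrom", "start", "end", "summit"]


def write_consensus_tsv(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    """Write consensus peaks as TSV with one FoldEnrich column per sample."""
    samples = sorted({s for p in peaks for s in p.fold_enrich})
    rows = []
    for p in peaks:
        row = {
            "peak_id": p.peak_id, "chrom": p.chrom, "start": p.start,
            "end": p.end, "summit": p.summit if p.summit is not None else -1,
        }
        for s in samples:
            row[f"FE_{s}"] = p.fold_enrich.get(s, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=_CONSENSUS_COLS + [f"FE_{s}" for s in samples]).to_csv(
        path, sep="\t", index=False
    )


def read_consensus_tsv(path: str | Path) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t")
    samples = [c[3:] for c in df.columns if c.startswith("FE_")]
    peaks = []
    for _, r in df.iterrows():
        fe = {s: float(r[f"FE_{s}"]) for s in samples if pd.notna(r[f"FE_{s}"])}
        summit = None if int(r["summit"]) < 0 else int(r["summit"])
        peaks.append(
            PeakRecord(str(r["peak_id"]), str(r["chrom"]), int(r["start"]),
                       int(r["end"]), summit=summit, fold_enrich=fe)
        )
    return peaks
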