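"""Strand-aware gene models from GTF/GFF3 annotations.

All coordinates inside :mod:`moltseq` are 0-based, half-open
(``[start, end)``), the BED convention.  GTF/GFF3 files use 1-based closed
coordinates and are converted on read and write.  Each gene is represented
by a single :class:`GeneModel`; when an annotation carries several
transcripts per gene, their exons are collapsed to the union, since the
downstream analysis (peak assignment, counting, FPKM) operates at gene
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "GeneModel",
    "PromoterRegion",
    "read_annotation",
    "write_gff3",
    "read_chrom_sizes",
    "tss_of",
    "tts_of",
    "promoter_of",
]

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class GeneModel:
    """A gene as a strand-aware interval with its exon structure.

    ``start``/``end`` delimit the transcribed unit (TSS to TTS, including
    introns); ``exons`` are non-overlapping sorted sub-intervals whose
    total width (``exonic_length``) is the exon-model length used for
    FPKM.  ``utr5``/``utr3`` are kept only when the annotation provides
    them.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start must be < end ({self.start}, {self.end})"
            )
        if not self.exons:
            # Genes annotated without exon records span their whole body.
            self.exons = [(self.start, self.end)]
        self.exons = _merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene body"
                )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        return tss_of(self)

    @property
    def tts(self) -> int:
        return tts_of(self)


@dataclass(frozen=True)
class PromoterRegion:
    """Symmetric window around a gene's TSS, clipped to the chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int


def tss_of(gene: GeneModel) -> int:
    """Transcription start site in internal coordinates.

    The TSS is the 5'-most transcribed base: ``start`` on the forward
    strand and ``end - 1`` on the reverse strand.
    """
    return gene.start if gene.strand == "+" else gene.end - 1


def tts_of(gene: GeneModel) -> int:
    """Transcription termination site (3'-most transcribed base)."""
    return gene.end - 1 if gene.strand == "+" else gene.start


def promoter_of(
    gene: GeneModel, flank: int = 2000, chrom_size: int | None = None
) -> PromoterRegion:
    """Promoter window ``[tss - flank, tss + flank + 1)``.

    The window is symmetric in genomic coordinates and always contains the
    TSS; it is clipped at position 0 and, when a chromosome size is known,
    at the chromosome end.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    tss = tss_of(gene)
    start = max(0, tss - flank)
    end = tss + flank + 1
    if chrom_size is not None:
        end = min(end, chrom_size)
    return PromoterRegion(gene.gene_id, gene.chrom, start, end)


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise AnnotationError(f"empty interval [{s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` sizes file."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        sizes[parts[0]] = int(parts[1])
    return sizes


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}


def _gene_id_of(feature: gffutils.Feature) -> str | None:
    for key in ("gene_id", "geneID", "ID"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def read_annotation(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Parse a GTF or GFF3 annotation into gene-level models.

    Features of type ``gene`` define gene bodies; ``exon`` and UTR
    features are attached to their gene through the ``gene_id`` attribute
    or, failing that, the ``Parent`` chain.  Multiple transcripts collapse
    to the union of their exons.  Genes without exon records get a single
    exon spanning the gene body.  Records missing a strand are rejected
    with a warning.

    Returns the models sorted by ``(chrom, start, gene_id)``.
    """
    if format not in ("gtf", "gff3"):
        raise ValueError(f"format must be 'gtf' or 'gff3', got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_transcripts=True,
            disable_infer_genes=True,
        )
    except Exception as exc:  # gffutils wraps line-level failures
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    raw: dict[str, dict] = {}
    n_rejected = 0
    for g in db.features_of_type("gene"):
        gid = _gene_id_of(g)
        if gid is None:
            n_rejected += 1
            continue
        if g.strand not in ("+", "-"):
            warnings.warn(f"gene {gid}: missing strand, record rejected")
            n_rejected += 1
            continue
        raw[gid] = {
            "chrom": g.seqid,
            "strand": g.strand,
            "start": g.start - 1,  # 1-based closed -> 0-based half-open
            "end": g.end,
            "exons": [],
            "utr5": [],
            "utr3": [],
        }

    def _resolve_gene(feature: gffutils.Feature) -> str | None:
        gid = _gene_id_of(feature)
        if gid in raw:
            return gid
        # walk up Parent links (exon -> mRNA -> gene)
        seen = set()
        current = feature
        while "Parent" in current.attributes:
            pid = current.attributes["Parent"][0]
            if pid in raw:
                return pid
            if pid in seen:
                return None
            seen.add(pid)
            try:
                current = db[pid]
            except gffutils.FeatureNotFoundError:
                return None
        return None

    for ftype, slot in (("exon", "exons"), *[(t, "utr5") for t in _UTR5_TYPES],
                        *[(t, "utr3") for t in _UTR3_TYPES]):
        for f in db.features_of_type(ftype):
            gid = _resolve_gene(f)
            if gid is None:
                n_rejected += 1
                continue
            raw[gid][slot].append((f.start - 1, f.end))

    if n_rejected:
        warnings.warn(f"{path.name}: {n_rejected} annotation record(s) could not be used")

    for gid, d in raw.items():
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=d["chrom"],
            strand=d["strand"],
            start=d["start"],
            end=d["end"],
            exons=d["exons"],
            utr5=_merge_intervals(d["utr5"]) if d["utr5"] else [],
            utr3=_merge_intervals(d["utr3"]) if d["utr3"] else [],
        )
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (converting back to 1-based closed)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        lines.append(
            "\t".join(
                [g.chrom, "moltseq", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id};gene_id={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                "\t".join(
                    [g.chrom, "moltseq", "exon", str(s + 1), str(e), ".", g.strand,
                     ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id};gene_id={g.gene_id}"]
                )
            )
        for name, ivs in (("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
            for i, (s, e) in enumerate(ivs, 1):
                lines.append(
                    "\t".join(
                        [g.chrom, "moltseq", name, str(s + 1), str(e), ".", g.strand,
                         ".", f"ID={g.gene_id}.{name}{i};Parent={g.gene_id};gene_id={g.gene_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")
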