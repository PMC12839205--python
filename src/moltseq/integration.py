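"""DEP-to-gene assignment and IDEG calling.

A differentially enriched peak is linked to one gene by a hierarchical
rule: a peak whose interval overlaps one or more promoter windows is
assigned to the overlapped gene whose TSS is closest to the peak anchor
(summit if called, else midpoint); a peak overlapping no promoter is
assigned to the gene with the nearest TSS on its chromosome, regardless
of distance.  Genes that are both differentially expressed and linked to
at least one DEP in the same stage comparison are the integrated
differentially expressed genes (IDEGs), classified up/down by their
RNA-seq fold-change sign.  No concordance between peak and expression
direction is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, PromoterRegion
from .peaks import PeakRecord

__all__ = ["IdegRecord", "GeneLocator", "map_dep_to_gene", "map_deps", "call_idegs",
           "write_ideg_table", "ideg_summary"]


@dataclass(frozen=True)
class IdegRecord:
    gene_id: str
    stage_pair: str
    rna_log2fc: float
    direction: str  # "up" | "down"
    linked_peak_ids: tuple[str, ...]
    mapping_modes: tuple[str, ...]  # parallel to linked_peak_ids


class GeneLocator:
    """Per-chromosome promoter index and sorted TSS arrays for assignment."""

    def __init__(self, genes: Sequence[GeneModel], promoters: Sequence[PromoterRegion]):
        by_gene = {p.gene_id: p for p in promoters}
        self.prom_trees: dict[str, IntervalTree] = {}
        self.tss: dict[str, np.ndarray] = {}
        self.tss_gene_ids: dict[str, list[str]] = {}
        tss_lists: dict[str, list[tuple[int, str]]] = {}
        self.gene_tss: dict[str, int] = {}
        for g in genes:
            self.gene_tss[g.gene_id] = g.tss
            prom = by_gene.get(g.gene_id)
            if prom is not None and prom.end > prom.start:
                self.prom_trees.setdefault(g.chrom, IntervalTree()).addi(
                    prom.start, prom.end, g.gene_id
                )
            tss_lists.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        for chrom, lst in tss_lists.items():
            lst.sort()
            self.tss[chrom] = np.array([t for t, _ in lst])
            self.tss_gene_ids[chrom] = [gid for _, gid in lst]


def map_dep_to_gene(
    peak: PeakRecord, locator: GeneLocator
) -> tuple[str, str] | None:
    """Assign a peak to ``(gene_id, mapping_mode)`` by the hierarchical rule.

    Mode is ``promoter_overlap`` when the full peak interval overlaps a
    promoter window (closest-TSS gene among the overlapped, ties broken by
    lexicographically smallest gene id), else ``nearest_tss``.  Returns
    None when the peak's chromosome carries no gene.
    """
    anchor = peak.anchor
    tree = locator.prom_trees.get(peak.chrom)
    if tree is not None:
        hits = tree.overlap(peak.start, peak.end)
        if hits:
            best = min(
                (abs(anchor - locator.gene_tss[iv.data]), iv.data) for iv in hits
            )
            return best[1], "promoter_overlap"
    tss = locator.tss.get(peak.chrom)
    if tss is None or len(tss) == 0:
        return None
    dist = np.abs(tss - anchor)
    candidates = np.flatnonzero(dist == dist.min())
    gids = [locator.tss_gene_ids[peak.chrom][i] for i in candidates]
    return min(gids), "nearest_tss"


def map_deps(
    peaks: Sequence[PeakRecord], locator: GeneLocator
) -> tuple[dict[str, tuple[str, str]], list[str]]:
    """Map each peak; returns ``(peak_id -> (gene_id, mode), unmapped_ids)``."""
    mapping: dict[str, tuple[str, str]] = {}
    unmapped: list[str] = []
    for p in peaks:
        res = map_dep_to_gene(p, locator)
        if res is None:
            unmapped.append(p.peak_id)
        else:
            mapping[p.peak_id] = res
    return mapping, unmapped


def call_idegs(
    deg_table: pd.DataFrame,
    dep_table: pd.DataFrame,
    dep_gene_map: Mapping[str, tuple[str, str]],
    stage_pair: str,
) -> list[IdegRecord]:
    """Intersect DEGs with DEP-linked genes.

    The IDEG set is the genes significant in ``deg_table`` that are the
    assigned gene of at least one significant peak in ``dep_table``.  Each
    IDEG carries every linked peak and is classified up when its RNA-seq
    log2 fold change is positive, down otherwise.  No peak-direction
    filter is applied, so the result is invariant to DEP fold-change signs.
    """
    sig_peaks = dep_table.loc[dep_table["significant"], "feature_id"]
    gene_links: dict[str, list[tuple[str, str]]] = {}
    for pid in sig_peaks:
        if pid in dep_gene_map:
            gid, mode = dep_gene_map[pid]
            gene_links.setdefault(gid, []).append((pid, mode))

    sig_degs = deg_table.loc[deg_table["significant"]]
    records: list[IdegRecord] = []
    for _, row in sig_degs.iterrows():
        gid = row["feature_id"]
        if gid not in gene_links:
            continue
        peaks, modes = zip(*gene_links[gid])
        lfc = float(row["log2fc"])
        records.append(
            IdegRecord(
                gene_id=gid,
                stage_pair=stage_pair,
                rna_log2fc=lfc,
                direction="up" if lfc > 0 else "down",
                linked_peak_ids=tuple(peaks),
                mapping_modes=tuple(modes),
            )
        )
    records.sort(key=lambda r: r.gene_id)
    return records


def ideg_summary(records: Sequence[IdegRecord], stage_pair: str) -> dict[str, int]:
    up = sum(1 for r in records if r.direction == "up")
    down = sum(1 for r in records if r.direction == "down")
    return {"stage_pair": stage_pair, "total": up + down, "up": up, "down": down}


def write_ideg_table(records: Sequence[IdegRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "stage_pair": r.stage_pair,
            "rna_log2fc": r.rna_log2fc,
            "direction": r.direction,
            "mapping_mode": ";".join(r.mapping_modes),
            "linked_peak_ids": ";".join(r.linked_peak_ids),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "stage_pair", "rna_log2fc", "direction",
                 "mapping_mode", "linked_peak_ids"],
    ).to_csv(path, sep="\t", index=False)
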