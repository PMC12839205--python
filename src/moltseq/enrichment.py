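"""GO over-representation of IDEG sets and signaling-pathway extraction.

The test is the one-sided hypergeometric upper tail: with ``N`` annotated
population genes, ``K`` of them carrying a term, and ``n`` study genes of
which ``k`` carry the term, ``p = P[X >= k]`` for
``X ~ Hypergeom(N, K, n)``.  Adjustment is Benjamini-Hochberg within each
GO namespace (BP/CC/MF).  Signaling pathways are the biological-process
terms whose name contains "signaling pathway"; they are reported with
their study-gene membership, ordered by gene count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diffstats import benjamini_hochberg

__all__ = [
    "GoAnnotationMap",
    "EnrichmentResult",
    "read_gene2term",
    "read_term_meta",
    "go_overrepresentation",
    "extract_signaling_pathways",
    "write_enrichment_tsv",
]

NAMESPACES = ("BP", "CC", "MF")


@dataclass
class GoAnnotationMap:
    """Gene -> GO term sets plus term metadata (name, namespace)."""

    gene2terms: dict[str, set[str]]
    term_meta: dict[str, tuple[str, str]]  # term_id -> (name, namespace)

    def __post_init__(self) -> None:
        for gid, terms in self.gene2terms.items():
            if not terms:
                raise ValueError(f"gene {gid} has an empty term set")
            for t in terms:
                if t not in self.term_meta:
                    raise ValueError(f"term {t} (gene {gid}) missing from metadata")

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.gene2terms)

    def genes_with_term(self, term_id: str) -> set[str]:
        return {g for g, ts in self.gene2terms.items() if term_id in ts}


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    namespace: str
    k: int  # study hits
    n: int  # study size
    K: int  # population hits
    N: int  # population size
    pvalue: float
    padj: float
    member_genes: tuple[str, ...]


def read_gene2term(path: str | Path) -> dict[str, set[str]]:
    """Two-column ``gene_id<TAB>term_id`` map, multiple rows per gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    g2t: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        g2t.setdefault(gene, set()).add(term)
    return g2t


def read_term_meta(path: str | Path) -> dict[str, tuple[str, str]]:
    """``term_id<TAB>name<TAB>namespace`` metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = {}
    for tid, name, ns in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        if ns not in NAMESPACES:
            raise ValueError(f"term {tid}: namespace must be one of {NAMESPACES}")
        meta[tid] = (name, ns)
    return meta


def go_overrepresentation(
    study_genes: Iterable[str],
    annotation: GoAnnotationMap,
    population_genes: Iterable[str] | None = None,
    min_hits: int = 1,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per GO term.

    The population defaults to every annotated gene; an explicit
    population (e.g. all expressed genes) is intersected with the
    annotated set.  Study genes without any annotation still count toward
    the study size ``n`` but can never be term hits, so adding one can
    only weaken every term's enrichment.  BH adjustment runs separately
    within each namespace; results are sorted by p-value.
    """
    population = (
        annotation.annotated_genes
        if population_genes is None
        else set(population_genes) & annotation.annotated_genes
    )
    study_all = set(study_genes)
    study = study_all & population
    if not study:
        raise ValueError("study set is empty (after restriction to the population)")
    N = len(population)
    n = len(study) + len(study_all - annotation.annotated_genes)
    if n > N:
        raise ValueError("study size exceeds the annotated population")

    term_pop: dict[str, set[str]] = {}
    term_study: dict[str, set[str]] = {}
    for gene in population:
        for t in annotation.gene2terms.get(gene, ()):
            term_pop.setdefault(t, set()).add(gene)
            if gene in study:
                term_study.setdefault(t, set()).add(gene)

    results: list[EnrichmentResult] = []
    for term, members in sorted(term_study.items()):
        k = len(members)
        if k < min_hits:
            continue
        K = len(term_pop[term])
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        name, ns = annotation.term_meta[term]
        results.append(
            EnrichmentResult(term, name, ns, k, n, K, N, min(p, 1.0), float("nan"),
                             tuple(sorted(members)))
        )

    for ns in NAMESPACES:
        idx = [i for i, r in enumerate(results) if r.namespace == ns]
        if idx:
            adj = benjamini_hochberg([results[i].pvalue for i in idx])
            for i, a in zip(idx, adj):
                results[i].padj = float(a)
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    return results


def extract_signaling_pathways(
    results: Sequence[EnrichmentResult],
    pattern: str = "signaling pathway",
) -> list[tuple[EnrichmentResult, int, tuple[str, ...]]]:
    """Biological-process terms whose name matches ``pattern``.

    Matching is case-insensitive substring; each entry carries the study
    gene count (``k``) and the member genes.  Ordered by gene count
    descending, then p-value.
    """
    pat = pattern.lower()
    hits = [r for r in results if r.namespace == "BP" and pat in r.name.lower()]
    hits.sort(key=lambda r: (-r.k, r.pvalue, r.term_id))
    return [(r, r.k, r.member_genes) for r in hits]


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "term_id": r.term_id, "name": r.name, "namespace": r.namespace,
            "k": r.k, "n": r.n, "K": r.K, "N": r.N,
            "pvalue": r.pvalue, "padj": r.padj,
            "member_genes": ";".join(r.member_genes),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["term_id", "name", "namespace", "k", "n", "K", "N",
                 "pvalue", "padj", "member_genes"],
    ).to_csv(path, sep="\t", index=False)
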