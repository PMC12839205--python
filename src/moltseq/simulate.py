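"""Synthetic study generator with planted, returned ground truth.

Emulates the downstream products of a four-stage molting-cycle design
(inter-molt C, pre-molt D, molt E, post-molt A; three biological
replicates per stage) so the whole pipeline can be exercised without
sequencing data:

* a gene annotation with strands and exon structure (GFF3),
* per-replicate ATAC peak calls with lognormal FoldEnrich noise,
  promoter-anchored peaks carrying planted accessibility shifts,
* a negative-binomial count matrix with planted expression shifts,
* a GO annotation in which one biological-process "signaling pathway"
  term is preferentially assigned to planted integrated genes,
* per-tool transmembrane-helix tables with planted 7-TMH receptors, and
* Ct tables consistent with the planted expression fold changes.

Effects are planted on disjoint gene sets per adjacent stage comparison;
the returned :class:`GroundTruth` is derived from the underlying stage
mean matrices, so genes whose planted shift spills into a neighbouring
comparison are accounted for.  Every quantity is drawn from
`numpy.random.default_rng` streams seeded from ``config.seed``, so a
fixed configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, promoter_of, write_gff3
from .integration import GeneLocator, map_dep_to_gene
from .peaks import PeakRecord
from .receptors import GPCR_ACTIVITY_TERM

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "generate_genome",
    "generate_accessibility",
    "generate_expression",
    "generate_go_and_structures",
    "generate_ct",
    "simulate_study",
    "write_study",
]

TOOLS = ("TMHMM", "PSIPRED", "SWISS-MODEL")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs; the defaults are the conditions the pipeline
    is validated under (four stages x three replicates, log2 effect 3,
    lognormal FoldEnrich noise sigma 0.2, NB dispersion 0.05)."""

    seed: int = 0
    n_chroms: int = 5
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (2000, 8000)
    intergenic_gap_range: tuple[int, int] = (6000, 14000)
    conditions: tuple[str, ...] = ("C", "D", "E", "A")
    replicates: int = 3
    # planted effect structure (fractions of n_genes, disjoint gene sets)
    planted_ideg_fraction: float = 0.02   # both DEP- and DEG-planted
    planted_dep_fraction: float = 0.03    # accessibility shift only
    planted_deg_fraction: float = 0.03    # expression shift only
    dep_effect_log2: float = 3.0          # delta
    deg_effect_log2: float = 3.0          # beta
    fe_noise_sigma: float = 0.2           # sd of log FoldEnrich
    nb_dispersion: float = 0.05
    # accessibility landscape
    promoter_peak_fraction: float = 0.8
    background_peak_fraction: float = 0.3
    peak_width: int = 400
    peak_jitter: int = 30
    fe_base_log_mean: float = float(np.log(5.0))
    fe_base_log_sd: float = 0.5
    # expression landscape
    expr_base_log_mean: float = float(np.log(200.0))
    expr_base_log_sd: float = 0.8
    library_size_jitter: float = 0.2
    # GO landscape
    n_go_terms: int = 300
    terms_per_gene_lambda: float = 4.0
    planted_term_size: int = 25
    planted_term_ideg_hits: int = 12
    planted_term_comparison: str = "D_vs_E"
    # receptors
    n_gpcr_planted: int = 5
    n_gpcr_activity_decoys: int = 2
    tool_noise_prob: float = 0.0
    # qPCR
    ct_sigma: float = 0.2
    ct_intercept: float = 30.0
    ct_reference_level: float = 16.0

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        c = self.conditions
        return [(c[i], c[(i + 1) % len(c)]) for i in range(len(c))]

    @property
    def samples(self) -> list[str]:
        return [f"Mu_{c}_{r + 1}" for c in self.conditions
                for r in range(self.replicates)]

    @property
    def sample_conditions(self) -> dict[str, str]:
        return {s: s.split("_")[1] for s in self.samples}

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


@dataclass
class GroundTruth:
    """Planted truth, derived from the underlying stage mean matrices."""

    true_dep_peaks: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    true_deg_genes: dict[str, dict[str, int]] = field(default_factory=dict)
    true_ideg_genes: dict[str, list[str]] = field(default_factory=dict)
    true_enriched_terms: list[str] = field(default_factory=list)
    true_gpcr_proteins: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    per_sample_peaks: dict[str, list[PeakRecord]]
    counts: pd.DataFrame
    library_sizes: pd.Series
    gene2terms: dict[str, set[str]]
    term_meta: dict[str, tuple[str, str]]
    tm_table: pd.DataFrame
    ct_table: pd.DataFrame
    truth: GroundTruth


def generate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping genes with 1-5 exons on ``n_chroms`` chromosomes."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = config._rng(1)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    gid = 0
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 0
        for _ in range(n):
            cursor += int(rng.integers(*config.intergenic_gap_range))
            length = int(rng.integers(*config.gene_length_range))
            start, end = cursor, cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 6))
            if n_exons == 1:
                exons = [(start, end)]
            else:
                cuts = np.sort(rng.choice(
                    np.arange(1, length), size=2 * (n_exons - 1), replace=False))
                bounds = [0, *cuts.tolist(), length]
                exons = [(start + bounds[2 * k], start + bounds[2 * k + 1])
                         for k in range(n_exons)]
            gid += 1
            genes.append(GeneModel(f"g{gid:05d}", chrom, strand, start, end, exons))
            cursor = end
        chrom_sizes[chrom] = cursor + int(rng.integers(*config.intergenic_gap_range))
    return genes, chrom_sizes


@dataclass
class _PlantingPlan:
    """Disjoint planted gene sets per comparison label."""

    ideg: dict[str, list[str]]
    dep_only: dict[str, list[str]]
    deg_only: dict[str, list[str]]
    deg_signs: dict[str, dict[str, int]]  # comparison -> gene -> +-1


def _plan_planting(config: SimulationConfig, genes: list[GeneModel]) -> _PlantingPlan:
    rng = config._rng(2)
    n = config.n_genes
    n_ideg = int(round(config.planted_ideg_fraction * n))
    n_dep = int(round(config.planted_dep_fraction * n))
    n_deg = int(round(config.planted_deg_fraction * n))
    labels = [_label(p) for p in config.comparisons]
    need = len(labels) * (n_ideg + n_dep + n_deg)
    if need > n:
        raise ValueError("planted fractions exceed the gene count")
    perm = rng.permutation([g.gene_id for g in genes])
    pos = 0
    plan = _PlantingPlan({}, {}, {}, {})
    for lab in labels:
        plan.ideg[lab] = sorted(perm[pos:pos + n_ideg]); pos += n_ideg
        plan.dep_only[lab] = sorted(perm[pos:pos + n_dep]); pos += n_dep
        plan.deg_only[lab] = sorted(perm[pos:pos + n_deg]); pos += n_deg
        signs = rng.choice([-1, 1], size=n_ideg + n_deg)
        plan.deg_signs[lab] = {
            g: int(s) for g, s in zip(plan.ideg[lab] + plan.deg_only[lab], signs)
        }
    return plan


def generate_accessibility(
    config: SimulationConfig,
    genes: list[GeneModel],
    plan: _PlantingPlan,
) -> tuple[dict[str, list[PeakRecord]], dict[str, list[tuple[str, int, int]]]]:
    """Per-sample peak calls plus the true differential peak intervals.

    Promoter-anchored peaks cover the planted genes (always) and a
    ``promoter_peak_fraction`` of the rest; intergenic background peaks
    are non-differential.  Replicate FoldEnrich is lognormal around the
    stage mean; planted peaks have the later stage's mean multiplied by
    ``2**dep_effect_log2``.  Peak boundaries jitter per sample to
    exercise consensus merging.
    """
    rng = config._rng(3)
    by_id = {g.gene_id: g for g in genes}
    planted_genes = {g for lab in plan.ideg for g in plan.ideg[lab]}
    planted_genes |= {g for lab in plan.dep_only for g in plan.dep_only[lab]}
    gene_to_comparison: dict[str, str] = {}
    for lab in plan.ideg:
        for g in plan.ideg[lab] + plan.dep_only[lab]:
            gene_to_comparison[g] = lab

    peaks: list[dict] = []  # peak prototypes
    for g in genes:
        has_peak = g.gene_id in planted_genes or rng.random() < config.promoter_peak_fraction
        if not has_peak:
            continue
        center = g.tss + int(rng.integers(-200, 201))
        half = config.peak_width // 2
        start = max(0, center - half)
        peaks.append({
            "chrom": g.chrom, "start": start, "end": start + config.peak_width,
            "comparison": gene_to_comparison.get(g.gene_id),
        })
    n_bg = int(round(config.background_peak_fraction * config.n_genes))
    chroms = sorted({g.chrom for g in genes})
    max_pos = {c: max(g.end for g in genes if g.chrom == c) for c in chroms}
    for _ in range(n_bg):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos[chrom]))
        peaks.append({"chrom": chrom, "start": start,
                      "end": start + config.peak_width, "comparison": None})

    conditions = list(config.conditions)
    n_peaks = len(peaks)
    base = np.exp(rng.normal(config.fe_base_log_mean, config.fe_base_log_sd, n_peaks))
    mean = np.tile(base[:, None], (1, len(conditions)))
    labels = [_label(p) for p in config.comparisons]
    later_stage = {_label(p): p[1] for p in config.comparisons}
    for i, p in enumerate(peaks):
        lab = p["comparison"]
        if lab is not None:
            j = conditions.index(later_stage[lab])
            mean[i, j] *= 2.0 ** config.dep_effect_log2

    per_sample: dict[str, list[PeakRecord]] = {s: [] for s in config.samples}
    cond_of = config.sample_conditions
    for i, p in enumerate(peaks):
        for s in config.samples:
            j = conditions.index(cond_of[s])
            fe = float(mean[i, j] * np.exp(rng.normal(0.0, config.fe_noise_sigma)))
            ds = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            de = int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
            start = max(0, p["start"] + ds)
            end = max(start + 1, p["end"] + de)
            summit = min(max((p["start"] + p["end"]) // 2, start), end - 1)
            per_sample[s].append(
                PeakRecord(f"{s}_peak_{i + 1}", p["chrom"], start, end,
                           summit=summit, fold_enrich={s: round(fe, 5)})
            )

    # truth from the stage mean matrix: any >= 2-fold stage-to-stage shift
    true_deps: dict[str, list[tuple[str, int, int]]] = {lab: [] for lab in labels}
    for lab, (a, b) in zip(labels, config.comparisons):
        ja, jb = conditions.index(a), conditions.index(b)
        lfc = np.log2(mean[:, jb] / mean[:, ja])
        for i in np.flatnonzero(np.abs(lfc) >= 1.0):
            p = peaks[i]
            true_deps[lab].append((p["chrom"], p["start"], p["end"]))
    return per_sample, true_deps


def generate_expression(
    config: SimulationConfig,
    genes: list[GeneModel],
    plan: _PlantingPlan,
) -> tuple[pd.DataFrame, pd.Series, dict[str, dict[str, int]], np.ndarray]:
    """NB count matrix, library sizes, true DEG signs and stage means.

    Gene base means are lognormal; planted genes have the later stage's
    mean multiplied by ``2**(sign * deg_effect_log2)``; counts are
    negative binomial with the configured dispersion after +-20% library
    size factors.
    """
    rng = config._rng(4)
    gene_ids = [g.gene_id for g in genes]
    idx = {g: i for i, g in enumerate(gene_ids)}
    conditions = list(config.conditions)
    base = np.exp(rng.normal(config.expr_base_log_mean, config.expr_base_log_sd,
                             len(gene_ids)))
    mean = np.tile(base[:, None], (1, len(conditions)))
    later_stage = {_label(p): p[1] for p in config.comparisons}
    for lab in (_label(p) for p in config.comparisons):
        j = conditions.index(later_stage[lab])
        for g, s in plan.deg_signs[lab].items():
            mean[idx[g], j] *= 2.0 ** (s * config.deg_effect_log2)

    jit = config.library_size_jitter
    sf = rng.uniform(1.0 - jit, 1.0 + jit, len(config.samples))
    cond_of = config.sample_conditions
    alpha = config.nb_dispersion
    cols = {}
    for s, f in zip(config.samples, sf):
        mu = mean[:, conditions.index(cond_of[s])] * f
        if alpha > 0:
            r = 1.0 / alpha
            cols[s] = rng.negative_binomial(r, r / (r + mu))
        else:
            cols[s] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    library_sizes = counts.sum(axis=0)

    true_degs: dict[str, dict[str, int]] = {}
    for lab, (a, b) in zip((_label(p) for p in config.comparisons), config.comparisons):
        ja, jb = conditions.index(a), conditions.index(b)
        lfc = np.log2(mean[:, jb] / mean[:, ja])
        hits = np.flatnonzero(np.abs(lfc) >= 1.0)
        true_degs[lab] = {gene_ids[i]: int(np.sign(lfc[i])) for i in hits}
    return counts, library_sizes, true_degs, mean


def _true_idegs(
    config: SimulationConfig,
    genes: list[GeneModel],
    true_deps: dict[str, list[tuple[str, int, int]]],
    true_degs: dict[str, dict[str, int]],
) -> dict[str, list[str]]:
    """True IDEGs = truly differential genes linked from truly differential
    peaks under the same hierarchical mapping rule the pipeline uses."""
    promoters = [promoter_of(g) for g in genes]
    locator = GeneLocator(genes, promoters)
    out: dict[str, list[str]] = {}
    for lab, intervals in true_deps.items():
        linked: set[str] = set()
        for i, (chrom, start, end) in enumerate(intervals):
            peak = PeakRecord(f"true_{i}", chrom, start, end,
                              summit=(start + end) // 2)
            res = map_dep_to_gene(peak, locator)
            if res is not None:
                linked.add(res[0])
        out[lab] = sorted(linked & set(true_degs[lab]))
    return out


def generate_go_and_structures(
    config: SimulationConfig,
    genes: list[GeneModel],
    true_idegs: dict[str, list[str]],
) -> tuple[dict[str, set[str]], dict[str, tuple[str, str]], pd.DataFrame, list[str]]:
    """GO annotation with a planted signaling-pathway term, plus TMH tables.

    One BP term ("G protein-coupled receptor signaling pathway") is
    preferentially assigned to true IDEGs of ``planted_term_comparison``.
    Its IDEG members split into planted GPCRs (GO:0004930 plus 7-TMH
    consensus counts) and activity decoys (GO:0004930 but per-tool counts
    drawn from {0..6, 8..12}, so no decoy can ever reach two tools at 7).
    """
    rng = config._rng(5)
    gene_ids = [g.gene_id for g in genes]
    term_meta: dict[str, tuple[str, str]] = {}
    ns_draw = rng.choice(["BP", "CC", "MF"], size=config.n_go_terms, p=[0.6, 0.2, 0.2])
    term_ids = []
    for i in range(config.n_go_terms):
        tid = f"GO:SIM{i + 1:04d}"
        term_ids.append(tid)
        term_meta[tid] = (f"simulated process {i + 1}", str(ns_draw[i]))

    gene2terms: dict[str, set[str]] = {}
    n_terms = rng.poisson(config.terms_per_gene_lambda, len(gene_ids))
    for g, k in zip(gene_ids, n_terms):
        if k == 0:
            continue
        k = min(int(k), config.n_go_terms)
        picks = rng.choice(config.n_go_terms, size=k, replace=False)
        gene2terms[g] = {term_ids[i] for i in picks}

    # planted signaling-pathway term
    planted_term = "GO:0007186"
    term_meta[planted_term] = ("G protein-coupled receptor signaling pathway", "BP")
    ideg_pool = true_idegs.get(config.planted_term_comparison, [])
    n_hits = min(config.planted_term_ideg_hits, len(ideg_pool))
    hit_genes = sorted(rng.choice(ideg_pool, size=n_hits, replace=False).tolist())
    others = sorted(set(gene_ids) - set(ideg_pool))
    n_fill = max(config.planted_term_size - n_hits, 0)
    fill = rng.choice(others, size=min(n_fill, len(others)), replace=False).tolist()
    for g in hit_genes + list(fill):
        gene2terms.setdefault(g, set()).add(planted_term)

    # a weaker decoy signaling term for the extraction ordering
    decoy_term = "GO:0007166"
    term_meta[decoy_term] = ("cell surface receptor signaling pathway", "BP")
    decoy_members = rng.choice(gene_ids, size=config.planted_term_size, replace=False)
    for g in decoy_members:
        gene2terms.setdefault(g, set()).add(decoy_term)

    # structures: planted GPCRs among the planted term's IDEG members
    n_gpcr = min(config.n_gpcr_planted, len(hit_genes))
    gpcr_genes = hit_genes[:n_gpcr]
    decoy_pool = hit_genes[n_gpcr:]
    activity_decoys = decoy_pool[:config.n_gpcr_activity_decoys]
    for g in gpcr_genes + activity_decoys:
        gene2terms.setdefault(g, set()).add(GPCR_ACTIVITY_TERM)

    non7 = np.array([0, 1, 2, 3, 4, 5, 6, 8, 9, 10, 11, 12])
    rows = []
    for g in gpcr_genes:
        counts = [7, 7, 7]
        if rng.random() < config.tool_noise_prob:
            t = int(rng.integers(len(TOOLS)))
            counts[t] += int(rng.choice([-1, 1]))
        for tool, c in zip(TOOLS, counts):
            rows.append({"protein_id": g, "tool": tool, "count": str(c)})
    for g in activity_decoys:
        for tool in TOOLS:
            rows.append({"protein_id": g, "tool": tool,
                         "count": str(int(rng.choice(non7)))})
    tm_table = pd.DataFrame(rows, columns=["protein_id", "tool", "count"])
    tm_table["raw_count"] = tm_table["count"].astype(int)
    tm_table["protomer_multiplicity"] = 1
    if GPCR_ACTIVITY_TERM not in term_meta:
        term_meta[GPCR_ACTIVITY_TERM] = ("G protein-coupled receptor activity", "MF")
    return gene2terms, term_meta, tm_table, gpcr_genes


def generate_ct(
    config: SimulationConfig,
    expr_means: np.ndarray,
    genes: list[GeneModel],
    target_genes: list[str],
) -> pd.DataFrame:
    """Ct table for the validated genes over the planted comparison's stages.

    ``Ct = intercept - log2(stage mean) + Normal(0, ct_sigma)`` per
    technical replicate; the reference gene sits at a constant level
    across conditions, so planted fold changes are recoverable by
    2^-ddCt.
    """
    rng = config._rng(6)
    conditions = list(config.conditions)
    a, b = config.planted_term_comparison.split("_vs_")
    idx = {g.gene_id: i for i, g in enumerate(genes)}
    rows = []
    for cond in (a, b):
        j = conditions.index(cond)
        for rep in range(1, config.replicates + 1):
            sample = f"q_{cond}_{rep}"
            for tech in range(1, 4):
                rows.append({
                    "sample_id": sample, "condition": cond, "gene": "beta-actin",
                    "replicate": tech,
                    "ct": round(config.ct_reference_level
                                + rng.normal(0.0, config.ct_sigma), 4),
                })
                for g in target_genes:
                    level = expr_means[idx[g], j]
                    rows.append({
                        "sample_id": sample, "condition": cond, "gene": g,
                        "replicate": tech,
                        "ct": round(config.ct_intercept - np.log2(level)
                                    + rng.normal(0.0, config.ct_sigma), 4),
                    })
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene",
                                       "replicate", "ct"])


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate every pipeline input plus the planted ground truth."""
    genes, chrom_sizes = generate_genome(config)
    plan = _plan_planting(config, genes)
    per_sample_peaks, true_deps = generate_accessibility(config, genes, plan)
    counts, library_sizes, true_degs, expr_means = generate_expression(
        config, genes, plan)
    true_idegs = _true_idegs(config, genes, true_deps, true_degs)
    gene2terms, term_meta, tm_table, gpcr_genes = generate_go_and_structures(
        config, genes, true_idegs)
    ct_table = generate_ct(config, expr_means, genes, gpcr_genes)
    truth = GroundTruth(
        true_dep_peaks=true_deps,
        true_deg_genes=true_degs,
        true_ideg_genes=true_idegs,
        true_enriched_terms=["GO:0007186"],
        true_gpcr_proteins=gpcr_genes,
    )
    return SimulatedStudy(config, genes, chrom_sizes, per_sample_peaks, counts,
                          library_sizes, gene2terms, term_meta, tm_table,
                          ct_table, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input in its standard text format.

    GFF3 annotation, chrom sizes, per-sample narrowPeak, count matrix and
    library sizes TSVs, gene2term and term metadata TSVs, TMH prediction
    TSV, Ct TSV, condition map and a truth JSON.  Returns the paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["annotation"] = out / "annotation.gff3"
    write_gff3(study.genes, paths["annotation"])
    paths["chrom_sizes"] = out / "chrom.sizes"
    paths["chrom_sizes"].write_text(
        "".join(f"{c}\t{s}\n" for c, s in sorted(study.chrom_sizes.items())))

    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for sample, peaks in study.per_sample_peaks.items():
        p = peak_dir / f"{sample}.narrowPeak"
        lines = []
        for pk in peaks:
            fe = pk.fold_enrich[sample]
            offset = pk.summit - pk.start if pk.summit is not None else -1
            lines.append("\t".join(map(str, [
                pk.chrom, pk.start, pk.end, pk.peak_id, 0, ".", fe, -1, -1, offset])))
        p.write_text("\n".join(lines) + "\n")
        paths[f"peaks/{sample}"] = p

    paths["counts"] = out / "counts.tsv"
    study.counts.to_csv(paths["counts"], sep="\t")
    paths["library_sizes"] = out / "library_sizes.tsv"
    study.library_sizes.rename("library_size").to_csv(paths["library_sizes"], sep="\t")
    paths["conditions"] = out / "conditions.tsv"
    pd.Series(study.config.sample_conditions, name="condition").rename_axis(
        "sample_id").to_csv(paths["conditions"], sep="\t")

    paths["gene2term"] = out / "gene2term.tsv"
    rows = [(g, t) for g in sorted(study.gene2terms)
            for t in sorted(study.gene2terms[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        paths["gene2term"], sep="\t", index=False)
    paths["term_meta"] = out / "term_meta.tsv"
    pd.DataFrame(
        [(t, n, ns) for t, (n, ns) in sorted(study.term_meta.items())],
        columns=["term_id", "name", "namespace"],
    ).to_csv(paths["term_meta"], sep="\t", index=False)

    paths["tm_predictions"] = out / "tm_predictions.tsv"
    study.tm_table[["protein_id", "tool", "count"]].to_csv(
        paths["tm_predictions"], sep="\t", index=False)
    paths["ct"] = out / "ct.tsv"
    study.ct_table.to_csv(paths["ct"], sep="\t", index=False)
    paths["truth"] = out / "truth.json"
    study.truth.to_json(paths["truth"])
    return paths
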