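"""End-to-end orchestration of the integrated ATAC + RNA analysis.

``run_all`` executes the stages in order — simulate (optional), consensus
peak building and functional annotation, differential peak and gene
calling per adjacent stage comparison, DEP-to-gene mapping and IDEG
intersection, GO/signaling-pathway enrichment, GPCR triage, and qPCR
validation — on a single configuration mapping, writing per-stage TSVs
and a machine-readable summary JSON into a run directory.

Input files follow the layout produced by :func:`moltseq.simulate.write_study`:
``annotation.gff3``, ``chrom.sizes``, ``peaks/<sample>.narrowPeak``,
``counts.tsv``, ``conditions.tsv``, ``gene2term.tsv``, ``term_meta.tsv``,
``tm_predictions.tsv`` and ``ct.tsv``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .annotation import promoter_of, read_annotation, read_chrom_sizes
from .diffstats import call_degs, call_deps, write_diff_table
from .enrichment import (GoAnnotationMap, extract_signaling_pathways,
                         go_overrepresentation, read_gene2term, read_term_meta,
                         write_enrichment_tsv)
from .integration import (GeneLocator, call_idegs, ideg_summary, map_deps,
                          write_ideg_table)
from .peaks import (GenomeRegions, merge_sample_peaks, read_narrowpeak,
                    region_distribution, write_consensus_tsv)
from .qpcr import read_ct_table, relative_expression, ttest_two_tailed
from .receptors import (classify_gpcr, filter_gpcr_candidates,
                        predictions_from_frame, read_tm_predictions,
                        write_gpcr_calls)
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger("moltseq")

DEFAULTS: dict[str, Any] = {
    "p_thresh": 0.05,
    "padj_thresh": 0.05,
    "lfc_thresh": 1.0,
    "promoter_flank": 2000,
    "downstream_extent": 3000,
    "prob_threshold": 0.5,
    "enrich_padj": 0.05,
    "signaling_pattern": "signaling pathway",
    "reference_gene": "beta-actin",
    "comparisons": ["C_vs_D", "D_vs_E", "E_vs_A", "A_vs_C"],
    "seed": 0,
}


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _validate(config: Mapping[str, Any]) -> dict[str, Any]:
    cfg = {**DEFAULTS, **dict(config)}
    for key in ("p_thresh", "padj_thresh", "lfc_thresh", "promoter_flank",
                "downstream_extent", "prob_threshold"):
        if cfg[key] < 0:
            raise ValueError(f"config {key} must be positive")
    if "input_dir" not in cfg or "output_dir" not in cfg:
        raise ValueError("config requires input_dir and output_dir")
    return cfg


def run_all(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run every stage; returns (and writes) the summary dictionary."""
    cfg = _validate(config)
    indir = Path(cfg["input_dir"])
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("moltseq %s | config hash %s | seed %s",
             __version__, _config_hash(cfg), cfg["seed"])

    try:
        if cfg.get("simulate"):
            sim_cfg = SimulationConfig(seed=int(cfg["seed"]),
                                       **cfg.get("simulate_options", {}))
            log.info("stage simulate -> %s", indir)
            write_study(simulate_study(sim_cfg), indir)

        summary: dict[str, Any] = {
            "version": __version__,
            "seed": cfg["seed"],
            "config_hash": _config_hash(cfg),
            "comparisons": {},
        }

        log.info("stage annotate-peaks")
        genes = read_annotation(indir / "annotation.gff3", "gff3")
        chrom_sizes = read_chrom_sizes(indir / "chrom.sizes")
        conditions = pd.read_csv(indir / "conditions.tsv", sep="\t",
                                 index_col=0)["condition"]
        per_sample = {
            s: read_narrowpeak(indir / "peaks" / f"{s}.narrowPeak", s)
            for s in conditions.index
        }
        consensus = merge_sample_peaks(per_sample, known_chroms=chrom_sizes)
        write_consensus_tsv(consensus, outdir / "consensus_peaks.tsv")
        regions = GenomeRegions(genes, cfg["promoter_flank"],
                                cfg["downstream_extent"], chrom_sizes)
        dist = region_distribution(consensus, regions)
        dist.rename_axis("region").to_csv(outdir / "region_distribution.tsv", sep="\t")
        summary["n_consensus_peaks"] = len(consensus)
        summary["region_distribution"] = dist["fraction"].round(6).to_dict()

        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
        promoters = [promoter_of(g, cfg["promoter_flank"],
                                 chrom_sizes.get(g.chrom)) for g in genes]
        locator = GeneLocator(genes, promoters)
        dep_map, unmapped = map_deps(consensus, locator)
        if unmapped:
            log.warning("%d peak(s) on chromosomes without genes", len(unmapped))

        annotation = GoAnnotationMap(read_gene2term(indir / "gene2term.tsv"),
                                     read_term_meta(indir / "term_meta.tsv"))
        signaling_genes: dict[str, set[str]] = {}

        for label in cfg["comparisons"]:
            cond_a, cond_b = label.split("_vs_")
            samples_a = sorted(conditions.index[conditions == cond_a])
            samples_b = sorted(conditions.index[conditions == cond_b])
            if not samples_a or not samples_b:
                raise ValueError(f"comparison {label}: unknown condition label")
            log.info("stage call-deps %s", label)
            dep = call_deps(consensus, samples_a, samples_b,
                            cfg["p_thresh"], cfg["lfc_thresh"])
            write_diff_table(dep, outdir / f"deps_{label}.tsv")
            log.info("stage call-degs %s", label)
            deg = call_degs(counts, samples_a, samples_b,
                            cfg["padj_thresh"], cfg["lfc_thresh"])
            write_diff_table(deg, outdir / f"degs_{label}.tsv")

            log.info("stage integrate %s", label)
            idegs = call_idegs(deg, dep, dep_map, label)
            write_ideg_table(idegs, outdir / f"idegs_{label}.tsv")
            comp_summary = {
                "n_dep": int(dep["significant"].sum()),
                "n_deg": int(deg["significant"].sum()),
                "ideg": ideg_summary(idegs, label),
            }

            log.info("stage enrich %s", label)
            study = [r.gene_id for r in idegs]
            pathways = []
            if study:
                try:
                    results = go_overrepresentation(study, annotation)
                except ValueError:
                    results = []
                if results:
                    write_enrichment_tsv(results, outdir / f"go_{label}.tsv")
                enriched = [r for r in results if r.padj <= cfg["enrich_padj"]]
                for res, count, members in extract_signaling_pathways(
                        enriched, cfg["signaling_pattern"]):
                    pathways.append({"term_id": res.term_id, "name": res.name,
                                     "gene_count": count, "padj": res.padj})
                    signaling_genes.setdefault(label, set()).update(members)
            comp_summary["signaling_pathways"] = pathways
            summary["comparisons"][label] = comp_summary

        log.info("stage triage-gpcr")
        tm_path = indir / "tm_predictions.tsv"
        gpcr_union: set[str] = set()
        per_comparison_gpcrs: dict[str, list[str]] = {}
        if tm_path.exists():
            tm = read_tm_predictions(tm_path)
            by_protein = predictions_from_frame(tm)
            calls = {}
            for label, members in sorted(signaling_genes.items()):
                candidates = filter_gpcr_candidates(sorted(members),
                                                    annotation.gene2terms)
                hits = []
                for gene in candidates:
                    if gene not in by_protein:
                        continue
                    call = classify_gpcr(by_protein[gene], cfg["prob_threshold"])
                    calls[gene] = call
                    if call.is_gpcr:
                        hits.append(gene)
                per_comparison_gpcrs[label] = hits
                gpcr_union.update(hits)
            write_gpcr_calls(calls.values(), outdir / "gpcr_calls.tsv")
        summary["gpcr"] = {
            "per_comparison": per_comparison_gpcrs,
            "union": sorted(gpcr_union),
            "n_union": len(gpcr_union),
        }

        log.info("stage qpcr")
        ct_path = indir / "ct.tsv"
        qpcr_results = []
        if ct_path.exists():
            ct = read_ct_table(ct_path)
            ref = cfg["reference_gene"]
            targets = sorted(set(ct["gene"]) - {ref})
            conds = list(dict.fromkeys(ct["condition"]))
            control = conds[0]
            for gene in targets:
                per_sample_fold, group = relative_expression(ct, gene, ref, control)
                by_cond = {
                    c: per_sample_fold.loc[per_sample_fold["condition"] == c,
                                           "delta_ct"].to_numpy()
                    for c in conds
                }
                for c in conds[1:]:
                    p = ttest_two_tailed(by_cond[control], by_cond[c])
                    fold = float(group.loc[group["condition"] == c,
                                           "mean_fold"].iloc[0])
                    qpcr_results.append({"gene": gene, "condition": c,
                                         "control": control,
                                         "fold": round(fold, 4),
                                         "pvalue": p})
            pd.DataFrame(qpcr_results).to_csv(outdir / "qpcr_results.tsv",
                                              sep="\t", index=False)
        summary["qpcr"] = qpcr_results

        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        log.info("run complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
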