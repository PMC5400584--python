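"""End-to-end orchestration: the machinery behind ``domainspot run-all``.

Order of operations: load (or simulate) inputs -> classify and
reference-validate mutations -> map to domains and MSA columns ->
per-class enrichment (cancer-gene mode against the background panel,
plus genome-wide mode) -> per-class, per-stratum hotspot detection ->
overlap and co-location analysis -> gene classification (20:20 rule and
domain-composition CV). Every output table is written with a fixed
column order and sorted rows, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from . import catalog, compare, enrichment, genes, hotspots
from .io import (
    MUTATION_CLASSES,
    RunConfig,
    read_domain_table,
    read_gene_labels,
    read_msa_dir,
    read_mutation_table,
    read_proteome,
    write_table,
)

logger = logging.getLogger("domainspot")


def load_inputs(config: RunConfig) -> dict:
    proteome = read_proteome(config.proteome_path)
    instances = read_domain_table(config.domains_path, proteome)
    mutations = read_mutation_table(config.mutations_path)
    labels = read_gene_labels(config.labels_path)
    msas = read_msa_dir(config.msa_dir, proteome)
    return {"proteome": proteome, "instances": instances,
            "mutations": mutations, "labels": labels, "msas": msas}


def ensure_msas(inputs: dict, config: RunConfig) -> None:
    """Align any family lacking a precomputed MSA with the built-in aligner."""
    proteome = inputs["proteome"]
    by_family: dict[str, dict] = {}
    for inst in inputs["instances"]:
        by_family.setdefault(inst.family_id, {})[inst.key] = \
            inst.subsequence(proteome[inst.protein_accession])
    for family_id, seqs in by_family.items():
        if family_id not in inputs["msas"]:
            if config.aligner == "external":
                raise RuntimeError(
                    f"family {family_id} has no MSA and --aligner external "
                    "expects precomputed alignments"
                )
            inputs["msas"][family_id] = hotspots.align_family(seqs, family_id)


def run_all(inputs: dict, config: RunConfig,
            background_family_ids=None) -> dict:
    """Run the full analysis on in-memory inputs; returns all result objects."""
    out: dict = {}
    classified, _ = catalog.classify_all(inputs["mutations"])
    kept, dropped = catalog.validate_references(classified, inputs["proteome"])
    mapped, unmapped = catalog.map_catalog(kept, inputs["instances"],
                                           inputs["msas"])
    out["classified"], out["dropped"] = kept, dropped
    out["mapped"], out["unmapped"] = mapped, unmapped

    families: dict[str, list] = {}
    for inst in inputs["instances"]:
        families.setdefault(inst.family_id, []).append(inst)
    if background_family_ids is None:
        background_family_ids = {f for f in families if f.startswith("BG_")}
    background = {f: families[f] for f in background_family_ids if f in families}
    signal = {f: i for f, i in families.items() if f not in background}
    n_samples = len({m.sample_id for m in inputs["mutations"]}) or 1
    labels = inputs["labels"]

    out["enrichment"] = {}
    out["enrichment_genome"] = {}
    for mclass in MUTATION_CLASSES:
        if signal and background:
            out["enrichment"][mclass] = enrichment.enrich_against_background(
                signal, background, mapped, mclass, n_samples, config.alpha)
        if len(families) >= 2:
            out["enrichment_genome"][mclass] = enrichment.enrich_genome_wide(
                families, mapped, mclass, n_samples, config.alpha)

    msa_lengths = {f: m.length for f, m in inputs["msas"].items()}
    out["hotspots"] = {}
    for mclass in MUTATION_CLASSES:
        out["hotspots"][mclass] = hotspots.run_hotspot_analysis(
            mapped, msa_lengths, labels, mclass, config.alpha,
            config.min_hotspot_count, config.correction)

    out["overlaps"] = {}
    out["colocated"] = {}
    for mclass in MUTATION_CLASSES:
        runs = out["hotspots"][mclass]
        sig = {d: runs[d].significant for d in ("TS", "OG", "genome")}
        out["overlaps"][mclass] = {
            level: compare.overlap_sets(sig["TS"], sig["OG"], sig["genome"],
                                        level, mclass)
            for level in ("family", "position")
        }
        out["colocated"][mclass] = compare.colocated_candidates(
            sig["genome"], sig["TS"], sig["OG"], labels)

    out["profiles"] = genes.gene_profiles(kept)
    matrix_genes = [g for g, c in labels.items() if c in ("TS", "OG", "both")]
    out["feature_matrix"] = genes.build_feature_matrix(
        matrix_genes, inputs["instances"])
    try:
        out["classifier"] = genes.cross_validate(
            out["feature_matrix"], labels, k_folds=10, seed=config.seed)
    except ValueError as exc:
        logger.warning("skipping domain-composition CV: %s", exc)
        out["classifier"] = None
    dual = [g for g, c in labels.items() if c == "both"]
    if out["classifier"] is not None and dual:
        out["dual_scores"] = genes.score_unlabelled(
            out["feature_matrix"], labels, dual)
    else:
        out["dual_scores"] = None
    return out


def write_results(results: dict, config: RunConfig) -> None:
    """Write one TSV per (analysis, mutation class), plus summaries."""
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)

    mapped_rows = [
        [m.mutation.protein_accession, m.family_id, m.domain.start,
         m.domain.end, m.mclass, m.mutation.position, m.local_pos,
         m.msa_column, m.mutation.source.sample_id, m.mutation.source.change]
        for m in sorted(results["mapped"], key=lambda m: (
            m.mutation.protein_accession, m.family_id, m.mutation.position,
            m.mutation.source.sample_id, m.mutation.source.change))
    ]
    write_table(pd.DataFrame(mapped_rows, columns=[
        "protein", "family", "start", "end", "mclass", "position",
        "local_pos", "msa_column", "sample", "change"]),
        os.path.join(out_dir, "mapped_mutations.tsv"))
    unmapped_rows = [[c, results["unmapped"].get(c, 0)] for c in MUTATION_CLASSES]
    write_table(pd.DataFrame(unmapped_rows, columns=["mclass", "unmapped"]),
                os.path.join(out_dir, "unmapped_counts.tsv"))

    for mclass in MUTATION_CLASSES:
        if mclass in results["enrichment"]:
            write_table(enrichment.enrichment_frame(results["enrichment"][mclass]),
                        os.path.join(out_dir, f"enrichment_cancer_{mclass}.tsv"))
        if mclass in results["enrichment_genome"]:
            write_table(
                enrichment.enrichment_frame(results["enrichment_genome"][mclass]),
                os.path.join(out_dir, f"enrichment_genome_{mclass}.tsv"))
        for dataset, analysis in results["hotspots"][mclass].items():
            write_table(hotspots.hotspot_frame(analysis.tests),
                        os.path.join(out_dir, f"hotspots_{dataset}_{mclass}.tsv"))
        for level, summary in results["overlaps"][mclass].items():
            write_table(compare.overlap_frame(summary),
                        os.path.join(out_dir, f"overlap_{mclass}_{level}.tsv"))
    write_table(hotspots.summary_frame(results["hotspots"]),
                os.path.join(out_dir, "hotspot_summary.tsv"))
    colocated = pd.concat([results["colocated"][c] for c in MUTATION_CLASSES],
                          ignore_index=True)
    write_table(colocated, os.path.join(out_dir, "colocated_candidates.tsv"))

    write_table(genes.twenty_twenty_frame(results["profiles"]),
                os.path.join(out_dir, "twenty_twenty.tsv"))
    if results["classifier"] is not None:
        report = results["classifier"]
        fold_rows = [[i, auc] for i, auc in enumerate(report.fold_aucs)]
        fold_rows.append(["pooled", report.pooled_auc])
        write_table(pd.DataFrame(fold_rows, columns=["fold", "roc_auc"]),
                    os.path.join(out_dir, "classifier_report.tsv"))
        write_table(report.scores.sort_values(["gene"]).reset_index(drop=True),
                    os.path.join(out_dir, "gene_scores.tsv"))
    if results["dual_scores"] is not None:
        write_table(results["dual_scores"],
                    os.path.join(out_dir, "dual_gene_scores.tsv"))
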