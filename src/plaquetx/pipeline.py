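"""End-to-end orchestration: simulate -> build-db -> assign -> dge -> compare
-> summarize, with a run manifest and the final report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import assign as asn
from . import compare, dge, io, simulate, summarize
from .refdb import GeneCatalog, compute_unique_regions

log = logging.getLogger("plaquetx")


def run_all(design: simulate.SimDesign, outdir, k: int = 14,
            params: asn.AlignParams | None = None,
            thresholds: compare.Thresholds | None = None) -> dict:
    """Run the whole pipeline on a synthetic design; returns the report.

    Writes every stage artifact (catalog FASTA, reads FASTQ, masks BED,
    count/label/DGE TSVs, report JSON and Markdown, run manifest) under
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or asn.AlignParams()
    thresholds = thresholds or compare.Thresholds()
    t0 = time.time()
    manifest = {"design": dataclasses.asdict(design), "k": k, "stages": {}}

    def stage(name):
        log.info("stage: %s (t=%.1fs)", name, time.time() - t0)
        manifest["stages"][name] = round(time.time() - t0, 2)

    stage("simulate")
    catalog = simulate.generate_catalog(design)
    catalog.to_fasta(outdir / "catalog.fasta")
    true_counts, sheet, truth = simulate.generate_counts(design, catalog)
    io.write_counts(true_counts, outdir / "true_counts.tsv")
    io.write_sample_sheet(sheet, outdir / "samples.tsv")
    io.write_truth(truth, outdir / "truth.tsv")
    design.to_json(outdir / "design.json")

    stage("build-db")
    masks = compute_unique_regions(catalog, k=k)
    masks.to_bed(outdir / "masks.bed")

    stage("assign")
    index = asn.build_seed_index(catalog, params)
    assignments = {}
    for sample, reads in simulate.reads_for_samples(design, catalog, true_counts):
        io.write_fastq(reads, outdir / f"reads_{sample}.fastq")
        assignments[sample] = asn.assign_reads(reads, index, masks, params)
    counts = asn.count_assignments(assignments, sheet, catalog)
    io.write_counts(counts, outdir / "assigned_counts.tsv")

    stage("dge")
    dge_table = dge.run_contrasts(counts, sheet)
    io.write_dge(dge_table, outdir / "dge.tsv")

    stage("compare")
    labels = compare.label_genes(dge_table, thresholds)
    io.write_labels(labels, outdir / "labels.tsv")
    shares = compare.species_contribution_shares(labels)
    shares.to_csv(outdir / "species_shares.tsv", sep="\t", index=False)
    conv_table, conv_summary = compare.convergence_analysis(labels)
    conv_table.to_csv(outdir / "convergence.tsv", sep="\t", index=False)
    consistency = compare.group_consistency_averages(counts, sheet, labels,
                                                     thresholds=thresholds)

    stage("summarize")
    fc = summarize.species_fold_change(counts, sheet)
    species_totals = counts.groupby(level="species_id").sum()
    # detection threshold scaled to the synthetic depth: ~1% of a sample
    threshold = max(1, int(0.01 * design.reads_per_sample))
    curve = summarize.accumulation_curve(species_totals, threshold=threshold,
                                         n_orderings=200, seed=design.seed)
    curve.to_csv(outdir / "accumulation.tsv", sep="\t", index=False)
    report = summarize.build_report(labels=labels, shares=shares,
                                    convergence_summary=conv_summary,
                                    consistency_averages=consistency,
                                    fold_changes=fc, curve=curve)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
    with open(outdir / "report.md", "w") as fh:
        fh.write(summarize.render_report_markdown(report))

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    log.info("done in %.1fs", manifest["runtime_s"])
    return report


def recount_labels(labels: pd.DataFrame) -> dict:
    """Independent tally of label x direction counts from a labels table;
    used to cross-check the report's sde_counts."""
    out: dict = {}
    for (label, direction), cell in labels[labels["label"] != "none"] \
            .groupby(["label", "direction"]):
        out.setdefault(label, {})[direction] = int(len(cell))
    return out
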