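"""End-to-end orchestration of a synthetic-data analysis run."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .background import calibrate
from .junctions import extract_junctions, support_annotated_utr
from .paralogs import analyze_paralog_pair, coverage_uniformity
from .qc import MarkerPanel, qc_report
from .quantify import count_detected, quantify
from .report import EvidenceReport, build_profile, write_run_summary
from .synthetic import SimulationConfig, simulate_dataset, write_dataset


def run_pipeline(run_config: dict, outdir: Path, seed: int = 0) -> dict:
    """Simulate a dataset, then run quantification, cutoff calibration,
    QC, read-level evidence and reporting; write all artifacts under
    ``outdir`` and return the machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = run_config.get("simulation", {})
    config = SimulationConfig(**sim_kwargs)
    ds = simulate_dataset(config, seed=seed)
    if run_config.get("write_dataset", True):
        write_dataset(ds, outdir / "dataset")

    unique_only = bool(run_config.get("unique_only", True))
    matrix = quantify(ds.fragments, ds.genes, unique_only=unique_only)
    matrix.to_dir(outdir / "expression")

    family = run_config.get("family", "OR")
    cal = calibrate(
        ds.fragments,
        ds.genes,
        ds.chromosome_lengths,
        family=family,
        n_replicates=int(run_config.get("null_replicates", 10)),
        seed=seed + 1000,
        unique_only=unique_only,
    )
    (outdir / "calibration.json").write_text(
        json.dumps(cal.summary(), indent=2)
    )

    report = qc_report(
        matrix.fpkm,
        MarkerPanel.builtin(run_config.get("target_panel", "retina")),
        MarkerPanel.builtin(run_config.get("contaminant_panel", "rpe")),
        gene_names=matrix.gene_info["gene_name"],
        family_genes=matrix.family_genes(family),
    )
    (outdir / "qc.json").write_text(
        json.dumps(report.summary(), indent=2)
    )

    evidence = EvidenceReport()
    truth = ds.truth
    if truth.paralog_pair[0]:
        by_id = {g.gene_id: g for g in ds.genes}
        ga, gb = (by_id[g] for g in truth.paralog_pair)

        def orf_seq(g):
            from Bio.Seq import Seq

            s = ds.genome[g.chromosome][g.cds[0]:g.cds[1]]
            return s if g.strand == "+" else str(Seq(s).reverse_complement())

        evidence.paralog_calls.append(
            analyze_paralog_pair(ds.fragments, ga, gb, orf_seq(ga), orf_seq(gb))
        )
    for g in ds.genes:
        if g.gene_id in (truth.overlap_gene, truth.overlap_twin):
            evidence.uniformity[g.gene_id] = coverage_uniformity(
                ds.fragments, g,
                chromosome_length=ds.chromosome_lengths[g.chromosome],
            )
    evidence.junction_support = support_annotated_utr(
        extract_junctions(ds.fragments), ds.genes
    )

    headline, full = build_profile(matrix, family, cal.selected_cutoff, evidence)
    headline.to_csv(outdir / "profile.tsv", sep="\t")
    full.to_csv(outdir / "profile_full.tsv", sep="\t")

    per_sample = count_detected(
        matrix.fpkm, matrix.family_genes(family), cal.selected_cutoff, "per_sample"
    )
    summary = {
        "seed": seed,
        "selected_cutoff": cal.selected_cutoff,
        "detected_per_sample": {k: int(v) for k, v in per_sample.items()},
        "detected_mean_fpkm": int(len(headline)),
        "true_expressed_family_genes": len(truth.expressed_or_genes),
        "paralog_call": (
            evidence.paralog_calls[0].call if evidence.paralog_calls else None
        ),
        "uniformity_flags": {
            gid: bool(f.flagged_uniform) for gid, f in evidence.uniformity.items()
        },
        "n_supported_utr_junctions": (
            int(evidence.junction_support["supported"].sum())
            if len(evidence.junction_support)
            else 0
        ),
    }
    write_run_summary(outdir / "run_summary.json", **summary)
    return summary
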