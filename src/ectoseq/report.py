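"""End-to-end result assembly: family profiles, cross-tissue counts,
evidence annexes and a machine-readable run summary."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ExpressionMatrix
from .quantify import classify_band, mean_expression


@dataclass
class EvidenceReport:
    """Per-gene read-level evidence collected by the evidence modules."""

    paralog_calls: list = field(default_factory=list)
    uniformity: dict = field(default_factory=dict)  # gene_id -> UniformityFlag
    junction_support: Optional[pd.DataFrame] = None
    #: gene groups reported as merged (indistinguishable paralogs)
    merged_groups: list = field(default_factory=list)


def build_profile(
    matrix: ExpressionMatrix,
    family: str,
    cutoff: float,
    evidence: EvidenceReport | None = None,
):
    """Family expression profile sorted by mean FPKM (descending).

    Returns (headline, full): the headline table keeps genes with mean
    FPKM >= cutoff; the full annex keeps every family gene.  Ties in
    mean FPKM break by gene name, lexicographically.
    """
    fam = matrix.family_genes(family)
    if not fam:
        warnings.warn(f"family {family!r} has no genes in the matrix")
        return pd.DataFrame(), pd.DataFrame()
    fpkm = matrix.fpkm.loc[fam]
    table = fpkm.copy()
    table.insert(0, "gene_name", matrix.gene_info.loc[fam, "gene_name"])
    table["mean_fpkm"] = mean_expression(fpkm, list(fpkm.columns))
    table["mean_tpm"] = mean_expression(matrix.tpm.loc[fam], list(fpkm.columns))
    table["band"] = classify_band(table["mean_fpkm"])
    table["detected"] = table["mean_fpkm"] >= cutoff
    flagged = set()
    merged = set()
    if evidence is not None:
        flagged = {
            gid for gid, f in evidence.uniformity.items() if f.flagged_uniform
        }
        merged = {g for grp in evidence.merged_groups for g in grp}
    table["uniform_coverage_flag"] = [g in flagged for g in table.index]
    table["paralog_merged"] = [g in merged for g in table.index]
    table = table.sort_values(
        ["mean_fpkm", "gene_name"], ascending=[False, True], kind="mergesort"
    )
    headline = table[table["detected"]]
    return headline, table


def tissue_detection_counts(
    matrices: Mapping[str, pd.DataFrame],
    family_genes: Sequence[str],
    cutoff: float,
    statistic: str = "mean",
):
    """Detected family genes per tissue plus pairwise overlap fractions.

    ``matrices`` maps tissue name -> FPKM matrix (genes x samples).
    The overlap fraction is asymmetric: row tissue A, column tissue B
    holds ``|detected(A) & detected(B)| / |detected(A)| * 100``.
    """
    detected: dict[str, set] = {}
    for tissue, fpkm in matrices.items():
        fam = [g for g in family_genes if g in fpkm.index]
        sub = fpkm.loc[fam]
        if statistic == "mean":
            det = set(sub.index[sub.mean(axis=1) >= cutoff])
        elif statistic == "per_sample":
            det = set(sub.index[(sub >= cutoff).any(axis=1)])
        else:
            raise ValueError("statistic must be 'mean' or 'per_sample'")
        detected[tissue] = det
    tissues = list(matrices)
    counts = pd.Series({t: len(detected[t]) for t in tissues}, dtype=int)
    overlap = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for a in tissues:
        for b in tissues:
            if len(detected[a]):
                overlap.loc[a, b] = (
                    100.0 * len(detected[a] & detected[b]) / len(detected[a])
                )
    return counts, overlap, detected


def profile_heatmap(profile: pd.DataFrame, sample_columns: Sequence[str], path) -> None:
    """Log-scaled heat map of a family profile (darker = higher FPKM,
    white = absent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.log10(profile[list(sample_columns)].to_numpy(dtype=float) + 1.0)
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * len(sample_columns), 1 + 0.3 * len(profile))
    )
    im = ax.imshow(data, aspect="auto", cmap="Greys", vmin=0)
    ax.set_xticks(range(len(sample_columns)), labels=list(sample_columns), rotation=90)
    ax.set_yticks(range(len(profile)), labels=list(profile["gene_name"]))
    fig.colorbar(im, ax=ax, label="log10(FPKM + 1)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_run_summary(path, **sections) -> None:
    """JSON run summary (inputs, seeds, cutoff, versions...)."""
    from . import __version__

    payload = {"ectoseq_version": __version__}
    payload.update(sections)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return str(obj)
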