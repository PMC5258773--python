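"""Sample-integrity QC: marker panels, contamination, correlations.

Marker-panel means summarize tissue identity (target panel high,
contaminant panel silent); the contamination ratio compares the two;
Pearson product-moment correlations between samples — optionally
restricted to an FPKM range or log-transformed — measure replicate
consistency, both genome-wide and over a gene family's profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class MarkerPanel:
    name: str
    gene_names: list[str]

    def __post_init__(self) -> None:
        if not self.gene_names:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError(f"panel {self.name!r} has duplicate gene names")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "MarkerPanel":
        from .io import read_panel
        from pathlib import Path

        return cls(name or Path(path).stem, read_panel(path))

    @classmethod
    def builtin(cls, name: str) -> "MarkerPanel":
        from .io import builtin_panel

        return cls(name, builtin_panel(name))


def _panel_rows(matrix: pd.DataFrame, panel: MarkerPanel, gene_names: pd.Series | None):
    """Rows of ``matrix`` matching the panel, by gene name if a
    gene_id -> gene_name mapping is given, else by index."""
    if gene_names is not None:
        ids = gene_names.index[gene_names.isin(panel.gene_names)]
    else:
        ids = matrix.index.intersection(panel.gene_names)
    found = matrix.loc[ids]
    missing = set(panel.gene_names) - (
        set(gene_names.loc[ids]) if gene_names is not None else set(ids)
    )
    return found, sorted(missing)


def panel_summary(
    matrix: pd.DataFrame,
    panel: MarkerPanel,
    gene_names: pd.Series | None = None,
):
    """Per-sample mean FPKM over the panel genes found in the matrix.

    Returns (summary, table): the per-sample mean and the individual
    per-gene values (heatmap-ready).  Missing panel genes are reported
    with a warning; a panel with no genes present is an error.
    """
    found, missing = _panel_rows(matrix, panel, gene_names)
    if found.empty:
        raise ValueError(f"no genes of panel {panel.name!r} present in the matrix")
    if missing:
        warnings.warn(f"panel {panel.name!r}: genes not in matrix: {missing}")
    return found.mean(axis=0), found


def contamination_ratio(
    matrix: pd.DataFrame,
    target_panel: MarkerPanel,
    contaminant_panel: MarkerPanel,
    gene_names: pd.Series | None = None,
    eps: float = 1e-6,
) -> pd.Series:
    """mean FPKM(contaminant) / (mean FPKM(target) + eps); lower is cleaner."""
    target_mean, _ = panel_summary(matrix, target_panel, gene_names)
    contam_mean, _ = panel_summary(matrix, contaminant_panel, gene_names)
    return contam_mean / (target_mean + eps)


def sample_correlation(
    matrix: pd.DataFrame,
    value_range: Optional[tuple[float, float]] = None,
    log_transform: bool = False,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    With ``value_range=(lo, hi)`` a gene enters a pair's computation
    only when BOTH samples' values lie inside [lo, hi].  With
    ``log_transform`` values become log10(x+1) first.  Pairs left with
    fewer than ``min_genes`` genes get NaN (with a warning).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    vals = matrix.astype(float)
    if log_transform:
        vals = np.log10(vals + 1.0)
    samples = list(vals.columns)
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            b = samples[j]
            x, y = vals[a], vals[b]
            if value_range is not None:
                lo, hi = value_range
                # range filter applies to the raw scale
                rx, ry = matrix[a], matrix[b]
                keep = (rx >= lo) & (rx <= hi) & (ry >= lo) & (ry <= hi)
                x, y = x[keep], y[keep]
            if len(x) < min_genes or x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"correlation {a} vs {b}: fewer than {min_genes} usable "
                    "genes (or constant values); reporting NA"
                )
                rho = np.nan
            else:
                rho = float(np.corrcoef(x, y)[0, 1])
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def family_profile_correlation(
    matrix: pd.DataFrame,
    family_genes: Sequence[str],
    value_range: Optional[tuple[float, float]] = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Sample correlation restricted to a gene family's profile."""
    fam = [g for g in family_genes if g in matrix.index]
    return sample_correlation(
        matrix.loc[fam], value_range=value_range, log_transform=log_transform
    )


@dataclass
class QCReport:
    panel_means: pd.DataFrame  # panels x samples
    panel_tables: dict
    contamination: pd.Series
    correlation_full: pd.DataFrame
    correlation_restricted: Optional[pd.DataFrame]
    family_correlation: Optional[pd.DataFrame]

    def summary(self) -> dict:
        return {
            "panel_means": self.panel_means.to_dict(),
            "contamination_ratio": self.contamination.to_dict(),
            "correlation_full": self.correlation_full.to_dict(),
            "correlation_restricted": (
                None
                if self.correlation_restricted is None
                else self.correlation_restricted.to_dict()
            ),
            "family_correlation": (
                None
                if self.family_correlation is None
                else self.family_correlation.to_dict()
            ),
        }


def qc_report(
    fpkm: pd.DataFrame,
    target_panel: MarkerPanel,
    contaminant_panel: MarkerPanel,
    gene_names: pd.Series | None = None,
    family_genes: Sequence[str] | None = None,
    value_range: Optional[tuple[float, float]] = (0.0, 30.0),
    expressed_only: bool = False,
) -> QCReport:
    """Assemble the full QC report for one expression matrix."""
    mat = fpkm
    if expressed_only:
        mat = fpkm.loc[(fpkm > 0).any(axis=1)]
    t_mean, t_tab = panel_summary(mat, target_panel, gene_names)
    c_mean, c_tab = panel_summary(mat, contaminant_panel, gene_names)
    panel_means = pd.DataFrame(
        {target_panel.name: t_mean, contaminant_panel.name: c_mean}
    ).T
    contam = contamination_ratio(mat, target_panel, contaminant_panel, gene_names)
    corr_full = sample_correlation(mat)
    corr_restricted = (
        sample_correlation(mat, value_range=value_range) if value_range else None
    )
    fam_corr = None
    if family_genes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam_corr = family_profile_correlation(mat, family_genes)
    return QCReport(panel_means, {target_panel.name: t_tab, contaminant_panel.name: c_tab}, contam, corr_full, corr_restricted, fam_corr)
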