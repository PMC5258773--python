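"""Read-level evidence for near-identical paralogs and coverage artifacts.

Two procedures formalize what a genome browser shows:

* the paralog caller decides which member of a highly homologous pair
  (e.g. 95% nucleotide identity) is actually expressed, by counting
  uniquely mapping fragments over the positions where the two ORFs
  differ — fragments at identical positions are uninformative;
* the coverage-uniformity statistic compares mean per-base coverage
  over a gene's exon union with its flanking windows; a gene whose
  ORF shows no specific accumulation over the local background is
  flagged, signaling that its FPKM may partially originate from an
  overlapping unannotated transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, expand_blocks


@dataclass
class ParalogCall:
    gene_a: str
    gene_b: str
    identity: Optional[float]
    positions_specific_a: np.ndarray
    positions_specific_b: np.ndarray
    unique_fragments_a: int
    unique_fragments_b: int
    call: str  # {A, B, both, neither, ambiguous}


@dataclass
class UniformityFlag:
    gene_id: str
    orf_mean_coverage: float
    flank_mean_coverage: float
    enrichment: float
    flagged_uniform: bool


def discriminative_positions(seq_a: str, seq_b: str):
    """Positions at which two gapless-aligned ORFs differ.

    Returns ``(positions_a, positions_b, identity)``; the position
    arrays are in each gene's own ORF coordinates (identical for a
    gapless comparison) and identity = matches/length.
    """
    sa, sb = seq_a.upper(), seq_b.upper()
    if len(sa) != len(sb):
        raise ValueError(
            "sequences differ in length; align them first (gapless "
            "comparison requires equal lengths)"
        )
    if not sa:
        raise ValueError("empty sequences")
    for s in (sa, sb):
        if set(s) - set("ACGT"):
            raise ValueError("sequences must be over the alphabet {A,C,G,T}")
    a = np.frombuffer(sa.encode(), dtype="S1")
    b = np.frombuffer(sb.encode(), dtype="S1")
    diff = np.flatnonzero(a != b)
    identity = 1.0 - len(diff) / len(a)
    return diff.copy(), diff.copy(), identity


def orf_positions_to_genomic(gene: GeneModel, positions: np.ndarray) -> np.ndarray:
    """Map ORF coordinates to genomic positions via the gene's CDS.

    ORF coordinate 0 is the first coding base in transcript orientation
    (so it maps to the CDS end on the minus strand).
    """
    if gene.cds is None:
        raise ValueError(f"gene {gene.gene_id} has no annotated CDS")
    lo, hi = gene.cds
    pos = np.asarray(positions, dtype=np.int64)
    if gene.strand == "+":
        out = lo + pos
    else:
        out = (hi - 1) - pos
    if ((out < lo) | (out >= hi)).any():
        raise ValueError("ORF position outside the CDS")
    return np.sort(out)


def _unique_fragment_support(
    fragments: pd.DataFrame, chromosome: str, genomic_positions: np.ndarray
) -> int:
    """Number of uniquely mapping fragments covering >= 1 position."""
    if len(genomic_positions) == 0 or not len(fragments):
        return 0
    frags = fragments[
        (fragments["chromosome"] == chromosome) & fragments["unique"].astype(bool)
    ]
    if not len(frags):
        return 0
    blocks = expand_blocks(frags)
    pos = np.sort(np.asarray(genomic_positions))
    lo = np.searchsorted(pos, blocks["start"].to_numpy())
    hi = np.searchsorted(pos, blocks["end"].to_numpy())
    hit = blocks.loc[hi > lo, "frag_idx"]
    return int(hit.nunique())


def call_expressed_paralog(
    fragments: pd.DataFrame,
    gene_a: GeneModel,
    gene_b: GeneModel,
    specific_positions_a: np.ndarray,
    specific_positions_b: np.ndarray,
    min_support: int = 5,
    max_contra: int = 1,
    identity: Optional[float] = None,
) -> ParalogCall:
    """Decide which paralog the unique fragments support.

    ``specific_positions_*`` are genomic positions specific to each
    gene (see :func:`orf_positions_to_genomic`).  Call A when support_a
    >= min_support and support_b <= max_contra (symmetrically B);
    ``both`` when both reach min_support; ``neither`` when both are
    below min_support; ``ambiguous`` otherwise.
    """
    pa = np.asarray(specific_positions_a, dtype=np.int64)
    pb = np.asarray(specific_positions_b, dtype=np.int64)
    if len(pa) == 0 and len(pb) == 0:
        warnings.warn(
            f"no discriminative positions between {gene_a.gene_id} and "
            f"{gene_b.gene_id}; call is ambiguous"
        )
        return ParalogCall(
            gene_a.gene_id, gene_b.gene_id, identity, pa, pb, 0, 0, "ambiguous"
        )
    sa = _unique_fragment_support(fragments, gene_a.chromosome, pa)
    sb = _unique_fragment_support(fragments, gene_b.chromosome, pb)
    if sa >= min_support and sb >= min_support:
        call = "both"
    elif sa >= min_support and sb <= max_contra:
        call = "A"
    elif sb >= min_support and sa <= max_contra:
        call = "B"
    elif sa < min_support and sb < min_support:
        call = "neither"
    else:
        call = "ambiguous"
    return ParalogCall(gene_a.gene_id, gene_b.gene_id, identity, pa, pb, sa, sb, call)


def analyze_paralog_pair(
    fragments: pd.DataFrame,
    gene_a: GeneModel,
    gene_b: GeneModel,
    seq_a: str,
    seq_b: str,
    min_support: int = 5,
    max_contra: int = 1,
) -> ParalogCall:
    """Convenience wrapper: discriminative positions from the two ORF
    sequences, mapped to genomic coordinates, then the call."""
    orf_a, orf_b, identity = discriminative_positions(seq_a, seq_b)
    ga = orf_positions_to_genomic(gene_a, orf_a)
    gb = orf_positions_to_genomic(gene_b, orf_b)
    return call_expressed_paralog(
        fragments, gene_a, gene_b, ga, gb,
        min_support=min_support, max_contra=max_contra, identity=identity,
    )


def _coverage_in_windows(blocks: pd.DataFrame, windows) -> float:
    """Total overlapped bases of ``blocks`` with a window list, divided
    by the total window length (mean per-base fragment coverage)."""
    total_len = sum(e - s for s, e in windows)
    if total_len <= 0:
        return 0.0
    bs = blocks["start"].to_numpy()
    be = blocks["end"].to_numpy()
    covered = 0
    for ws, we in windows:
        covered += np.maximum(
            0, np.minimum(be, we) - np.maximum(bs, ws)
        ).sum()
    return float(covered) / total_len


def coverage_uniformity(
    fragments: pd.DataFrame,
    gene: GeneModel,
    flank_bp: int = 5000,
    enrichment_threshold: float = 2.0,
    chromosome_length: Optional[int] = None,
    eps: float = 1e-9,
) -> UniformityFlag:
    """Mean coverage over the exon union vs the two flanking windows.

    ``flagged_uniform`` is True when ORF/flank enrichment falls below
    the threshold — evenly covered, no specific accumulation at the
    ORF.  Fragments from all samples are pooled.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    frags = fragments[fragments["chromosome"] == gene.chromosome]
    blocks = (
        expand_blocks(frags)
        if len(frags)
        else pd.DataFrame(columns=["frag_idx", "chromosome", "start", "end"])
    )
    span = gene.span
    left = (max(0, span[0] - flank_bp), span[0])
    right_end = span[1] + flank_bp
    if chromosome_length is not None:
        right_end = min(right_end, chromosome_length)
    right = (span[1], right_end)
    orf_cov = _coverage_in_windows(blocks, gene.exon_union)
    flank_cov = _coverage_in_windows(blocks, [w for w in (left, right) if w[1] > w[0]])
    enrichment = orf_cov / (flank_cov + eps)
    return UniformityFlag(
        gene_id=gene.gene_id,
        orf_mean_coverage=orf_cov,
        flank_mean_coverage=flank_cov,
        enrichment=enrichment,
        flagged_uniform=enrichment < enrichment_threshold,
    )
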