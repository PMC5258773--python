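"""Intergenic-repositioning background null and cutoff calibration.

The family's gene models are relocated — with exon/intron structure
and strand preserved — to uniformly sampled positions in the
intergenic space (genome minus annotated genes plus a buffer).
Fragments mapping to the shifted models estimate the background of
detection; the detection cutoff is the smallest candidate FPKM
threshold above which the mean number of background detections does
not exceed a tolerated count (zero by default).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, merge_intervals
from .quantify import compute_fpkm, count_fragments


class IntergenicPlacementError(RuntimeError):
    pass


def _free_intervals(
    genes: Sequence[GeneModel],
    placed: Sequence[GeneModel],
    chromosome_lengths: Mapping[str, int],
    buffer_bp: int,
) -> dict[str, list[tuple[int, int]]]:
    blocked: dict[str, list] = {c: [] for c in chromosome_lengths}
    for g in list(genes) + list(placed):
        s, e = g.span
        blocked[g.chromosome].append(
            (max(0, s - buffer_bp), min(chromosome_lengths[g.chromosome], e + buffer_bp))
        )
    free = {}
    for c, length in chromosome_lengths.items():
        out, pos = [], 0
        for s, e in merge_intervals(blocked[c]):
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append((pos, length))
        free[c] = out
    return free


def sample_intergenic_placements(
    annotation: Sequence[GeneModel],
    family: str,
    chromosome_lengths: Mapping[str, int],
    rng: np.random.Generator,
    buffer_bp: int = 1000,
    max_retries: int = 1000,
) -> list[GeneModel]:
    """Relocate every family gene to a random intergenic position.

    Each shifted model keeps its exon-length vector and strand; its
    start is drawn uniformly over all positions where the full span
    fits in the pooled intergenic space (any chromosome) without
    touching an annotated gene (± buffer) or a previously placed
    shifted model.
    """
    family_genes = [g for g in annotation if g.family == family]
    shifted: list[GeneModel] = []
    for g in family_genes:
        span_len = g.span[1] - g.span[0]
        placed = False
        for _ in range(max_retries):
            free = _free_intervals(annotation, shifted, chromosome_lengths, buffer_bp)
            # uniform over valid start positions across all chromosomes
            cands = [
                (c, s, e) for c, ivs in free.items() for s, e in ivs
                if e - s >= span_len
            ]
            if not cands:
                break
            weights = np.array([e - s - span_len + 1 for _, s, e in cands], dtype=float)
            i = rng.choice(len(cands), p=weights / weights.sum())
            c, s, e = cands[i]
            start = int(s + rng.integers(0, e - s - span_len + 1))
            new = g.shifted(start)
            if new.chromosome != c:
                new = dataclasses.replace(new, chromosome=c)
            shifted.append(new)
            placed = True
            break
        if not placed:
            raise IntergenicPlacementError(
                f"could not place shifted model for {g.gene_id} "
                f"(span {span_len} bp) in the remaining intergenic space"
            )
    return shifted


def evaluate_background(
    fragments: pd.DataFrame,
    shifted_annotation: Sequence[GeneModel],
    bins: Sequence[tuple[float, float]],
    library_size: pd.Series,
    unique_only: bool = False,
    blocks: pd.DataFrame | None = None,
):
    """Quantify fragments against shifted models and bin their FPKM.

    FPKM is computed with the ORIGINAL per-sample library sizes so the
    background is on the same scale as the real quantification.

    Returns (binned, fpkm): ``binned`` is a bins x samples count table
    of shifted genes whose FPKM falls in each half-open bin
    ``(lo, hi]``; ``fpkm`` the shifted genes x samples FPKM matrix.
    """
    for (l0, h0), (l1, h1) in zip(bins, bins[1:]):
        if l1 < h0:
            raise ValueError("bins must be ordered and disjoint")
    counts, _, _ = count_fragments(
        fragments, shifted_annotation, unique_only=unique_only, blocks=blocks
    )
    lengths = pd.Series(
        {g.gene_id: g.exon_union_length for g in shifted_annotation}
    )
    fpkm = compute_fpkm(counts, lengths, library_size.reindex(counts.columns))
    labels = [f"({lo},{hi}]" for lo, hi in bins]
    binned = pd.DataFrame(0, index=labels, columns=fpkm.columns, dtype=int)
    for (lo, hi), label in zip(bins, labels):
        binned.loc[label] = ((fpkm > lo) & (fpkm <= hi)).sum(axis=0).astype(int)
    return binned, fpkm


def select_cutoff(
    real_detected: Sequence[float],
    background_detected: Sequence[float],
    candidate_thresholds: Sequence[float],
    max_background_count: float = 0.0,
) -> float:
    """Smallest candidate threshold with tolerable mean background.

    ``real_detected``/``background_detected`` are the mean numbers of
    family genes detected at FPKM > t for each candidate t.  Returns
    the smallest t whose mean background count is <= the tolerance; if
    none qualifies, the largest candidate with a warning.
    """
    cands = list(candidate_thresholds)
    if not cands:
        raise ValueError("no candidate thresholds given")
    if any(b > a for a, b in zip(cands[1:], cands)):
        raise ValueError("candidate thresholds must be ascending")
    bg = list(background_detected)
    if len(bg) != len(cands):
        raise ValueError("background_detected must align with candidates")
    for t, b in zip(cands, bg):
        if b <= max_background_count:
            return float(t)
    warnings.warn(
        "no candidate threshold reaches the background tolerance; "
        "falling back to the largest candidate"
    )
    return float(cands[-1])


def background_fraction(real_mean: float, background_mean: float):
    """Background detections as a percentage of real detections.

    Returns ``100 * background/real`` (full precision); NaN when the
    real mean is zero (undefined, reported as NA).
    """
    if real_mean == 0:
        warnings.warn("real detection mean is zero; background fraction is NA")
        return float("nan")
    return 100.0 * background_mean / real_mean


DEFAULT_BINS = ((0.0, 0.1), (0.1, 0.3), (0.3, float("inf")))
DEFAULT_CANDIDATES = (0.1, 0.3)


@dataclass
class NullCalibration:
    """Result of the randomized intergenic calibration."""

    n_replicates: int
    bins: tuple
    #: mean count of family genes per FPKM bin across samples
    real_detected: pd.Series
    #: mean count at shifted positions per bin (across samples and replicates)
    background_detected: pd.Series
    #: percent background per bin (NaN where real_detected == 0)
    background_fraction: pd.Series
    selected_cutoff: float
    seeds: list[int]
    #: mean detections at FPKM > t per candidate threshold
    real_above: pd.Series = field(default=None)
    background_above: pd.Series = field(default=None)
    #: family genes x samples FPKM from the real quantification
    family_fpkm: pd.DataFrame = field(default=None)

    def summary(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "selected_cutoff": self.selected_cutoff,
            "seeds": self.seeds,
            "bins": [list(b) for b in self.bins],
            "real_detected": self.real_detected.to_dict(),
            "background_detected": self.background_detected.to_dict(),
            "background_fraction": {
                k: (None if pd.isna(v) else v)
                for k, v in self.background_fraction.items()
            },
            "real_above": self.real_above.to_dict(),
            "background_above": self.background_above.to_dict(),
        }


def calibrate(
    fragments: pd.DataFrame,
    annotation: Sequence[GeneModel],
    chromosome_lengths: Mapping[str, int],
    family: str = "OR",
    n_replicates: int = 10,
    seed: int = 0,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    candidate_thresholds: Sequence[float] = DEFAULT_CANDIDATES,
    buffer_bp: int = 1000,
    unique_only: bool = False,
    max_background_count: float = 0.0,
    library_size: pd.Series | None = None,
    real_fpkm: pd.DataFrame | None = None,
) -> NullCalibration:
    """Full calibration: real quantification, ``n_replicates`` shifted
    annotations, binned background detections and cutoff selection."""
    family_ids = [g.gene_id for g in annotation if g.family == family]
    if not family_ids:
        raise ValueError(f"no genes with family tag {family!r}")
    from .models import expand_blocks

    # apply the unique filter once and reuse the expanded blocks across
    # the real quantification and every null replicate
    work = fragments
    if unique_only:
        work = fragments[fragments["unique"].astype(bool)].reset_index(drop=True)
    blocks_cache = expand_blocks(work)
    if real_fpkm is None or library_size is None:
        counts, library_size, _ = count_fragments(
            work, annotation, blocks=blocks_cache
        )
        lengths = pd.Series({g.gene_id: g.exon_union_length for g in annotation})
        real_fpkm = compute_fpkm(counts, lengths, library_size)
    fam_fpkm = real_fpkm.loc[family_ids]

    labels = [f"({lo},{hi}]" for lo, hi in bins]
    real_binned = pd.Series(
        {
            label: float(((fam_fpkm > lo) & (fam_fpkm <= hi)).sum(axis=0).mean())
            for (lo, hi), label in zip(bins, labels)
        }
    )
    real_above = pd.Series(
        {t: float((fam_fpkm > t).sum(axis=0).mean()) for t in candidate_thresholds}
    )

    seeds = [int(seed) + r for r in range(n_replicates)]
    bg_binned_reps, bg_above_reps = [], []
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        shifted = sample_intergenic_placements(
            annotation, family, chromosome_lengths, rng, buffer_bp=buffer_bp
        )
        _assert_shift_invariants(annotation, shifted, chromosome_lengths, buffer_bp)
        binned, bg_fpkm = evaluate_background(
            work, shifted, bins, library_size, blocks=blocks_cache
        )
        bg_binned_reps.append(binned.mean(axis=1))
        bg_above_reps.append(
            pd.Series(
                {
                    t: float((bg_fpkm > t).sum(axis=0).mean())
                    for t in candidate_thresholds
                }
            )
        )
    bg_binned = pd.concat(bg_binned_reps, axis=1).mean(axis=1)
    bg_above = pd.concat(bg_above_reps, axis=1).mean(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frac = pd.Series(
            {
                label: background_fraction(real_binned[label], bg_binned[label])
                for label in labels
            }
        )
    cutoff = select_cutoff(
        real_above.to_numpy(),
        bg_above.to_numpy(),
        list(candidate_thresholds),
        max_background_count=max_background_count,
    )
    return NullCalibration(
        n_replicates=n_replicates,
        bins=tuple(bins),
        real_detected=real_binned,
        background_detected=bg_binned,
        background_fraction=frac,
        selected_cutoff=cutoff,
        seeds=seeds,
        real_above=real_above,
        background_above=bg_above,
        family_fpkm=fam_fpkm,
    )


def _assert_shift_invariants(annotation, shifted, chromosome_lengths, buffer_bp):
    """Structure preservation and no-overlap guarantees, checked every run."""
    by_id = {g.gene_id: g for g in annotation}
    for s in shifted:
        orig = by_id[s.gene_id]
        orig_lens = [
            [e - b for b, e in t] for t in orig.transcripts
        ]
        new_lens = [[e - b for b, e in t] for t in s.transcripts]
        if orig_lens != new_lens:
            raise AssertionError(f"exon-length vector changed for {s.gene_id}")
    spans = []
    for g in annotation:
        a, b = g.span
        spans.append((g.chromosome, a - buffer_bp, b + buffer_bp, "annot"))
    for s in shifted:
        a, b = s.span
        spans.append((s.chromosome, a, b, "shift"))
    spans.sort()
    for (c0, a0, b0, k0), (c1, a1, b1, k1) in zip(spans, spans[1:]):
        if c0 == c1 and a1 < b0 and "shift" in (k0, k1):
            raise AssertionError("shifted model overlaps an annotated gene or another shifted model")
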