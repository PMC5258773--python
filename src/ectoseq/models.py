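"""Core data structures shared across the pipeline.

Coordinates are 0-based half-open throughout the in-memory model; GTF
emission converts to 1-based inclusive (see :mod:`ectoseq.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

#: Column order of the canonical in-memory fragment table (a pandas
#: DataFrame).  ``block_sizes``/``block_starts`` follow the BED12
#: convention: comma-separated, block starts relative to ``start``.
FRAGMENT_COLUMNS = [
    "sample_id",
    "chromosome",
    "start",
    "end",
    "block_count",
    "block_sizes",
    "block_starts",
    "unique",
]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/adjacent runs merged."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """A gene with one or more transcripts on a single chromosome.

    Parameters
    ----------
    transcripts
        One exon-interval list per transcript; exons are 0-based
        half-open, sorted and non-overlapping within a transcript.
    family
        Free-form family tag; the pipeline uses ``"OR"``,
        ``"marker_retina"``, ``"marker_rpe"`` and ``"other"``.
    cds
        Genomic interval of the coding region (single-interval ORF),
        if annotated.  Used to tell 5'UTR exons from coding exons.
    """

    gene_id: str
    gene_name: str
    chromosome: str
    strand: str
    transcripts: list[list[Interval]]
    family: str = "other"
    cds: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for exons in self.transcripts:
            if not exons:
                raise ValueError(f"gene {self.gene_id} has an empty transcript")
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"gene {self.gene_id}: exons overlap or are unsorted"
                    )
            if any(s >= e for s, e in exons):
                raise ValueError(f"gene {self.gene_id}: empty exon interval")

    @property
    def exon_union(self) -> list[Interval]:
        return merge_intervals(iv for t in self.transcripts for iv in t)

    @property
    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union)

    @property
    def span(self) -> Interval:
        union = self.exon_union
        return (union[0][0], union[-1][1])

    def shifted(self, new_start: int) -> "GeneModel":
        """Copy with identical exon/intron structure relocated so the
        gene span begins at ``new_start`` (same chromosome and strand)."""
        offset = new_start - self.span[0]
        return GeneModel(
            gene_id=self.gene_id,
            gene_name=self.gene_name,
            chromosome=self.chromosome,
            strand=self.strand,
            transcripts=[
                [(s + offset, e + offset) for s, e in t] for t in self.transcripts
            ],
            family=self.family,
            cds=None if self.cds is None else (self.cds[0] + offset, self.cds[1] + offset),
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression container.

    ``counts``, ``fpkm`` and ``tpm`` share index (gene_id) and columns
    (sample_id); ``library_size`` is the per-sample total of fragments
    assigned to annotated genes.  ``gene_info`` carries gene_name,
    family and exon-union length per gene.
    """

    counts: pd.DataFrame
    fpkm: pd.DataFrame
    tpm: pd.DataFrame
    library_size: pd.Series
    gene_info: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def family_genes(self, family: str) -> list[str]:
        return list(self.gene_info.index[self.gene_info["family"] == family])

    def to_dir(self, outdir) -> None:
        from pathlib import Path
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
        self.tpm.to_csv(outdir / "tpm.tsv", sep="\t")
        self.gene_info.to_csv(outdir / "gene_info.tsv", sep="\t")
        from . import __version__

        sidecar = {
            "library_size": {k: int(v) for k, v in self.library_size.items()},
            "version": __version__,
        }
        (outdir / "quantification.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_dir(cls, outdir) -> "ExpressionMatrix":
        from pathlib import Path
        import json

        outdir = Path(outdir)
        counts = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col=0)
        fpkm = pd.read_csv(outdir / "fpkm.tsv", sep="\t", index_col=0)
        tpm = pd.read_csv(outdir / "tpm.tsv", sep="\t", index_col=0)
        gene_info = pd.read_csv(outdir / "gene_info.tsv", sep="\t", index_col=0)
        sidecar = json.loads((outdir / "quantification.json").read_text())
        library_size = pd.Series(sidecar["library_size"])
        return cls(counts, fpkm, tpm, library_size, gene_info)


def fragments_frame(
    sample_id: Sequence[str] | str,
    chromosome: Sequence[str] | str,
    blocks: Sequence[Sequence[Interval]],
    unique: Sequence[bool] | bool = True,
) -> pd.DataFrame:
    """Build a fragment table from per-fragment block lists.

    Convenience constructor used by tests and small examples; the
    simulator builds its tables directly from numpy arrays.
    """
    n = len(blocks)
    if isinstance(sample_id, str):
        sample_id = [sample_id] * n
    if isinstance(chromosome, str):
        chromosome = [chromosome] * n
    if isinstance(unique, (bool, np.bool_)):
        unique = [bool(unique)] * n
    starts, ends, counts, sizes, offs = [], [], [], [], []
    for blist in blocks:
        blist = sorted(blist)
        s0 = blist[0][0]
        starts.append(s0)
        ends.append(blist[-1][1])
        counts.append(len(blist))
        sizes.append(",".join(str(e - s) for s, e in blist))
        offs.append(",".join(str(s - s0) for s, e in blist))
    return pd.DataFrame(
        {
            "sample_id": list(sample_id),
            "chromosome": list(chromosome),
            "start": starts,
            "end": ends,
            "block_count": counts,
            "block_sizes": sizes,
            "block_starts": offs,
            "unique": list(unique),
        }
    )[FRAGMENT_COLUMNS]


def expand_blocks(fragments: pd.DataFrame) -> pd.DataFrame:
    """Explode a fragment table into one row per block.

    Returns a DataFrame with columns ``frag_idx`` (positional index into
    ``fragments``), ``chromosome``, ``start``, ``end``.  Single-block
    fragments (the vast majority) are passed through without string
    parsing.
    """
    frags = fragments.reset_index(drop=True)
    single = frags["block_count"].to_numpy() == 1
    parts = []
    if single.any():
        sub = frags.loc[single]
        parts.append(
            pd.DataFrame(
                {
                    "frag_idx": sub.index.to_numpy(),
                    "chromosome": sub["chromosome"].to_numpy(),
                    "start": sub["start"].to_numpy(),
                    "end": sub["end"].to_numpy(),
                }
            )
        )
    multi = frags.loc[~single]
    if len(multi):
        size_lists = multi["block_sizes"].astype(str).str.split(",")
        off_lists = multi["block_starts"].astype(str).str.split(",")
        n_blocks = size_lists.str.len().to_numpy()
        rep_idx = np.repeat(multi.index.to_numpy(), n_blocks)
        rep_chrom = np.repeat(multi["chromosome"].to_numpy(), n_blocks)
        rep_start0 = np.repeat(multi["start"].to_numpy(), n_blocks)
        sizes = np.array(
            [int(x) for lst in size_lists for x in lst], dtype=np.int64
        )
        offs = np.array([int(x) for lst in off_lists for x in lst], dtype=np.int64)
        starts = rep_start0 + offs
        parts.append(
            pd.DataFrame(
                {
                    "frag_idx": rep_idx,
                    "chromosome": rep_chrom,
                    "start": starts,
                    "end": starts + sizes,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["frag_idx", "chromosome", "start", "end"])
    return pd.concat(parts, ignore_index=True)


def fragment_blocks(row: pd.Series) -> list[Interval]:
    """Block intervals of a single fragment-table row.

    Single-block rows may carry empty block strings; the block is then
    simply ``[start, end)``.
    """
    s0 = int(row["start"])
    sizes = [int(x) for x in str(row["block_sizes"]).split(",") if x != ""]
    offs = [int(x) for x in str(row["block_starts"]).split(",") if x != ""]
    if not sizes:
        return [(s0, int(row["end"]))]
    return [(s0 + o, s0 + o + sz) for sz, o in zip(sizes, offs)]
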