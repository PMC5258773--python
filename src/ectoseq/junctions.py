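"""Splice-junction evidence for annotated 5'UTR exons.

Split fragments (multi-block records) witness splice junctions: each
gap between adjacent blocks is one junction (end of block i, start of
block i+1).  Fragments spanning the junction between a non-coding
upstream exon and the coding exon are in-silico evidence that the
annotated transcript structure — not merely the ORF — is expressed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, fragment_blocks

JUNCTION_COLUMNS = ["sample_id", "chromosome", "donor", "acceptor", "count"]


def extract_junctions(fragments: pd.DataFrame) -> pd.DataFrame:
    """Tally junctions from split fragments, per sample.

    Returns a table with columns sample_id, chromosome, donor,
    acceptor, count, where donor < acceptor are the genomic gap
    boundaries (strand-agnostic storage).
    """
    multi = fragments[fragments["block_count"] > 1].reset_index(drop=True)
    if not len(multi):
        return pd.DataFrame(columns=JUNCTION_COLUMNS)
    from .models import expand_blocks

    blocks = expand_blocks(multi)  # row-major: blocks of a fragment are adjacent
    fi = blocks["frag_idx"].to_numpy()
    same = fi[1:] == fi[:-1]
    donor = blocks["end"].to_numpy()[:-1][same]
    acceptor = blocks["start"].to_numpy()[1:][same]
    owner = fi[1:][same]
    tab = (
        pd.DataFrame(
            {
                "sample_id": multi["sample_id"].to_numpy()[owner],
                "chromosome": multi["chromosome"].to_numpy()[owner],
                "donor": donor,
                "acceptor": acceptor,
            }
        )
        .groupby(["sample_id", "chromosome", "donor", "acceptor"])
        .size()
        .reset_index(name="count")
    )
    return tab[JUNCTION_COLUMNS]


def annotated_utr_introns(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Annotated introns whose (strand-aware) upstream exon is fully
    non-coding and downstream exon contains ORF sequence."""
    rows = []
    for g in genes:
        if g.cds is None:
            continue
        lo, hi = g.cds
        for tx in g.transcripts:
            for (s0, e0), (s1, e1) in zip(tx, tx[1:]):
                left_coding = max(s0, lo) < min(e0, hi)
                right_coding = max(s1, lo) < min(e1, hi)
                if g.strand == "+":
                    upstream_nc, downstream_cds = not left_coding, right_coding
                else:
                    upstream_nc, downstream_cds = not right_coding, left_coding
                if upstream_nc and downstream_cds:
                    rows.append((g.gene_id, g.chromosome, g.strand, e0, s1))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "strand", "donor", "acceptor"]
    ).drop_duplicates(ignore_index=True)


def support_annotated_utr(
    junctions: pd.DataFrame,
    genes: Sequence[GeneModel],
    min_count: int = 2,
) -> pd.DataFrame:
    """Spanning-fragment support for each annotated 5'UTR junction.

    Counts are summed over samples (a junction observed in any sample
    counts; the per-sample breakdown remains in ``junctions``).
    Returns gene_id, chromosome, donor, acceptor, n_spanning_fragments,
    annotated (always True here) and supported (count >= min_count).
    """
    introns = annotated_utr_introns(genes)
    if not len(introns):
        return pd.DataFrame(
            columns=[
                "gene_id",
                "chromosome",
                "donor",
                "acceptor",
                "n_spanning_fragments",
                "annotated",
                "supported",
            ]
        )
    if len(junctions):
        pooled = (
            junctions.groupby(["chromosome", "donor", "acceptor"])["count"]
            .sum()
            .reset_index()
        )
        merged = introns.merge(pooled, on=["chromosome", "donor", "acceptor"], how="left")
        merged["count"] = merged["count"].fillna(0).astype(int)
    else:
        merged = introns.copy()
        merged["count"] = 0
    out = merged.rename(columns={"count": "n_spanning_fragments"})
    out["annotated"] = True
    out["supported"] = out["n_spanning_fragments"] >= min_count
    return out.drop(columns=["strand"])


def novel_junctions(
    junctions: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Observed junctions not matching any annotated intron (reported
    only; no call is based on them)."""
    annotated = set()
    for g in genes:
        for tx in g.transcripts:
            for (s0, e0), (s1, e1) in zip(tx, tx[1:]):
                annotated.add((g.chromosome, e0, s1))
    if not len(junctions):
        return junctions.copy()
    key = list(zip(junctions["chromosome"], junctions["donor"], junctions["acceptor"]))
    mask = [k not in annotated for k in key]
    return junctions[mask].reset_index(drop=True)


def write_junction_bed(junctions: pd.DataFrame, path, gene_ids=None) -> None:
    """6-column BED: name = geneID:donor-acceptor, score = count."""
    pooled = (
        junctions.groupby(["chromosome", "donor", "acceptor"])["count"]
        .sum()
        .reset_index()
        if "sample_id" in junctions.columns
        else junctions
    )
    with Path(path).open("w") as fh:
        for _, row in pooled.iterrows():
            gid = ""
            if gene_ids is not None:
                gid = gene_ids.get(
                    (row["chromosome"], row["donor"], row["acceptor"]), ""
                )
            name = f"{gid}:{row['donor']}-{row['acceptor']}"
            fh.write(
                f"{row['chromosome']}\t{row['donor']}\t{row['acceptor']}\t"
                f"{name}\t{int(row['count'])}\t.\n"
            )


def read_junction_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "donor", "acceptor", "name", "count", "strand"],
    )
    return df[["chromosome", "donor", "acceptor", "count"]]
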