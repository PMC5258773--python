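"""Readers and writers for the standard formats the pipeline touches.

GTF carries the annotation (1-based inclusive on disk, converted to the
package's 0-based half-open model), FASTA the genome, BED12 the aligned
fragments (score field: 1 = uniquely mapping, 0 = multi-mapping), and
optionally SAM with the NH tag encoding uniqueness (NH > 1 => multi).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import FRAGMENT_COLUMNS, GeneModel


# ---------------------------------------------------------------------------
# GTF

def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GTF (gene/transcript/exon/CDS features).

    Attributes: gene_id, transcript_id, gene_name and a custom
    ``family`` tag. Internal 0-based half-open coordinates become
    1-based inclusive on disk.
    """
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            span = g.span
            base_attr = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'family "{g.family}";'
            )
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        "ectoseq",
                        "gene",
                        str(span[0] + 1),
                        str(span[1]),
                        ".",
                        g.strand,
                        ".",
                        base_attr,
                    ]
                )
                + "\n"
            )
            for ti, exons in enumerate(g.transcripts, start=1):
                tid = f"{g.gene_id}.t{ti}"
                tattr = (
                    f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                    f'gene_name "{g.gene_name}"; family "{g.family}";'
                )
                fh.write(
                    "\t".join(
                        [
                            g.chromosome,
                            "ectoseq",
                            "transcript",
                            str(exons[0][0] + 1),
                            str(exons[-1][1]),
                            ".",
                            g.strand,
                            ".",
                            tattr,
                        ]
                    )
                    + "\n"
                )
                for s, e in exons:
                    fh.write(
                        "\t".join(
                            [
                                g.chromosome,
                                "ectoseq",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                g.strand,
                                ".",
                                tattr,
                            ]
                        )
                        + "\n"
                    )
                if g.cds is not None:
                    for s, e in exons:
                        cs, ce = max(s, g.cds[0]), min(e, g.cds[1])
                        if cs < ce:
                            fh.write(
                                "\t".join(
                                    [
                                        g.chromosome,
                                        "ectoseq",
                                        "CDS",
                                        str(cs + 1),
                                        str(ce),
                                        ".",
                                        g.strand,
                                        "0",
                                        tattr,
                                    ]
                                )
                                + "\n"
                            )


def read_gtf(path) -> list[GeneModel]:
    """Parse a GTF file into :class:`GeneModel` objects (via gffutils)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes["gene_id"][0]
        name = gene.attributes.get("gene_name", [gid])[0]
        family = gene.attributes.get("family", ["other"])[0]
        transcripts = []
        cds_lo, cds_hi = None, None
        for tx in db.children(gene, featuretype="transcript"):
            exons = sorted(
                (ex.start - 1, ex.end) for ex in db.children(tx, featuretype="exon")
            )
            if exons:
                transcripts.append(exons)
            for c in db.children(tx, featuretype="CDS"):
                lo, hi = c.start - 1, c.end
                cds_lo = lo if cds_lo is None else min(cds_lo, lo)
                cds_hi = hi if cds_hi is None else max(cds_hi, hi)
        if not transcripts:
            # single-feature gene without transcript children
            transcripts = [[(gene.start - 1, gene.end)]]
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=name,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                transcripts=transcripts,
                family=family,
                cds=None if cds_lo is None else (cds_lo, cds_hi),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED12 fragments

def write_bed12(fragments: pd.DataFrame, path) -> None:
    """Write one sample's fragments as BED12 (score 1=unique, 0=multi)."""
    frags = fragments
    n = len(frags)
    # single-block rows may carry empty block strings internally
    sizes = frags["block_sizes"].astype(str).to_numpy(dtype=object)
    offs = frags["block_starts"].astype(str).to_numpy(dtype=object)
    empty = (sizes == "") | (sizes == "nan")
    if empty.any():
        span = (frags["end"] - frags["start"]).astype(str).to_numpy(dtype=object)
        sizes = np.where(empty, span, sizes)
        offs = np.where(empty, "0", offs)
    frags = frags.assign(block_sizes=sizes, block_starts=offs)
    df = pd.DataFrame(
        {
            "chrom": frags["chromosome"].to_numpy(),
            "chromStart": frags["start"].to_numpy(),
            "chromEnd": frags["end"].to_numpy(),
            "name": [f"frag{i}" for i in range(n)],
            "score": frags["unique"].astype(int).to_numpy(),
            "strand": ["."] * n,
            "thickStart": frags["start"].to_numpy(),
            "thickEnd": frags["end"].to_numpy(),
            "itemRgb": ["0"] * n,
            "blockCount": frags["block_count"].to_numpy(),
            "blockSizes": frags["block_sizes"].to_numpy(),
            "blockStarts": frags["block_starts"].to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed12(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a BED12 fragment file; sample id defaults to the file stem."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "chrom",
            "chromStart",
            "chromEnd",
            "name",
            "score",
            "strand",
            "thickStart",
            "thickEnd",
            "itemRgb",
            "blockCount",
            "blockSizes",
            "blockStarts",
        ],
        dtype={"blockSizes": str, "blockStarts": str},
    )
    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chromosome": df["chrom"],
            "start": df["chromStart"],
            "end": df["chromEnd"],
            "block_count": df["blockCount"],
            "block_sizes": df["blockSizes"].str.rstrip(","),
            "block_starts": df["blockStarts"].str.rstrip(","),
            "unique": df["score"].astype(int) == 1,
        }
    )
    return out[FRAGMENT_COLUMNS]


# ---------------------------------------------------------------------------
# SAM fragments (optional dialect)

def write_sam(
    fragments: pd.DataFrame, path, chromosome_lengths: Mapping[str, int]
) -> None:
    """Write fragments as single-end SAM records; gaps between blocks
    become N cigar operations, uniqueness is the NH tag (1 or 2)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": int(length)}
            for name, length in chromosome_lengths.items()
        ],
    }
    ref_ids = {name: i for i, name in enumerate(chromosome_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in fragments.reset_index(drop=True).iterrows():
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"frag{i}"
            a.flag = 0
            a.reference_id = ref_ids[row["chromosome"]]
            a.reference_start = int(row["start"])
            a.mapping_quality = 255
            from .models import fragment_blocks

            blocks = fragment_blocks(row)
            s0 = blocks[0][0]
            sizes = [e - s for s, e in blocks]
            offs = [s - s0 for s, e in blocks]
            cigar = []
            for j, (sz, off) in enumerate(zip(sizes, offs)):
                if j > 0:
                    gap = off - (offs[j - 1] + sizes[j - 1])
                    if gap > 0:
                        cigar.append((3, gap))  # N
                cigar.append((0, sz))  # M
            a.cigartuples = cigar
            a.query_sequence = "N" * sum(sizes)
            a.set_tag("NH", 1 if bool(row["unique"]) else 2)
            out.write(a)


def read_sam(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read single-end SAM records into the fragment table (NH>1 => multi)."""
    import pysam

    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            blocks = rec.get_blocks()
            s0 = blocks[0][0]
            rows.append(
                {
                    "sample_id": sample_id,
                    "chromosome": rec.reference_name,
                    "start": s0,
                    "end": blocks[-1][1],
                    "block_count": len(blocks),
                    "block_sizes": ",".join(str(e - s) for s, e in blocks),
                    "block_starts": ",".join(str(s - s0) for s, e in blocks),
                    "unique": (rec.get_tag("NH") if rec.has_tag("NH") else 1) <= 1,
                }
            )
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Marker panels

def read_panel(path) -> list[str]:
    """Plain-text gene list: one name per line, '#' comments allowed."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    if not names:
        raise ValueError(f"panel file {path} contains no gene names")
    return names


def builtin_panel(name: str) -> list[str]:
    """Bundled marker panels: ``retina`` (neural retina) or ``rpe``."""
    from importlib import resources

    ref = resources.files("ectoseq").joinpath(f"data/panels/{name}.txt")
    with resources.as_file(ref) as p:
        return read_panel(p)
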