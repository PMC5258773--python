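"""Synthetic genome / annotation / aligned-fragment generator.

Produces a toy genome with known ground truth that reproduces the
statistical structure the detection pipeline assumes:

* marker genes for two tissue panels (target panel highly expressed,
  contaminant panel silent),
* a family of short single-ORF "OR-like" genes, mostly unexpressed,
* one multi-exon family gene with two alternative 5'UTR exons upstream
  of a single coding exon (split fragments span the junctions),
* a paralog pair at ~95% nucleotide identity with only one member
  expressed (substitutions at regular spacing so every fragment-sized
  window contains discriminative positions),
* a gene overlapped by an unannotated transcript producing even
  coverage across ORF and flanks, plus a matched twin with genuine
  expression at the same level,
* diffuse intergenic background fragments at a configured rate.

Per gene and sample, exonic fragment counts are Poisson with mean
``true_fpkm * exon_union_kb * library_size/1e6``; fragment starts are
uniform over the transcript and split into blocks across introns.
Abundances of the filler ("other") genes are rescaled so that
``sum(FPKM_g * L_g) = 1e9`` across the annotation — the identity real
FPKM values satisfy — which makes the configured marker/family
abundances true FPKM-scale values and FPKM recovery unbiased.

Fragments are emitted as already-aligned records; no aligner is run,
and uniqueness is a per-fragment flag (multi-mapping is simulated for
fragments lying entirely within paralog-identical segments).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import FRAGMENT_COLUMNS, GeneModel

BASES = np.frombuffer(b"ACGT", dtype="S1")


class PlacementError(RuntimeError):
    """Raised when gene placement on a chromosome is infeasible."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults emulate a three-replicate bulk RNA-seq design with a
    scaled-down receptor family: 20 OR-like genes of which 8 are truly
    expressed, one million fragments per sample, and diffuse intergenic
    background at 0.5 fragments/kb.
    """

    genome_size: int = 2_000_000
    n_chromosomes: int = 2
    n_marker_genes: int = 21
    n_or_genes: int = 20
    n_other_genes: int = 40
    fraction_or_expressed: float = 0.4
    #: FPKM-scale abundance grid cycled over the filler genes (rescaled,
    #: see module docstring).
    expression_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    #: True FPKM values cycled over the expressed family genes.
    or_expression_grid: Sequence[float] = (6.0, 9.0, 13.0, 18.0)
    #: True FPKM values cycled over target-panel marker genes.
    marker_expression_grid: Sequence[float] = (3300.0, 1000.0, 500.0, 200.0, 100.0)
    library_size: int = 1_000_000
    n_samples: int = 3
    intergenic_noise_rate: float = 0.5  # fragments per intergenic kb
    paralog_identity: float = 0.95
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    min_fragment_length: int = 30
    #: Apparent FPKM the unannotated overlapping transcript confers on
    #: the overlapped gene (and true FPKM of its matched twin).
    overlap_apparent_fpkm: float = 5.0
    overlap_flank_bp: int = 5000
    #: Gamma-Poisson over-dispersion (1/size); None = pure Poisson.
    overdispersion: Optional[float] = None
    #: Rescale filler abundances so sum(FPKM*L) = 1e9 (see module doc).
    normalize_fpkm_scale: bool = True
    seed: int = 0

    # structural constants of the toy gene models
    or_orf_length: int = 930
    utr_exon_length: int = 150
    marker_exon_length: int = 1000
    marker_intron_length: int = 400
    other_exon_length: int = 2000

    def validate(self) -> None:
        if self.genome_size <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_size and n_chromosomes must be positive")
        for name in ("n_marker_genes", "n_or_genes", "n_other_genes", "n_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_or_expressed <= 1.0:
            raise ValueError("fraction_or_expressed must be in [0, 1]")
        if any(v < 0 for v in self.expression_grid):
            raise ValueError("expression_grid values must be >= 0")
        if not 0.0 < self.paralog_identity <= 1.0:
            raise ValueError("paralog_identity must be in (0, 1]")
        if self.n_or_genes and self.n_or_genes < 4:
            raise ValueError(
                "n_or_genes must be 0 or >= 4 (paralog pair + 5'UTR gene + spares)"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class GroundTruth:
    """Known truth of a simulated dataset."""

    #: genes x samples true FPKM-scale abundance
    abundance: pd.DataFrame
    paralog_pair: tuple[str, str] = ("", "")
    expressed_paralog: str = ""
    overlap_gene: str = ""
    overlap_twin: str = ""
    #: (chromosome, start, end) of the unannotated overlapping transcript
    overlap_region: Optional[tuple[str, int, int]] = None
    utr_gene: str = ""
    #: (chromosome, donor, acceptor) of each true 5'UTR junction
    utr_junctions: list[tuple[str, int, int]] = field(default_factory=list)
    expressed_or_genes: list[str] = field(default_factory=list)
    #: gene_id -> sorted genomic positions where the paralogs differ
    paralog_discriminative: dict[str, np.ndarray] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        roles = pd.Series("", index=self.abundance.index, dtype=object)
        if self.expressed_paralog:
            roles[self.expressed_paralog] = "expressed_paralog"
            silent = [g for g in self.paralog_pair if g != self.expressed_paralog]
            for g in silent:
                roles[g] = "silent_paralog"
        if self.overlap_gene:
            roles[self.overlap_gene] = "overlap_gene"
        if self.overlap_twin:
            roles[self.overlap_twin] = "overlap_twin"
        if self.utr_gene:
            roles[self.utr_gene] = "utr_gene"
        tab = self.abundance.copy()
        tab.insert(0, "role", roles)
        tab.to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene_id")
        junc = pd.DataFrame(
            self.utr_junctions, columns=["chromosome", "donor", "acceptor"]
        )
        junc.insert(0, "gene_id", self.utr_gene)
        junc.to_csv(outdir / "truth_junctions.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation generation

def _gene_structures(config: SimulationConfig, panels: tuple[list[str], list[str]]):
    """Plan gene identities, families, structures and base abundances.

    Returns a list of dicts with keys: gene_id, gene_name, family,
    exon_lengths (per transcript), intron pattern handled by builder,
    role, abundance.
    """
    retina_names, rpe_names = panels
    plan = []
    n_ret = min(len(retina_names), (config.n_marker_genes + 1) // 2)
    n_rpe = min(len(rpe_names), config.n_marker_genes - n_ret)
    extra = config.n_marker_genes - n_ret - n_rpe
    marker_names = [(n, "marker_retina") for n in retina_names[:n_ret]]
    marker_names += [(n, "marker_rpe") for n in rpe_names[:n_rpe]]
    marker_names += [(f"MARK{i}", "marker_retina") for i in range(extra)]
    mg = list(config.marker_expression_grid)
    k_ret = 0
    for i, (name, fam) in enumerate(marker_names):
        if fam == "marker_retina":
            ab = mg[k_ret % len(mg)]
            k_ret += 1
        else:
            ab = 0.0  # contaminant panel silent by design
        plan.append(
            dict(
                gene_id=f"MRK{i + 1:03d}",
                gene_name=name,
                family=fam,
                kind="marker",
                abundance=ab,
                role="",
            )
        )

    # OR-like family: paralog pair at indices 0/1, 5'UTR gene at index 2
    n_expressed = int(round(config.fraction_or_expressed * config.n_or_genes))
    org = list(config.or_expression_grid)
    expressed_extra = max(0, n_expressed - 2)  # beyond utr gene + paralog A
    k = 0
    for i in range(config.n_or_genes):
        gid = f"OR{i + 1:03d}"
        role, ab, kind = "", 0.0, "or"
        if i == 0:
            role = "paralog_a"
            ab = 10.0 if n_expressed >= 1 else 0.0
        elif i == 1:
            role, ab = "paralog_b", 0.0
        elif i == 2:
            role, kind = "utr_gene", "or_utr"
            ab = max(org) if n_expressed >= 2 else 0.0
        elif k < expressed_extra:
            ab = org[k % len(org)]
            k += 1
        plan.append(
            dict(
                gene_id=gid,
                gene_name=f"ORL{i + 1}",
                family="OR",
                kind=kind,
                abundance=ab,
                role=role,
            )
        )

    # filler genes; the first two are the overlap gene and its twin
    eg = list(config.expression_grid)
    for i in range(config.n_other_genes):
        gid = f"GEN{i + 1:03d}"
        role, ab, kind = "", 0.0, "other"
        if i == 0:
            role, kind, ab = "overlap_gene", "small_other", 0.0
        elif i == 1:
            role, kind = "overlap_twin", "small_other"
            ab = config.overlap_apparent_fpkm
        else:
            ab = eg[(i - 2) % len(eg)] if eg else 0.0
        plan.append(
            dict(
                gene_id=gid,
                gene_name=f"GENE{i + 1}",
                family="other",
                kind=kind,
                abundance=ab,
                role=role,
            )
        )
    return plan


def _build_gene(entry, chrom, start, strand, config: SimulationConfig) -> GeneModel:
    """Materialize one planned gene at a genomic start position."""
    kind = entry["kind"]
    if kind == "marker":
        L, I = config.marker_exon_length, config.marker_intron_length
        exons = [(start, start + L), (start + L + I, start + 2 * L + I)]
        transcripts = [exons]
        cds = (exons[0][0], exons[-1][1])
    elif kind == "or":
        exons = [(start, start + config.or_orf_length)]
        transcripts = [exons]
        cds = exons[0]
    elif kind == "or_utr":
        u, orf = config.utr_exon_length, config.or_orf_length
        if strand == "+":
            utr1 = (start, start + u)
            utr2 = (start + u + 300, start + 2 * u + 300)
            cds = (utr2[1] + 150, utr2[1] + 150 + orf)
        else:
            cds = (start, start + orf)
            utr2 = (cds[1] + 150, cds[1] + 150 + u)
            utr1 = (utr2[1] + 300, utr2[1] + 300 + u)
        transcripts = [sorted([utr1, cds]), sorted([utr2, cds])]
    elif kind == "small_other":
        exons = [(start, start + config.or_orf_length)]
        transcripts = [exons]
        cds = exons[0]
    else:
        exons = [(start, start + config.other_exon_length)]
        transcripts = [exons]
        cds = (exons[0][0], exons[-1][1])
    return GeneModel(
        gene_id=entry["gene_id"],
        gene_name=entry["gene_name"],
        chromosome=chrom,
        strand=strand,
        transcripts=transcripts,
        family=entry["family"],
        cds=cds,
    )


def _gene_span_length(entry, config: SimulationConfig) -> int:
    kind = entry["kind"]
    if kind == "marker":
        return 2 * config.marker_exon_length + config.marker_intron_length
    if kind in ("or", "small_other"):
        return config.or_orf_length
    if kind == "or_utr":
        return 2 * config.utr_exon_length + 300 + 150 + config.or_orf_length
    return config.other_exon_length


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Generate (genes, genome, truth) for a simulation config.

    Genes are placed non-overlapping with intergenic gaps of at least
    ``overlap_flank_bp + 1000`` bp; the designed overlap is carried by
    an *unannotated* transcript region recorded in the ground truth,
    not by a second annotated gene.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    from .io import builtin_panel

    plan = _gene_structures(config, (builtin_panel("retina"), builtin_panel("rpe")))
    chrom_len = config.genome_size // config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # shuffle placement order, round-robin over chromosomes
    order = rng.permutation(len(plan))
    per_chrom: dict[str, list] = {c: [] for c in chrom_names}
    for j, idx in enumerate(order):
        per_chrom[chrom_names[j % config.n_chromosomes]].append(plan[idx])

    min_gap = config.overlap_flank_bp + 1000
    genes: list[GeneModel] = []
    for chrom in chrom_names:
        entries = per_chrom[chrom]
        spans = [_gene_span_length(e, config) for e in entries]
        need = sum(spans) + (len(entries) + 1) * min_gap
        if need > chrom_len:
            raise PlacementError(
                f"cannot place {len(entries)} genes on {chrom}: "
                f"need {need} bp, have {chrom_len} bp"
            )
        slack = chrom_len - need
        # distribute the slack over the n+1 gaps
        w = rng.dirichlet(np.ones(len(entries) + 1)) if entries else np.array([1.0])
        extra = np.floor(w * slack).astype(int)
        pos = 0
        for e, span, ex in zip(entries, spans, extra[:-1]):
            pos += min_gap + int(ex)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_build_gene(e, chrom, pos, strand, config))
            pos += span
    genes.sort(key=lambda g: (g.chromosome, g.span[0]))

    exonic = sum(g.exon_union_length for g in genes)
    if exonic * 2 > config.genome_size:
        raise PlacementError(
            f"total exonic span {exonic} exceeds half the genome "
            f"({config.genome_size} bp)"
        )

    # genome sequence
    genome_arr = {
        c: rng.integers(0, 4, size=chrom_len, dtype=np.int8) for c in chrom_names
    }
    by_id = {g.gene_id: g for g in genes}
    plan_by_id = {e["gene_id"]: e for e in plan}

    # paralog pair: copy A's ORF into B's locus with substitutions at
    # regular spacing so every window holds discriminative positions
    truth = GroundTruth(abundance=pd.DataFrame())
    if config.n_or_genes >= 4:
        ga, gb = by_id["OR001"], by_id["OR002"]
        if gb.strand != ga.strand:
            # duplicated genes keep a consistent ORF orientation so the
            # gapless ORF comparison is meaningful
            gb = dataclasses.replace(gb, strand=ga.strand)
            by_id["OR002"] = gb
            for i, g in enumerate(genes):
                if g.gene_id == "OR002":
                    genes[i] = gb
        a0, a1 = ga.cds
        b0, b1 = gb.cds
        fwd_a = genome_arr[ga.chromosome][a0:a1].copy()
        # ORF-orientation sequence of A
        orf_a = fwd_a if ga.strand == "+" else (3 - fwd_a)[::-1]
        spacing = max(2, int(round(1.0 / max(1e-9, 1.0 - config.paralog_identity))))
        sub_pos = np.arange(spacing // 2, len(orf_a), spacing)  # ORF coords
        orf_b = orf_a.copy()
        orf_b[sub_pos] = (orf_b[sub_pos] + 1) % 4
        fwd_b = orf_b if gb.strand == "+" else (3 - orf_b)[::-1]
        genome_arr[gb.chromosome][b0:b1] = fwd_b
        # genomic positions of the discriminative (differing) sites
        if ga.strand == "+":
            disc_a, disc_b = a0 + sub_pos, b0 + sub_pos
        else:
            disc_a, disc_b = (a1 - 1) - sub_pos, (b1 - 1) - sub_pos
        truth.paralog_pair = (ga.gene_id, gb.gene_id)
        truth.expressed_paralog = (
            ga.gene_id if plan_by_id[ga.gene_id]["abundance"] > 0 else ""
        )
        truth.paralog_discriminative = {
            ga.gene_id: np.sort(disc_a),
            gb.gene_id: np.sort(disc_b),
        }

        # 5'UTR junctions of the multi-exon gene
        gu = by_id["OR003"]
        truth.utr_gene = gu.gene_id
        for tx in gu.transcripts:
            for (s0, e0), (s1, e1) in zip(tx, tx[1:]):
                truth.utr_junctions.append((gu.chromosome, e0, s1))

    if config.n_other_genes >= 2:
        og = by_id["GEN001"]
        truth.overlap_gene = og.gene_id
        truth.overlap_twin = "GEN002"
        s, e = og.span
        truth.overlap_region = (
            og.chromosome,
            max(0, s - config.overlap_flank_bp),
            min(chrom_len, e + config.overlap_flank_bp),
        )

    # abundance table: configured values; filler genes rescaled so that
    # sum(FPKM * L) = 1e9 over the annotation
    ab = pd.Series(
        {g.gene_id: float(plan_by_id[g.gene_id]["abundance"]) for g in genes}
    )
    lengths = pd.Series({g.gene_id: g.exon_union_length for g in genes})
    if config.normalize_fpkm_scale:
        filler = [
            g.gene_id
            for g in genes
            if plan_by_id[g.gene_id]["kind"] == "other"
        ]
        fixed_mass = float((ab.drop(filler) * lengths.drop(filler)).sum())
        filler_mass = float((ab[filler] * lengths[filler]).sum())
        if filler_mass > 0 and fixed_mass < 1e9:
            ab[filler] *= (1e9 - fixed_mass) / filler_mass
    samples = [f"sample{i + 1}" for i in range(config.n_samples)]
    truth.abundance = pd.DataFrame(
        np.tile(ab.to_numpy()[:, None], (1, len(samples))),
        index=ab.index,
        columns=samples,
    )
    truth.expressed_or_genes = [
        g.gene_id for g in genes if g.family == "OR" and ab[g.gene_id] > 0
    ]

    genome = {c: arr_to_seq(a) for c, a in genome_arr.items()}
    return genes, genome, truth


def arr_to_seq(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# fragment simulation

def _transcript_layout(exons):
    starts = np.array([s for s, e in exons])
    lens = np.array([e - s for s, e in exons])
    cum = np.concatenate([[0], np.cumsum(lens)])
    return starts, lens, cum


def _fragment_lengths(n, config: SimulationConfig, rng, max_len):
    fl = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n)
    ).astype(np.int64)
    return np.clip(fl, config.min_fragment_length, max_len)


def _map_to_blocks(t0, fl, exons):
    """Map transcript-coordinate fragments (start t0, length fl) onto
    genomic blocks. Returns (start, end, count, sizes_str, starts_str)."""
    starts, lens, cum = _transcript_layout(exons)
    t1 = t0 + fl
    j0 = np.searchsorted(cum, t0, side="right") - 1
    j1 = np.searchsorted(cum, t1 - 1, side="right") - 1
    g_start = starts[j0] + (t0 - cum[j0])
    g_end = starts[j1] + (t1 - cum[j1])
    n = len(t0)
    out_start = g_start
    out_end = g_end
    bc = (j1 - j0 + 1).astype(np.int64)
    sizes = np.empty(n, dtype=object)
    offs = np.empty(n, dtype=object)
    single = bc == 1
    if single.any():
        # single-block rows carry empty block strings (block = [start, end))
        sizes[single] = ""
        offs[single] = ""
    for combo in np.unique(np.stack([j0[~single], j1[~single]]), axis=1).T if (~single).any() else []:
        a, b = int(combo[0]), int(combo[1])
        m = (j0 == a) & (j1 == b)
        # first block: tail of exon a; middle: full exons; last: head of exon b
        first = (starts[a] + lens[a]) - g_start[m]
        parts_sizes = [first]
        parts_offs = [np.zeros(m.sum(), dtype=np.int64)]
        for mid in range(a + 1, b):
            parts_sizes.append(np.full(m.sum(), lens[mid]))
            parts_offs.append(starts[mid] - g_start[m])
        parts_sizes.append(g_end[m] - starts[b])
        parts_offs.append(starts[b] - g_start[m])
        size_mat = np.stack(parts_sizes, axis=1)
        off_mat = np.stack(parts_offs, axis=1)
        joined_sizes = [",".join(map(str, row)) for row in size_mat]
        joined_offs = [",".join(map(str, row)) for row in off_mat]
        sizes[m] = joined_sizes
        offs[m] = joined_offs
    return out_start, out_end, bc, sizes, offs


def _draw_counts(mu: float, config: SimulationConfig, rng) -> int:
    if mu <= 0:
        return 0
    if config.overdispersion:
        size = 1.0 / config.overdispersion
        lam = rng.gamma(size, mu / size)
        return int(rng.poisson(lam))
    return int(rng.poisson(mu))


def intergenic_intervals(
    genes: Sequence[GeneModel], chromosome_lengths: dict[str, int], buffer_bp: int = 0
) -> dict[str, list[tuple[int, int]]]:
    """Complement of gene spans (padded by ``buffer_bp``) per chromosome."""
    from .models import merge_intervals

    spans: dict[str, list] = {c: [] for c in chromosome_lengths}
    for g in genes:
        s, e = g.span
        spans.setdefault(g.chromosome, []).append(
            (max(0, s - buffer_bp), min(chromosome_lengths[g.chromosome], e + buffer_bp))
        )
    out = {}
    for c, length in chromosome_lengths.items():
        free, pos = [], 0
        for s, e in merge_intervals(spans.get(c, [])):
            if s > pos:
                free.append((pos, s))
            pos = max(pos, e)
        if pos < length:
            free.append((pos, length))
        out[c] = free
    return out


def simulate_fragments(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate aligned fragments for every sample.

    Returns ``(fragments, drawn_counts)``: the fragment table
    (coordinate-sorted within each sample) and the genes x samples
    matrix of exonic counts actually drawn (the simulator's own record,
    used by exact-recovery tests).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom_lengths = _chrom_lengths_from_config(config)
    samples = list(truth.abundance.columns)
    by_id = {g.gene_id: g for g in genes}
    drawn = pd.DataFrame(0, index=truth.abundance.index, columns=samples, dtype=np.int64)

    disc_by_chrom: dict[str, np.ndarray] = {}
    for gid, pos in truth.paralog_discriminative.items():
        c = by_id[gid].chromosome
        disc_by_chrom[c] = np.sort(
            np.concatenate([disc_by_chrom.get(c, np.empty(0, dtype=np.int64)), pos])
        )

    inter = intergenic_intervals(genes, chrom_lengths, buffer_bp=0)
    frames = []
    for s in samples:
        parts = []
        for g in genes:
            a = float(truth.abundance.at[g.gene_id, s])
            if a <= 0:
                continue
            mu = a * (g.exon_union_length / 1e3) * (config.library_size / 1e6)
            n = _draw_counts(mu, config, rng)
            drawn.at[g.gene_id, s] = n
            if n == 0:
                continue
            tx_idx = rng.integers(0, len(g.transcripts), size=n)
            for ti in range(len(g.transcripts)):
                m = int((tx_idx == ti).sum())
                if m == 0:
                    continue
                exons = g.transcripts[ti]
                tlen = sum(e - s0 for s0, e in exons)
                fl = _fragment_lengths(m, config, rng, tlen)
                t0 = rng.integers(0, tlen - fl + 1)
                st, en, bc, sizes, offs = _map_to_blocks(t0, fl, exons)
                uniq = np.ones(m, dtype=bool)
                disc = disc_by_chrom.get(g.chromosome)
                if disc is not None and g.gene_id in truth.paralog_pair:
                    # multi-mapping iff the fragment covers no position
                    # where the paralogs differ
                    lo = np.searchsorted(disc, st)
                    hi = np.searchsorted(disc, en)
                    uniq = hi > lo
                parts.append(
                    pd.DataFrame(
                        {
                            "sample_id": s,
                            "chromosome": g.chromosome,
                            "start": st,
                            "end": en,
                            "block_count": bc,
                            "block_sizes": sizes,
                            "block_starts": offs,
                            "unique": uniq,
                        }
                    )
                )

        # unannotated overlapping transcript: uniform single-block
        # fragments across the recorded region
        if truth.overlap_region is not None and config.overlap_apparent_fpkm > 0:
            c, r0, r1 = truth.overlap_region
            rate = config.overlap_apparent_fpkm * config.library_size / 1e9
            span = max(0, (r1 - r0) - int(config.fragment_length_mean))
            n_ov = rng.poisson(rate * span)
            if n_ov:
                fl = _fragment_lengths(n_ov, config, rng, r1 - r0)
                st = r0 + rng.integers(0, np.maximum(1, (r1 - r0) - fl + 1))
                parts.append(
                    pd.DataFrame(
                        {
                            "sample_id": s,
                            "chromosome": c,
                            "start": st,
                            "end": st + fl,
                            "block_count": 1,
                            "block_sizes": "",
                            "block_starts": "",
                            "unique": True,
                        }
                    )
                )

        # diffuse intergenic noise
        if config.intergenic_noise_rate > 0:
            for c, ivs in inter.items():
                usable = [
                    (s0, e0) for s0, e0 in ivs
                    if e0 - s0 > config.min_fragment_length
                ]
                if not usable:
                    continue
                total = sum(e0 - s0 for s0, e0 in usable)
                n_noise = rng.poisson(config.intergenic_noise_rate * total / 1e3)
                if n_noise == 0:
                    continue
                w = np.array([e0 - s0 for s0, e0 in usable], dtype=float)
                pick = rng.choice(len(usable), size=n_noise, p=w / w.sum())
                iv_s = np.array([usable[i][0] for i in pick])
                iv_e = np.array([usable[i][1] for i in pick])
                fl = _fragment_lengths(
                    n_noise, config, rng, int(config.fragment_length_mean * 3)
                )
                fl = np.minimum(fl, iv_e - iv_s)
                st = iv_s + rng.integers(0, np.maximum(1, (iv_e - iv_s) - fl + 1))
                parts.append(
                    pd.DataFrame(
                        {
                            "sample_id": s,
                            "chromosome": c,
                            "start": st,
                            "end": st + fl,
                            "block_count": 1,
                            "block_sizes": "",
                            "block_starts": "",
                            "unique": True,
                        }
                    )
                )

        if parts:
            frame = pd.concat(parts, ignore_index=True)
            frame = frame.sort_values(
                ["chromosome", "start", "end"], kind="mergesort"
            ).reset_index(drop=True)
            frames.append(frame)
    if frames:
        fragments = pd.concat(frames, ignore_index=True)[FRAGMENT_COLUMNS]
    else:
        fragments = pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return fragments, drawn


def _chrom_lengths_from_config(config: SimulationConfig) -> dict[str, int]:
    chrom_len = config.genome_size // config.n_chromosomes
    return {f"chr{i + 1}": chrom_len for i in range(config.n_chromosomes)}


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    genome: dict[str, str]
    truth: GroundTruth
    fragments: pd.DataFrame
    drawn_counts: pd.DataFrame

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None, **overrides
) -> SimulatedDataset:
    """One-call simulation: annotation + genome + fragments + truth."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    genes, genome, truth = generate_annotation(config, rng)
    fragments, drawn = simulate_fragments(genes, truth, config, rng)
    return SimulatedDataset(config, genes, genome, truth, fragments, drawn)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write genome (FASTA), annotation (GTF), per-sample fragments
    (BED12) and the ground-truth manifest (TSV) to a directory."""
    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(ds.genome, outdir / "genome.fa")
    eio.write_gtf(ds.genes, outdir / "annotation.gtf")
    for s, sub in ds.fragments.groupby("sample_id", sort=True):
        eio.write_bed12(sub, outdir / f"{s}.bed")
    ds.truth.write(outdir)
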