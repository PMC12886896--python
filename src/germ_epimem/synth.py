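"""Synthetic genomes, annotations, ChIP libraries, 22G FASTQ and count matrices.

Every generator is a pure function of its parameters including the seed,
and every planted effect is recorded in a :class:`SyntheticTruth` so that
downstream stages can be tested for parameter recovery.  The generators
emulate the structure of a two-genotype worm chromatin study: IP/input
ChIP libraries with Gaussian TSS-localized enrichment and a planted subset
of genes gaining signal in the mutant; small-RNA libraries dominated by
21-23 nt 5'-G antisense reads with planted per-gene up/down effects; and
negative-binomial count matrices for generic differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from germ_epimem.core_io import (
    CountMatrix,
    Gene,
    Genome,
    GenomeAnnotation,
    GenomicInterval,
    ReadSet,
    SmallRNARead,
    tss_of,
)

__all__ = [
    "SyntheticTruth",
    "ChipSimParams",
    "simulate_genome",
    "simulate_annotation",
    "simulate_chip_library",
    "simulate_smallrna_fastq",
    "simulate_count_matrix",
]

GENOTYPES = ("wild_type", "mutant")
ROLES = ("IP", "input")


def _rng_for(seed: int, *context) -> np.random.Generator:
    """Independent generator for (seed, context...) via SeedSequence spawning.

    String context entries are folded in through their UTF-8 bytes so that
    e.g. (seed, "mutant", "IP", 1) and (seed, "wild_type", "input", 1)
    yield unrelated streams.
    """
    entropy: list[int] = [seed]
    for item in context:
        if isinstance(item, str):
            entropy.extend(item.encode())
        else:
            entropy.append(int(item))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SyntheticTruth:
    """Planted effects of a synthetic scenario, keyed by gene id.

    ``enriched_genes`` maps gene id -> H3K4me3 fold multiplier applied in
    the mutant IP; ``sr_up_genes`` / ``sr_down_genes`` map gene id ->
    planted 22G log2 fold-change (positive / negative); ``de_genes`` maps
    feature id -> planted mRNA log2 fold-change.  ``sr_valid_counts``
    records, per emitted small-RNA library, the exact number of reads that
    pass the 22G class filter and the per-gene tallies.
    """

    enriched_genes: dict[str, float] = field(default_factory=dict)
    sr_up_genes: dict[str, float] = field(default_factory=dict)
    sr_down_genes: dict[str, float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    sr_valid_counts: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sr_up_genes) & set(self.sr_down_genes):
            raise ValueError("a gene cannot be both 22G-up and 22G-down")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, mult in self.enriched_genes.items():
            rows.append({"gene_id": gid, "effect": "h3k4me3_gain", "value": mult})
        for gid, lfc in self.sr_up_genes.items():
            rows.append({"gene_id": gid, "effect": "sr22g_up", "value": lfc})
        for gid, lfc in self.sr_down_genes.items():
            rows.append({"gene_id": gid, "effect": "sr22g_down", "value": lfc})
        for gid, lfc in self.de_genes.items():
            rows.append({"gene_id": gid, "effect": "mrna_de", "value": lfc})
        return pd.DataFrame(rows, columns=["gene_id", "effect", "value"])

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SyntheticTruth":
        truth = cls()
        for _, row in frame.iterrows():
            target = {
                "h3k4me3_gain": truth.enriched_genes,
                "sr22g_up": truth.sr_up_genes,
                "sr22g_down": truth.sr_down_genes,
                "mrna_de": truth.de_genes,
            }[row["effect"]]
            target[row["gene_id"]] = float(row["value"])
        return truth

    @classmethod
    def load_tsv(cls, path) -> "SyntheticTruth":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class ChipSimParams:
    """Parameters of the ChIP library generator.

    ``depth`` is the input-library size; IP libraries are the sum of a
    Poisson background (``background_rate`` expected reads per bp) and
    per-gene Poisson peak reads placed Gaussian around the TSS with sd
    ``peak_width``.  ``baseline_peak_height`` is the expected number of
    peak reads per gene, multiplied by the gene's truth multiplier in the
    mutant IP.
    """

    n_replicates: int = 2
    depth: int = 200_000
    peak_width: float = 150.0
    background_rate: float = 0.1
    baseline_peak_height: float = 300.0
    mutant_multiplier: float = 3.0
    fragment_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_replicates",
            "depth",
            "peak_width",
            "background_rate",
            "baseline_peak_height",
            "fragment_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mutant_multiplier < 1:
            raise ValueError("mutant_multiplier must be >= 1")


def simulate_genome(n_chrom: int, chrom_length: int, seed: int) -> Genome:
    """Uniform i.i.d. A/C/G/T chromosomes named chrI, chrII, ..."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    rng = _rng_for(seed, "genome")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    names = _roman_names(n_chrom)
    sequences = {}
    for name in names:
        draw = rng.integers(0, 4, size=chrom_length)
        sequences[name] = bases[draw].tobytes().decode("ascii")
    return Genome(sequences)


def _roman_names(n: int) -> list[str]:
    numerals = []
    for i in range(1, n + 1):
        value, out = i, ""
        for arabic, roman in (
            (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I"),
        ):
            while value >= arabic:
                out += roman
                value -= arabic
        numerals.append(f"chr{out}")
    return numerals


def simulate_annotation(
    genome: Genome,
    n_genes: int,
    gene_length: int = 500,
    spacing: int = 1000,
    seed: int = 0,
) -> GenomeAnnotation:
    """Lay out non-overlapping single-exon genes with random strands.

    Genes are distributed over chromosomes proportionally to capacity;
    within each chromosome a gene occupies a random offset inside its
    (gene_length + spacing) slot, so TSS positions are irregular but
    collision-free.
    """
    slot = gene_length + spacing
    capacity = {c: length // slot for c, length in genome.lengths.items()}
    total_capacity = sum(capacity.values())
    if n_genes > total_capacity:
        raise ValueError(
            f"cannot place {n_genes} genes of {gene_length} bp with {spacing} bp "
            f"spacing: capacity is {total_capacity}"
        )
    rng = _rng_for(seed, "annotation")
    # round-robin assignment over chromosomes in genome order
    chrom_of: list[str] = []
    remaining = dict(capacity)
    chroms = list(genome.lengths)
    ci = 0
    while len(chrom_of) < n_genes:
        chrom = chroms[ci % len(chroms)]
        if remaining[chrom] > 0:
            chrom_of.append(chrom)
            remaining[chrom] -= 1
        ci += 1
    genes: list[Gene] = []
    used = {c: 0 for c in chroms}
    for i, chrom in enumerate(chrom_of):
        slot_index = used[chrom]
        used[chrom] += 1
        offset = int(rng.integers(0, spacing + 1))
        start = slot_index * slot + offset
        strand = "+" if rng.random() < 0.5 else "-"
        interval = GenomicInterval(chrom, start, start + gene_length, strand)
        genes.append(
            Gene(gene_id=f"g{i:04d}", interval=interval, exons=[interval])
        )
    return GenomeAnnotation(genes)


def simulate_chip_library(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    params: ChipSimParams,
    genome: Genome,
    genotype: str,
    role: str,
    replicate: int,
) -> ReadSet:
    """One ChIP library: uniform input, or background + TSS-peaked IP.

    IP peak reads for a gene have expected count baseline_peak_height
    times the truth multiplier (mutant genotype only); read 5' positions
    are drawn Normal(TSS, peak_width) and clipped to the chromosome;
    strands are random.  Deterministic for fixed
    (params.seed, genotype, role, replicate).
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    rng = _rng_for(params.seed, "chip", genotype, role, replicate)
    lengths = genome.lengths
    chroms = list(lengths)
    chrom_len = np.array([lengths[c] for c in chroms], dtype=np.int64)
    total = int(chrom_len.sum())

    chrom_col: list[str] = []
    pos_parts: list[np.ndarray] = []
    if role == "input":
        # uniform positions over the concatenated genome
        flat = rng.integers(0, total, size=params.depth)
        bounds = np.cumsum(chrom_len)
        which = np.searchsorted(bounds, flat, side="right")
        offset = flat - np.concatenate(([0], bounds[:-1]))[which]
        for ci, chrom in enumerate(chroms):
            sel = which == ci
            if sel.any():
                chrom_col.extend([chrom] * int(sel.sum()))
                pos_parts.append(offset[sel])
    else:
        n_bg = rng.poisson(params.background_rate * total)
        flat = rng.integers(0, total, size=n_bg)
        bounds = np.cumsum(chrom_len)
        which = np.searchsorted(bounds, flat, side="right")
        offset = flat - np.concatenate(([0], bounds[:-1]))[which]
        for ci, chrom in enumerate(chroms):
            sel = which == ci
            if sel.any():
                chrom_col.extend([chrom] * int(sel.sum()))
                pos_parts.append(offset[sel])
        for gene in annotation:
            chrom, tss = tss_of(gene)
            expect = params.baseline_peak_height
            if genotype == "mutant" and gene.gene_id in truth.enriched_genes:
                expect *= truth.enriched_genes[gene.gene_id]
            n_peak = rng.poisson(expect)
            if n_peak == 0:
                continue
            pos = np.rint(rng.normal(tss, params.peak_width, size=n_peak)).astype(np.int64)
            pos = np.clip(pos, 0, lengths[chrom] - 1)
            chrom_col.extend([chrom] * n_peak)
            pos_parts.append(pos)
    pos5 = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=np.int64)
    strand = np.where(rng.random(len(pos5)) < 0.5, "+", "-")
    reads = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos5": pos5,
            "strand": strand,
            "length": np.full(len(pos5), 50, dtype=np.int64),
        }
    )
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------


def _g_start_positions(genome: Genome, gene: Gene, k: int) -> np.ndarray:
    """Exon start offsets where the antisense k-mer naturally begins with G.

    An antisense read to a template window [s, s+k) is the reverse
    complement of the forward strand there when the gene is on '+'
    (requiring base C at s+k-1), and the forward sequence itself when the
    gene is on '-' (requiring base G at s).
    """
    seq = genome.sequences[gene.interval.chrom]
    out = []
    for exon in gene.exons:
        if len(exon) < k:
            continue
        window = np.frombuffer(seq[exon.start : exon.end].encode(), dtype=np.uint8)
        if gene.interval.strand == "+":
            ok = window[k - 1 :] == ord("C")
        else:
            ok = window[: len(window) - k + 1] == ord("G")
        out.append(exon.start + np.flatnonzero(ok))
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


def _antisense_read(genome: Genome, gene: Gene, start: int, k: int) -> str:
    from germ_epimem.smallrna import revcomp

    seq = genome.sequences[gene.interval.chrom][start : start + k]
    return revcomp(seq) if gene.interval.strand == "+" else seq


def simulate_smallrna_fastq(
    genome: Genome,
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    n_reads: int,
    frac_valid: float = 0.8,
    seed: int = 0,
    genotype: str = "wild_type",
    library_label: str | None = None,
) -> tuple[list[SmallRNARead], pd.Series]:
    """Emit a small-RNA library with an exactly bookkept valid-22G subset.

    Each read is independently valid with probability ``frac_valid``.
    Valid reads are 21-23 nt antisense reads over exons of genes sampled
    proportionally to lognormal per-gene abundances (truth sr_up/sr_down
    log2 multipliers applied for the mutant genotype), with the 5' base
    naturally G where the template allows, otherwise overwritten and
    flagged ``|forcedG`` in the read id.  Invalid reads violate the class
    rule by construction (wrong length, or 21-23 nt with a non-G start).

    Returns (reads, per-gene valid counts); the counts (plus the total)
    are also recorded in ``truth.sr_valid_counts`` under ``library_label``.
    """
    if not (0 <= frac_valid <= 1):
        raise ValueError("frac_valid must be in [0, 1]")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if any(not g.exons for g in annotation):
        raise ValueError("annotation has genes without exons")
    rng = _rng_for(seed, "smallrna", genotype)
    gene_ids = annotation.gene_ids
    # per-gene base abundances are a property of the scenario, drawn from
    # the truth params seed so every library shares them
    abund_rng = _rng_for(int(truth.params.get("seed", 0)), "sr_abundance")
    base_abund = abund_rng.lognormal(mean=0.0, sigma=0.5, size=len(gene_ids))
    weights = base_abund.copy()
    if genotype == "mutant":
        for i, gid in enumerate(gene_ids):
            if gid in truth.sr_up_genes:
                weights[i] *= 2.0 ** truth.sr_up_genes[gid]
            elif gid in truth.sr_down_genes:
                weights[i] *= 2.0 ** truth.sr_down_genes[gid]
    weights = weights / weights.sum()

    g_positions = {
        (gene.gene_id, k): _g_start_positions(genome, gene, k)
        for gene in annotation
        for k in (21, 22, 23)
    }
    genes_by_id = {g.gene_id: g for g in annotation}

    valid_mask = rng.random(n_reads) < frac_valid
    gene_draws = rng.choice(len(gene_ids), size=n_reads, p=weights)
    reads: list[SmallRNARead] = []
    per_gene = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=np.int64)
    for i in range(n_reads):
        gid = gene_ids[gene_draws[i]]
        gene = genes_by_id[gid]
        if valid_mask[i]:
            k = int(rng.integers(21, 24))
            candidates = g_positions[(gid, k)]
            forced = candidates.size == 0
            if forced:
                exon = gene.exons[int(rng.integers(len(gene.exons)))]
                start = int(rng.integers(exon.start, max(exon.start + 1, exon.end - k + 1)))
            else:
                start = int(candidates[rng.integers(candidates.size)])
            seq = _antisense_read(genome, gene, start, k)
            if forced:
                seq = "G" + seq[1:]
            rid = f"sr{i:06d}|{gid}" + ("|forcedG" if forced else "")
            reads.append(SmallRNARead(rid, seq))
            per_gene[gid] += 1
        else:
            # violate the class rule: wrong length, or right length, non-G start
            if rng.random() < 0.5:
                k = int(rng.choice([18, 19, 20, 24, 25]))
                start_base = None
            else:
                k = int(rng.integers(21, 24))
                start_base = "ACT"[int(rng.integers(3))]
            exon = gene.exons[int(rng.integers(len(gene.exons)))]
            start = int(rng.integers(exon.start, max(exon.start + 1, exon.end - k + 1)))
            seq = _antisense_read(genome, gene, start, k)
            if start_base is not None:
                seq = start_base + seq[1:]
            reads.append(SmallRNARead(f"sr{i:06d}|invalid", seq))
    label = library_label or f"{genotype}"
    truth.sr_valid_counts[label] = {
        "n_valid": int(per_gene.sum()),
        "per_gene": per_gene.to_dict(),
    }
    return reads, per_gene


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def simulate_count_matrix(
    n_features: int,
    groups: tuple[str, str] = ("wild_type", "mutant"),
    reps: int = 4,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    effect_log2fc: float = 0.0,
    frac_affected: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts with a planted effect in the second group.

    A ``frac_affected`` fraction of features gets mean * 2**effect_log2fc
    in group 2; dispersion 0 degenerates to Poisson.  Returns the matrix
    and a truth whose ``de_genes`` lists the affected features with their
    planted log2 fold-change.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if reps < 2:
        raise ValueError("need >= 2 replicates per group")
    rng = _rng_for(seed, "counts")
    feature_ids = [f"f{i:05d}" for i in range(n_features)]
    n_affected = int(round(frac_affected * n_features)) if effect_log2fc != 0 else 0
    affected = rng.choice(n_features, size=n_affected, replace=False) if n_affected else []
    mu = np.full((n_features, 2 * reps), base_mean, dtype=float)
    for idx in affected:
        mu[idx, reps:] = base_mean * 2.0**effect_log2fc
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    sample_ids = [f"{g}_{i + 1}" for g in groups for i in range(reps)]
    condition = {f"{g}_{i + 1}": g for g in groups for i in range(reps)}
    matrix = CountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        condition=condition,
    )
    truth = SyntheticTruth(
        de_genes={feature_ids[i]: effect_log2fc for i in affected},
        params={
            "seed": seed,
            "n_features": n_features,
            "reps": reps,
            "base_mean": base_mean,
            "dispersion": dispersion,
            "effect_log2fc": effect_log2fc,
            "frac_affected": frac_affected,
        },
    )
    return matrix, truth
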