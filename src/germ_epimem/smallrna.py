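"""22G-RNA class extraction, exact end-to-end mapping, per-gene counting.

22G-RNAs are the C. elegans secondary siRNA class, operationalized here
exactly as a read filter: 21-23 nt long with a 5' guanosine.  Kept reads
are mapped to the genome requiring a perfect end-to-end match on either
strand; multimappers (up to 100 loci) are assigned one locus uniformly at
random with a per-read seeded generator, mirroring random-multimapper
single-reporting aligner behaviour.  Counting is unstranded over exons,
with multi-gene-ambiguous alignments dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from germ_epimem.core_io import Genome, GenomeAnnotation, SmallRNARead

__all__ = [
    "Alignment",
    "FilterReport",
    "filter_22g",
    "ExactMatchIndex",
    "map_exact",
    "count_per_gene",
]

MIN_LEN, MAX_LEN = 21, 23
MAX_HITS = 100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One reported genomic locus of a read; exact match guaranteed."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_hits: int


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    too_short: int = 0
    too_long: int = 0
    non_g_start: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": ["input", "kept", "too_short", "too_long", "non_g_start"],
                "count": [
                    self.n_input,
                    self.n_kept,
                    self.too_short,
                    self.too_long,
                    self.non_g_start,
                ],
            }
        )


def filter_22g(reads: list[SmallRNARead]) -> tuple[list[SmallRNARead], FilterReport]:
    """Keep reads 21-23 nt long starting with G; report rejections by reason.

    Length is checked before the 5' base, so a 24 nt read starting with A
    counts as ``too_long``.  An N first base fails the G test.
    """
    kept: list[SmallRNARead] = []
    report = FilterReport(n_input=len(reads))
    for read in reads:
        n = len(read.sequence)
        if n < MIN_LEN:
            report.too_short += 1
        elif n > MAX_LEN:
            report.too_long += 1
        elif read.sequence[0] != "G":
            report.non_g_start += 1
        else:
            kept.append(read)
            report.n_kept += 1
    return kept, report


class ExactMatchIndex:
    """Seed-and-verify hash index over the forward strand of the genome.

    One table of fixed-length seed k-mers (default 21, the shortest 22G
    length) is built; a query looks up its seed prefix and verifies the
    full read against the genome string.  A read matches position
    (chrom, i) on ``+`` when it equals the genomic substring there, and
    on ``-`` when its reverse complement does.  Queries shorter than the
    seed fall back to a direct string scan.
    """

    def __init__(self, genome: Genome, seed_length: int = 21) -> None:
        self.genome = genome
        self.seed_length = seed_length
        table: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - seed_length + 1):
                table.setdefault(seq[i : i + seed_length], []).append((chrom, i))
        self._table = table

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        k = len(query)
        if k < self.seed_length:
            out = []
            for chrom, seq in self.genome.sequences.items():
                start = seq.find(query)
                while start != -1:
                    out.append((chrom, start))
                    start = seq.find(query, start + 1)
            return out
        hits = []
        for chrom, i in self._table.get(query[: self.seed_length], ()):
            if self.genome.sequences[chrom][i : i + k] == query:
                hits.append((chrom, i))
        return hits

    def hits(self, sequence: str) -> list[tuple[str, int, str]]:
        """All (chrom, start, strand) loci whose sequence matches exactly.

        A palindromic sequence matches the same locus on both strands and
        both are reported, as an aligner scanning both strands would.
        """
        loci = [(c, i, "+") for c, i in self._forward_hits(sequence)]
        loci += [(c, i, "-") for c, i in self._forward_hits(revcomp(sequence))]
        return loci


def map_exact(
    reads: list[SmallRNARead],
    genome: Genome,
    seed: int,
    index: ExactMatchIndex | None = None,
) -> list[Alignment]:
    """Map reads end-to-end with zero mismatches.

    Reads with no exact hit are unmapped (absent from output); reads with
    1-100 hits get exactly one alignment chosen uniformly at random by a
    generator seeded from (seed, read_id) so the choice is reproducible
    per read; reads with more than 100 hits are discarded.
    """
    if index is None:
        index = ExactMatchIndex(genome)
    alignments: list[Alignment] = []
    for read in reads:
        loci = index.hits(read.sequence)
        if not loci or len(loci) > MAX_HITS:
            continue
        if len(loci) == 1:
            chrom, start, strand = loci[0]
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, *read.read_id.encode()])
            )
            chrom, start, strand = loci[rng.integers(len(loci))]
        alignments.append(
            Alignment(
                read_id=read.read_id,
                chrom=chrom,
                start=start,
                end=start + len(read.sequence),
                strand=strand,
                n_hits=len(loci),
            )
        )
    return alignments


def count_per_gene(
    alignments: list[Alignment], annotation: GenomeAnnotation
) -> pd.Series:
    """Unstranded per-gene counts of alignments overlapping exons.

    An alignment is assigned to a gene when it overlaps >= 1 bp of any of
    its exons, regardless of strand; alignments touching exons of more
    than one gene are dropped as ambiguous.  Every gene in the annotation
    appears in the result (zero when unhit).
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene in annotation:
        if not gene.exons:
            raise ValueError(f"gene {gene.gene_id} has no exons")
        for exon in gene.exons:
            by_chrom.setdefault(exon.chrom, []).append(
                (exon.start, exon.end, gene.gene_id)
            )
    # sorted starts + the longest exon length bound the candidate range for
    # any query, turning each lookup into a searchsorted plus a short scan
    tables: dict[str, tuple[np.ndarray, list[tuple[int, int, str]], int]] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows])
        max_len = max(r[1] - r[0] for r in rows)
        tables[chrom] = (starts, rows, max_len)
    tallies: dict[str, int] = {}
    for aln in alignments:
        table = tables.get(aln.chrom)
        if table is None:
            continue
        starts, rows, max_len = table
        lo = int(np.searchsorted(starts, aln.start - max_len, side="left"))
        hi = int(np.searchsorted(starts, aln.end, side="left"))
        genes_hit = {
            gid for e0, e1, gid in rows[lo:hi] if e0 < aln.end and aln.start < e1
        }
        if len(genes_hit) == 1:
            gid = genes_hit.pop()
            tallies[gid] = tallies.get(gid, 0) + 1
    counts = pd.Series(0, index=pd.Index(annotation.gene_ids, name="gene_id"), dtype=np.int64)
    for gid, n in tallies.items():
        counts[gid] = n
    return counts
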