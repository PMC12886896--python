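"""Core data model and readers/writers for the pipeline's file formats.

Every coordinate inside the package is **0-based, half-open** ``[start, end)``
on the forward strand, the BED/bedGraph convention.  GFF3 (1-based, closed)
is converted on read and write; nothing else ever converts.  Chromosome
names are taken verbatim from the input files — no "chr" aliasing.

All text readers and writers are gzip-transparent: a path ending in ``.gz``
is opened through :mod:`gzip`.
"""

from __future__ import annotations

import gzip
import math
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-", ".")

_DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """An input file violates its format contract."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    """A reference genome: chromosome name -> uppercase DNA string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-DNA characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` with a strand in ``{+, -, .}``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Gene:
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [self.interval]
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon on different chrom/strand"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon outside gene interval"
                )


@dataclass
class GenomeAnnotation:
    """An ordered collection of genes with unique ids."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class BinnedTrack:
    """Fixed-bin numeric signal: one vector per chromosome.

    Bins tile ``[0, length)`` left to right; the last bin may be shorter
    than ``bin_size``.  ``scale`` tags the stage of normalization
    (``raw`` fragment counts, ``cpm``, or ``log2_ratio``).
    """

    bin_size: int
    values: dict[str, np.ndarray]
    scale: str = "raw"
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.scale not in ("raw", "cpm", "log2_ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, vec in self.values.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite values on {chrom}")
        if self.chrom_lengths is not None:
            for chrom, length in self.chrom_lengths.items():
                expect = math.ceil(length / self.bin_size)
                got = len(self.values[chrom])
                if got != expect:
                    raise ValueError(
                        f"{chrom}: {got} bins but ceil({length}/{self.bin_size}) = {expect}"
                    )

    def same_structure(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )


@dataclass
class EnrichmentTrack(BinnedTrack):
    """A log2-ratio track (IP/input or mutant/wild-type)."""

    numerator_label: str = "IP"
    denominator_label: str = "input"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.scale = "log2_ratio"
        super().__post_init__()


@dataclass
class ReadSet:
    """Aligned single-end reads as a table of 5' positions.

    ``reads`` has columns ``chrom`` (str), ``pos5`` (0-based 5'-end
    coordinate), ``strand`` (+/-), ``length`` (bp).
    """

    reads: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"chrom", "pos5", "strand", "length"} - set(self.reads.columns)
        if missing:
            raise ValueError(f"ReadSet missing columns: {sorted(missing)}")

    @property
    def library_size(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SmallRNARead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id}: non-DNA characters {sorted(bad)}")


class CountMatrix:
    """Integer counts, features x samples, with a condition label per sample."""

    def __init__(
        self,
        counts: pd.DataFrame,
        condition: dict[str, str] | None = None,
    ) -> None:
        if counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("negative counts")
        self.counts = counts.astype(np.int64)
        if condition is not None:
            missing = set(counts.columns) - set(condition)
            if missing:
                raise ValueError(f"samples without condition: {sorted(missing)}")
            self.condition = {s: condition[s] for s in counts.columns}
        else:
            self.condition = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.condition == other.condition
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Sequences are uppercased; the description after the first whitespace is
    dropped from the record name.  Duplicate names, empty files and
    non-DNA characters raise :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if name in sequences:
                raise FormatError(f"duplicate FASTA record name {name!r}")
            seq = str(record.seq).upper()
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"record {name!r}: non-DNA characters {sorted(bad)}"
                )
            sequences[name] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in genome.sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _gff3_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff3(path, biotype_filter: str | None = "protein_coding") -> GenomeAnnotation:
    """Parse gene and exon features from a GFF3 file.

    Coordinates (1-based closed) are converted to the internal 0-based
    half-open convention.  Genes are kept when their ``biotype`` attribute
    matches ``biotype_filter`` (pass ``None`` to keep all); exons attach to
    parents through ``ID``/``Parent``.  Exons whose parent cannot be
    resolved are skipped with a warning; a row with the wrong column count
    raises :class:`FormatError` with its line number.
    """
    import warnings

    gene_rows: dict[str, dict] = {}
    exon_rows: list[tuple[str, GenomicInterval]] = []
    order: list[str] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path} line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _, ftype, start, end, _, strand, _, attr_raw = cols
            if ftype not in ("gene", "exon"):
                continue
            try:
                interval = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            attrs = _gff3_attributes(attr_raw)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise FormatError(f"{path} line {lineno}: gene without ID")
                gene_rows[gene_id] = {
                    "interval": interval,
                    "biotype": attrs.get("biotype", attrs.get("gene_biotype", "")),
                    "exons": [],
                }
                order.append(gene_id)
            else:
                parent = attrs.get("Parent")
                if parent is None:
                    warnings.warn(f"{path} line {lineno}: exon without Parent, skipped")
                    continue
                # Parent may point at a transcript; strip to the gene id if
                # it matches, otherwise resolve later and warn on failure.
                exon_rows.append((parent, interval))
    for parent, interval in exon_rows:
        target = parent if parent in gene_rows else None
        if target is None:
            # transcript-level Parent ids of the form <gene>.<n> resolve to the gene
            stem = parent.rsplit(".", 1)[0]
            target = stem if stem in gene_rows else None
        if target is None:
            warnings.warn(f"exon with unresolvable Parent {parent!r}, skipped")
            continue
        gene_rows[target]["exons"].append(interval)
    genes = []
    for gene_id in order:
        row = gene_rows[gene_id]
        if biotype_filter is not None and row["biotype"] != biotype_filter:
            continue
        genes.append(
            Gene(
                gene_id=gene_id,
                interval=row["interval"],
                exons=sorted(row["exons"], key=lambda e: e.start),
                biotype=row["biotype"],
            )
        )
    return GenomeAnnotation(genes)


def write_gff3(annotation: GenomeAnnotation, path, source: str = "germ_epimem") -> None:
    """Write genes and exons as GFF3 (converting back to 1-based closed)."""
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for gene in annotation:
            iv = gene.interval
            handle.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={gene.gene_id};biotype={gene.biotype}\n"
            )
            for i, exon in enumerate(gene.exons, start=1):
                handle.write(
                    f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\tID={gene.gene_id}.e{i};Parent={gene.gene_id}\n"
                )


def tss_of(gene: Gene) -> tuple[str, int]:
    """0-based position of the first transcribed base of a gene.

    The gene-level TSS is the 5' end of the gene feature: ``start`` on the
    plus strand, ``end - 1`` on the minus strand.  An unstranded gene has
    no TSS and raises ``ValueError``.
    """
    iv = gene.interval
    if iv.strand == "+":
        return iv.chrom, iv.start
    if iv.strand == "-":
        return iv.chrom, iv.end - 1
    raise ValueError(f"gene {gene.gene_id} is unstranded: no TSS")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a binned track as 4-column bedGraph (0-based half-open).

    Adjacent bins with identical values are merged into one line.  Values
    are written with ``repr`` so that a write -> read round trip
    reproduces them bit-exactly.
    """
    bs = track.bin_size
    with _open_text(path, "wt") as handle:
        for chrom in track.values:
            vec = track.values[chrom]
            if track.chrom_lengths is not None:
                chrom_len = track.chrom_lengths[chrom]
            else:
                chrom_len = len(vec) * bs
            run_start = 0
            for i in range(1, len(vec) + 1):
                if i == len(vec) or vec[i] != vec[run_start]:
                    start = run_start * bs
                    end = min(i * bs, chrom_len)
                    handle.write(f"{chrom}\t{start}\t{end}\t{float(vec[run_start])!r}\n")
                    run_start = i


def read_bedgraph(path, genome_lengths: dict[str, int], bin_size: int) -> BinnedTrack:
    """Read a bedGraph into a :class:`BinnedTrack`, expanding merged runs.

    Intervals must align to the bin grid and must not overlap; positions
    not covered by any line default to 0.
    """
    values = {
        chrom: np.zeros(math.ceil(length / bin_size))
        for chrom, length in genome_lengths.items()
    }
    covered_to: dict[str, int] = {chrom: -1 for chrom in genome_lengths}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path} line {lineno}: expected 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom not in values:
                raise FormatError(f"{path} line {lineno}: unknown chromosome {chrom!r}")
            if start < covered_to[chrom]:
                raise FormatError(
                    f"{path} line {lineno}: overlapping interval on {chrom} at {start}"
                )
            if start % bin_size != 0:
                raise FormatError(
                    f"{path} line {lineno}: interval start {start} not on the {bin_size} bp grid"
                )
            covered_to[chrom] = end
            b0 = start // bin_size
            b1 = math.ceil(end / bin_size)
            values[chrom][b0:b1] = value
    return BinnedTrack(
        bin_size=bin_size, values=values, scale="raw", chrom_lengths=dict(genome_lengths)
    )


# ---------------------------------------------------------------------------
# BED6 read sets
# ---------------------------------------------------------------------------


def write_reads_bed(reads: ReadSet, path) -> None:
    """Write aligned reads as BED6 (one interval per read, score = 0)."""
    df = reads.reads
    plus = df["strand"] == "+"
    starts = np.where(plus, df["pos5"], df["pos5"] - df["length"] + 1)
    ends = np.where(plus, df["pos5"] + df["length"], df["pos5"] + 1)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": starts,
            "end": ends,
            "name": [f"r{i}" for i in range(len(df))],
            "score": 0,
            "strand": df["strand"],
        }
    )
    with _open_text(path, "wt") as handle:
        out.to_csv(handle, sep="\t", header=False, index=False)


def read_reads_bed(path) -> ReadSet:
    """Read BED6 intervals back into a :class:`ReadSet` of 5'-anchored reads."""
    df = pd.read_csv(
        _open_text(path),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: BED interval with end <= start")
    plus = df["strand"] == "+"
    reads = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos5": np.where(plus, df["start"], df["end"] - 1),
            "strand": df["strand"],
            "length": df["end"] - df["start"],
        }
    )
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path) -> list[SmallRNARead]:
    """Read a FASTQ file; sequences uppercased, qualities ignored."""
    reads: list[SmallRNARead] = []
    with _open_text(path) as handle:
        try:
            for record in SeqIO.parse(handle, "fastq"):
                reads.append(SmallRNARead(record.id, str(record.seq).upper()))
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed FASTQ after record {len(reads)}: {exc}"
            ) from exc
    return reads


def write_fastq(reads: list[SmallRNARead], path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


# ---------------------------------------------------------------------------
# TSV count matrices
# ---------------------------------------------------------------------------


def read_counts_tsv(path, condition: dict[str, str] | None = None) -> CountMatrix:
    """Read a features x samples TSV (header row of sample ids) of integer counts."""
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    float_view = df.to_numpy(dtype=float, copy=False) if df.size else np.empty((0, 0))
    try:
        as_int = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer count: {exc}") from exc
    if df.size and not np.array_equal(float_view, as_int.to_numpy(dtype=float)):
        raise FormatError(f"{path}: non-integer count values")
    return CountMatrix(as_int, condition=condition)


def write_counts_tsv(matrix: CountMatrix, path) -> None:
    with _open_text(path, "wt") as handle:
        matrix.counts.to_csv(handle, sep="\t", index_label="feature_id")
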