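"""Binned, normalized, input-corrected ChIP enrichment tracks.

The stage order mirrors standard ChIP-seq track generation: each library is
binned (10 bp default) as fragment counts, CPM-normalized individually,
replicates averaged, and only then ratioed against input — so the log2
enrichment is a ratio of replicate-mean CPM tracks.
"""

from __future__ import annotations

import math

import numpy as np

from germ_epimem.core_io import BinnedTrack, EnrichmentTrack, Genome, ReadSet

__all__ = [
    "EnrichmentTrack",
    "bin_coverage",
    "cpm_normalize",
    "mean_tracks",
    "enrichment_ratio",
    "fold_change_track",
]


def fragment_intervals(
    reads, chrom_length: int, fragment_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend reads from their 5' ends to fragments, clipped to the chromosome.

    ``reads`` is a DataFrame slice with ``pos5`` and ``strand`` columns.
    Returns (starts, ends) as half-open intervals.
    """
    pos5 = reads["pos5"].to_numpy(dtype=np.int64)
    plus = (reads["strand"] == "+").to_numpy()
    starts = np.where(plus, pos5, pos5 - fragment_length + 1)
    ends = np.where(plus, pos5 + fragment_length, pos5 + 1)
    starts = np.clip(starts, 0, chrom_length)
    ends = np.clip(ends, 0, chrom_length)
    return starts, ends


def bin_coverage(
    reads: ReadSet,
    genome: Genome,
    bin_size: int = 10,
    fragment_length: int = 200,
) -> BinnedTrack:
    """Fragment-count coverage in fixed bins.

    Each read is extended from its 5' end in its strand direction to
    ``fragment_length`` bp (clipped at chromosome edges); the fragment adds
    1 to every bin it overlaps.  Runs in O(reads + bins) via a difference
    array.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = genome.lengths
    unknown = set(reads.reads["chrom"].unique()) - set(lengths)
    if unknown:
        raise ValueError(f"reads on unknown chromosome(s): {sorted(unknown)}")
    values: dict[str, np.ndarray] = {}
    grouped = dict(iter(reads.reads.groupby("chrom", sort=False))) if len(reads.reads) else {}
    for chrom, length in lengths.items():
        n_bins = math.ceil(length / bin_size)
        diff = np.zeros(n_bins + 1)
        sub = grouped.get(chrom)
        if sub is not None and len(sub):
            starts, ends = fragment_intervals(sub, length, fragment_length)
            keep = ends > starts
            b0 = starts[keep] // bin_size
            b1 = (ends[keep] - 1) // bin_size  # last bin overlapped, inclusive
            np.add.at(diff, b0, 1.0)
            np.add.at(diff, b1 + 1, -1.0)
        values[chrom] = np.cumsum(diff[:-1])
    return BinnedTrack(
        bin_size=bin_size, values=values, scale="raw", chrom_lengths=dict(lengths)
    )


def cpm_normalize(track: BinnedTrack, library_size: int) -> BinnedTrack:
    """Scale bin values to counts-per-million of the library."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return BinnedTrack(
        bin_size=track.bin_size,
        values={c: v * 1e6 / library_size for c, v in track.values.items()},
        scale="cpm",
        chrom_lengths=track.chrom_lengths,
    )


def mean_tracks(tracks: list[BinnedTrack]) -> BinnedTrack:
    """Per-bin arithmetic mean of tracks with identical bin structure."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for other in tracks[1:]:
        if not first.same_structure(other) or first.scale != other.scale:
            raise ValueError("tracks differ in bin structure or scale")
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.values
    }
    return BinnedTrack(
        bin_size=first.bin_size,
        values=values,
        scale=first.scale,
        chrom_lengths=first.chrom_lengths,
    )


def enrichment_ratio(
    ip: BinnedTrack,
    input_: BinnedTrack,
    pseudocount: float = 1.0,
    numerator_label: str = "IP",
    denominator_label: str = "input",
) -> EnrichmentTrack:
    """Per-bin log2((IP + pc) / (input + pc)) of two CPM tracks.

    The pseudocount (CPM units) bounds the ratio and pins zero-coverage
    bins at log2 = 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not ip.same_structure(input_):
        raise ValueError("IP and input tracks differ in bin structure")
    values = {
        chrom: np.log2((ip.values[chrom] + pseudocount) / (input_.values[chrom] + pseudocount))
        for chrom in ip.values
    }
    return EnrichmentTrack(
        bin_size=ip.bin_size,
        values=values,
        chrom_lengths=ip.chrom_lengths,
        numerator_label=numerator_label,
        denominator_label=denominator_label,
        pseudocount=pseudocount,
    )


def fold_change_track(
    mutant: EnrichmentTrack, wildtype: EnrichmentTrack
) -> EnrichmentTrack:
    """Per-bin mutant - wild-type difference of log2 enrichments.

    On the log2 scale the difference of enrichments is the log2
    fold-change of mutant over wild-type signal.
    """
    if not mutant.same_structure(wildtype):
        raise ValueError("tracks differ in bin structure")
    if mutant.scale != "log2_ratio" or wildtype.scale != "log2_ratio":
        raise ValueError("fold_change_track requires log2_ratio tracks")
    values = {
        chrom: mutant.values[chrom] - wildtype.values[chrom] for chrom in mutant.values
    }
    return EnrichmentTrack(
        bin_size=mutant.bin_size,
        values=values,
        chrom_lengths=mutant.chrom_lengths,
        numerator_label="mutant",
        denominator_label="wild_type",
        pseudocount=mutant.pseudocount,
    )
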