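"""Genome-wide sliding-window differential H3K4me3 binding.

Fragments are counted into a 200 bp / 10 bp-step sliding window grid (a
fragment increments every window it overlaps, with no deduplication across
the overlapping windows) and the per-window counts go through the shared
negative-binomial machinery in :mod:`germ_epimem.nbstats`.  Neighbouring
windows share fragments, so window tests are correlated; FDR over windows
is reported but only raw-p calibration is asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from germ_epimem.core_io import (
    CountMatrix,
    Genome,
    GenomeAnnotation,
    GenomicInterval,
    ReadSet,
    tss_of,
)
from germ_epimem.nbstats import add_q_values, estimate_dispersion, nb_wald_test, size_factors
from germ_epimem.tracks import fragment_intervals

__all__ = [
    "WindowGrid",
    "make_windows",
    "window_counts",
    "window_differential",
    "windows_to_genes",
]


@dataclass
class WindowGrid:
    """Sliding windows per chromosome: starts 0, step, 2*step, ...

    Only fully-contained windows exist: start + window_size <= L, so a
    chromosome shorter than one window contributes none.
    """

    window_size: int
    step: int
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window_size):
            raise ValueError("require window_size >= step >= 1")

    def n_windows(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        if length < self.window_size:
            return 0
        return (length - self.window_size) // self.step + 1

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_windows(chrom)) * self.step

    def windows(self, chrom: str) -> list[GenomicInterval]:
        return [
            GenomicInterval(chrom, int(s), int(s) + self.window_size)
            for s in self.starts(chrom)
        ]

    def window_ids(self) -> list[str]:
        ids = []
        for chrom in self.chrom_lengths:
            ids.extend(
                f"{chrom}:{s}-{s + self.window_size}" for s in self.starts(chrom)
            )
        return ids


def make_windows(genome: Genome, window_size: int = 200, step: int = 10) -> WindowGrid:
    """Tile every chromosome with fixed windows at a constant shift."""
    return WindowGrid(window_size=window_size, step=step, chrom_lengths=genome.lengths)


def window_counts(
    grid: WindowGrid,
    read_sets: dict[str, ReadSet],
    fragment_length: int = 200,
    condition: dict[str, str] | None = None,
) -> CountMatrix:
    """Fragment-overlap counts per window for each sample.

    A fragment [f0, f1) overlaps windows with start s satisfying
    f0 - window_size < s < f1, i.e. a contiguous run of starts, so each
    fragment is two operations on a difference array.
    """
    w, step = grid.window_size, grid.step
    columns = {}
    for sample, rs in read_sets.items():
        unknown = set(rs.reads["chrom"].unique()) - set(grid.chrom_lengths)
        if unknown:
            raise ValueError(f"sample {sample}: unknown chromosome(s) {sorted(unknown)}")
        per_chrom = []
        grouped = dict(iter(rs.reads.groupby("chrom", sort=False))) if len(rs.reads) else {}
        for chrom, length in grid.chrom_lengths.items():
            n = grid.n_windows(chrom)
            diff = np.zeros(n + 1, dtype=np.int64)
            sub = grouped.get(chrom)
            if n and sub is not None and len(sub):
                f0, f1 = fragment_intervals(sub, length, fragment_length)
                keep = f1 > f0
                f0, f1 = f0[keep], f1[keep]
                # smallest window index with start > f0 - w
                lo = np.maximum(0, (f0 - w) // step + 1)
                # largest window index with start < f1, capped at grid end
                hi = np.minimum(n - 1, (f1 - 1) // step)
                ok = hi >= lo
                np.add.at(diff, lo[ok], 1)
                np.add.at(diff, hi[ok] + 1, -1)
            per_chrom.append(np.cumsum(diff[:-1]))
        columns[sample] = np.concatenate(per_chrom) if per_chrom else np.array([], dtype=np.int64)
    frame = pd.DataFrame(columns, index=grid.window_ids())
    return CountMatrix(frame, condition=condition)


def window_differential(
    counts: CountMatrix,
    condition: dict[str, str] | None = None,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """NB Wald test over windows with BH-adjusted q-values."""
    condition = condition if condition is not None else counts.condition
    factors = size_factors(counts)
    dispersions = estimate_dispersion(counts, factors, condition=condition)
    return add_q_values(
        nb_wald_test(counts, factors, dispersions, condition=condition, group_order=group_order)
    )


def _parse_window_id(window_id: str) -> GenomicInterval:
    chrom, _, span = window_id.rpartition(":")
    start, _, end = span.partition("-")
    return GenomicInterval(chrom, int(start), int(end))


def windows_to_genes(
    significant_windows: list[str],
    annotation: GenomeAnnotation,
    mode: str = "tss_window",
    halfwidth: int = 500,
) -> set[str]:
    """Genes whose TSS window (or body) intersects a significant window.

    ``significant_windows`` are window ids of the form ``chrom:start-end``.
    """
    if mode not in ("tss_window", "gene_body"):
        raise ValueError(f"unknown mode {mode!r}")
    intervals = [_parse_window_id(w) for w in significant_windows]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    hits: set[str] = set()
    for gene in annotation:
        if mode == "tss_window":
            chrom, tss = tss_of(gene)
            g0, g1 = tss - halfwidth, tss + halfwidth
        else:
            chrom = gene.interval.chrom
            g0, g1 = gene.interval.start, gene.interval.end
        for iv in by_chrom.get(chrom, ()):
            if iv.start < g1 and g0 < iv.end:
                hits.add(gene.gene_id)
                break
    return hits
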