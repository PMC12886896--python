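"""Metagene profiles, TSS-window scores, and the cumulative-80% classifier.

Per-gene H3K4me3 is summarized as the mean log2 enrichment over the bins
intersecting a TSS +/- 500 bp window.  The mutant - wild-type score delta
drives the "H3K4me3-enriched gene" classification: genes with a positive
delta are ranked by delta and the shortest prefix whose cumulative delta
reaches 80% of the total increased enrichment is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from germ_epimem.core_io import EnrichmentTrack, GenomeAnnotation, tss_of

__all__ = [
    "MetageneMatrix",
    "metagene_matrix",
    "average_profile",
    "tss_window_score",
    "build_score_table",
    "select_enriched_genes",
    "compare_scores",
]


@dataclass
class MetageneMatrix:
    """Genes x TSS-relative-offsets matrix of enrichment values.

    ``offsets`` are bin-center positions in bp relative to the TSS.
    Minus-strand rows are orientation-flipped so positive offsets are
    downstream of transcription.  Positions off the chromosome ends are
    NaN and excluded from averages.
    """

    gene_ids: list[str]
    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.offsets)):
            raise ValueError("matrix shape does not match gene_ids x offsets")


def metagene_matrix(
    track: EnrichmentTrack,
    annotation: GenomeAnnotation,
    upstream: int = 1000,
    downstream: int = 1000,
) -> MetageneMatrix:
    """Extract bins covering [TSS - upstream, TSS + downstream) per gene."""
    bs = track.bin_size
    if upstream % bs or downstream % bs:
        raise ValueError(f"upstream/downstream must be multiples of bin_size {bs}")
    n_up, n_down = upstream // bs, downstream // bs
    n_cols = n_up + n_down
    values = np.full((len(annotation), n_cols), np.nan)
    for row, gene in enumerate(annotation):
        chrom, tss = tss_of(gene)
        if chrom not in track.values:
            raise ValueError(f"gene {gene.gene_id}: chromosome {chrom!r} not in track")
        vec = track.values[chrom]
        tss_bin = tss // bs
        b0, b1 = tss_bin - n_up, tss_bin + n_down
        lo, hi = max(b0, 0), min(b1, len(vec))
        if lo < hi:
            values[row, lo - b0 : hi - b0] = vec[lo:hi]
        if gene.interval.strand == "-":
            values[row] = values[row][::-1]
    offsets = (np.arange(-n_up, n_down) * bs + bs / 2).astype(float)
    return MetageneMatrix(annotation.gene_ids, offsets, values)


def average_profile(matrix: MetageneMatrix) -> np.ndarray:
    """Column-wise mean over genes, ignoring off-chromosome (NaN) cells."""
    if len(matrix.gene_ids) == 0:
        raise ValueError("empty metagene matrix")
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix.values, axis=0)


def tss_window_score(
    track: EnrichmentTrack,
    annotation: GenomeAnnotation,
    halfwidth: int = 500,
) -> pd.Series:
    """Mean enrichment over bins intersecting TSS +/- halfwidth, per gene.

    Windows extending past a chromosome end are truncated rather than
    dropped; the score is the mean over the surviving bins.
    """
    bs = track.bin_size
    if halfwidth % bs:
        raise ValueError(f"halfwidth must be a multiple of bin_size {bs}")
    scores = {}
    for gene in annotation:
        chrom, tss = tss_of(gene)
        if chrom not in track.values:
            raise ValueError(f"gene {gene.gene_id}: chromosome {chrom!r} not in track")
        vec = track.values[chrom]
        # bins intersecting the half-open window [tss - halfwidth, tss + halfwidth)
        b0 = max((tss - halfwidth) // bs, 0)
        b1 = min(math.ceil((tss + halfwidth) / bs), len(vec))
        scores[gene.gene_id] = float(np.mean(vec[b0:b1]))
    return pd.Series(scores, name="score")


def build_score_table(
    track_wt: EnrichmentTrack,
    track_mut: EnrichmentTrack,
    annotation: GenomeAnnotation,
    halfwidth: int = 500,
) -> pd.DataFrame:
    """Per-gene wild-type and mutant TSS-window scores and their delta.

    Returns a DataFrame indexed by gene_id with columns ``score_wt``,
    ``score_mut``, ``delta`` (mutant minus wild-type), one row per
    annotated gene in annotation order.
    """
    if not track_wt.same_structure(track_mut):
        raise ValueError("tracks differ in bin structure")
    wt = tss_window_score(track_wt, annotation, halfwidth)
    mut = tss_window_score(track_mut, annotation, halfwidth)
    table = pd.DataFrame({"score_wt": wt, "score_mut": mut})
    table["delta"] = table["score_mut"] - table["score_wt"]
    table.index.name = "gene_id"
    return table.loc[annotation.gene_ids]


def select_enriched_genes(
    table: pd.DataFrame,
    fraction: float = 0.8,
    min_wt_score: float | None = None,
) -> list[str]:
    """Genes contributing the top ``fraction`` of total increased enrichment.

    Genes with delta > 0 are ranked by delta descending (ties broken by
    gene_id ascending); with T the sum of all positive deltas, the shortest
    prefix whose cumulative delta reaches ``fraction * T`` is returned, in
    rank order.  No positive deltas -> empty list.

    ``min_wt_score`` optionally restricts the candidates to genes whose
    TSS already carries wild-type signal at or above the threshold.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    candidates = table[table["delta"] > 0]
    if min_wt_score is not None:
        candidates = candidates[candidates["score_wt"] >= min_wt_score]
    if candidates.empty:
        return []
    # stable sort: gene_id ascending first, then delta descending, so ties
    # in delta fall back to lexicographic gene order
    ranked = candidates.sort_index().sort_values(
        "delta", ascending=False, kind="mergesort"
    )
    deltas = ranked["delta"].to_numpy()
    target = fraction * deltas.sum()
    cum = np.cumsum(deltas)
    # first index where the cumulative sum reaches the target (floating
    # slack guards the fraction=1 boundary)
    k = int(np.searchsorted(cum, target - 1e-12 * max(1.0, abs(target)))) + 1
    return list(ranked.index[:k])


def compare_scores(table: pd.DataFrame) -> dict[str, float]:
    """Welch two-sided unpaired t-test of mutant vs wild-type scores.

    Compares ``score_mut`` against ``score_wt`` across genes (the two
    columns treated as independent samples).  Returns the t statistic, the
    Welch-Satterthwaite degrees of freedom, and the two-sided p-value;
    degenerate zero-variance inputs are flagged.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 genes")
    wt = table["score_wt"].to_numpy(dtype=float)
    mut = table["score_mut"].to_numpy(dtype=float)
    degenerate = wt.var(ddof=1) == 0 and mut.var(ddof=1) == 0
    if degenerate:
        if np.all(wt.mean() == mut.mean()):
            return {"t_statistic": 0.0, "df": float(len(wt) + len(mut) - 2),
                    "p_value": 1.0, "degenerate_variance": True}
        return {"t_statistic": math.copysign(math.inf, wt.mean() - mut.mean()),
                "df": float(len(wt) + len(mut) - 2),
                "p_value": float(np.nextafter(0, 1)), "degenerate_variance": True}
    res = stats.ttest_ind(wt, mut, equal_var=False)
    return {
        "t_statistic": float(res.statistic),
        "df": float(res.df),
        "p_value": float(res.pvalue),
        "degenerate_variance": False,
    }
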