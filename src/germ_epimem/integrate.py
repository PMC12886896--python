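"""Gene-set integration: overlaps, crosstabs and reference fractions.

Combines the H3K4me3-enriched gene set with 22G-RNA and mRNA differential
call sets, and with externally supplied target-gene lists (WAGO and
Mutator pathway targets and the like), into overlap counts, an optional
hypergeometric enrichment p-value, and the headline crosstab: how many
enriched genes show 22G deregulation (split up/down) and how many show an
mRNA change.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from germ_epimem.nbstats import DECallSet

__all__ = ["CrossTab", "overlap_sets", "build_crosstab", "fraction_in_reference"]


@dataclass
class CrossTab:
    n_enriched: int
    n_enriched_with_22g_change: int
    n_22g_up: int
    n_22g_down: int
    n_enriched_with_mrna_change: int
    n_mrna_up: int
    n_mrna_down: int

    def __post_init__(self) -> None:
        if self.n_22g_up + self.n_22g_down != self.n_enriched_with_22g_change:
            raise ValueError("22G up/down counts do not sum to the total")
        if self.n_mrna_up + self.n_mrna_down != self.n_enriched_with_mrna_change:
            raise ValueError("mRNA up/down counts do not sum to the total")
        for value in (
            self.n_enriched_with_22g_change,
            self.n_22g_up,
            self.n_22g_down,
            self.n_enriched_with_mrna_change,
            self.n_mrna_up,
            self.n_mrna_down,
        ):
            if value > self.n_enriched:
                raise ValueError("category count exceeds number of enriched genes")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_enriched": self.n_enriched,
            "n_enriched_with_22g_change": self.n_enriched_with_22g_change,
            "n_22g_up": self.n_22g_up,
            "n_22g_down": self.n_22g_down,
            "n_enriched_with_mrna_change": self.n_enriched_with_mrna_change,
            "n_mrna_up": self.n_mrna_up,
            "n_mrna_down": self.n_mrna_down,
        }


def overlap_sets(set_a: set, set_b: set, universe: set) -> dict:
    """Exact overlap counts plus an upper-tail hypergeometric p-value.

    p is the probability of observing >= |a & b| marked elements when
    drawing |a| from a universe of which |b| are marked.  The p-value is
    an explicit extension beyond plain Venn counting and is reported but
    not used for any calling decision.
    """
    for name, s in (("a", set_a), ("b", set_b)):
        stray = s - universe
        if stray:
            raise ValueError(
                f"set {name} has elements outside the universe: {sorted(stray)[:5]}"
            )
    n_overlap = len(set_a & set_b)
    # P(X >= k) with X ~ Hypergeom(M=|U|, n=|b|, N=|a|)
    p = float(stats.hypergeom.sf(n_overlap - 1, len(universe), len(set_b), len(set_a)))
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_overlap": n_overlap,
        "n_union": len(set_a | set_b),
        "p_hypergeometric": p,
    }


def build_crosstab(
    enriched: set[str] | list[str],
    de22g: DECallSet,
    demrna: DECallSet,
) -> CrossTab:
    """Count enriched genes falling in each differential-call category."""
    enriched_set = set(enriched)
    return CrossTab(
        n_enriched=len(enriched_set),
        n_enriched_with_22g_change=len(enriched_set & (de22g.up | de22g.down)),
        n_22g_up=len(enriched_set & de22g.up),
        n_22g_down=len(enriched_set & de22g.down),
        n_enriched_with_mrna_change=len(enriched_set & (demrna.up | demrna.down)),
        n_mrna_up=len(enriched_set & demrna.up),
        n_mrna_down=len(enriched_set & demrna.down),
    )


def fraction_in_reference(gene_set: set[str], reference_list: set[str]) -> float:
    """|gene_set intersect reference| / |gene_set|."""
    if not gene_set:
        raise ValueError("empty gene set")
    return len(set(gene_set) & set(reference_list)) / len(set(gene_set))
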