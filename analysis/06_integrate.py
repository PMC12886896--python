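"""Integrate the H3K4me3-enriched gene set with 22G and mRNA call sets.

Builds the headline crosstab (how many enriched genes show 22G
deregulation, split up/down, and how many show an mRNA change) and the
pairwise overlap table with hypergeometric enrichment p-values.
"""

from pathlib import Path

import pandas as pd

from germ_epimem.core_io import read_counts_tsv, read_gff3
from germ_epimem.nbstats import DECallSet
from germ_epimem.pipeline import PipelineConfig, stage_de, stage_integrate

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "demo_data"
OUT = ROOT / "results" / "pipeline"

config = PipelineConfig.from_yaml(DATA / "config.yaml")
annotation = read_gff3(config.annotation)


def read_list(name):
    return {l.strip() for l in (OUT / name).read_text().splitlines() if l.strip()}


selected = [
    l.strip() for l in (OUT / "enriched_genes.txt").read_text().splitlines() if l.strip()
]
calls22g = DECallSet(read_list("sr22g_up.txt"), read_list("sr22g_down.txt"))

mrna = read_counts_tsv(config.mrna_counts)
mrna = read_counts_tsv(
    config.mrna_counts, condition={s: s.rsplit("_", 1)[0] for s in mrna.sample_ids}
)
_, callsmrna = stage_de(mrna, min_fold_change=1.0, max_fdr=0.01, outdir=OUT, label="mrna")

crosstab = stage_integrate(
    selected, calls22g, callsmrna, set(annotation.gene_ids), {}, OUT
)

print("crosstab of the integrated gene sets:")
for key, value in crosstab.as_dict().items():
    print(f"  {key:30s} {value}")
overlaps = pd.read_csv(OUT / "pairwise_overlaps.tsv", sep="\t")
row = overlaps.query("set_a == 'enriched' and set_b == 'sr22g_down'").iloc[0]
print(f"enriched vs 22G-down overlap: {int(row['n_overlap'])} genes, "
      f"hypergeometric p = {row['p_hypergeometric']:.3g}")
print(f"crosstab, overlap table and Venn sets under {OUT}")
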