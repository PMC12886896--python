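"""Generate the synthetic two-genotype study with recorded ground truth.

Writes the scenario bundle (genome, annotation, ChIP read BEDs, small-RNA
FASTQ, mRNA counts, truth table, pipeline config) to results/demo_data/.
"""

from pathlib import Path

from germ_epimem.pipeline import make_demo
from germ_epimem.synth import SyntheticTruth

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "demo_data"
SEED = 1

config_path = make_demo(DATA, seed=SEED)
truth = SyntheticTruth.load_tsv(DATA / "truth.tsv")

print(f"scenario written to {DATA}")
print(f"  genes with planted H3K4me3 gain (x3): {len(truth.enriched_genes)}")
print(f"  genes with planted 22G up (log2fc +2): {len(truth.sr_up_genes)}")
print(f"  genes with planted 22G down (log2fc -2): {len(truth.sr_down_genes)}")
print(f"  genes with planted mRNA change: {len(truth.de_genes)}")
print(f"  pipeline config: {config_path}")
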