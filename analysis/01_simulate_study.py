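"""Generate the synthetic two-fraction 3'-Seq study used by all later steps.

52 individuals x {nuclear, total} libraries over 300 multi-PAS genes, with
planted apaQTLs (10% of genes, |beta| = 1.5), internal-priming traps (10% of
genes) and intronic-isoform decay in the total fraction (survival 0.3).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, get_study

study = get_study(SEED)
truth, geno = study["truth"], study["genotypes"]

RESULTS.mkdir(exist_ok=True)
truth.true_pas.drop(columns=["motif_offset"]).to_csv(
    RESULTS / "truth_pas.tsv", sep="\t", index=False
)
truth.qtl_effects.to_csv(RESULTS / "truth_qtl_effects.tsv", sep="\t", index=False)

print(f"genes: {len(truth.gene_models)}  true PAS: {len(truth.true_pas)}")
print("PAS per category:", truth.true_pas.category.value_counts().to_dict())
print(f"planted apaQTLs: {len(truth.qtl_effects)}  traps: {len(truth.artifact_sites)}")
print(f"variants: {len(geno.variants)}  individuals: {len(geno.individuals)}")
print(f"libraries: {len(study['read_set'].libraries)}  "
      f"reads: {study['read_set'].n_reads:,}")
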