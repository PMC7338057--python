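"""Map cis-apaQTLs in each fraction (25 kb window, 200 permutations, 10% BH).

Usage ratios are rank inverse-normal transformed per PAS; the top 4 phenotype
PCs serve as covariates; empirical permutation p-values feed BH across all
tested PAS within a fraction.  Full per-PAS tables are cached under scratch/;
the significant calls land in results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, get_qtl_tables, get_study

study = get_study(SEED)
truth = study["truth"]
qtl_genes = set(truth.qtl_effects.gene_id)

RESULTS.mkdir(exist_ok=True)
tables = get_qtl_tables(study, SEED)
for fraction, table in tables.items():
    sig = table[table.significant]
    sig.to_csv(RESULTS / f"apaqtl_{fraction}_significant.tsv", sep="\t", index=False)
    true_hits = sig.gene_id.isin(qtl_genes)
    print(f"[{fraction}] tested PAS: {len(table)}  significant: {len(sig)}  "
          f"in planted genes: {true_hits.sum()}  "
          f"planted genes recovered: {sig.gene_id[true_hits].nunique()}/{len(qtl_genes)}")
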