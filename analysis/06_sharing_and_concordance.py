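"""Cross-fraction sharing and effect-size agreement of apaQTLs.

pi1 estimates how many nuclear-significant associations replicate in the
total fraction; raw-slope concordance checks that genetic effects on PAS
choice agree across fractions; a category enrichment and an annotation
bootstrap illustrate the downstream comparisons.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, get_qtl_tables, get_study

from apaqtl import stats as ds

study = get_study(SEED)
truth = study["truth"]

tables = get_qtl_tables(study, SEED)
nuc, tot = tables["nuclear"], tables["total"]
merged = nuc[nuc.significant].merge(tot, on="pas_id", suffixes=("_nuc", "_tot"))

est = ds.pi1_estimate(merged.nominal_p_tot.to_numpy())
r, slope, p = ds.effect_concordance(merged.slope_raw_nuc, merged.slope_raw_tot)
print(f"nuclear-significant PAS re-tested in total: {len(merged)}")
print(f"sharing pi1 = {est.pi1:.3f}   slope concordance r = {r:.3f} "
      f"(r^2 = {r * r:.3f}, slope = {slope:.3f})")

# enrichment of small nominal p among genes with a planted effect
qtl_genes = set(truth.qtl_effects.gene_id)
cats = nuc.gene_id.map(lambda g: "planted" if g in qtl_genes else "background")
enr = ds.category_enrichment(nuc.nominal_p, cats)
print(f"planted-gene enrichment (one-sided rank-sum): p = {enr.p_value.iloc[0]:.3g}")

# genic-context bootstrap for the significant lead variants
ann = truth.annotation_frame().rename(columns={"feature": "label"})[
    ["chrom", "start", "end", "label"]
]
leads = nuc[nuc.significant].lead_snp.str.split(":", expand=True)
variants = pd.DataFrame(dict(chrom=leads[0], pos=leads[1].astype(int)))
boot = ds.annotation_overlap_bootstrap(variants, ann, n_boot=1000, seed=SEED)
boot.to_csv(RESULTS / "lead_variant_context_bootstrap.tsv", sep="\t", index=False)

summary = pd.DataFrame(
    [dict(metric="pi1_nuclear_in_total", value=est.pi1, n=len(merged)),
     dict(metric="slope_concordance_r", value=r, n=len(merged)),
     dict(metric="slope_concordance_r2", value=r * r, n=len(merged)),
     dict(metric="planted_gene_enrichment_p", value=enr.p_value.iloc[0], n=len(nuc))]
)
summary.to_csv(RESULTS / "sharing_summary.tsv", sep="\t", index=False)
print(boot.to_string(index=False))
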