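"""Post-GWAS interpretation on synthetic annotation tables.

Maps scan results to genes within 15 kb, selects hit genes at nominal
p < 0.01, tests term enrichment with the hypergeometric tail + BH-FDR and
the minimum-overlap/percentage filters, checks candidate regions against a
QTL interval table, and profiles localized LD around the top SNP.
The gene/term/QTL tables here are synthetic stand-ins for a real
annotation release.
"""

import numpy as np
import pandas as pd

import ssgwas as s
from ssgwas.config import SimConfig

rng = np.random.default_rng(4)
cfg = SimConfig(n_founders=200, n_generations=2, seed=4, prop_genotyped=1.0)
ped = s.simulate_pedigree(cfg)
geno = s.simulate_genotypes(ped, cfg)

# synthetic gene annotation: 40 genes per chromosome, 20 kb long
genes = []
for c in range(1, cfg.n_chromosomes + 1):
    starts = np.sort(rng.integers(1, cfg.chromosome_length_bp - 20_000, 40))
    for k, st in enumerate(starts):
        genes.append((f"gene_c{c}_{k}", c, int(st), int(st + 20_000)))
annotation = pd.DataFrame(genes, columns=["gene_id", "chrom", "start_bp",
                                          "end_bp"])

# synthetic scan: uniform p-values with a planted signal on chromosome 1
results = geno.snp_map.assign(p=rng.uniform(size=geno.n_snps))
planted = results.chrom == 1
results.loc[planted, "p"] = results.loc[planted, "p"] ** 3

mapping = s.map_snps_to_genes(results[["snp_id", "chrom", "pos_bp"]],
                              annotation)
hits, background = s.select_gene_hits(results, annotation, p_nominal=0.01)
print(f"{len(mapping)} SNP-gene links within 15 kb; background "
      f"{len(background)} genes, {len(hits)} hit genes at p < 0.01")

terms = {"chr1_module": set(annotation.loc[annotation.chrom == 1, "gene_id"]),
         "random_module": set(rng.choice(annotation.gene_id, 60, replace=False))}
enr = s.enrich(hits, background, terms)
print(enr[["term_id", "n_hits_in_term", "pct_of_term", "raw_p", "bh_fdr",
           "passes_filters"]].to_string(index=False))

qtl = pd.DataFrame({"chrom": [1, 1, 2], "start_bp": [1, 40_000_000, 1],
                    "end_bp": [30_000_000, 80_000_000, 50_000_000],
                    "category": ["morphology", "beef", "milk"]})
top = results.sort_values("p").head(5)[["snp_id", "chrom", "pos_bp"]]
overlaps, pct = s.region_qtl_overlap(top, qtl, flank_bp=500_000)
print("QTL category shares among overlaps:")
print(pct.to_string(index=False))

local = s.localized_ld(geno, top.snp_id.iloc[0])
print(f"localized LD around {top.snp_id.iloc[0]}: "
      f"{(local.ld_class == 'red').sum()} SNPs in r2 > 0.8 within 0.5 Mb")
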