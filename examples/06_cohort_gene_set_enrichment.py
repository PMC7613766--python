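"""Cohort gene sets and preranked gene-set enrichment.

Maps each HMG20B peak to its nearest gene, builds one gene set per strength
cohort (promoter-class peaks), and scores each set against the
knockdown-response ranked list with the weighted running-sum ES and
gene-set-permutation significance.
"""

import cooccupy as cp

cfg = cp.SimulationConfig(seed=1)
genome = cp.generate_genome(cfg)
truth = cp.plant_sites(genome, cfg)
peaks = cp.emit_peaks(truth, genome, cfg)
genes, ranked, gene_truth = cp.generate_genes_and_expression(truth, genome, cfg)

hp = peaks["hmg20b"]
cohorts = cp.assign_cohorts(hp, 10)
mapping = cp.map_nearest_gene(hp, genes)
print("peak class counts:", mapping["class"].value_counts().to_dict())

sets = cp.build_cohort_gene_sets(cohorts, mapping, peak_class="promoter")
res = cp.gsea(ranked, sets, n_perm=500, seed=1)
print(f"\n{len(ranked)} ranked genes; enrichment by cohort gene set:")
print(res[["size", "es", "nes", "p", "fdr_q"]].round(3))
# Genes near the strongest peaks were planted as knockdown-responsive, so
# enrichment (low q) concentrates in the top cohorts and vanishes toward the
# weakest — the signature linking binding strength to transcriptional
# response.
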