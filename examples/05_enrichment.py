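"""Representation-factor enrichment of kinase/phosphatase-like catalogs.

Runs the full route: simulate the cohort, call differential expression with
two test variants, intersect the up-calls, and test the common upregulated
genes for over-representation of each planted catalog.
"""

import snreadthrough as srt

cohort = srt.default_cohort(seed=0, n_genes=8000, dispersion=0.02)
counts, groups, truth = srt.simulate_count_matrix(cohort)
kd = list(groups[groups == "catalytic_kd"].index)
ctrl = list(groups[groups == "control"].index)

up, down = srt.intersect_calls(
    srt.simple_de(counts, kd, ctrl, equal_var=False),
    srt.simple_de(counts, kd, ctrl, equal_var=True))
print(f"common upregulated genes: {len(up)} "
      f"(planted: {len(truth['planted_up']['catalytic_kd'])})")

table = srt.enrich(up, truth["geneset_catalogs"], universe=set(counts.index))
print(table.to_string(index=False))
# RF = (k*N)/(K*n) is the observed/expected overlap: RF > 1 with a small
# hypergeometric p means the catalog is over-represented among the common
# upregulated genes.  The universe N is printed so the numbers are
# self-describing.
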