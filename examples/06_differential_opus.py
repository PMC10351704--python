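"""ANCOM-style detection of differentially abundant OPUs.

For every OPU, its additive log-ratios against all other OPUs are compared
between the two sample groups by rank-sum tests with BH correction; the W
statistic counts rejections and high-W OPUs are flagged as differential.
"""

import wsdgat as w

study = w.simulate_study(seed=1, n_samples_per_group=6)
fam = study.all_proteins().query("gene_class == 'family'")

opus = w.greedy_cluster(dict(zip(fam["protein_id"], fam["seq"])), cutoff=0.8)
table = w.filter_opus(
    w.opu_abundance(opus, fam[["protein_id", "sample_id", "weight"]]),
    min_sequences=10,
)
matrix = table.to_sample_matrix()
groups = [study.groups[s] for s in matrix.index]

result = w.ancom_w(matrix, groups, alpha=0.05)
detected = result[result["detected"]].sort_values("W", ascending=False)
print(f"{len(detected)} of {len(result)} OPUs differential between groups")
print(detected.head(10))
# W counts, per OPU, how many of its log-ratio contrasts reject at the BH
# threshold; an OPU near W = m-1 shifts against nearly every other OPU.
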