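"""Call differentially expressed genes with the correlated two-sample t.

The statistic pairs induced and uninduced replicates and subtracts twice the
covariance term from the variance of the difference, so positively correlated
replicate pairs gain power over the naive independent t-test.
"""

from regulonrank import SyntheticConfig, call_degs, generate_expression, \
    run_gene_tests

config = SyntheticConfig(n_genes=2_000, pair_correlation=0.5, seed=7)
em, truth = generate_expression(config)

table = run_gene_tests(
    em,
    induced_samples=em.group_samples("WT", "caerulein"),
    uninduced_samples=em.group_samples("WT", "saline"),
    deg_alpha=0.05,
)
degs = call_degs(table, deg_alpha=0.05, threshold_on="p")

print(table.head(5).round(4).to_string(index=False))
print(f"\ncalled DEGs (raw P < 0.05): {len(degs)} of {len(table)} genes")
print(f"planted DEGs recovered    : {len(degs & truth)} of {len(truth)}")
mean_gamma = table["gamma"].mean()
print(f"mean within-pair correlation gamma: {mean_gamma:.3f}")
# gamma near the simulated 0.5 shows the statistic is exploiting the paired
# structure; recovery below 100% reflects genuine power limits at n = 3.
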