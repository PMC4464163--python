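"""Simulate a replicated two-genotype, two-treatment expression study.

Generates a small synthetic study — a 12-sample log2 expression matrix
(2 genotypes x 2 treatments x 3 replicates), a TF->target network with five
DEG-enriched "active" regulons, and the planted ground truth — then writes
it to disk in the package's TSV formats.
"""

from regulonrank import SyntheticConfig, generate_study

config = SyntheticConfig(
    n_genes=2_000,
    n_tfs=100,
    n_active_tfs=5,
    targets_per_tf=(20, 40),
    seed=42,
)
bundle = generate_study(config)
paths = bundle.write("scratch/example_study")

em = bundle.expression
print(f"expression matrix: {em.n_genes} genes x {em.n_samples} samples")
print(f"sample groups    : {sorted(set(map(tuple, em.design[['genotype','treatment']].values)))}")
print(f"network          : {bundle.network.n_pairs} TF->target pairs, "
      f"{len(bundle.network.tfs)} TFs")
for genotype, degs in bundle.truth_degs.items():
    print(f"planted DEGs [{genotype}]: {len(degs)}")
print(f"planted active TFs: {sorted(bundle.active_tfs)}")
print(f"files written to  : {paths['matrix'].parent}")
# The planted DEGs and active TFs are the ground truth every later stage is
# judged against; the knockout genotype carries twice the wild-type DEG load.
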