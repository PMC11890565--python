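"""Build the candidate feature matrix from the three molecular platforms.

Mutations are binarized at the gene level (plus variant-level TP53
columns), gene-level copy number is collapsed to segment means and called
gain/loss at +/-0.3, and expression signatures are median-scored and
median-centered.
"""

from tnbcprog import (
    CohortConfig,
    assemble_features,
    binarize_mutations,
    collapse_segments,
    generate_cohort,
    score_signatures,
)

cohort = generate_cohort(CohortConfig(
    datasets={"train": 150}, baselines={"train": (1.1, 18.0)},
    n_signatures=40, n_mutation_genes=50, n_tp53_variants=12, n_segments=20, seed=3,
))

mut = binarize_mutations(
    cohort.mutations, cohort.mutation_genes,
    patients=cohort.clinical.index, tp53_variant_catalog=cohort.tp53_variants,
)
cn = collapse_segments(
    cohort.cn_genes, {s.segment_id: list(s.genes) for s in cohort.segment_catalog}
)
sigs = score_signatures(cohort.expression, cohort.signature_catalog)
fm = assemble_features(cohort.clinical, mut, cn, sigs)

print(f"assembled feature matrix: {fm.values.shape[0]} patients x "
      f"{fm.values.shape[1]} features")
print(fm.category.value_counts().to_string())
print(f"segment gain frequency (mean over segments): {cn.gain.mean().mean():.3f}")
print(f"segment loss frequency (mean over segments): {cn.loss.mean().mean():.3f}")
# Column count = 1 stage + |signatures| + |genes| + |TP53 variants|
# + 2 x |segments| (separate gain and loss indicator families).
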