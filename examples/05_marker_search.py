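"""Search marker panels: one factor (or a pair) per cluster, scored by d.

The tree stays fixed (fitted on cluster means); candidate panels substitute
individual factor values for the cluster means at prediction time and are
scored with d = (1/N_S) * sqrt(sum of squared log-time residuals).
"""

from cholestage import (
    SyntheticSpec,
    anova_screen,
    build_sample_table,
    cluster_factors,
    count_single_combinations,
    fit_tree,
    generate,
    normalize_factors,
    sample_double_combinations,
    score_all_single_combinations,
    score_combination,
    significant_ids,
    similarity_matrix,
)

data, truth = generate(SyntheticSpec(noise_sd=0.1, seed=42))
keep = significant_ids(anova_screen(data))
norm = normalize_factors(data.subset(keep))
clusters = cluster_factors(similarity_matrix(norm), 6, norm)
table = build_sample_table(clusters, norm)
tree = fit_tree(table)

sizes = [clusters.sizes[c] for c in clusters.cluster_labels]
print(f"cluster sizes {sizes} -> "
      f"{count_single_combinations(sizes)} single-factor panels")

singles = score_all_single_combinations(tree, norm, clusters, table)
print("\nbest single-factor panels (one factor per cluster, ascending d):")
print(singles.head(3).to_string(index=False))

doubles = sample_double_combinations(clusters, n=2000, seed=0)
scored = sorted(
    (score_combination(tree, norm, table, combo) for combo in doubles),
    key=lambda s: s.d,
)
best = scored[0]
print(f"\nbest of {len(scored)} sampled two-factor panels: d = {best.d:.4f}")
for c, pair in zip(clusters.cluster_labels, best.combo):
    print(f"  cluster {c}: {' + '.join(pair)}")
# Smaller d = staging closer to the true sacrifice times; averaging two
# factors per cluster damps replicate noise, so the best double panel
# usually edges out the best single panel.
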