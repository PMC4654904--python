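"""Dimension reduction: ANOVA across time points plus the 0 h vs 6 h test.

Each factor is tested for significant regulation over the disease course
(one-way ANOVA, time as grouping), with Holm family-wise correction over
all factors; the Welch t-test targets the initial 6 h response.
"""

from cholestage import (
    SyntheticSpec,
    anova_screen,
    generate,
    significant_ids,
    welch_initial_test,
)

data, truth = generate(SyntheticSpec(noise_sd=0.1, seed=42))

screened = anova_screen(data, alpha=0.05)
keep = significant_ids(screened)
print(f"ANOVA + Holm: {len(keep)}/{data.n_factors} factors significant "
      f"(p_adj < 0.05)")
print("top 5 by adjusted p-value:")
for r in screened[:5]:
    print(f"  {r.factor_id:<18} F = {r.statistic:8.1f}  p_adj = {r.p_adj:.2e}")

false_pos = [f for f in keep if truth.archetype_of[f] is None]
print(f"null factors passing the screen: {len(false_pos)} "
      f"(family-wise error control at work)")

welch = welch_initial_test(data)
n_initial = sum(r.significant for r in welch)
print(f"Welch 0 h vs 6 h: {n_initial} factors with a significant initial "
      f"response — dominated by the 6 h spike and early-peak archetypes")
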