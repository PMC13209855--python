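"""Homogeneous-group letters for a nine-formulation moisture comparison.

Bench tables report each metric as mean ± SD (n = 3) with superscript
letters: formulations sharing a letter are not significantly different by
Tukey's HSD at p ≤ 0.05. This example runs the summary-statistics path on
the bundled moisture data and prints the letter display.
"""

from capmetrics import reference, stats

g = stats.GroupData.from_summary_dict(reference.MOISTURE_PCT, n=3)
anova = stats.anova_oneway(g)
print(f"one-way ANOVA: F({anova.df_between},{anova.df_within}) = "
      f"{anova.f_statistic:.1f}, p = {anova.p_value:.2e}")

comparisons = stats.tukey_hsd(g, alpha=0.05)
letters = stats.compact_letter_display(comparisons,
                                       dict(zip(g.labels, g.means)))

print(f"{'code':<6}{'moisture %':>12}   letters")
for code in sorted(letters, key=lambda c: -dict(zip(g.labels, g.means))[c]):
    mean, sd = reference.MOISTURE_PCT[code]
    print(f"{code:<6}{mean:>8.2f} ± {sd:.2f}   {letters[code]}")
# Five distinct letters appear: the gum-arabic control (highest moisture)
# sits alone in group 'a', and the three driest starch formulations share
# the bottom group 'e'.
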