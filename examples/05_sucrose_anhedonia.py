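"""Sucrose-consumption trajectories and the stress x time ANOVA.

The generator emulates the behavioural read-out of a chronic-mild-stress
protocol: control intake drifts up, stressed intake declines from week 2,
and the Bonferroni-adjusted weekly comparisons first reach significance at
week 4 — the onset of measurable anhedonia.
"""

from stereosyn import simulate_sucrose_intake, sucrose_analysis
from stereosyn.stats import render_p

intake = simulate_sucrose_intake(n_per_group=4, n_weeks=9, seed=3)
result = sucrose_analysis(intake)

print(f"stress main effect: F{result.df} = {result.statistic:.1f}, {render_p(result.p_value)}")
print(f"first significant week: {result.effects['first_significant_week']}")
for entry in result.posthoc:
    star = "*" if entry.significant else " "
    print(f"  {entry.comparison}: t = {entry.t:5.2f}, adjusted {render_p(entry.p_adjusted)} {star}")
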