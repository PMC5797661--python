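"""Group statistics from the packaged per-animal summary table.

Loads the transcribed individual-values table (8 rats, 4 per group),
rebuilds the group means +/- SEM, and runs the unpaired Student t-tests on
the total synapse and axon counts.  The t statistics printed here are the
recomputable group-level results: total asymmetric synapses t = 2.84
(one-tailed P < 0.05), symmetric t = 1.78 (P = 0.06), myelinated axons
t = 2.64 (two-tailed P < 0.05).
"""

from stereosyn import ingest_table1, summarize_group, table1_group_tests
from stereosyn.stats import render_p

summaries = ingest_table1()
control = [s for s in summaries if s.group == "control"]

group = summarize_group(control)
for field in ("density_asym", "density_sym", "total_asym", "total_axon"):
    row = group[group["field"] == field].iloc[0]
    print(f"control {field}: {row['mean']:.3g} +/- {row['sem']:.2g}")

for name, result in table1_group_tests(summaries).items():
    print(
        f"{name}: t = {result.statistic:.2f} ({result.tail}-tailed, "
        f"df = {result.df}), {render_p(result.p_value)}"
    )
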