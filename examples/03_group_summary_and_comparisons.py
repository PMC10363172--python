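"""Group-level reporting: the mean ± SD parameter table, exact Mann-Whitney
comparisons between formulations, and the dose trend across the
extended-release arms.
"""

from depotnca import (
    RunConfig,
    compare_groups,
    dose_trend,
    format_summary,
    paper_design,
    simulate_study,
    summarize_parameters,
)
from depotnca.pipeline import analyze_table

cfg = RunConfig.default(seed=7)
design = paper_design()
table, _ = simulate_study(design, cfg.population.to_population(), seed=7)
results = analyze_table(table, cfg)
group_of = dict(table[["subject_id", "group_label"]]
                .drop_duplicates().itertuples(index=False))

summary = summarize_parameters(results, design, group_of)
print(format_summary(summary))
print()

comps = compare_groups(results, group_of,
                       pairs=[(design.groups[0].label, g.label)
                              for g in design.groups[1:]],
                       parameters=("cmax", "t_half", "auc_inf"))
print("BSR vs each EXR arm (exact Mann-Whitney, Bonferroni over all tests):")
for c in comps:
    print(f"  {c.parameter:10s} {c.group_b:16s} U={c.u_statistic:5.1f} "
          f"p={c.p_exact:.3f} adj={c.p_adjusted:.3f} [{c.method}]")
print()

trend = dose_trend(summary, design, formulation="EXR")
print(f"EXR Cmax means {trend['cmax']['means']} at doses {trend['doses']}: "
      f"strictly increasing = {trend['cmax']['strictly_increasing']}, "
      f"log-log slope = {trend['cmax']['loglog_slope']:.2f}")
# Under the simulated between-subject spread none of the comparisons reach
# significance at these group sizes, and exposure rises with dose - the
# qualitative pattern expected for two comparable depot formulations.
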