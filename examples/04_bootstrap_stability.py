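"""Two-step bootstrap model selection: how stable is the selected model?

Step 1 re-runs the whole selection path (screen + backward elimination) in
bootstrap resamples and keeps predictors appearing in >= 40% of the models.
Step 2 re-selects from that qualified set in fresh resamples and tabulates
the resulting model compositions.  A low top frequency means the "final"
model is one of many near-equivalent compositions the data could support.
Bootstrap sizes are scaled to 100+100 here to keep the example quick.
"""

import warnings

import stabmi as sm

warnings.simplefilter("ignore")

table, _ = sm.generate(sm.shoulder_preset(seed=1))
config = sm.AnalysisConfig(b_step1=100, b_step2=100)
cc = sm.complete_cases(table, [table.outcome_name()] + table.candidates())
col = sm.collinearity_filter(cc.table, table.candidates(), config.collinearity_r)

res = sm.bootstrap_select(cc.table, "persistent", list(col.retained),
                          config, seed=3)
print("step-1 inclusion fractions (qualified at >= 40%):")
for name, frac in sorted(res.step1_inclusion.fractions.items(),
                         key=lambda kv: -kv[1])[:8]:
    mark = "*" if name in res.qualified else " "
    print(f"  {mark} {name:28s} {frac:.0%}")

freq = res.step2_frequencies
print(f"\nstep 2 tabulated {freq.total_models} models "
      f"({freq.failed_replicates} failed replicates excluded)")
print("most frequently selected compositions:")
for comp, count, pct in freq.top(5):
    print(f"  {count:4d} ({pct:4.1f}%)  {comp.label()}")
print("\npredictor ranks by step-2 inclusion fraction:")
for name, frac, rank in res.final_rank:
    print(f"  {rank}. {name:28s} {frac:.0%}")
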