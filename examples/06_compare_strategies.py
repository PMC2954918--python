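"""Run all four development strategies on one cohort and compare.

CCA (complete cases), MI-5 (five imputations + inclusion-fraction pooling),
B (two-step bootstrap on complete cases) and MI-5+B (the bootstrap inside
every imputed dataset).  Model composition typically differs across
strategies — that sensitivity is the methodological point — while validated
performance stays similar.  Bootstrap sizes are scaled down for speed.
"""

import warnings

import stabmi as sm

warnings.simplefilter("ignore")

table, _ = sm.generate(sm.shoulder_preset(seed=1))
config = sm.AnalysisConfig(b_step1=100, b_step2=100, b_validation=100)

bundles = []
for method in ("cca", "mi", "b", "mi_b"):
    bundle = sm.run_strategy(table, config, method, seed=2)
    bundles.append(bundle)
    print(f"[{method:4s}] {bundle.composition.label()}")

print()
print(sm.render_tables(bundles))
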