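"""Bootstrap optimism-corrected internal validation of a developed model.

Apparent performance (c-index, calibration slope, Nagelkerke R²) is
measured on the derivation data; 200 bootstrap resamples estimate how much
of it is overoptimism, and corrected c = apparent c − optimism.
"""

import warnings

import stabmi as sm

warnings.simplefilter("ignore")

table, _ = sm.generate(sm.shoulder_preset(seed=1))
config = sm.AnalysisConfig()
cc = sm.complete_cases(table, [table.outcome_name()] + table.candidates())
report = sm.screen(cc.table, "persistent", table.candidates(), config)
model = sm.backward_eliminate(cc.table, "persistent", list(report.retained),
                              config.alpha_backward).model

perf = sm.validate_optimism(cc.table, "persistent", model.predictors,
                            config, seed=5)
print(f"model: {', '.join(model.predictors)}")
print(f"apparent c-index : {perf.apparent_c:.3f} "
      f"(95% CI {perf.c_ci_low:.3f}-{perf.c_ci_high:.3f})")
print(f"calibration slope: {perf.calibration_slope:.3f} "
      "(1 on the derivation data by construction)")
print(f"Nagelkerke R2    : {perf.r2_nagelkerke:.3f}")
print(f"optimism         : {perf.optimism:.3f}")
print(f"corrected c-index: {perf.corrected_c:.3f}")
print(f"shrunk slope for new data ~ {1 - perf.slope_optimism:.3f}")
# The corrected c is the honest estimate of discrimination in new patients
# from the same population; the gap to the apparent c is what selection and
# coefficient estimation overfit.
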