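"""Complete-case development: screen the candidates and backward-eliminate.

The screen chains a collinearity filter (|r| >= 0.5, keep the clinically
easier variable), a univariable pre-selection at alpha = 0.157, and the
events-per-variable power check.  Backward elimination then drops the
weakest predictor (largest likelihood-ratio p) until all p <= 0.157.
"""

import warnings

import stabmi as sm

warnings.simplefilter("ignore")

table, _ = sm.generate(sm.shoulder_preset(seed=1))
config = sm.AnalysisConfig()
cc = sm.complete_cases(table, [table.outcome_name()] + table.candidates())

report = sm.screen(cc.table, "persistent", table.candidates(), config)
for dropped, kept, r in report.dropped_collinear:
    print(f"collinear: dropped {dropped} in favour of {kept} (r = {r:.2f})")
print(f"univariable screen retained {len(report.retained)} candidates "
      f"(EPV = {report.epv:.1f}; >10 means adequately powered)")

result = sm.backward_eliminate(cc.table, "persistent",
                               list(report.retained), config.alpha_backward)
print("\nfinal model (log-odds per predictor):")
for name, beta in result.model.coefficients.items():
    print(f"  {name:28s} {beta:+.3f}")
for name, p in result.removal_trace:
    print(f"removed {name} (p = {p:.3f})")
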