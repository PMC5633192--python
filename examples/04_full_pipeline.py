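"""Run the complete surrogate-assisted optimization flow on synthetic data.

normalize -> stratified split -> grid search -> epsilon-SVR fit -> adaptive
GA search, at reduced scale (population 60, 50 generations, 3-fold CV) so it
finishes in about a minute.  Since the data generator's true optimum is
known, the report can be judged against it.
"""

import numpy as np

from welanopt import pipeline, synth
from welanopt.aga import WIDE_BOUNDS
from welanopt.data_prep import CONDITION_COLUMNS

spec = synth.default_spec(seed=11)
config = pipeline.reduced_scale_config(seed=11, synth_spec=spec)
report = pipeline.run_pipeline(config)

print(f"records: {report.n_records} ({report.n_train} train / {report.n_test} test), "
      f"levels {report.level_counts}")
print(f"grid winner: c = {report.best_c:g}, g = {report.best_g:g}; "
      f"CVmse = {report.best_cvmse:.5f}")
print(f"test-set accuracy r^2 = {report.test_r2:.4f}")
print(f"\npredicted maximum production: {report.predicted_max_production:.2f} g/L "
      f"(generator truth {spec.y_star:g} g/L)")

best_observed = None
print(f"{'variable':>20s} {'proposed':>10s} {'true opt':>10s} {'err (% width)':>14s}")
for name, true, w in zip(CONDITION_COLUMNS, spec.x_star_array, WIDE_BOUNDS.width):
    got = report.optimal_conditions[name]
    print(f"{name:>20s} {got:10.3f} {true:10.3f} {abs(got - true) / w * 100:13.1f}%")

improvement = pipeline.report_improvement(
    report.predicted_max_production, float(np.max(synth.synth_generate(spec)["production"]))
)
print(f"\npredicted improvement over the best generated record: {improvement:+.1f}%")
print("\nAt n = 67 the surrogate locates the optimum only coarsely (errors of"
      "\n~5-15% of each bound's width are typical); the proposal is a region"
      "\nto explore experimentally, not a point estimate.")
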