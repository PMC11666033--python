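"""Run the complete study pipeline on a small configuration.

Writes every analysis table (metric values, ranks, variances, variance
tests, threshold curves and slopes, correlation drift, manifest) under
an output directory.  Equivalent CLI:

    prevmetrics all --seed 7 --out study_small --k 40 --down-iters 4 --up-iters 4
"""

import json

from prevmetrics import (GeneratorConfig, StudyConfig, SweepConfig, run_study)

cfg = StudyConfig(
    generator=GeneratorConfig(n=1000),
    sweep=SweepConfig(k=40, down_iters=4, up_iters=4),
    model_families=("GLM", "RF"),
    cv_folds=3,
    threshold_mode="uniform-grid",
    threshold_grid_size=51,
    out_dir="study_small",
).with_seed(7)

result = run_study(cfg)
print(f"artifacts written to {result.out_dir}:")
for path in sorted(result.out_dir.iterdir()):
    print(f"  {path.name}")

summary = json.loads((result.out_dir / "summary.json").read_text())
print(f"\ndatasets: {summary['n_datasets']}, "
      f"prevalence {summary['prevalence_range'][0]:.2f}"
      f"-{summary['prevalence_range'][1]:.2f}")
print(f"most consistent metric by mean rank variance: "
      f"{min(summary['mean_rank_variance_by_metric'], key=summary['mean_rank_variance_by_metric'].get)}")
print(f"negative significant threshold slopes: "
      f"{summary['negative_significant_slopes']} of {summary['n_slopes']}")
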