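"""Train the three-model weighted ensemble on a small phantom cohort.

Generates 20 malignant and 14 benign phantoms (80:20 split), trains the
random forest, the frozen-backbone whole-image model and the patch CNN,
optimizes the fusion weights/cutoff on the training split, and prints the
test-split confusion counts and rates.  Expect a couple of minutes on one
CPU core.
"""

from ebusml import EnsemblePipeline, PipelineConfig, generate_cohort

cohort = generate_cohort(20, 14, seed=5)
pipe = EnsemblePipeline(PipelineConfig(seed=5)).fit(cohort)
print(f"optimized weights {pipe.ensemble_cfg.weights}, "
      f"cutoff {pipe.ensemble_cfg.cutoff:.2f}")

result = pipe.evaluate(cohort, "test")
report = result["fused"]
print(f"test confusion: TP={report.tp} FN={report.fn} "
      f"FP={report.fp} TN={report.tn}")
for key, value in report.as_percent().items():
    print(f"  {key:12s} {value}")
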