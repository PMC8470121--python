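"""The whole recognition pipeline on a synthetic dataset, with the
channel-weighting ablation.

Generates 6 actions x 20 trials (4 s each), splits half/half,
denoises, segments, extracts features, weights channels, tunes the
SVM with the tiered-selection GA, and reports test accuracy with and
without the weighted feature method.
"""

import numpy as np

import semgkit as sk

config = sk.PipelineConfig(
    sim=sk.SimConfig(n_per_class=20, duration=4.0),
    profiles=sk.default_profiles(burst_onset=1.0, burst_duration=2.6),
    ga=sk.GAConfig(pop_size=20, max_generations=6, cv_folds=3),
    ablate_wfm=True,
    seed=11,
)
report = sk.run_pipeline(config)

res = report["result"]
print(f"records: {report['n_records']} generated, {report['n_segmented']} segmented")
print(f"tuned hyperparameters: c={res['best_c']:.4g}, g={res['best_g']:.4g}")
print(f"cross-validated fitness: {res['cv_fitness']:.4f}")
print(f"test accuracy with channel weighting:    {res['test_accuracy']:.4f}")
print(f"test accuracy without channel weighting: "
      f"{report['ablation_no_wfm']['test_accuracy']:.4f}")
print("confusion matrix (rows = actual, cols = predicted):")
print(np.array(res["confusion_matrix"]))
# On these well-separated synthetic profiles both arms should be at or
# near 100%; the weighting's benefit shows on noisier, subtler data.
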