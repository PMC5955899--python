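"""Two-stage fusion classification under leave-one-subject-out validation.

Runs the full pipeline on a synthetic cohort: per-variable first-stage
models (ridge-ranked feature elimination + random forest with inner 4-fold
grid search), logistic-regression fusion of the probability triplets, and
mean voting over each left-out subject's sessions.
"""

from keydyn import (
    PipelineConfig,
    extract_feature_table,
    generate_cohort,
    run_loso,
    selection_frequency,
)

cohort = generate_cohort(n_pd=8, n_control=7, sessions_per_subject=8, seed=2024)
features = extract_feature_table(cohort.subjects)
print(f"{len(features)} (session, variable) feature rows extracted")

result = run_loso(features, PipelineConfig(seed=5, n_trees=15))

print("\nsubject-level fused probabilities (mean vote over sessions):")
for sid, pred in result.predictions.items():
    flag = "" if pred.predicted_label == pred.label else "   <-- misclassified"
    print(f"  {sid} ({pred.label:7s}): P(PD) = {pred.probability:.2f} "
          f"-> {pred.predicted_label}{flag}")

freq = selection_frequency(result)
top = freq[freq["selected_pct"] >= 80].sort_values("selected_pct", ascending=False)
print("\nfeatures selected in >= 80% of LOSO loops:")
print(top.to_string(index=False))
print(
    "\nThe consistently selected features are the expected PD signatures:"
    "\nHT level, NFT skewness/spread and NP level."
)
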