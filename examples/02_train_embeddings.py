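"""Train skip-gram embeddings on a synthetic cohort and inspect neighbors.

The generator plants latent conditions whose events co-occur along
patients' pathways; after training, a target diagnosis's nearest
neighbors are dominated by codes emitted by the same condition.
"""

from clinalign import (
    SyntheticConfig,
    TrainingConfig,
    generate_cohort,
    nearest_neighbors,
    train_embeddings,
)

cohort, truth = generate_cohort(SyntheticConfig(n_patients=500, seed=7))
sentences = [cohort.pathways[p].events for p in cohort.patient_ids]
model = train_embeddings(sentences, TrainingConfig(dim=50, window=5, epochs=5, seed=1))
print(f"vocabulary: {len(model)} codes, dim {model.dim}")

diag = truth.condition_diagnoses[0][0]  # a planted target diagnosis
print(f"nearest neighbors of {diag}:")
for code in nearest_neighbors(model, model.vector(diag), k=6, exclude={diag}):
    print("  ", code)
# Neighbors sharing the condition's signature (labs, prescriptions, the
# condition's other target diagnosis) confirm the planted signal was learned.
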