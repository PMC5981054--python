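# Methods

This note records the models, parameter choices, and numerical decisions
behind clinalign, and what the synthetic experiments do and do not show.

## Pathways and cohort filters

A clinical pathway is one patient's chronologically ordered sequence of
type-prefixed event codes (`l_`, `c_`, `s_`, `d_`, `p_`) with admission
boundaries. Admissions are ordered by their earliest event; within an
admission, simultaneous events are ordered by a fixed type order
(condition, symptom, diagnosis, lab, prescription) and then code, so a
pathway is a deterministic function of the input event multiset —
required for reproducible embedding training. Diagnosis codes are
generalized to ICD-9 level 3: numeric codes keep three leading digits of
the integer part, V codes keep V + two digits, E codes E + three digits.

Two cohort filters apply, in this order: patients with fewer than 2
admissions are dropped (no final admission to predict), then codes
occurring in fewer than a threshold number of *distinct* admissions are
removed (one count per admission regardless of repeats). The reference
threshold for hospital-scale data is 50 admissions; the synthetic
scenarios use 5, proportional to their cohort sizes. In cross-validated
experiments the filters are fit on the training fold only; test pathways
are restricted implicitly because out-of-vocabulary events never enter a
patient vector.

## Embeddings

Per-site models are skip-gram with negative sampling, implemented in
package (numpy + a numba kernel) with the classic word2vec training
scheme: dynamic window (per-center reduction drawn uniformly from
1..window), 5 negative samples from a unigram^0.75 table, learning rate
decaying linearly from 0.025 to 1e-4, and per-token hash-seeded uniform
initialization in (−0.5/dim, 0.5/dim). Training is strictly serial and
all randomness flows from one seed, so a run is bit-reproducible; a
`workers` knob exists but values other than 1 are rejected rather than
trading determinism silently. Reference hyperparameters are dim 350 /
window 30 (structured pathways; window 100 for concept streams from
notes); the synthetic experiments use dim 50 / window 5 / 5 epochs, which
the scaled corpora support equally well. `min_count` defaults to 1
because rarity filtering is the pathway module's job.

One consequence of hash-seeded initialization is deliberate: two sites
trained with the *same* seed start each shared token at the same point,
so their spaces retain a weak residual alignment after training. The
scenario runners use a shared training seed for site models by default,
which reproduces the empirical observation that raw cross-site vectors
("Local" compensation) perform slightly above chance while remaining far
below harmonized compensation. The group-similarity scenario instead
trains its sites with different seeds, modeling fully independent
hospitals.

## Harmonization

Scaled orthogonal Procrustes with translation: anchors X (reference) and
Y (moving) are column-centered, `X_cᵀ Y_c = U Σ Vᵀ`, `Q = U Vᵀ`,
`k = trace(Σ)/trace(Y_cᵀ Y_c)`, and the residual
`‖X_c − k Y_c Qᵀ‖_F` is reported. Numerical decisions:

* The scale denominator uses the **centered** Y Gram trace — the only
  choice under which a pure translation of the same configuration
  recovers k = 1, as the objective demands.
* Q acts on row vectors as v → Qv (matrix form `Y_c Qᵀ`), consistent
  with the SVD recipe above; this is asserted against
  `scipy.linalg.orthogonal_procrustes` in the tests.
* No reflection constraint: det(Q) may be −1; the objective does not
  forbid reflections and constraining them would worsen the fit.
* With repeated or zero singular values Q is not unique; tests assert on
  the transform's *action*, never entrywise on Q, except for generic
  full-rank constructions where uniqueness holds.
* Fits with fewer than dim + 1 anchors warn (rotation under-determined:
  exact on anchors, arbitrary on the orthogonal complement).

Multi-site alignment is hub-based: each non-reference model is fitted
pairwise against the reference, and the reference is centered once at the
mean of the union of its anchor rows; each moving model is shifted into
that union-centered frame so all anchor images coincide. Simultaneous
generalized Procrustes is out of scope.

Fusion of two harmonized models: anchors get the size-weighted average
`w·v_A + (1−w)·v_B`; a code present in only one vocabulary is averaged
with its single nearest neighbor (cosine, ties lexicographic) from the
other site; a non-anchor code whose identical label appears in both
vocabularies is treated as a de facto correspondence and averaged with
the same weights. Genuinely conflicting embeddings under different labels
are both kept — resolving them is explicitly out of scope.

## Patient vectors and PDPS

The patient vector is `normalize(Σ_{c∈S} V_c e^{−λ t_c})` with t_c
measured in event ranks (last event t = 0). "Normalize" is L2: it makes
the vector cosine-compatible and lets per-site partial vectors be summed
and renormalized meaningfully. λ defaults to 0 (the plain sum direction);
experiments expose it as a parameter since no single reference value is
canonical. Events missing from the vocabulary are skipped and counted;
an all-skipped pathway yields a flagged zero vector that scores 0 and is
excluded from AUC denominators.

Cross-site combination normalizes each per-site partial vector before
summation (equalizing site influence) and renormalizes the sum; the
pre-normalization is a config switch (`prenormalize_parts`, default on).

AUC is the midrank Mann–Whitney estimator; macro averages over diagnoses
are unweighted. Similar-patient retrieval returns bank members whose
cosine to the query strictly exceeds mean + 1 population SD of the
query's similarities over the bank; label voting returns the positive
fraction among them, with an empty set mapped to a flagged,
uninformative 0.5 (the retrieval scenario excludes such votes from AUC
rather than injecting a constant).

## Synthetic cohorts

The generator is a latent-condition mixture: each patient carries 1–2 of
K latent conditions; each admission emits 6–12 typed events (type mix:
30% lab, 25% prescription, 15% condition, 15% symptom, 15% diagnosis)
from the patient's conditions' per-type categorical distributions. A
condition's distribution over a type's vocabulary is a softmax
`p ∝ exp(γ u)` over fixed uniform scores u, with γ =
`emission_concentration` (default 10, concentrating ~90% of mass on
roughly a dozen signature codes per type; γ → ∞ degenerates to one code
per condition and type). Each condition owns two target diagnosis codes
(ICD-9-style 3-digit stems from 100 up), strongly over-weighted in its
diagnosis emissions so diagnoses recur across admissions as billing codes
do; the final admission appends the targets as label events, each flipped
to a random background diagnosis (stems from 500 up) with probability
`label_noise` (default 0.05). Optional synonym groups make blocks of lab
codes distributionally exchangeable surface forms of one concept,
emulating CUI groups. Defaults are a 2000-patient, 20-condition cohort —
40 planted diagnoses, mirroring the two-disjoint-sets-of-20 deletion
design of the incomplete-information experiment.

What the generator does **not** emulate: realistic marginal code
frequencies, inter-event timing, comorbidity structure beyond 1–2
conditions, coding drift over time, or free-text notes. Passing tests
therefore show that the pipeline recovers a planted co-occurrence signal
and that harmonization restores cross-site comparability under the
model's assumptions — not that any particular AUC level would transfer
to real EHR data.

## Scenario harness

All scenarios are pure functions of (config, seed): sub-seeds are derived
by hashing, embedding training is serial, and reports embed the full
config. Patient-level k-fold cross-validation (default 10 folds) is used
for prediction scenarios; replicate-level claims (arm orderings) are
tested as paired mean differences over ≥ 10 scenario seeds, never
single-run comparisons. A leakage guard asserts that no test-fold patient
contributes to any training corpus.

Scaling: scenario defaults use 2000 synthetic patients, 20 conditions,
dim 50 — sizes chosen so the planted signal is comfortably learnable and
a full replicate runs in seconds; ordering tests use 1200–2000 patients
with a single evaluated fold per seed, trading fold-averaging for seed
replication. Candidate diagnoses default to the top-N most frequent
training labels (N = number of planted targets), standing in for a "most
common diagnoses" list.

Scenario-specific choices worth noting:

* *Incomplete information*: deleted sets are the two disjoint halves of
  the 40 planted targets (one of each condition's two target codes per
  site); each missing diagnosis is scored at the site lacking it and the
  macro average runs over all 40. Anchor pools exclude the planted
  targets.
* *Split history*: the shared ("kept") code set doubles as the anchor
  pool, matching the idea that the corresponding pairs are exactly the
  codes two sites recognize in common; everything else gets a per-site
  suffix. Combined arms use the reference site's diagnosis vectors (the
  per-site variants are symmetric).
* *Size imbalance*: arms share one test fold; the fused model serves
  both hospitals' predictions, and non-degradation is measured against
  the large site's local model.
* *Group similarity*: harmonized vectors live in a mean-centered frame,
  where cosines are systematically lower than in the raw (uncentered)
  global model whose vectors share a large common component at this
  corpus scale; the comparable baseline `global_centered` (global model
  minus its column mean) is reported alongside the raw `global` value.
  The "frequent members" variant keeps group members in the upper half of
  corpus frequency.
* *Patient retrieval*: the compensation experiment deletes all site-2
  training patients carrying the diagnosis of interest, retraining
  site 2's model per diagnosis over a small diagnosis subset (default 5).

## Known limitations

* The skip-gram trainer is optimized for determinism and desk-scale
  corpora, not throughput; million-token corpora are out of its intended
  range.
* Hub harmonization degrades gracefully but has no global consistency
  objective across ≥ 3 sites.
* PDPS scores are similarities, not calibrated probabilities.
* The similar-patient threshold (mean + 1 SD, strict) can return an
  empty set for flat similarity profiles by design; callers must handle
  the flagged uninformative vote.
* Anchor selection assumes identity correspondences (same code string at
  both sites); externally supplied anchor files may pair different
  strings, but automatic selection cannot discover such pairs.
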