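"""Patient vectors, PDPS scoring, and similarity-based prediction.

A patient's pathway S is condensed into a single *patient vector*

    v(S) = normalize( sum_{c in S} V_c * exp(-lambda * t_c) )

where V_c is the embedding of event c, lambda >= 0 a time-decay factor and
t_c the number of events between c and the pathway's last event (the last
event has t = 0, so recent events dominate for lambda > 0; lambda = 0
gives the plain sum direction). The patient-diagnosis projection
similarity (PDPS) score of diagnosis d is then cosine(V_d, v(S)); ranking
test patients by this score and comparing against their true
final-admission diagnoses yields a rank-based (Mann-Whitney) AUC per
diagnosis.

The same patient vectors support cross-site use once embeddings are
harmonized: per-site partial vectors are summed and renormalized to
approximate the global vector, and a similar-patient search returns bank
members more than one standard deviation above the mean cosine, whose
labels vote on the query's diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set

import numpy as np
from scipy.stats import rankdata

from .embeddings import EmbeddingModel, cosine
from .errors import ConfigError, EvaluationError, UnknownCodeError
from .pathways import ClinicalPathway

__all__ = [
    "DecayConfig",
    "PatientVector",
    "PredictionResult",
    "patient_vector",
    "pdps_score",
    "predict_diagnoses",
    "combine_local_patient_vectors",
    "evaluate_auc",
    "macro_auc",
    "auc_from_scores",
    "most_similar_patients",
    "vote_predict",
    "VoteResult",
    "rank_of_match",
    "group_similarity",
    "GroupSimilarityResult",
]


@dataclass(frozen=True)
class DecayConfig:
    """Time-decay factor lambda; time is measured in event ranks, with the
    pathway's last event at t = 0."""

    lam: float = 0.0
    time_scale: str = "event_rank"

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigError(f"lambda must be >= 0, got {self.lam}")
        if self.time_scale != "event_rank":
            raise ConfigError("only event_rank time scale is supported")


@dataclass
class PatientVector:
    """Unit-norm decay-weighted event-vector sum (or zero when nothing in
    the pathway had an embedding — then ``evaluable`` is False)."""

    patient_id: str
    vector: np.ndarray
    n_events_used: int = 0
    n_events_skipped: int = 0

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        norm = np.linalg.norm(self.vector)
        if norm > 0 and abs(norm - 1.0) > 1e-9:
            self.vector = self.vector / norm

    @property
    def evaluable(self) -> bool:
        return bool(np.linalg.norm(self.vector) > 0)

    @property
    def dim(self) -> int:
        return int(self.vector.shape[0])


@dataclass
class PredictionResult:
    """PDPS scores of one patient over a candidate diagnosis set."""

    patient_id: str
    scores: Dict[str, float]
    labels: Optional[Dict[str, int]] = None
    missing_candidates: List[str] = field(default_factory=list)
    evaluable: bool = True


def patient_vector(
    pathway_or_events,
    model: EmbeddingModel,
    decay: DecayConfig = DecayConfig(),
) -> PatientVector:
    """Build the time-decayed, L2-normalized patient vector.

    Accepts a :class:`ClinicalPathway` or a plain code sequence. Events
    absent from the vocabulary are skipped and counted; if every event is
    skipped the zero vector comes back flagged non-evaluable.
    """
    if isinstance(pathway_or_events, ClinicalPathway):
        pid = pathway_or_events.patient_id
        events = pathway_or_events.events
    else:
        pid = ""
        events = list(pathway_or_events)
    n = len(events)
    if n == 0:
        return PatientVector(pid, np.zeros(model.dim), 0, 0)
    acc = np.zeros(model.dim, dtype=np.float64)
    used = 0
    last = n - 1
    for i, code in enumerate(events):
        if code in model:
            acc += model.vector(code).astype(np.float64) * math.exp(
                -decay.lam * (last - i)
            )
            used += 1
    return PatientVector(pid, acc, used, n - used)


def pdps_score(patient: PatientVector, diagnosis_vector: np.ndarray) -> float:
    """cosine(V_d, patient vector); 0.0 for a non-evaluable patient."""
    d = np.asarray(diagnosis_vector, dtype=np.float64)
    if np.linalg.norm(d) == 0.0:
        raise EvaluationError("zero diagnosis vector")
    if not patient.evaluable:
        return 0.0
    return cosine(patient.vector, d)


def predict_diagnoses(
    pathway: ClinicalPathway,
    model: EmbeddingModel,
    candidates: Sequence[str],
    decay: DecayConfig = DecayConfig(),
    diagnosis_model: Optional[EmbeddingModel] = None,
    diagnosis_vectors: Optional[Mapping[str, np.ndarray]] = None,
) -> PredictionResult:
    """Score candidate next diagnoses from the pre-final-admission history.

    The pathway is truncated to events strictly before the final
    admission. Candidates absent from the vocabulary are reported in
    ``missing_candidates`` rather than scored. ``diagnosis_model`` /
    ``diagnosis_vectors`` let the candidate vectors come from a different
    (e.g. compensated) source than the patient-vector model.
    """
    history = pathway.events_before_final_admission()
    pv = patient_vector(history, model, decay)
    pv.patient_id = pathway.patient_id
    dmodel = diagnosis_model if diagnosis_model is not None else model
    scores: Dict[str, float] = {}
    missing: List[str] = []
    for cand in candidates:
        if diagnosis_vectors is not None and cand in diagnosis_vectors:
            vec = np.asarray(diagnosis_vectors[cand])
        elif cand in dmodel:
            vec = dmodel.vector(cand)
        else:
            missing.append(cand)
            continue
        scores[cand] = pdps_score(pv, vec)
    return PredictionResult(
        patient_id=pathway.patient_id,
        scores=scores,
        missing_candidates=missing,
        evaluable=pv.evaluable,
    )


def combine_local_patient_vectors(
    parts: Sequence[PatientVector], prenormalize_parts: bool = True
) -> PatientVector:
    """Approximate the global patient vector from per-site partial vectors.

    Each part is built from one site's (harmonized) embedding over that
    site's share of the history; parts are summed and the sum
    renormalized. Zero (non-evaluable) parts are excluded; with
    ``prenormalize_parts`` (default) each part enters at unit norm so
    sites contribute equally. An all-zero input yields a flagged zero
    vector.
    """
    if not parts:
        raise ConfigError("need at least one part")
    dims = {p.dim for p in parts}
    if len(dims) != 1:
        raise ConfigError(f"parts disagree on dimension: {sorted(dims)}")
    acc = np.zeros(parts[0].dim, dtype=np.float64)
    used = skipped = 0
    for p in parts:
        if not p.evaluable:
            skipped += p.n_events_skipped
            continue
        acc += p.vector  # PatientVector already stores unit norm
        used += p.n_events_used
        skipped += p.n_events_skipped
    pid = parts[0].patient_id
    return PatientVector(pid, acc, used, skipped)


def auc_from_scores(
    positives: Sequence[float], negatives: Sequence[float]
) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    pos = np.asarray(positives, dtype=np.float64)
    neg = np.asarray(negatives, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("AUC needs at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def evaluate_auc(results: Iterable[PredictionResult], diagnosis: str) -> float:
    """AUC of one diagnosis over a collection of scored patients.

    Uses ``result.labels[diagnosis]`` as ground truth; patients without a
    score or a label for the diagnosis, or flagged non-evaluable, are
    excluded. Raises a typed error naming the diagnosis when either class
    is empty.
    """
    pos, neg = [], []
    for r in results:
        if not r.evaluable or r.labels is None:
            continue
        if diagnosis not in r.scores or diagnosis not in r.labels:
            continue
        (pos if r.labels[diagnosis] else neg).append(r.scores[diagnosis])
    if not pos or not neg:
        raise EvaluationError(
            f"AUC undefined for {diagnosis!r}: {len(pos)} positives, "
            f"{len(neg)} negatives"
        )
    return auc_from_scores(pos, neg)


def macro_auc(
    results: Sequence[PredictionResult], diagnoses: Sequence[str]
) -> float:
    """Unweighted mean AUC over the evaluable diagnoses in ``diagnoses``."""
    aucs = []
    for d in diagnoses:
        try:
            aucs.append(evaluate_auc(results, d))
        except EvaluationError:
            continue
    if not aucs:
        raise EvaluationError("no diagnosis in the list was evaluable")
    return float(np.mean(aucs))


def _bank_similarities(
    query: PatientVector, bank: Sequence[PatientVector]
) -> np.ndarray:
    if not query.evaluable:
        raise EvaluationError("zero query vector")
    mat = np.vstack([b.vector for b in bank])
    norms = np.linalg.norm(mat, axis=1)
    sims = np.zeros(len(bank))
    ok = norms > 0
    sims[ok] = (mat[ok] @ query.vector) / norms[ok]
    return sims


def most_similar_patients(
    query: PatientVector, bank: Sequence[PatientVector]
) -> Set[str]:
    """Bank patients whose cosine to the query exceeds mean + 1 SD.

    The threshold uses the population SD of the query's similarities over
    the whole bank, with a strict inequality — so a flat similarity
    profile returns the empty set.
    """
    if len(bank) < 2:
        raise ConfigError("bank must contain at least 2 patients")
    sims = _bank_similarities(query, bank)
    threshold = sims.mean() + sims.std()
    return {b.patient_id for b, s in zip(bank, sims) if s > threshold}


class VoteResult(NamedTuple):
    probability: float
    informative: bool  # False when the similar set was empty


def vote_predict(
    similar: Set[str], label_map: Mapping[str, int]
) -> VoteResult:
    """Fraction of similar patients with label 1; empty set -> 0.5 flagged."""
    if not similar:
        return VoteResult(0.5, False)
    votes = [int(bool(label_map.get(pid, 0))) for pid in similar]
    return VoteResult(float(np.mean(votes)), True)


def rank_of_match(
    query: PatientVector, bank: Sequence[PatientVector], target_id: str
) -> float:
    """1-based rank of ``target_id`` by descending cosine (midrank ties)."""
    ids = [b.patient_id for b in bank]
    if target_id not in ids:
        raise EvaluationError(f"target {target_id!r} not in bank")
    sims = _bank_similarities(query, bank)
    ranks = rankdata(-sims)  # descending, midrank
    return float(ranks[ids.index(target_id)])


@dataclass
class GroupSimilarityResult:
    per_group: Dict[str, float]
    overall_mean: float
    n_skipped: int


def group_similarity(
    vectors: EmbeddingModel | Mapping[str, np.ndarray],
    groups: Mapping[str, Set[str]],
) -> GroupSimilarityResult:
    """Mean pairwise within-group cosine, per group and overall.

    Groups emulate synonym (CUI-style) groupings: members are surface
    forms of one concept. Groups with fewer than two members present in
    the vocabulary are skipped and counted; the overall value is the
    unweighted mean over evaluable groups.
    """
    def has(code):
        return code in vectors
    def vec(code):
        return vectors.vector(code) if isinstance(vectors, EmbeddingModel) else vectors[code]

    per_group: Dict[str, float] = {}
    skipped = 0
    for gid in sorted(groups):
        members = sorted(c for c in groups[gid] if has(c))
        if len(members) < 2:
            skipped += 1
            continue
        sims = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                sims.append(cosine(vec(members[i]), vec(members[j])))
        per_group[gid] = float(np.mean(sims))
    if not per_group:
        raise EvaluationError("no group has >= 2 members in the vocabulary")
    overall = float(np.mean(list(per_group.values())))
    return GroupSimilarityResult(per_group, overall, skipped)
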