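"""Scenario harness: end-to-end cross-site experiments on synthetic cohorts.

Five scenarios exercise the full pipeline (generate -> filter -> split into
sites -> train per-site skip-grams -> harmonize -> predict/retrieve ->
evaluate), each mirroring a cross-hospital situation:

* ``incomplete_info``   — each site lacks a disjoint set of planted
  diagnoses; missing diagnosis vectors are compensated with random
  vectors, raw other-site vectors, or Procrustes-harmonized other-site
  vectors, and compared against the pooled-data global model.
* ``split_history``     — every patient's history is spread over three
  sites with private code suffixes; per-site partial patient vectors are
  combined with and without harmonization.
* ``size_imbalance``    — an 80/20 .. 95/5 split; the small site's model
  is harmonized into the large site's space and fused (size-weighted
  anchors, nearest-neighbor completion).
* ``group_similarity``  — synonym-group coherence when members carry
  vectors from randomly assigned sites, before/after harmonization.
* ``patient_retrieval`` — cross-site retrieval rank of each patient's
  globally-most-similar partner, and similar-patient label voting when
  one site lacks the diagnosis of interest.

Metrics are macro (unweighted mean) AUC over the planted candidate
diagnoses, or mean cosine / retrieval rank where the scenario calls for
it. Evaluation is patient-level k-fold cross-validated; the cohort
filters are fit on the training fold only, and no test-fold patient ever
contributes to embedding training (asserted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .embeddings import EmbeddingModel, TrainingConfig, train_embeddings
from .errors import ConfigError, EvaluationError
from .harmonize import AnchorSet, fuse_models, harmonize_multi, harmonize_pair, select_anchors
from .pathways import ClinicalPathway, Cohort, filter_cohort, sentences_from_cohort
from .predict import (
    DecayConfig,
    PatientVector,
    PredictionResult,
    combine_local_patient_vectors,
    group_similarity,
    macro_auc,
    most_similar_patients,
    patient_vector,
    pdps_score,
    rank_of_match,
    vote_predict,
)
from .synthdata import (
    GroundTruth,
    SyntheticConfig,
    delete_diagnoses,
    generate_cohort,
    split_sites,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "ScenarioReport",
    "cross_validate",
    "run_incomplete_info",
    "run_split_history",
    "run_size_imbalance",
    "run_group_similarity",
    "run_patient_retrieval",
    "run_scenario",
]

SCENARIOS = (
    "incomplete_info",
    "split_history",
    "size_imbalance",
    "group_similarity",
    "patient_retrieval",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything a scenario run needs; runs are pure functions of this."""

    scenario: str
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    training: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(dim=50, window=5, epochs=5, seed=7)
    )
    anchor_fraction: float = 0.4
    anchor_fractions: Tuple[float, ...] = ()  # per-scenario grid; empty -> default
    anchor_strategy: str = "random_fraction"
    site_fractions: Tuple[float, ...] = (0.5, 0.5)
    size_ratios: Tuple[Tuple[float, float], ...] = ((0.8, 0.2), (0.9, 0.1), (0.95, 0.05))
    lam: float = 0.0
    n_folds: int = 10
    eval_folds: Optional[int] = None  # evaluate only the first k folds
    candidate_policy: str = "top_n"  # top_n | all_diagnoses
    top_n: Optional[int] = None  # None -> number of planted targets
    min_event_admissions: int = 5
    n_retrieval_diagnoses: int = 5
    n_rank_queries: int = 200
    frequent_fraction: float = 0.5
    arms: Tuple[str, ...] = ()  # empty -> all arms
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if not (0.0 < self.anchor_fraction <= 1.0):
            raise ConfigError("anchor_fraction must be in (0, 1]")
        if self.candidate_policy not in ("top_n", "all_diagnoses"):
            raise ConfigError(f"unknown candidate_policy {self.candidate_policy!r}")
        if self.eval_folds is not None and not (1 <= self.eval_folds <= self.n_folds):
            raise ConfigError("eval_folds must be in [1, n_folds]")


@dataclass
class ScenarioReport:
    """Per-arm metric table plus full provenance."""

    scenario: str
    arms: Dict[str, Dict[str, Any]]
    provenance: Dict[str, Any]
    extras: Dict[str, Any] = field(default_factory=dict)

    def macro(self, arm: str) -> float:
        return float(self.arms[arm]["macro"])

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=default)

    def to_csv(self, path) -> None:
        import csv

        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["arm", "metric", "value"])
            for arm in sorted(self.arms):
                for metric, value in sorted(self.arms[arm].items()):
                    if isinstance(value, (int, float)):
                        writer.writerow([arm, metric, value])


def _subseed(seed: int, *idx: int) -> int:
    """Derive a stable sub-seed below 2**31."""
    h = seed & 0xFFFFFFFFFFFFFFFF
    for i in idx:
        h = ((h * 0x100000001B3) ^ (i + 1)) & 0xFFFFFFFFFFFFFFFF
    return h % (2**31 - 1)


def cross_validate(
    cohort: Cohort, n_folds: int, seed: int = 0
) -> List[Tuple[Cohort, Cohort]]:
    """Patient-level k-fold partition (fold sizes differ by <= 1)."""
    ids = cohort.patient_ids
    if n_folds > len(ids):
        raise EvaluationError(f"{n_folds} folds but only {len(ids)} patients")
    if n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    folds = [list(f) for f in np.array_split(perm, n_folds)]
    out = []
    for i, test_ids in enumerate(folds):
        train_ids = [pid for j, f in enumerate(folds) if j != i for pid in f]
        train, test = cohort.subset(train_ids), cohort.subset(test_ids)
        assert not (set(train.pathways) & set(test.pathways))  # leakage guard
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# shared plumbing

def _train(cohort: Cohort, tc: TrainingConfig) -> EmbeddingModel:
    return train_embeddings(sentences_from_cohort(cohort), tc)


def _candidates(train: Cohort, config: ScenarioConfig, gt: GroundTruth) -> List[str]:
    """Candidate diagnosis list: all labels seen in training, or the top-N
    most frequent (ties lexicographic)."""
    counts: Dict[str, int] = {}
    for labels in train.label_map.values():
        for d in labels:
            counts[d] = counts.get(d, 0) + 1
    if config.candidate_policy == "all_diagnoses":
        return sorted(counts)
    top_n = config.top_n or len(gt.target_diagnoses)
    return sorted(sorted(counts, key=lambda d: (-counts[d], d))[:top_n])


def _label(test: Cohort, pid: str, candidates: Sequence[str]) -> Dict[str, int]:
    labels = test.label_map.get(pid, set())
    return {d: int(d in labels) for d in candidates}


def _score_fold(
    test: Cohort,
    pv_model: EmbeddingModel,
    candidates: Sequence[str],
    lam: float,
    diagnosis_vectors: Optional[Mapping[str, np.ndarray]] = None,
    diagnosis_model: Optional[EmbeddingModel] = None,
    label_candidates: Optional[Sequence[str]] = None,
) -> List[PredictionResult]:
    """PDPS-score every test patient's pre-final history.

    ``label_candidates`` maps score keys to label keys when candidates are
    site-suffixed variants of the label codes (same order as candidates).
    """
    dmodel = diagnosis_model if diagnosis_model is not None else pv_model
    decay = DecayConfig(lam)
    lab_cands = list(label_candidates) if label_candidates is not None else list(candidates)
    results = []
    for pid in test.patient_ids:
        pw = test.pathways[pid]
        pv = patient_vector(pw.events_before_final_admission(), pv_model, decay)
        scores: Dict[str, float] = {}
        for cand, lab in zip(candidates, lab_cands):
            if diagnosis_vectors is not None and cand in diagnosis_vectors:
                vec = np.asarray(diagnosis_vectors[cand])
            elif cand in dmodel:
                vec = dmodel.vector(cand)
            else:
                continue
            scores[lab] = pdps_score(pv, vec)
        results.append(
            PredictionResult(
                patient_id=pid,
                scores=scores,
                labels=_label(test, pid, lab_cands),
                evaluable=pv.evaluable,
            )
        )
    return results


def _provenance(config: ScenarioConfig) -> Dict[str, Any]:
    import scipy

    return {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__},
        "timestamp": time.time(),
    }


def _folds_for(config: ScenarioConfig, cohort: Cohort) -> List[Tuple[Cohort, Cohort]]:
    folds = cross_validate(cohort, config.n_folds, seed=_subseed(config.seed, 1))
    if config.eval_folds is not None:
        folds = folds[: config.eval_folds]
    return folds


def _wanted(config: ScenarioConfig, arm: str) -> bool:
    return not config.arms or arm in config.arms


def _mean_over_folds(per_fold: Dict[str, List[float]]) -> Dict[str, Dict[str, Any]]:
    return {
        arm: {"macro": float(np.mean(vals)), "per_fold": vals}
        for arm, vals in per_fold.items()
        if vals
    }


# ---------------------------------------------------------------------------
# incomplete information

def run_incomplete_info(config: ScenarioConfig) -> ScenarioReport:
    """Compensating missing diagnosis vectors across two sites.

    The planted target diagnoses are split into two disjoint sets; each
    site's training data has one set's events deleted. Arms score each
    missing diagnosis at the site lacking it (macro over all deleted
    codes): ``global`` (pooled model), ``random`` (seeded unit-norm
    random vectors), ``local`` (raw other-site vectors), and
    ``prot_<pct>`` (other-site vectors after pairwise harmonization at
    each anchor fraction).
    """
    if config.scenario != "incomplete_info":
        raise ConfigError(f"config is for {config.scenario!r}")
    syn = replace(config.synthetic, seed=_subseed(config.seed, 0))
    cohort, gt = generate_cohort(syn)
    targets = gt.target_diagnoses
    half = [set(targets[0::2]), set(targets[1::2])]  # disjoint deleted sets
    fractions = config.anchor_fractions or (0.1, 0.4, 0.7)

    per_fold: Dict[str, List[float]] = {}
    for fold_i, (train, test) in enumerate(_folds_for(config, cohort)):
        train = filter_cohort(train, 2, config.min_event_admissions)
        candidates = _candidates(train, config, gt)
        deleted = [sorted(h & set(candidates)) for h in half]
        sites = split_sites(train, config.site_fractions, seed=_subseed(config.seed, 2, fold_i))
        site_models = [
            _train(delete_diagnoses(site, half[i]), config.training)
            for i, site in enumerate(sites[:2])
        ]

        def arm_auc(dvecs, models=None, dmodels=None):
            models = models or site_models
            per_site = []
            for i in (0, 1):
                res = _score_fold(
                    test,
                    models[i],
                    deleted[i],
                    config.lam,
                    diagnosis_vectors=dvecs[i] if dvecs else None,
                    diagnosis_model=(dmodels[i] if dmodels else None),
                )
                per_site.append(macro_auc(res, deleted[i]))
            return float(np.mean(per_site))

        if _wanted(config, "global"):
            g = _train(train, config.training)
            per_fold.setdefault("global", []).append(arm_auc(None, models=[g, g]))
        if _wanted(config, "random"):
            rng = np.random.default_rng(_subseed(config.seed, 3, fold_i))
            dvecs = []
            for i in (0, 1):
                vecs = {}
                for d in deleted[i]:
                    v = rng.standard_normal(config.training.dim)
                    vecs[d] = v / np.linalg.norm(v)
                dvecs.append(vecs)
            per_fold.setdefault("random", []).append(arm_auc(dvecs))
        if _wanted(config, "local"):
            dvecs = [
                {d: site_models[1 - i].vector(d) for d in deleted[i] if d in site_models[1 - i]}
                for i in (0, 1)
            ]
            per_fold.setdefault("local", []).append(arm_auc(dvecs))
        anchor_pool = (
            set(site_models[0].vocabulary)
            & set(site_models[1].vocabulary)
        ) - set(targets)
        for frac in fractions:
            arm = f"prot_{int(round(frac * 100))}"
            if not _wanted(config, arm):
                continue
            models, dvecs = [], []
            for i in (0, 1):
                anchors = select_anchors(
                    site_models[i],
                    site_models[1 - i],
                    config.anchor_strategy,
                    frac,
                    seed=_subseed(config.seed, 4, fold_i),
                    pool=anchor_pool,
                )
                h = harmonize_pair(site_models[i], site_models[1 - i], anchors)
                models.append(h.reference)
                dvecs.append({d: h.moving.vector(d) for d in deleted[i] if d in h.moving})
            per_fold.setdefault(arm, []).append(arm_auc(dvecs, models=models))

    return ScenarioReport(
        scenario=config.scenario,
        arms=_mean_over_folds(per_fold),
        provenance=_provenance(config),
        extras={"deleted_diagnoses": [sorted(h) for h in half]},
    )


# ---------------------------------------------------------------------------
# split patient history

def _split_pathway_sections(events: Sequence[str], n_sections: int = 3) -> List[List[str]]:
    """Contiguous near-equal thirds of an event sequence."""
    return [list(part) for part in np.array_split(np.asarray(events, dtype=object), n_sections)]


def _section_cohort(cohort: Cohort, section: int, n_sections: int = 3) -> Cohort:
    """Keep only each patient's section-th third of events (full pathway),
    preserving admission indices; emptied pathways are dropped."""
    pathways = {}
    for pid, pw in cohort.pathways.items():
        parts_ev = _split_pathway_sections(pw.events, n_sections)
        parts_ai = _split_pathway_sections(pw.admission_index, n_sections)
        ev = parts_ev[section]
        if ev:
            pathways[pid] = ClinicalPathway(pid, ev, [int(a) for a in parts_ai[section]])
    label_map = {p: set(s) for p, s in cohort.label_map.items() if p in pathways}
    return Cohort(pathways=pathways, label_map=label_map)


def run_split_history(config: ScenarioConfig) -> ScenarioReport:
    """Patients whose histories are spread across three suffixed sites.

    Each training patient's pathway is cut into three contiguous sections;
    site m trains on section m with suffix ``_m<m>`` on every code outside
    the shared (anchor) set. Test patients' pre-final histories are cut
    and suffixed the same way. Arms: ``global``, per-site
    ``local<m>_original`` / ``local<m>_prot``, and the summed-and-
    renormalized ``combined_original`` / ``combined_prot`` (diagnosis
    vectors from site 1, the hub reference).
    """
    if config.scenario != "split_history":
        raise ConfigError(f"config is for {config.scenario!r}")
    syn = replace(config.synthetic, seed=_subseed(config.seed, 0))
    cohort, gt = generate_cohort(syn)
    suffixes = ["_m1", "_m2", "_m3"]

    per_fold: Dict[str, List[float]] = {}
    coverage: List[float] = []
    for fold_i, (train, test) in enumerate(_folds_for(config, cohort)):
        train = filter_cohort(train, 2, config.min_event_admissions)
        candidates = _candidates(train, config, gt)

        vocab = sorted({c for pw in train.pathways.values() for c in pw.events})
        rng = np.random.default_rng(_subseed(config.seed, 2, fold_i))
        n_keep = int(np.ceil(config.anchor_fraction * len(vocab)))
        keep = set(
            np.asarray(vocab, dtype=object)[
                np.sort(rng.choice(len(vocab), size=n_keep, replace=False))
            ]
        )

        from .synthdata import relabel_site_codes

        site_cohorts = [
            relabel_site_codes(_section_cohort(train, m), suffixes[m], keep)
            for m in range(3)
        ]
        models = [_train(sc, config.training) for sc in site_cohorts]
        g = _train(train, config.training) if _wanted(config, "global") else None

        anchor_sets = {
            j: select_anchors(models[0], models[j], "random_fraction", 1.0, pool=keep)
            for j in (1, 2)
        }
        harmonized = harmonize_multi(models, anchor_sets, reference_index=0)

        def site_cands(m: int) -> List[str]:
            return [c if c in keep else c + suffixes[m] for c in candidates]

        if g is not None:
            res = _score_fold(test, g, candidates, config.lam)
            per_fold.setdefault("global", []).append(macro_auc(res, candidates))

        # per-patient sectioned pre-final histories, suffixed per site
        sections: Dict[str, List[List[str]]] = {}
        for pid in test.patient_ids:
            history = test.pathways[pid].events_before_final_admission()
            parts = _split_pathway_sections(history, 3)
            sections[pid] = [
                [c if c in keep else c + suffixes[m] for c in parts[m]]
                for m in range(3)
            ]
            used = sum(len(p) for p in parts)
            if used:
                coverage.append(len(parts[0]) / used)

        decay = DecayConfig(config.lam)

        def local_vectors(model_list) -> Dict[str, List[PatientVector]]:
            out = {}
            for pid in test.patient_ids:
                out[pid] = [
                    patient_vector(sections[pid][m], model_list[m], decay)
                    for m in range(3)
                ]
            return out

        def score_with(pv_by_pid: Dict[str, PatientVector], dmodel, m: int):
            results = []
            cands = site_cands(m)
            for pid in test.patient_ids:
                pv = pv_by_pid[pid]
                scores = {
                    lab: pdps_score(pv, dmodel.vector(c))
                    for c, lab in zip(cands, candidates)
                    if c in dmodel
                }
                results.append(
                    PredictionResult(pid, scores, _label(test, pid, candidates),
                                     evaluable=pv.evaluable)
                )
            return macro_auc(results, candidates)

        for tag, model_list in (("original", models), ("prot", harmonized)):
            locs = local_vectors(model_list)
            for m in range(3):
                arm = f"local{m + 1}_{tag}"
                if _wanted(config, arm):
                    per_site = {pid: locs[pid][m] for pid in locs}
                    per_fold.setdefault(arm, []).append(
                        score_with(per_site, model_list[m], m)
                    )
            arm = f"combined_{tag}"
            if _wanted(config, arm):
                combined = {
                    pid: combine_local_patient_vectors(locs[pid]) for pid in locs
                }
                per_fold.setdefault(arm, []).append(
                    score_with(combined, model_list[0], 0)
                )

    return ScenarioReport(
        scenario=config.scenario,
        arms=_mean_over_folds(per_fold),
        provenance=_provenance(config),
        extras={"mean_section1_event_share": float(np.mean(coverage)) if coverage else None},
    )


# ---------------------------------------------------------------------------
# hospitals with different sizes

def run_size_imbalance(config: ScenarioConfig) -> ScenarioReport:
    """Small-hospital fusion: for each size ratio and anchor fraction,
    harmonize the small site into the large site's space, fuse with
    size-proportional weights, and compare ``small_local`` /
    ``large_local`` / ``fused`` AUC on a shared test fold."""
    if config.scenario != "size_imbalance":
        raise ConfigError(f"config is for {config.scenario!r}")
    syn = replace(config.synthetic, seed=_subseed(config.seed, 0))
    cohort, gt = generate_cohort(syn)
    fractions = config.anchor_fractions or (0.4, 0.7, 1.0)

    per_fold: Dict[str, List[float]] = {}
    for fold_i, (train, test) in enumerate(_folds_for(config, cohort)):
        train = filter_cohort(train, 2, config.min_event_admissions)
        candidates = _candidates(train, config, gt)
        for ratio in config.size_ratios:
            big_f, small_f = ratio
            tag = f"{int(round(big_f * 100))}-{int(round(small_f * 100))}"
            big, small = split_sites(
                train, [big_f, small_f], seed=_subseed(config.seed, 2, fold_i)
            )
            m_big = _train(big, config.training)
            m_small = _train(small, config.training)

            for base, model in (("large_local", m_big), ("small_local", m_small)):
                arm = f"{tag}|{base}"
                if _wanted(config, arm):
                    res = _score_fold(test, model, candidates, config.lam)
                    per_fold.setdefault(arm, []).append(macro_auc(res, candidates))

            for frac in fractions:
                arm = f"{tag}|anchors{int(round(frac * 100))}|fused"
                if not _wanted(config, arm):
                    continue
                anchors = select_anchors(
                    m_big,
                    m_small,
                    config.anchor_strategy,
                    frac,
                    seed=_subseed(config.seed, 3, fold_i),
                )
                h = harmonize_pair(m_big, m_small, anchors)
                fused = fuse_models(h.reference, h.moving, anchors, weight_a=big_f)
                res = _score_fold(test, fused, candidates, config.lam)
                per_fold.setdefault(arm, []).append(macro_auc(res, candidates))

    return ScenarioReport(
        scenario=config.scenario,
        arms=_mean_over_folds(per_fold),
        provenance=_provenance(config),
    )


# ---------------------------------------------------------------------------
# synonym-group (CUI-analogue) similarity

def run_group_similarity(config: ScenarioConfig) -> ScenarioReport:
    """Within-synonym-group cosine coherence under mixed site assignment.

    Trains a global model and two half-cohort site models, randomly
    assigns each group member a site-1 or site-2 vector, and reports the
    overall mean within-group cosine for the global model, the mixed
    unharmonized assignment, and the mixed harmonized assignment — plus
    the variant restricted to the most frequent members.
    """
    if config.scenario != "group_similarity":
        raise ConfigError(f"config is for {config.scenario!r}")
    if config.synthetic.n_synonym_groups < 1:
        raise ConfigError("group_similarity needs synonym groups")
    syn = replace(config.synthetic, seed=_subseed(config.seed, 0))
    cohort, gt = generate_cohort(syn)
    cohort = filter_cohort(cohort, 2, config.min_event_admissions)
    groups = {g: set(m) for g, m in gt.synonym_groups.items()}

    s1, s2 = split_sites(cohort, config.site_fractions, seed=_subseed(config.seed, 2))
    g_model = _train(cohort, config.training)
    # sites train with different seeds: truly independently trained models
    m1 = _train(s1, config.training)
    m2 = _train(s2, replace(config.training, seed=config.training.seed + 1))
    anchors = select_anchors(
        m1, m2, config.anchor_strategy, config.anchor_fraction,
        corpus_frequencies=_corpus_frequencies(cohort),
        seed=_subseed(config.seed, 3),
    )
    h = harmonize_pair(m1, m2, anchors)

    rng = np.random.default_rng(_subseed(config.seed, 4))
    assignment: Dict[str, int] = {}
    for gid in sorted(groups):
        for code in sorted(groups[gid]):
            assignment[code] = int(rng.integers(0, 2))

    def mixed_vectors(site_models) -> Dict[str, np.ndarray]:
        out = {}
        for code, site in assignment.items():
            pick = site_models[site] if code in site_models[site] else site_models[1 - site]
            if code in pick:
                out[code] = pick.vector(code)
        return out

    freqs = _corpus_frequencies(cohort)
    member_counts = sorted(
        freqs.get(c, 0) for ms in groups.values() for c in ms
    )
    cut = member_counts[int((1.0 - config.frequent_fraction) * len(member_counts))]
    frequent_groups = {
        gid: {c for c in ms if freqs.get(c, 0) >= cut} for gid, ms in groups.items()
    }

    arms: Dict[str, Dict[str, Any]] = {}

    def add(arm: str, vectors, grp):
        if not _wanted(config, arm):
            return
        try:
            res = group_similarity(vectors, grp)
        except EvaluationError:
            return
        arms[arm] = {
            "macro": res.overall_mean,
            "per_group": res.per_group,
            "n_groups_skipped": res.n_skipped,
        }

    add("global", g_model, groups)
    # harmonized vectors live in a mean-centered frame; the comparable
    # global baseline is the global model centered the same way
    g_centered = EmbeddingModel(
        vocabulary=list(g_model.vocabulary),
        matrix=g_model.matrix - g_model.matrix.mean(axis=0),
        metadata={"centered": True},
    )
    add("global_centered", g_centered, groups)
    add("mixed_original", mixed_vectors([m1, m2]), groups)
    add("mixed_prot", mixed_vectors([h.reference, h.moving]), groups)
    add("mixed_original_frequent", mixed_vectors([m1, m2]), frequent_groups)
    add("mixed_prot_frequent", mixed_vectors([h.reference, h.moving]), frequent_groups)

    return ScenarioReport(
        scenario=config.scenario, arms=arms, provenance=_provenance(config)
    )


def _corpus_frequencies(cohort: Cohort) -> Dict[str, int]:
    freqs: Dict[str, int] = {}
    for pw in cohort.pathways.values():
        for c in pw.events:
            freqs[c] = freqs.get(c, 0) + 1
    return freqs


# ---------------------------------------------------------------------------
# patient similarity / retrieval

def run_patient_retrieval(config: ScenarioConfig) -> ScenarioReport:
    """Cross-site similar-patient retrieval and label-vote prediction.

    Rank experiment: the globally-most-similar site-2 partner of each
    site-1 patient is ranked in the site-2 bank using local patient
    vectors, with and without harmonization (``mean_rank_*`` extras).

    Compensation experiment: for each diagnosis of interest, site 2's
    training patients carrying it are removed; test patients are scored by
    voting over their above-threshold most-similar training patients in
    four arms — (a) site-1 query / site-1 bank, (b) site-2 query /
    depleted site-2 bank, (c) unharmonized site-2 query / site-1 bank,
    (d) harmonized site-2 query / site-1 bank.
    """
    if config.scenario != "patient_retrieval":
        raise ConfigError(f"config is for {config.scenario!r}")
    syn = replace(config.synthetic, seed=_subseed(config.seed, 0))
    cohort, gt = generate_cohort(syn)
    train, test = _folds_for(config, cohort)[0]
    train = filter_cohort(train, 2, config.min_event_admissions)
    decay = DecayConfig(config.lam)

    s1, s2 = split_sites(train, config.site_fractions, seed=_subseed(config.seed, 2))
    m1 = _train(s1, config.training)
    m2 = _train(s2, config.training)
    g_model = _train(train, config.training)
    anchors = select_anchors(
        m1, m2, config.anchor_strategy, config.anchor_fraction,
        corpus_frequencies=_corpus_frequencies(train),
        seed=_subseed(config.seed, 3),
    )
    h = harmonize_pair(m1, m2, anchors)

    def vectors(cohort_: Cohort, model: EmbeddingModel) -> Dict[str, PatientVector]:
        return {
            pid: patient_vector(cohort_.pathways[pid], model, decay)
            for pid in cohort_.patient_ids
        }

    # --- rank experiment --------------------------------------------------
    gv1 = vectors(s1, g_model)
    gv2 = vectors(s2, g_model)
    bank_ids = sorted(gv2)
    bank_mat = np.vstack([gv2[p].vector for p in bank_ids])
    queries = sorted(gv1)[: config.n_rank_queries]

    partners = {}
    for pid in queries:
        if not gv1[pid].evaluable:
            continue
        sims = bank_mat @ gv1[pid].vector
        partners[pid] = bank_ids[int(np.argmax(sims))]

    ranks: Dict[str, List[float]] = {"original": [], "prot": []}
    for tag, (qm, bm) in (("original", (m1, m2)), ("prot", (h.reference, h.moving))):
        qv = {pid: patient_vector(s1.pathways[pid], qm, decay) for pid in partners}
        bank = [patient_vector(s2.pathways[p], bm, decay) for p in bank_ids]
        for pid, partner in partners.items():
            if qv[pid].evaluable:
                ranks[tag].append(rank_of_match(qv[pid], bank, partner))

    # --- compensation (voting) experiment ---------------------------------
    targets = gt.target_diagnoses[: config.n_retrieval_diagnoses]
    arm_aucs: Dict[str, List[float]] = {k: [] for k in ("a", "b", "c", "d")}
    from .predict import auc_from_scores

    bank1 = vectors(s1, m1)
    for di, diag in enumerate(targets):
        carriers = {pid for pid, labels in s2.label_map.items() if diag in labels}
        s2_d = s2.subset(set(s2.patient_ids) - carriers)
        m2_d = _train(s2_d, config.training)
        anchors_d = select_anchors(
            m1, m2_d, config.anchor_strategy, config.anchor_fraction,
            corpus_frequencies=_corpus_frequencies(train),
            seed=_subseed(config.seed, 5, di),
        )
        h_d = harmonize_pair(m1, m2_d, anchors_d)

        bank_sets = {
            "a": [bank1[p] for p in sorted(bank1)],
            "b": [patient_vector(s2_d.pathways[p], m2_d, decay) for p in s2_d.patient_ids],
            "c": [bank1[p] for p in sorted(bank1)],
            "d": [
                patient_vector(s1.pathways[p], h_d.reference, decay)
                for p in s1.patient_ids
            ],
        }
        label_sets = {
            "a": {p: int(diag in s1.label_map.get(p, set())) for p in s1.patient_ids},
            "b": {p: int(diag in s2_d.label_map.get(p, set())) for p in s2_d.patient_ids},
            "c": {p: int(diag in s1.label_map.get(p, set())) for p in s1.patient_ids},
            "d": {p: int(diag in s1.label_map.get(p, set())) for p in s1.patient_ids},
        }
        query_models = {"a": m1, "b": m2_d, "c": m2_d, "d": h_d.moving}

        for arm in ("a", "b", "c", "d"):
            if not _wanted(config, arm):
                continue
            pos, neg = [], []
            for pid in test.patient_ids:
                history = test.pathways[pid].events_before_final_admission()
                pv = patient_vector(history, query_models[arm], decay)
                if not pv.evaluable:
                    continue
                similar = most_similar_patients(pv, bank_sets[arm])
                vote = vote_predict(similar, label_sets[arm])
                if not vote.informative:
                    continue  # empty similar set: no vote, excluded
                y = int(diag in test.label_map.get(pid, set()))
                (pos if y else neg).append(vote.probability)
            if pos and neg:
                arm_aucs[arm].append(auc_from_scores(pos, neg))

    arms = {
        f"arm_{k}": {"macro": float(np.mean(v)), "per_diagnosis": v}
        for k, v in arm_aucs.items()
        if v
    }
    return ScenarioReport(
        scenario=config.scenario,
        arms=arms,
        provenance=_provenance(config),
        extras={
            "mean_rank_original": float(np.mean(ranks["original"])) if ranks["original"] else None,
            "mean_rank_prot": float(np.mean(ranks["prot"])) if ranks["prot"] else None,
            "n_rank_queries": len(partners),
            "bank_size": len(bank_ids),
        },
    )


_RUNNERS = {
    "incomplete_info": run_incomplete_info,
    "split_history": run_split_history,
    "size_imbalance": run_size_imbalance,
    "group_similarity": run_group_similarity,
    "patient_retrieval": run_patient_retrieval,
}


def run_scenario(config: ScenarioConfig) -> ScenarioReport:
    """Dispatch to the scenario's runner."""
    return _RUNNERS[config.scenario](config)
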