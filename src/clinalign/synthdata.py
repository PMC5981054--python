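"""Synthetic multi-admission EHR cohorts with planted latent structure.

Real clinical event streams are protected; everything in this package is
exercised instead on cohorts drawn from a latent-condition mixture model:

* each patient carries one or two latent *conditions* (disease topics);
* each admission emits typed coded events (labs, prescriptions,
  conditions, symptoms, diagnoses) from the patient's conditions'
  per-type categorical emission distributions, whose peakedness is set by
  ``emission_concentration`` (softmax over fixed uniform scores — the
  infinite-concentration limit emits one deterministic code per condition
  and type);
* each condition owns one or more *target diagnosis* codes, heavily
  over-weighted in its diagnosis emissions (diagnoses recur across
  admissions, as ICD billing codes do in real records) and written into
  the final admission as the ground-truth label, flipped to a random
  background diagnosis with probability ``label_noise``;
* optional synonym groups make several lab codes distributionally
  exchangeable surface forms of one concept, emulating CUI groups.

The planted pathway->diagnosis signal is what the embedding, alignment and
prediction layers are measured against. Generators are pure functions of
(config, seed). The module also provides site splitting, suffix
relabeling (simulated private terminologies), targeted diagnosis deletion,
and a ground-truth-transformed embedding harness for alignment recovery
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .embeddings import EmbeddingModel
from .errors import ConfigError
from .harmonize import HarmonizationTransform
from .pathways import (
    ClinicalPathway,
    Cohort,
    EventType,
    MedicalEvent,
    cohort_from_events,
    truncate_icd9,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_events",
    "split_sites",
    "relabel_site_codes",
    "delete_diagnoses",
    "simulate_transformed_embedding",
]

_TYPE_ORDER = [
    EventType.LAB,
    EventType.PRESCRIPTION,
    EventType.CONDITION,
    EventType.SYMPTOM,
    EventType.DIAGNOSIS,
]
_TYPE_PROBS = np.array([0.30, 0.25, 0.15, 0.15, 0.15])
_TYPE_CODE_FMT = {
    EventType.LAB: "L{:03d}",
    EventType.PRESCRIPTION: "P{:03d}",
    EventType.CONDITION: "C{:03d}",
    EventType.SYMPTOM: "S{:03d}",
}
# Diagnosis stems are ICD-9-style 3-digit strings: targets from 100 up,
# background codes from 500 up; raw events carry a decimal sub-code so the
# level-3 truncation path is exercised.
_TARGET_BASE = 100
_BACKGROUND_BASE = 500


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generative parameters (defaults are the study
    conditions: a 2000-patient, 20-condition cohort with 40 planted target
    diagnoses)."""

    n_patients: int = 2000
    n_conditions: int = 20
    vocab_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "lab": 150,
            "prescription": 120,
            "condition": 80,
            "symptom": 80,
            "diagnosis": 100,
        }
    )
    admissions_per_patient: Tuple[int, int] = (2, 5)
    events_per_admission: Tuple[int, int] = (6, 12)
    emission_concentration: float = 10.0
    label_noise: float = 0.05
    diagnoses_per_condition: int = 2
    conditions_per_patient: Tuple[int, int] = (1, 2)
    n_synonym_groups: int = 15
    synonym_group_size: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_conditions < 1:
            raise ConfigError("n_patients and n_conditions must be positive")
        for t in _TYPE_ORDER:
            if self.vocab_sizes.get(t.value, 0) < 1:
                raise ConfigError(f"vocab size for {t.value!r} must be positive")
        for name, rng_ in (
            ("admissions_per_patient", self.admissions_per_patient),
            ("events_per_admission", self.events_per_admission),
            ("conditions_per_patient", self.conditions_per_patient),
        ):
            lo, hi = rng_
            if not (1 <= lo <= hi):
                raise ConfigError(f"{name} range {rng_} is empty or non-positive")
        if not (0.0 <= self.label_noise < 0.5):
            raise ConfigError("label_noise must be in [0, 0.5)")
        if self.emission_concentration <= 0:
            raise ConfigError("emission_concentration must be positive")
        if self.diagnoses_per_condition < 1:
            raise ConfigError("diagnoses_per_condition must be >= 1")
        n_targets = self.n_conditions * self.diagnoses_per_condition
        if n_targets > self.vocab_sizes["diagnosis"]:
            raise ConfigError(
                f"{n_targets} target diagnoses exceed the diagnosis vocabulary "
                f"({self.vocab_sizes['diagnosis']})"
            )
        if n_targets > _BACKGROUND_BASE - _TARGET_BASE:
            raise ConfigError("too many target diagnoses for the code numbering scheme")
        if self.conditions_per_patient[1] > self.n_conditions:
            raise ConfigError("conditions_per_patient exceeds n_conditions")
        if self.n_synonym_groups * self.synonym_group_size > self.vocab_sizes["lab"]:
            raise ConfigError("synonym groups exceed the lab vocabulary")


@dataclass
class GroundTruth:
    """What was planted: who has which condition, which diagnosis codes a
    condition targets (prefixed, level-3), the emission distributions, and
    the synonym groups (prefixed member codes)."""

    patient_conditions: Dict[str, Tuple[int, ...]]
    condition_diagnoses: Dict[int, Tuple[str, ...]]
    emissions: Dict[int, Dict[str, np.ndarray]]
    synonym_groups: Dict[str, Set[str]]

    @property
    def target_diagnoses(self) -> List[str]:
        return sorted({d for ds in self.condition_diagnoses.values() for d in ds})

    def positives(self, diagnosis: str) -> Set[str]:
        """Patients whose conditions target the given prefixed diagnosis."""
        conds = {
            k for k, ds in self.condition_diagnoses.items() if diagnosis in ds
        }
        return {
            pid
            for pid, ks in self.patient_conditions.items()
            if conds & set(ks)
        }


def _softmax_scores(rng: np.random.Generator, size: int, gamma: float,
                    boost: Optional[Sequence[int]] = None) -> np.ndarray:
    """exp(gamma * u) / sum, u ~ U(0,1) iid, computed stably so the
    gamma -> inf limit is a one-hot at the (boosted) argmax."""
    u = rng.random(size)
    if boost is not None:
        u[np.asarray(boost, dtype=int)] = 1.5 + rng.random(len(boost))
    z = gamma * (u - u.max())
    p = np.exp(z)
    return p / p.sum()


def _diag_stem(i: int, n_targets: int) -> str:
    return str(_TARGET_BASE + i) if i < n_targets else str(_BACKGROUND_BASE + i - n_targets)


def generate_events(config: SyntheticConfig) -> Tuple[List[MedicalEvent], GroundTruth]:
    """Draw the raw (unprefixed, untruncated) event stream plus ground truth."""
    rng = np.random.default_rng(config.seed)
    K = config.n_conditions
    dpc = config.diagnoses_per_condition
    n_targets = K * dpc
    gamma = config.emission_concentration
    vocab_n = {t: config.vocab_sizes[t.value] for t in _TYPE_ORDER}

    # --- planted structure ------------------------------------------------
    condition_diagnoses = {
        k: tuple(f"d_{_diag_stem(k * dpc + j, n_targets)}" for j in range(dpc))
        for k in range(K)
    }
    emissions: Dict[int, Dict[str, np.ndarray]] = {}
    for k in range(K):
        per_type: Dict[str, np.ndarray] = {}
        for t in _TYPE_ORDER:
            boost = (
                list(range(k * dpc, (k + 1) * dpc))
                if t is EventType.DIAGNOSIS
                else None
            )
            per_type[t.value] = _softmax_scores(rng, vocab_n[t], gamma, boost)
        emissions[k] = per_type

    # synonym groups over lab codes: a seeded permutation carved into
    # disjoint blocks; an emitted member is resampled uniformly in-group
    lab_perm = rng.permutation(vocab_n[EventType.LAB])
    group_of_lab = np.full(vocab_n[EventType.LAB], -1, dtype=int)
    group_members: List[np.ndarray] = []
    synonym_groups: Dict[str, Set[str]] = {}
    for g in range(config.n_synonym_groups):
        members = lab_perm[
            g * config.synonym_group_size : (g + 1) * config.synonym_group_size
        ]
        group_of_lab[members] = g
        group_members.append(members)
        synonym_groups[f"g{g:02d}"] = {
            "l_" + _TYPE_CODE_FMT[EventType.LAB].format(i) for i in members
        }

    # --- per-patient skeleton --------------------------------------------
    a_lo, a_hi = config.admissions_per_patient
    e_lo, e_hi = config.events_per_admission
    c_lo, c_hi = config.conditions_per_patient

    patient_conditions: Dict[str, Tuple[int, ...]] = {}
    ev_cond: List[np.ndarray] = []
    ev_type: List[np.ndarray] = []
    ev_adm: List[np.ndarray] = []
    pid_list: List[str] = []
    n_adms: List[int] = []
    for p in range(config.n_patients):
        pid = f"p{p:05d}"
        pid_list.append(pid)
        n_cond = int(rng.integers(c_lo, c_hi + 1))
        conds = np.sort(rng.choice(K, size=n_cond, replace=False))
        patient_conditions[pid] = tuple(int(c) for c in conds)
        n_adm = int(rng.integers(a_lo, a_hi + 1))
        n_adms.append(n_adm)
        n_ev = rng.integers(e_lo, e_hi + 1, size=n_adm)
        total = int(n_ev.sum())
        ev_cond.append(conds[rng.integers(0, n_cond, size=total)])
        ev_type.append(rng.choice(len(_TYPE_ORDER), size=total, p=_TYPE_PROBS))
        ev_adm.append(np.repeat(np.arange(n_adm), n_ev))

    cond_arr = np.concatenate(ev_cond)
    type_arr = np.concatenate(ev_type)
    adm_arr = np.concatenate(ev_adm)
    pat_arr = np.repeat(np.arange(config.n_patients), [len(a) for a in ev_adm])

    # --- code sampling, bucketed by (condition, type) ---------------------
    code_idx = np.empty(cond_arr.shape[0], dtype=int)
    for k in range(K):
        for ti, t in enumerate(_TYPE_ORDER):
            mask = (cond_arr == k) & (type_arr == ti)
            m = int(mask.sum())
            if m:
                cum = np.cumsum(emissions[k][t.value])
                code_idx[mask] = np.searchsorted(cum, rng.random(m), side="right")

    # synonym substitution for lab events
    lab_mask = type_arr == _TYPE_ORDER.index(EventType.LAB)
    grouped = lab_mask & (group_of_lab[np.where(lab_mask, code_idx, 0)] >= 0)
    if grouped.any():
        gids = group_of_lab[code_idx[grouped]]
        pick = rng.integers(0, config.synonym_group_size, size=int(grouped.sum()))
        code_idx[grouped] = np.array(
            [group_members[g][i] for g, i in zip(gids, pick)]
        )

    diag_ti = _TYPE_ORDER.index(EventType.DIAGNOSIS)
    sub_digit = rng.integers(0, 10, size=cond_arr.shape[0])

    # --- assemble events in patient order ---------------------------------
    events: List[MedicalEvent] = []
    offset = 0
    n_diag_codes = vocab_n[EventType.DIAGNOSIS]
    for p, pid in enumerate(pid_list):
        total = len(ev_adm[p])
        ts = 0
        for i in range(offset, offset + total):
            t = _TYPE_ORDER[type_arr[i]]
            if type_arr[i] == diag_ti:
                raw = f"{_diag_stem(int(code_idx[i]), n_targets)}.{sub_digit[i]}"
            else:
                raw = _TYPE_CODE_FMT[t].format(int(code_idx[i]))
            events.append(
                MedicalEvent(pid, f"{pid}-a{adm_arr[i]}", ts, t, raw)
            )
            ts += 1
        # final-admission label events: the conditions' target diagnoses,
        # each flipped to a random background code with prob label_noise
        last_adm = n_adms[p] - 1
        for k in patient_conditions[pid]:
            for j in range(dpc):
                if rng.random() < config.label_noise:
                    bg = int(rng.integers(n_targets, n_diag_codes))
                    stem = _diag_stem(bg, n_targets)
                else:
                    stem = _diag_stem(k * dpc + j, n_targets)
                events.append(
                    MedicalEvent(
                        pid,
                        f"{pid}-a{last_adm}",
                        ts,
                        EventType.DIAGNOSIS,
                        f"{stem}.{rng.integers(0, 10)}",
                    )
                )
                ts += 1
        offset += total

    gt = GroundTruth(
        patient_conditions=patient_conditions,
        condition_diagnoses=condition_diagnoses,
        emissions=emissions,
        synonym_groups=synonym_groups,
    )
    return events, gt


def generate_cohort(config: SyntheticConfig) -> Tuple[Cohort, GroundTruth]:
    """Generate a cohort (pathways + final-admission labels) and its
    ground truth; fully reproducible from ``config.seed``."""
    events, gt = generate_events(config)
    cohort = cohort_from_events(events, icd9_truncate=True)
    return cohort, gt


def split_sites(
    cohort: Cohort, fractions: Sequence[float], seed: int = 0
) -> List[Cohort]:
    """Random disjoint patient-level partition with sizes floor(f * N)
    (remainder to the first site)."""
    fr = np.asarray(list(fractions), dtype=float)
    if fr.size < 1 or np.any(fr <= 0):
        raise ConfigError("fractions must be positive")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fr.sum()}")
    ids = cohort.patient_ids
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    sizes = [int(np.floor(f * len(ids))) for f in fr]
    sizes[0] += len(ids) - sum(sizes)
    out, start = [], 0
    for s in sizes:
        out.append(cohort.subset(perm[start : start + s]))
        start += s
    return out


def relabel_site_codes(cohort: Cohort, suffix: str, keep: Set[str]) -> Cohort:
    """Append ``suffix`` to every code not in ``keep`` (the simulated
    shared terminology), in pathways and labels alike."""

    def rl(code: str) -> str:
        return code if code in keep else code + suffix

    pathways = {
        pid: ClinicalPathway(pid, [rl(c) for c in pw.events], list(pw.admission_index))
        for pid, pw in cohort.pathways.items()
    }
    label_map = {
        pid: {rl(c) for c in labels} for pid, labels in cohort.label_map.items()
    }
    return Cohort(pathways=pathways, label_map=label_map)


def delete_diagnoses(cohort: Cohort, codes: Set[str]) -> Cohort:
    """Remove every event whose (prefixed) code is in ``codes`` and the
    corresponding label entries; pathways emptied by the deletion are
    dropped."""
    pathways: Dict[str, ClinicalPathway] = {}
    n_dropped = 0
    for pid, pw in cohort.pathways.items():
        ev, ai = [], []
        for c, a in zip(pw.events, pw.admission_index):
            if c not in codes:
                ev.append(c)
                ai.append(a)
        if ev:
            pathways[pid] = ClinicalPathway(pid, ev, ai)
        else:
            n_dropped += 1
    if n_dropped:
        logger.debug("delete_diagnoses dropped %d emptied pathways", n_dropped)
    label_map = {}
    for pid, labels in cohort.label_map.items():
        if pid not in pathways:
            continue
        remaining = labels - codes
        if remaining:
            label_map[pid] = remaining
    return Cohort(pathways=pathways, label_map=label_map)


def simulate_transformed_embedding(
    model: EmbeddingModel,
    k0: float,
    rotation_seed: int = 0,
    noise_sd: float = 0.0,
    translation: Optional[np.ndarray] = None,
    rotation: Optional[np.ndarray] = None,
) -> Tuple[EmbeddingModel, HarmonizationTransform]:
    """A ground-truth-transformed copy of ``model`` for recovery tests.

    The copy's rows are the *inverse* image of the reference under a known
    map (rotation R from the QR factorization of a seeded Gaussian matrix,
    uniform scale ``k0``, translation), plus optional iid Gaussian noise.
    The returned forward transform (Q=R, k=k0, the construction's means)
    is what a Procrustes fit on corresponding rows should recover.
    """
    if k0 <= 0:
        raise ConfigError(f"k0 must be positive, got {k0}")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    m = model.dim
    rng = np.random.default_rng(rotation_seed)
    if rotation is not None:
        R = np.asarray(rotation, dtype=np.float64)
        if R.shape != (m, m):
            raise ConfigError("rotation must be m x m")
    else:
        q, r = np.linalg.qr(rng.standard_normal((m, m)))
        R = q * np.sign(np.diag(r))  # canonical deterministic rotation
    if translation is None:
        translation = np.zeros(m)
    translation = np.asarray(translation, dtype=np.float64)
    if translation.shape != (m,):
        raise ConfigError("translation must be an m-vector")

    A = model.matrix.astype(np.float64)
    mu_A = A.mean(axis=0)
    B = (A - mu_A) @ R / k0 + translation
    if noise_sd > 0:
        B = B + rng.normal(0.0, noise_sd, size=B.shape)
    true_t = HarmonizationTransform(
        Q=R, k=k0, mu_X=mu_A, mu_Y=translation, n_anchors=len(model)
    )
    out = EmbeddingModel(
        vocabulary=list(model.vocabulary),
        matrix=B,
        metadata={**model.metadata, "simulated_transform": True},
    )
    return out, true_t
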