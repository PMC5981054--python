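"""Anchored orthogonal Procrustes harmonization of embedding spaces.

Two skip-gram models trained at different sites live in unrelated
coordinate systems even when they encode the same clinical structure.
Given *anchor pairs* — codes known to denote the same event at both sites
(in practice, shared standardized terminology such as ICD-9) — the spaces
can be aligned by scaled orthogonal Procrustes analysis:

    min_{Q orthogonal, k > 0}  || (X - 1 mu_X^T) - k Q (Y - 1 mu_Y^T) ||_F

where X and Y are the anchor rows of the reference model A and the moving
model B, and mu_X, mu_Y their column means. The closed-form solution comes
from one SVD: with X_c^T Y_c = U S V^T,

    Q = U V^T,   k = trace(S) / trace(Y_c^T Y_c)

(the denominator uses the *centered* Y Gram trace — the only choice under
which a pure translation of the same configuration recovers k = 1). The
whole reference model is then translated by -mu_X and every moving row v
is mapped to k Q (v - mu_Y), putting both sites in one comparable space.

The module also extends the pairwise fit to three or more sites (hub
strategy: each non-reference model is aligned to the reference) and fuses
two harmonized models of unequal size into a single vocabulary-union model
(size-weighted averaging on anchors, nearest-neighbor completion
elsewhere).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from .embeddings import EmbeddingModel, cosine, nearest_neighbors
from .errors import AlignmentError, ConfigError

__all__ = [
    "AnchorSet",
    "HarmonizationTransform",
    "select_anchors",
    "fit_procrustes",
    "apply_transform",
    "harmonize_pair",
    "HarmonizedPair",
    "harmonize_multi",
    "fuse_models",
]

_ORTHO_TOL = 1e-8


@dataclass
class AnchorSet:
    """Ordered corresponding-code pairs (code in A, code in B)."""

    pairs: List[Tuple[str, str]]
    selection: str = "given"  # given | random_fraction | top_frequency_fraction
    fraction: Optional[float] = None

    def __post_init__(self):
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left):
            raise ConfigError("duplicate left codes in anchor set")
        if len(set(right)) != len(right):
            raise ConfigError("duplicate right codes in anchor set")

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_against(self, model_a: EmbeddingModel, model_b: EmbeddingModel) -> None:
        for a, b in self.pairs:
            if a not in model_a:
                raise ConfigError(f"anchor code {a!r} missing from reference model")
            if b not in model_b:
                raise ConfigError(f"anchor code {b!r} missing from moving model")


@dataclass
class HarmonizationTransform:
    """The fitted map: orthogonal Q, scale k, anchor means mu_X / mu_Y.

    A moving-side row v maps to ``k Q (v - mu_Y)`` (+ an optional hub
    ``offset`` used by multi-site alignment); a reference-side row maps to
    ``v - mu_X``.
    """

    Q: np.ndarray
    k: float
    mu_X: np.ndarray
    mu_Y: np.ndarray
    residual: float = float("nan")
    n_anchors: int = 0
    offset: np.ndarray | None = None

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=np.float64)
        self.mu_X = np.asarray(self.mu_X, dtype=np.float64)
        self.mu_Y = np.asarray(self.mu_Y, dtype=np.float64)
        m = self.Q.shape[0]
        if self.Q.shape != (m, m):
            raise ConfigError("Q must be square")
        if self.mu_X.shape != (m,) or self.mu_Y.shape != (m,):
            raise ConfigError("mean vectors must match Q's dimension")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ConfigError(f"scale k must be positive and finite, got {self.k}")
        err = np.max(np.abs(self.Q.T @ self.Q - np.eye(m)))
        if err > 1e-6:  # construction guard; fits are tested to 1e-8
            raise ConfigError(f"Q not orthogonal (max |Q^T Q - I| = {err:.2e})")

    @property
    def dim(self) -> int:
        return int(self.Q.shape[0])

    def orthogonality_error(self) -> float:
        return float(np.max(np.abs(self.Q.T @ self.Q - np.eye(self.dim))))

    def map_moving(self, rows: np.ndarray) -> np.ndarray:
        out = self.k * (np.asarray(rows, dtype=np.float64) - self.mu_Y) @ self.Q.T
        if self.offset is not None:
            out = out + self.offset
        return out

    def map_reference(self, rows: np.ndarray) -> np.ndarray:
        return np.asarray(rows, dtype=np.float64) - self.mu_X


def select_anchors(
    model_a: EmbeddingModel,
    model_b: EmbeddingModel,
    strategy: str = "random_fraction",
    fraction: float = 1.0,
    corpus_frequencies: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    pool: Optional[Sequence[str]] = None,
) -> AnchorSet:
    """Pick identity anchor pairs from the shared vocabulary.

    The candidate pool is the set of codes present in both vocabularies
    (optionally restricted to ``pool``). ``random_fraction`` samples
    ceil(fraction * pool) codes with the given seed;
    ``top_frequency_fraction`` takes the most frequent ones by
    ``corpus_frequencies`` (ties lexicographic).
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    common = sorted(set(model_a.vocabulary) & set(model_b.vocabulary))
    if pool is not None:
        restrict = set(pool)
        common = [c for c in common if c in restrict]
    if not common:
        raise AlignmentError("no common codes between the two vocabularies")
    n_take = math.ceil(fraction * len(common))
    if strategy == "random_fraction":
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(len(common), size=n_take, replace=False))
        codes = [common[i] for i in chosen]
    elif strategy == "top_frequency_fraction":
        if corpus_frequencies is None:
            raise ConfigError("top_frequency_fraction requires corpus_frequencies")
        codes = sorted(
            sorted(common, key=lambda c: (-corpus_frequencies.get(c, 0), c))[:n_take]
        )
    else:
        raise ConfigError(f"unknown anchor strategy {strategy!r}")
    return AnchorSet(
        pairs=[(c, c) for c in codes], selection=strategy, fraction=fraction
    )


def fit_procrustes(X: np.ndarray, Y: np.ndarray) -> HarmonizationTransform:
    """Fit the scaled orthogonal Procrustes map from anchor matrices.

    ``X`` holds the reference model's anchor rows, ``Y`` the moving
    model's, row i of each being the same underlying event. Returns the
    transform minimizing ``||X_c - k Y_c Q^T||_F`` with Q orthogonal,
    together with the achieved Frobenius residual. Warns when n < m + 1
    (rotation under-determined: the fit is exact on anchors but not unique).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape != Y.shape:
        raise AlignmentError(f"anchor matrices must share shape, got {X.shape} vs {Y.shape}")
    n, m = X.shape
    if n < 2:
        raise AlignmentError("need at least 2 anchor pairs")
    mu_X = X.mean(axis=0)
    mu_Y = Y.mean(axis=0)
    Xc = X - mu_X
    Yc = Y - mu_Y
    y_gram = float(np.sum(Yc * Yc))
    if y_gram <= 0.0 or not np.isfinite(y_gram):
        raise AlignmentError("centered moving anchors have zero variance")
    if n < m + 1:
        warnings.warn(
            f"only {n} anchors for dimension {m}: rotation under-determined",
            stacklevel=2,
        )
    U, S, Vt = scipy.linalg.svd(Xc.T @ Yc)
    Q = U @ Vt
    k = float(np.sum(S)) / y_gram
    residual = float(np.linalg.norm(Xc - k * (Yc @ Q.T)))
    return HarmonizationTransform(
        Q=Q, k=k, mu_X=mu_X, mu_Y=mu_Y, residual=residual, n_anchors=n
    )


def apply_transform(
    model: EmbeddingModel, t: HarmonizationTransform, side: str
) -> EmbeddingModel:
    """Map a whole model into the common space.

    ``side="reference"`` translates every row by -mu_X; ``side="moving"``
    centers by mu_Y, rotates by Q and scales by k. The vocabulary is
    unchanged.
    """
    if model.dim != t.dim:
        raise AlignmentError(f"model dim {model.dim} != transform dim {t.dim}")
    if side == "reference":
        mat = t.map_reference(model.matrix)
    elif side == "moving":
        mat = t.map_moving(model.matrix)
    else:
        raise ConfigError(f"side must be 'reference' or 'moving', got {side!r}")
    meta = dict(model.metadata)
    meta["harmonized_side"] = side
    return EmbeddingModel(
        vocabulary=list(model.vocabulary), matrix=mat, metadata=meta
    )


class HarmonizedPair(NamedTuple):
    reference: EmbeddingModel
    moving: EmbeddingModel
    transform: HarmonizationTransform
    residual: float


def harmonize_pair(
    model_a: EmbeddingModel, model_b: EmbeddingModel, anchors: AnchorSet
) -> HarmonizedPair:
    """Fit on the anchor rows and map both models into one space."""
    anchors.validate_against(model_a, model_b)
    X = model_a.rows([a for a, _ in anchors.pairs])
    Y = model_b.rows([b for _, b in anchors.pairs])
    t = fit_procrustes(X, Y)
    return HarmonizedPair(
        reference=apply_transform(model_a, t, "reference"),
        moving=apply_transform(model_b, t, "moving"),
        transform=t,
        residual=t.residual,
    )


def harmonize_multi(
    models: Sequence[EmbeddingModel],
    anchor_sets: Mapping[int, AnchorSet],
    reference_index: int = 0,
) -> List[EmbeddingModel]:
    """Hub alignment of >= 2 sites into the reference model's space.

    ``anchor_sets[i]`` gives, for each non-reference model i, pairs of
    (code in reference, code in model i). The reference is centered once,
    at the mean of the union of its anchor rows; each moving model is
    fitted pairwise against the reference and then shifted into the same
    union-centered frame, so anchor images coincide across all sites.
    """
    if len(models) < 2:
        raise ConfigError("need at least 2 models")
    if not (0 <= reference_index < len(models)):
        raise ConfigError(f"reference_index {reference_index} out of range")
    ref = models[reference_index]
    dims = {m.dim for m in models}
    if len(dims) != 1:
        raise AlignmentError(f"models disagree on dimension: {sorted(dims)}")
    for i in range(len(models)):
        if i != reference_index and i not in anchor_sets:
            raise ConfigError(f"missing anchor set for model {i}")

    union_codes = sorted(
        {a for i, aset in anchor_sets.items() if i != reference_index for a, _ in aset.pairs}
    )
    if not union_codes:
        raise ConfigError("anchor sets are empty")
    mu_union = ref.rows(union_codes).mean(axis=0)

    out: List[EmbeddingModel] = [None] * len(models)  # type: ignore[list-item]
    ref_meta = dict(ref.metadata)
    ref_meta["harmonized_side"] = "reference"
    out[reference_index] = EmbeddingModel(
        vocabulary=list(ref.vocabulary),
        matrix=ref.matrix.astype(np.float64) - mu_union,
        metadata=ref_meta,
    )
    for i, model in enumerate(models):
        if i == reference_index:
            continue
        aset = anchor_sets[i]
        aset.validate_against(ref, model)
        t = fit_procrustes(
            ref.rows([a for a, _ in aset.pairs]),
            model.rows([b for _, b in aset.pairs]),
        )
        # shift from this pair's mu_X frame into the union-centered frame
        t.offset = t.mu_X - mu_union
        out[i] = apply_transform(model, t, "moving")
    return out


def fuse_models(
    a_f: EmbeddingModel,
    b_f: EmbeddingModel,
    anchors: AnchorSet,
    weight_a: float,
) -> EmbeddingModel:
    """Fuse two harmonized site models into one vocabulary-union model.

    Anchor-pair codes get the size-weighted average
    ``weight_a * v_A + (1 - weight_a) * v_B``. A non-anchor code present
    in only one site is averaged with its single nearest neighbor (cosine,
    ties lexicographic) from the other site. A non-anchor code whose label
    appears in both vocabularies is treated as a de facto correspondence
    and averaged with the same weights; genuinely conflicting embeddings
    under different labels are simply both kept.
    """
    if not (0.0 < weight_a < 1.0):
        raise ConfigError(f"weight_a must be in (0, 1), got {weight_a}")
    if len(anchors) == 0:
        raise ConfigError("anchor set is empty")
    anchors.validate_against(a_f, b_f)
    if a_f.dim != b_f.dim:
        raise AlignmentError("models disagree on dimension")
    w_b = 1.0 - weight_a

    anchor_a = {a for a, _ in anchors.pairs}
    anchor_b = {b for _, b in anchors.pairs}
    fused: Dict[str, np.ndarray] = {}

    for a, b in anchors.pairs:
        v = weight_a * a_f.vector(a) + w_b * b_f.vector(b)
        fused[a] = v
        fused.setdefault(b, v)

    vocab_a, vocab_b = set(a_f.vocabulary), set(b_f.vocabulary)
    for code in sorted(vocab_a - anchor_a):
        if code in fused:
            continue
        if code in vocab_b and code not in anchor_b:
            fused[code] = weight_a * a_f.vector(code) + w_b * b_f.vector(code)
        else:
            v = a_f.vector(code)
            nn = nearest_neighbors(b_f, v, k=1)
            fused[code] = (v + b_f.vector(nn[0])) / 2.0
    for code in sorted(vocab_b - anchor_b):
        if code in fused:
            continue
        v = b_f.vector(code)
        nn = nearest_neighbors(a_f, v, k=1)
        fused[code] = (v + a_f.vector(nn[0])) / 2.0

    vocab = sorted(fused)
    matrix = np.vstack([fused[c] for c in vocab])
    return EmbeddingModel(
        vocabulary=vocab,
        matrix=matrix,
        metadata={"fused": True, "weight_a": weight_a, "n_anchors": len(anchors)},
    )
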