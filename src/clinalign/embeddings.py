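"""Contextual embeddings of medical event codes.

Each site trains a skip-gram (word2vec) model over its pathway "sentences",
mapping every sufficiently frequent event code to a dense vector; codes that
occur in similar clinical contexts end up close in cosine distance. Models
are exchanged in the word2vec *text* format (header line ``<n> <m>``, then
one token + vector per line), which is the interchange format for
harmonization and prediction.

The trainer is an in-package implementation of skip-gram with negative
sampling (see :mod:`clinalign._sgns`): serial, seeded, and therefore
bit-reproducible run-to-run. Initial vectors are derived from a per-token
hash mixed with the seed — the word2vec convention — so the same token
starts at the same point in any corpus trained with the same seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import numpy as np

from ._sgns import train_sgns
from .errors import ConfigError, EvaluationError, FormatError, UnknownCodeError

__all__ = [
    "EmbeddingModel",
    "TrainingConfig",
    "train_embeddings",
    "write_word2vec_text",
    "read_word2vec_text",
    "get_vector",
    "cosine",
    "nearest_neighbors",
]


@dataclass
class EmbeddingModel:
    """A vocabulary of codes mapped to rows of an ``n x m`` real matrix."""

    vocabulary: List[str]
    matrix: np.ndarray
    metadata: dict = field(default_factory=dict)
    _index: Dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ConfigError("embedding matrix must be 2-D")
        n, m = self.matrix.shape
        if n != len(self.vocabulary):
            raise ConfigError(
                f"vocabulary size {len(self.vocabulary)} != matrix rows {n}"
            )
        if m < 2:
            raise ConfigError("embedding dimension must be >= 2")
        if len(set(self.vocabulary)) != n:
            raise ConfigError("duplicate codes in vocabulary")
        if not np.all(np.isfinite(self.matrix)):
            raise ConfigError("embedding matrix contains non-finite values")
        self._index = {c: i for i, c in enumerate(self.vocabulary)}

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, code: str) -> np.ndarray:
        try:
            return self.matrix[self._index[code]]
        except KeyError:
            raise UnknownCodeError(f"code {code!r} not in vocabulary") from None

    def rows(self, codes: Sequence[str]) -> np.ndarray:
        """Matrix rows for ``codes`` (in order), erroring on unknowns."""
        try:
            idx = [self._index[c] for c in codes]
        except KeyError as exc:
            raise UnknownCodeError(f"code {exc.args[0]!r} not in vocabulary") from None
        return self.matrix[idx]


@dataclass(frozen=True)
class TrainingConfig:
    """Skip-gram hyperparameters.

    ``dim=350`` and ``window=30`` are the reference settings for structured
    EHR pathways (window 100 for concept streams from clinical notes);
    experiments at synthetic desk scale use smaller values. The
    architecture is fixed to skip-gram with negative sampling. ``workers``
    exists as a knob, but only single-threaded training is implemented —
    that is what makes runs bit-reproducible — so values other than 1 are
    rejected rather than silently serialized.
    """

    dim: int = 350
    window: int = 30
    min_count: int = 1
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 1
    workers: int = 1

    def __post_init__(self):
        if self.dim < 2:
            raise ConfigError("dim must be >= 2")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if self.min_count < 0:
            raise ConfigError("min_count must be >= 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.negative < 1:
            raise ConfigError("negative must be >= 1")
        if self.workers != 1:
            raise ConfigError(
                "only single-threaded (workers=1) training is implemented; "
                "determinism requires a serial update order"
            )


def _fnv1a64(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for b in data:
        h ^= b
        h = (h * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def _init_vectors(vocabulary: Sequence[str], dim: int, seed: int) -> np.ndarray:
    """Per-token hash-seeded uniform init in (-0.5/dim, 0.5/dim)."""
    syn0 = np.empty((len(vocabulary), dim), dtype=np.float32)
    for i, tok in enumerate(vocabulary):
        h = _fnv1a64(tok.encode("utf-8")) ^ (seed & 0xFFFFFFFFFFFFFFFF)
        rng = np.random.default_rng(h)
        syn0[i] = (rng.random(dim, dtype=np.float64) - 0.5) / dim
    return syn0


def _negative_table(counts: np.ndarray, size: int = 1 << 17) -> np.ndarray:
    weights = counts.astype(np.float64) ** 0.75
    cum = np.cumsum(weights / weights.sum())
    grid = (np.arange(size) + 0.5) / size
    return np.searchsorted(cum, grid).astype(np.int32)


def train_embeddings(
    sentences: Iterable[Sequence[str]], config: TrainingConfig = TrainingConfig()
) -> EmbeddingModel:
    """Train a skip-gram model over token sequences.

    The vocabulary is exactly the set of tokens occurring at least
    ``config.min_count`` times, ordered by descending corpus frequency
    (ties lexicographic). Out-of-vocabulary tokens are dropped from the
    training stream. Raises :class:`ConfigError` on an empty corpus or an
    empty post-filter vocabulary.
    """
    sentences = [list(s) for s in sentences if s]
    if not sentences:
        raise ConfigError("empty corpus: no non-empty sentences")

    counts = Counter(tok for s in sentences for tok in s)
    vocab = sorted(
        (t for t, c in counts.items() if c >= max(config.min_count, 1)),
        key=lambda t: (-counts[t], t),
    )
    if not vocab:
        raise ConfigError(
            f"no token reaches min_count={config.min_count}; corpus has "
            f"{len(counts)} distinct tokens"
        )
    index = {t: i for i, t in enumerate(vocab)}

    encoded: List[np.ndarray] = []
    for s in sentences:
        ids = [index[t] for t in s if t in index]
        if ids:
            encoded.append(np.asarray(ids, dtype=np.int32))
    corpus = (
        np.concatenate(encoded) if encoded else np.empty(0, dtype=np.int32)
    )
    if corpus.size == 0:
        raise ConfigError("corpus empty after vocabulary filtering")
    offsets = np.zeros(len(encoded) + 1, dtype=np.int64)
    np.cumsum([len(e) for e in encoded], out=offsets[1:])

    syn0 = _init_vectors(vocab, config.dim, config.seed)
    syn1 = np.zeros_like(syn0)
    table = _negative_table(np.asarray([counts[t] for t in vocab]))

    train_sgns(
        corpus,
        offsets,
        syn0,
        syn1,
        table,
        config.window,
        config.epochs,
        config.negative,
        config.alpha,
        config.min_alpha,
        config.seed & 0x7FFFFFFFFFFFFFFF,
    )

    metadata = {
        "backend": "clinalign-sgns",
        "architecture": "skip-gram",
        "dim": config.dim,
        "window": config.window,
        "min_count": config.min_count,
        "epochs": config.epochs,
        "negative": config.negative,
        "alpha": config.alpha,
        "min_alpha": config.min_alpha,
        "seed": config.seed,
        "workers": config.workers,
        "n_sentences": len(sentences),
        "n_tokens": int(corpus.size),
    }
    return EmbeddingModel(vocabulary=vocab, matrix=syn0, metadata=metadata)


# ---------------------------------------------------------------------------
# word2vec text interchange format

def write_word2vec_text(model: EmbeddingModel, destination) -> None:
    """Write ``<n> <m>`` header then one ``token v1 ... vm`` line per code.

    Components are printed with 9 significant digits, keeping round-trip
    error per component below 1e-6.
    """
    n, m = model.matrix.shape
    with Path(destination).open("w", encoding="utf-8") as fh:
        fh.write(f"{n} {m}\n")
        for i, tok in enumerate(model.vocabulary):
            comps = " ".join(f"{x:.9g}" for x in model.matrix[i])
            fh.write(f"{tok} {comps}\n")


def read_word2vec_text(source) -> EmbeddingModel:
    """Read a word2vec text file, validating header and row arity."""
    path = Path(source)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: header must be '<n> <m>'", line=1)
        try:
            n, m = int(header[0]), int(header[1])
        except ValueError:
            raise FormatError(f"{path}: non-integer header {header}", line=1) from None
        vocab: List[str] = []
        matrix = np.empty((n, m), dtype=np.float32)
        lineno = 1
        for i in range(n):
            lineno += 1
            line = fh.readline()
            if not line:
                raise FormatError(
                    f"{path}: expected {n} rows, file ended after {i}", line=lineno
                )
            parts = line.rstrip("\n").split(" ")
            if len(parts) != m + 1:
                raise FormatError(
                    f"{path}: expected token + {m} components, got "
                    f"{len(parts) - 1} components",
                    line=lineno,
                )
            vocab.append(parts[0])
            try:
                matrix[i] = [float(x) for x in parts[1:]]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric vector component", line=lineno
                ) from None
        trailing = fh.readline()
        if trailing.strip():
            raise FormatError(
                f"{path}: more rows than the header's {n}", line=lineno + 1
            )
    return EmbeddingModel(vocabulary=vocab, matrix=matrix, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# Vector utilities

def get_vector(model: EmbeddingModel, code: str) -> np.ndarray:
    """The embedding row for ``code`` (typed error when unknown)."""
    return model.vector(code)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), in [-1, 1]; typed error on a zero-norm argument."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ConfigError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise EvaluationError("cosine undefined for a zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def nearest_neighbors(
    model: EmbeddingModel,
    query_vector: np.ndarray,
    k: int,
    exclude: Optional[Set[str]] = None,
) -> List[str]:
    """The ``k`` codes with highest cosine to the query.

    Ties break lexicographically; codes in ``exclude`` (and zero-norm rows)
    are skipped. With ``k >= len(model)`` the full (non-excluded)
    vocabulary comes back totally ordered.
    """
    q = np.asarray(query_vector, dtype=np.float64)
    nq = np.linalg.norm(q)
    if nq == 0.0:
        raise EvaluationError("cosine undefined for a zero-norm query")
    exclude = exclude or set()
    norms = np.linalg.norm(model.matrix.astype(np.float64), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (model.matrix.astype(np.float64) @ q) / (norms * nq)
    ranked = sorted(
        (
            (-sims[i], code)
            for i, code in enumerate(model.vocabulary)
            if code not in exclude and norms[i] > 0.0
        ),
    )
    return [code for _, code in ranked[:k]]
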