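"""Model contract and tokenization adapters.

A nucleotide probability model is anything that, given a DNA/RNA sequence,
returns a per-position probability distribution over the four bases
(A, C, G, T in that fixed order), computed with the *full, unmasked*
sequence as context.  Genomic language models that emit k-mer-level
distributions (overlapping or nonoverlapping tokenization) are adapted to
this per-nucleotide contract by the functions in this module.

Sequences are plain Python strings over {A, C, G, T}; U is mapped to T at
ingest and ambiguity codes are rejected, because the dependency equations
have no principled substitution set for them.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default probability clip applied before any odds computation
DEFAULT_EPS = 1e-9


class NucdepError(Exception):
    """Base class for package errors."""


class SequenceError(NucdepError):
    """Sequence fails the {A,C,G,T} alphabet contract."""


class CapabilityError(NucdepError):
    """Operation requires a model capability (masking, autoregression) it lacks."""


class DegenerateInputError(NucdepError):
    """Numerically degenerate input (e.g. renormalization over ~zero mass)."""


def clean_sequence(raw: str, *, allow_n: bool = False) -> str:
    """Uppercase, map U->T, and validate a nucleotide string.

    Raises :class:`SequenceError` naming the first offending position.
    """
    seq = raw.upper().replace("U", "T")
    allowed = set("ACGTN") if allow_n else set("ACGT")
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise SequenceError(f"invalid residue {ch!r} at position {pos}")
    return seq


def encode(seq: str) -> np.ndarray:
    """Sequence string -> int array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded by clean_sequence
        raise SequenceError(f"invalid residue {exc.args[0]!r}") from exc


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def clip_profile(probs: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Clip probabilities into [eps, 1-eps] and renormalize rows.

    Guarantees finite odds downstream; the clip count is negligible for
    well-behaved models but protects against p of exactly 0 or 1.
    """
    clipped = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    return clipped / clipped.sum(axis=-1, keepdims=True)


def validate_profile(probs: np.ndarray, n: int, tol: float = 1e-6) -> None:
    probs = np.asarray(probs)
    if probs.shape != (n, 4):
        raise ValueError(f"profile shape {probs.shape} != ({n}, 4)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=tol):
        raise ValueError("profile rows must sum to 1")


class NucleotideModel(abc.ABC):
    """Contract every dependency computation consumes.

    Attributes
    ----------
    style
        One of ``bidirectional``, ``overlapping_kmer``, ``nonoverlapping_kmer``,
        ``autoregressive``.  For ``autoregressive``, the distribution at
        position i may depend only on residues 0..i-1.
    max_context
        Longest sequence the model accepts.
    supports_mask
        Whether :meth:`predict_masked` is implemented.
    """

    style: str = "bidirectional"
    max_context: int = 1_000_000
    supports_mask: bool = False
    model_id: str = "model"

    @abc.abstractmethod
    def predict(self, seq: str) -> np.ndarray:
        """Return the N x 4 per-position base probabilities (unmasked context)."""

    def predict_masked(self, seq: str, i: int) -> np.ndarray:
        """Profile with position ``i`` replaced by the mask token."""
        raise CapabilityError(f"{type(self).__name__} does not support masking")


class CallCountingModel(NucleotideModel):
    """Wrapper counting model evaluations; used to verify call-count contracts."""

    def __init__(self, inner: NucleotideModel):
        self.inner = inner
        self.style = inner.style
        self.max_context = inner.max_context
        self.supports_mask = inner.supports_mask
        self.model_id = inner.model_id
        self.n_calls = 0

    def predict(self, seq: str) -> np.ndarray:
        self.n_calls += 1
        return self.inner.predict(seq)

    def predict_masked(self, seq: str, i: int) -> np.ndarray:
        self.n_calls += 1
        return self.inner.predict_masked(seq, i)


class UniformModel(NucleotideModel):
    """Context-free model assigning fixed base probabilities at every position.

    The null model: its dependency map is identically zero.
    """

    style = "bidirectional"
    supports_mask = True
    model_id = "product"

    def __init__(self, base_probs=(0.25, 0.25, 0.25, 0.25)):
        p = np.asarray(base_probs, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("base_probs must be a 4-vector summing to 1")
        self.base_probs = p

    def predict(self, seq: str) -> np.ndarray:
        return np.tile(self.base_probs, (len(seq), 1))

    def predict_masked(self, seq: str, i: int) -> np.ndarray:
        return self.predict(seq)


# ---------------------------------------------------------------------------
# k-mer adapters
# ---------------------------------------------------------------------------


@dataclass
class KmerPrediction:
    """Token-level k-mer distributions from a k-mer-tokenized model.

    ``token_probs`` has one row per token position and ``4**k`` columns; the
    k-mer with bases ``(b_0 .. b_{k-1})`` maps to column
    ``sum(b_t * 4**(k-1-t))`` (first base most significant).  For
    ``overlap=True`` there is one token per sequence window
    (``T = N - k + 1``); for ``overlap=False`` the grid is anchored at
    position 0 with ``T = N // k``.
    """

    token_probs: np.ndarray
    k: int
    overlap: bool

    def __post_init__(self):
        self.token_probs = np.asarray(self.token_probs, dtype=float)
        if self.token_probs.ndim != 2 or self.token_probs.shape[1] != 4**self.k:
            raise ValueError(
                f"token_probs must be T x 4^{self.k}, got {self.token_probs.shape}"
            )
        if not np.allclose(self.token_probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("token rows must sum to 1")


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = idx * 4 + BASE_INDEX[b]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(ALPHABET[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def token_index(i: int, k: int) -> tuple[int, int]:
    """Nucleotide position -> (token, within-token offset) on a nonoverlapping grid.

    ``token = i // k`` and ``offset = i % k``, the standard mapping for
    nonoverlapping k-mer tokenization anchored at position 0.
    """
    if i < 0 or k < 1:
        raise ValueError(f"require i >= 0 and k >= 1, got i={i}, k={k}")
    return i // k, i % k


def _marginal_onto_offset(token_row: np.ndarray, k: int, offset: int) -> np.ndarray:
    """Marginalize a 4^k k-mer distribution onto the base at one offset."""
    cube = token_row.reshape((4,) * k)
    axes = tuple(a for a in range(k) if a != offset)
    return cube.sum(axis=axes)


def profile_from_overlapping_kmers(
    kmers: KmerPrediction, seq: str
) -> np.ndarray:
    """Per-nucleotide profile from overlapping k-mer token distributions.

    Each nucleotide is covered by up to ``k`` tokens; each covering token
    implies a 4-vector for it (marginalizing the k-mer distribution onto the
    nucleotide's slot).  The per-base probability is the arithmetic mean of
    the implied vectors, renormalized.  Nucleotides near the sequence edges
    are covered by fewer than ``k`` tokens and are averaged over those
    available.
    """
    if not kmers.overlap:
        raise ValueError("expected overlap=True k-mer predictions")
    n, k = len(seq), kmers.k
    t_expected = n - k + 1
    if kmers.token_probs.shape[0] != t_expected:
        raise ValueError(
            f"token count {kmers.token_probs.shape[0]} != N-k+1 = {t_expected}"
        )
    profile = np.zeros((n, 4))
    for i in range(n):
        lo = max(0, i - k + 1)
        hi = min(i, t_expected - 1)
        implied = [
            _marginal_onto_offset(kmers.token_probs[t], k, i - t)
            for t in range(lo, hi + 1)
        ]
        row = np.mean(implied, axis=0)
        profile[i] = row / row.sum()
    return profile


def profile_from_overlapping_kmers_sum(
    kmers: KmerPrediction, seq: str
) -> np.ndarray:
    """Alternative aggregation: sum (not average) over covering k-mers.

    Provided for comparison only; averaging is the default because summing
    performs worse at recovering base-level dependencies.
    """
    if not kmers.overlap:
        raise ValueError("expected overlap=True k-mer predictions")
    n, k = len(seq), kmers.k
    t_expected = n - k + 1
    profile = np.zeros((n, 4))
    for i in range(n):
        lo = max(0, i - k + 1)
        hi = min(i, t_expected - 1)
        row = np.sum(
            [
                _marginal_onto_offset(kmers.token_probs[t], k, i - t)
                for t in range(lo, hi + 1)
            ],
            axis=0,
        )
        profile[i] = row / row.sum()
    return profile


def profile_from_nonoverlapping_kmers(
    kmers: KmerPrediction, ref: str
) -> np.ndarray:
    """Per-nucleotide profile from nonoverlapping k-mer token distributions.

    For the nucleotide at offset ``p`` of token ``t``, only the four k-mers
    matching the reference at every offset except ``p`` are kept; their
    masses are renormalized to sum to one, and the entry for base ``b`` is
    the renormalized mass of the k-mer carrying ``b`` at offset ``p``.
    """
    if kmers.overlap:
        raise ValueError("expected overlap=False k-mer predictions")
    n, k = len(ref), kmers.k
    t_expected = n // k
    if kmers.token_probs.shape[0] != t_expected:
        raise ValueError(
            f"token count {kmers.token_probs.shape[0]} != N//k = {t_expected}"
        )
    usable = t_expected * k  # trailing partial token has no prediction
    profile = np.zeros((usable, 4))
    ref_idx = encode(ref)
    for i in range(usable):
        t, p = token_index(i, k)
        # column indices of the 4 candidate k-mers differing only at offset p
        base_col = 0
        for off in range(k):
            if off != p:
                base_col += int(ref_idx[t * k + off]) * 4 ** (k - 1 - off)
        cols = base_col + np.arange(4) * 4 ** (k - 1 - p)
        masses = kmers.token_probs[t, cols]
        total = masses.sum()
        if total <= 0 or not np.isfinite(total):
            raise DegenerateInputError(
                f"cannot renormalize ~zero candidate k-mer mass at position {i}"
            )
        profile[i] = masses / total
    return profile


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

_MODEL_REGISTRY: dict[str, object] = {}


def register_model(name: str):
    """Decorator registering a model factory under ``name``."""

    def deco(factory):
        _MODEL_REGISTRY[name] = factory
        return factory

    return deco


def get_model(name: str, **params) -> NucleotideModel:
    if name not in _MODEL_REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(_MODEL_REGISTRY)}"
        )
    return _MODEL_REGISTRY[name](**params)


def registered_models() -> list[str]:
    return sorted(_MODEL_REGISTRY)


@register_model("product")
@register_model("uniform")
def _uniform_factory(base_probs=(0.25, 0.25, 0.25, 0.25)) -> UniformModel:
    return UniformModel(base_probs)
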