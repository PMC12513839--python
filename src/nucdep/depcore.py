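"""Core dependency computations.

The dependency of a target position j on a query position i is the largest
absolute log2 odds-ratio change, across the four target bases, of the
model's predicted distribution at j when the query base is substituted:

    e_{i,j,k_alt} = max_k | log2( odds(n_j = k | ..., n_i = k_alt, ...)
                                / odds(n_j = k | ..., n_i = k_ref, ...) ) |

with odds(p) = p / (1 - p).  The per-pair dependency e_{i,j} maximizes over
the three alternative query bases; self-dependencies (i = j) are undefined
and stored as NaN.  No position is ever masked for these predictions.

A full map costs exactly 3N + 1 model evaluations: one reference profile
plus one profile per (position, alternative base).  Each evaluation yields
a whole row of targets, which is what makes the map affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    ALPHABET,
    BASE_INDEX,
    DEFAULT_EPS,
    CapabilityError,
    NucleotideModel,
    clean_sequence,
    clip_profile,
    reverse_complement,
)


@dataclass
class VariantSpec:
    """Single-nucleotide substitution: ref base at 0-based ``pos`` -> ``alt``."""

    pos: int
    ref: str
    alt: str
    name: str = ""

    def __post_init__(self):
        self.ref = self.ref.upper().replace("U", "T")
        self.alt = self.alt.upper().replace("U", "T")
        if self.ref not in ALPHABET or self.alt not in ALPHABET:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    def check_against(self, seq: str) -> None:
        if self.pos >= len(seq):
            raise ValueError(f"variant position {self.pos} outside sequence")
        if seq[self.pos] != self.ref:
            raise ValueError(
                f"reference mismatch at {self.pos}: sequence has "
                f"{seq[self.pos]}, variant says {self.ref}"
            )


@dataclass
class DependencyMap:
    """Square matrix of dependencies, query rows x target columns.

    Off-diagonal entries are nonnegative and finite; the diagonal carries
    NaN sentinels because self-dependencies are undefined.
    """

    e: np.ndarray
    metric: str = "substitution"
    model_id: str = ""
    seq_id: str = ""
    strand_source: np.ndarray | None = None

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        if self.e.ndim != 2 or self.e.shape[0] != self.e.shape[1]:
            raise ValueError("dependency matrix must be square")

    @property
    def n(self) -> int:
        return self.e.shape[0]

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.n, dtype=bool)
        return self.e[mask]


@dataclass
class LogOddsGrid:
    """Signed log2 odds ratios for one (query, target) pair.

    Rows: the three alternative query bases in A,C,G,T order minus the
    reference base; columns: the four target bases.  The maximum absolute
    entry equals the dependency-map value for the pair.
    """

    g: np.ndarray
    query: int
    target: int
    ref_base: str
    alt_bases: tuple[str, str, str]

    def max_abs(self) -> float:
        return float(np.abs(self.g).max())


@dataclass
class InfluenceScore:
    value: float
    variant: VariantSpec
    window: tuple[int, int]


def log2_odds_ratio(p_alt, p_ref):
    """log2 of the odds ratio between two probabilities (odds = p/(1-p))."""
    p_alt = np.asarray(p_alt, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    return np.log2(p_alt / (1.0 - p_alt)) - np.log2(p_ref / (1.0 - p_ref))


def _profile(model: NucleotideModel, seq: str, eps: float) -> np.ndarray:
    return clip_profile(model.predict(seq), eps)


def _substitute(seq: str, i: int, base: str) -> str:
    return seq[:i] + base + seq[i + 1:]


def variant_row_dependencies(
    model: NucleotideModel, seq: str, variant: VariantSpec,
    eps: float = DEFAULT_EPS, ref_profile: np.ndarray | None = None,
) -> np.ndarray:
    """e_{i,j,k_alt} for all targets j at once (entry at j = i is NaN)."""
    variant.check_against(seq)
    if ref_profile is None:
        ref_profile = _profile(model, seq, eps)
    alt_profile = _profile(model, _substitute(seq, variant.pos, variant.alt), eps)
    row = np.abs(log2_odds_ratio(alt_profile, ref_profile)).max(axis=1)
    row[variant.pos] = np.nan
    return row


def variant_target_dependency(
    model: NucleotideModel, seq: str, variant: VariantSpec, j: int,
    eps: float = DEFAULT_EPS,
) -> float:
    """Single-pair dependency e_{i,j,k_alt}."""
    if j == variant.pos:
        raise ValueError("self-dependencies are undefined (j == variant.pos)")
    return float(variant_row_dependencies(model, seq, variant, eps)[j])


def dependency_map(
    model: NucleotideModel, seq: str, eps: float = DEFAULT_EPS,
    seq_id: str = "",
) -> DependencyMap:
    """Full substitution-based dependency map (3N + 1 model evaluations)."""
    seq = clean_sequence(seq)
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 positions for a dependency map")
    if n > model.max_context:
        raise CapabilityError(f"sequence length {n} exceeds model context")
    ref_profile = _profile(model, seq, eps)
    ref_log_odds = np.log2(ref_profile / (1.0 - ref_profile))
    e = np.full((n, n), np.nan)
    for i in range(n):
        best = np.zeros(n)
        for alt in ALPHABET:
            if alt == seq[i]:
                continue
            alt_profile = _profile(model, _substitute(seq, i, alt), eps)
            alt_log_odds = np.log2(alt_profile / (1.0 - alt_profile))
            best = np.maximum(
                best, np.abs(alt_log_odds - ref_log_odds).max(axis=1)
            )
        best[i] = np.nan
        e[i] = best
    return DependencyMap(e, metric="substitution", model_id=model.model_id,
                         seq_id=seq_id)


def log_odds_grid(
    model: NucleotideModel, seq: str, i: int, j: int, eps: float = DEFAULT_EPS
) -> LogOddsGrid:
    """Signed 3 x 4 log2 odds-ratio grid for one (query, target) pair."""
    if i == j:
        raise ValueError("self-dependencies are undefined (i == j)")
    seq = clean_sequence(seq)
    ref_profile = _profile(model, seq, eps)
    alts = tuple(b for b in ALPHABET if b != seq[i])
    g = np.empty((3, 4))
    for r, alt in enumerate(alts):
        alt_profile = _profile(model, _substitute(seq, i, alt), eps)
        g[r] = log2_odds_ratio(alt_profile[j], ref_profile[j])
    return LogOddsGrid(g=g, query=i, target=j, ref_base=seq[i], alt_bases=alts)


def variant_influence_score(
    model: NucleotideModel, seq: str, variant: VariantSpec,
    window: tuple[int, int] | None = None, eps: float = DEFAULT_EPS,
) -> InfluenceScore:
    """Mean of e_{i,j,k_alt} over targets j in ``window`` (j != i).

    ``window`` is 0-based half-open; default is the whole sequence.  Models
    with restricted receptive fields should be scored on a central window.
    """
    seq = clean_sequence(seq)
    if window is None:
        window = (0, len(seq))
    lo, hi = window
    if not (0 <= lo < hi <= len(seq)):
        raise ValueError(f"window {window} outside sequence of length {len(seq)}")
    targets = [j for j in range(lo, hi) if j != variant.pos]
    if not targets:
        raise ValueError("window contains no valid target position")
    row = variant_row_dependencies(model, seq, variant, eps)
    return InfluenceScore(value=float(np.mean(row[targets])), variant=variant,
                          window=window)


def mask_dependency_map(
    model: NucleotideModel, seq: str, eps: float = DEFAULT_EPS,
    seq_id: str = "",
) -> DependencyMap:
    """Mask-based dependency map (N + 1 model evaluations).

    The query position is replaced by the mask token instead of being
    substituted; otherwise identical to :func:`dependency_map`.
    """
    if not model.supports_mask:
        raise CapabilityError("model does not support masking")
    seq = clean_sequence(seq)
    n = len(seq)
    ref_profile = _profile(model, seq, eps)
    ref_log_odds = np.log2(ref_profile / (1.0 - ref_profile))
    e = np.full((n, n), np.nan)
    for i in range(n):
        masked = clip_profile(model.predict_masked(seq, i), eps)
        masked_log_odds = np.log2(masked / (1.0 - masked))
        row = np.abs(masked_log_odds - ref_log_odds).max(axis=1)
        row[i] = np.nan
        e[i] = row
    return DependencyMap(e, metric="mask", model_id=model.model_id, seq_id=seq_id)


def reconstruction_llr(
    model: NucleotideModel, seq: str, variant: VariantSpec,
    eps: float = DEFAULT_EPS,
) -> float:
    """log2 P(alt) - log2 P(ref) at the variant position, unmasked context.

    The reconstruction baseline: negative values mean the model considers
    the alternative base less likely than the reference.
    """
    seq = clean_sequence(seq)
    variant.check_against(seq)
    profile = _profile(model, seq, eps)[variant.pos]
    return float(
        np.log2(profile[BASE_INDEX[variant.alt]])
        - np.log2(profile[BASE_INDEX[variant.ref]])
    )


def symmetrize_max(m: DependencyMap | np.ndarray) -> np.ndarray:
    """out[i,j] = out[j,i] = max(e[i,j], e[j,i]); diagonal stays NaN."""
    e = m.e if isinstance(m, DependencyMap) else np.asarray(m, dtype=float)
    if e.ndim != 2 or e.shape[0] != e.shape[1]:
        raise ValueError("input must be square")
    return np.fmax(e, e.T)


def autoregressive_dependency_map(
    model: NucleotideModel, seq: str, eps: float = DEFAULT_EPS,
    combine: str = "fill", strands: str = "both", seq_id: str = "",
) -> DependencyMap:
    """Dependency map for an autoregressive (5'->3') model.

    A query can only influence targets 3' of it, so the forward pass fills
    entries with j > i; a second pass on the reverse-complement strand fills
    the complementary triangle after mapping position p to N-1-p.

    combine="fill" returns the two-triangle map with per-entry strand
    provenance; combine="max" additionally takes the elementwise maximum of
    the map and its transpose, the mitigation that suppresses strand-specific
    edge artifacts.  ``strands`` restricts the computation to "+" (forward
    pass only: entries with j < i stay NaN), "-" (reverse pass only), or
    "both".
    """
    if model.style != "autoregressive":
        raise CapabilityError("model is not autoregressive")
    if combine not in ("fill", "max"):
        raise ValueError("combine must be 'fill' or 'max'")
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    seq = clean_sequence(seq)
    n = len(seq)
    e = np.full((n, n), np.nan)
    strand = np.full((n, n), " ", dtype="<U1")
    if strands in ("both", "+"):
        fwd = dependency_map(model, seq, eps).e
        upper = np.triu_indices(n, k=1)
        e[upper] = fwd[upper]
        strand[upper] = "+"
    if strands in ("both", "-"):
        rev = dependency_map(model, reverse_complement(seq), eps).e
        for i in range(n):
            for j in range(i):
                e[i, j] = rev[n - 1 - i, n - 1 - j]
                strand[i, j] = "-"
    if combine == "max":
        e = np.fmax(e, e.T)
    return DependencyMap(e, metric="substitution", model_id=model.model_id,
                         seq_id=seq_id, strand_source=strand)
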