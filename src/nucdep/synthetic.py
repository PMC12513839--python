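"""Exact synthetic probability models emulating genomic language model behavior.

The central object is a pairwise coupling (Potts-like) sequence model

    P(s) ∝ exp( Σ_i h_i(s_i) + Σ_{(i,j)} J_ij(s_i, s_j) )

whose single-position conditionals have a closed form computable in
O(degree).  Couplings planted between complementary bases produce the
antiparallel-diagonal signature of RNA stems; dense mutual couplings among
a few positions produce the on-diagonal blocks characteristic of
transcription-factor motifs; pairwise identity couplings between two copies
of a subsequence produce the (anti)parallel diagonals of duplications.
Because every conditional is exact, downstream detectors can be validated
against brute-force enumeration with no trained weights involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    ALPHABET,
    BASE_INDEX,
    COMPLEMENT,
    NucleotideModel,
    encode,
    reverse_complement,
)

# Watson-Crick and wobble reward matrices (rows = base at i, cols = base at j)
WC_MATRIX = np.zeros((4, 4))
for _a, _b in [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]:
    WC_MATRIX[BASE_INDEX[_a], BASE_INDEX[_b]] = 1.0
WOBBLE_MATRIX = np.zeros((4, 4))
for _a, _b in [("G", "T"), ("T", "G")]:
    WOBBLE_MATRIX[BASE_INDEX[_a], BASE_INDEX[_b]] = 1.0


class PairwiseCouplingModel(NucleotideModel):
    """Pairwise-coupled sequence distribution with exact conditionals.

    Parameters
    ----------
    h
        N x 4 field matrix (per-position base preferences).
    couplings
        Mapping ``(i, j) -> 4 x 4`` coupling matrix with ``i < j``;
        ``J[(i, j)][a, b]`` rewards base ``a`` at i co-occurring with base
        ``b`` at j.
    temperature
        Divides all energies; 1 by default.
    """

    style = "bidirectional"
    supports_mask = True

    def __init__(self, h, couplings=None, temperature: float = 1.0,
                 model_id: str = "coupling"):
        self.h = np.asarray(h, dtype=float)
        if self.h.ndim != 2 or self.h.shape[1] != 4:
            raise ValueError("h must be N x 4")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.temperature = float(temperature)
        self.model_id = model_id
        self.couplings: dict[tuple[int, int], np.ndarray] = {}
        for (i, j), J in (couplings or {}).items():
            if not (0 <= i < j < self.length):
                raise ValueError(f"coupling ({i},{j}) out of order or bounds")
            J = np.asarray(J, dtype=float)
            if J.shape != (4, 4):
                raise ValueError("coupling matrices must be 4 x 4")
            self.couplings[(i, j)] = J
        self.max_context = self.length

    @property
    def length(self) -> int:
        return self.h.shape[0]

    # -- closed-form conditionals ------------------------------------------

    def _logits(self, idx: np.ndarray) -> np.ndarray:
        """Per-position conditional logits given all other residues."""
        logits = self.h.copy()
        for (i, j), J in self.couplings.items():
            logits[j] += J[idx[i], :]
            logits[i] += J[:, idx[j]]
        return logits / self.temperature

    def predict(self, seq: str) -> np.ndarray:
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != model length {self.length}")
        logits = self._logits(encode(seq))
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict_masked(self, seq: str, i: int) -> np.ndarray:
        """Exact mask semantics: marginalize the query base out.

        Row j (j != i) becomes P(n_j | all residues except i), summing the
        joint over the 4 possible bases at i; row i is its conditional given
        the rest (the mask does not hide i from itself).
        """
        if not 0 <= i < self.length:
            raise ValueError(f"mask position {i} out of range")
        idx = encode(seq)
        base = self.h / self.temperature  # start from fields only
        logits = self._logits(idx)
        profile = np.exp(logits - logits.max(axis=1, keepdims=True))
        profile /= profile.sum(axis=1, keepdims=True)

        # positions coupled to i need the exact 2-site marginalization
        partners = [
            (j, J, True) if a == i else (a, J, False)
            for (a, j), J in self.couplings.items()
            if a == i or j == i
        ]
        if not partners:
            return profile
        # log-weights for the 4 possible bases at i given everything but i, j
        for j, J, i_is_first in partners:
            # w_a = h_i(a) + couplings of i with all fixed residues except j
            w = base[i].copy()
            for (p, q), Jpq in self.couplings.items():
                if p == i and q != j:
                    w += Jpq[:, idx[q]] / self.temperature
                elif q == i and p != j:
                    w += Jpq[idx[p], :] / self.temperature
            # logits at j from everything except i
            lj = base[j].copy()
            for (p, q), Jpq in self.couplings.items():
                if p == j and q != i:
                    lj += Jpq[:, idx[q]] / self.temperature
                elif q == j and p != i:
                    lj += Jpq[idx[p], :] / self.temperature
            Jij = (J if i_is_first else J.T) / self.temperature
            # P(n_j=b | rest\{i}) ∝ Σ_a exp(w_a + J_ij(a,b) + lj_b)
            mat = w[:, None] + Jij + lj[None, :]
            mat -= mat.max()
            pj = np.exp(mat).sum(axis=0)
            profile[j] = pj / pj.sum()
        return profile

    # -- exhaustive reference quantities -----------------------------------

    def energy(self, idx: np.ndarray) -> float:
        e = float(self.h[np.arange(self.length), idx].sum())
        for (i, j), J in self.couplings.items():
            e += float(J[idx[i], idx[j]])
        return e / self.temperature

    def all_sequences_energies(self) -> tuple[np.ndarray, np.ndarray]:
        """Enumerate all 4^N sequences and their energies (N <= 10 guard)."""
        n = self.length
        if n > 10:
            raise ValueError("full enumeration limited to N <= 10")
        grids = np.indices((4,) * n).reshape(n, -1).T  # (4^N, N)
        energies = self.h[np.arange(n)[:, None], grids.T].sum(axis=0).astype(float)
        for (i, j), J in self.couplings.items():
            energies += J[grids[:, i], grids[:, j]]
        return grids, energies / self.temperature

    def spec_dict(self) -> dict:
        """JSON-serializable description that rebuilds this exact model."""
        return {
            "kind": "coupling",
            "h": self.h.tolist(),
            "couplings": [
                {"i": int(i), "j": int(j), "J": J.tolist()}
                for (i, j), J in sorted(self.couplings.items())
            ],
            "temperature": self.temperature,
            "model_id": self.model_id,
        }

    @classmethod
    def from_spec_dict(cls, spec: dict) -> "PairwiseCouplingModel":
        couplings = {
            (c["i"], c["j"]): np.asarray(c["J"], dtype=float)
            for c in spec.get("couplings", [])
        }
        return cls(
            np.asarray(spec["h"], dtype=float),
            couplings,
            temperature=spec.get("temperature", 1.0),
            model_id=spec.get("model_id", "coupling"),
        )


class MarkovChainModel(NucleotideModel):
    """First-order autoregressive model: P(n_i | n_{i-1}).

    The simplest model satisfying the autoregressive contract — mutating a
    residue never changes predictions at earlier positions.  With all
    transition rows equal it degenerates to a context-free (product) model.
    """

    style = "autoregressive"
    supports_mask = False

    def __init__(self, initial, transition, model_id: str = "markov"):
        self.initial = np.asarray(initial, dtype=float)
        self.transition = np.asarray(transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("initial must be (4,), transition (4, 4)")
        if not np.isclose(self.initial.sum(), 1.0) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("rows must sum to 1")
        self.model_id = model_id

    def predict(self, seq: str) -> np.ndarray:
        idx = encode(seq)
        out = np.empty((len(seq), 4))
        out[0] = self.initial
        if len(seq) > 1:
            out[1:] = self.transition[idx[:-1]]
        return out


# ---------------------------------------------------------------------------
# planted-structure generators
# ---------------------------------------------------------------------------


@dataclass
class StemSpec:
    """A planted helix: base pairs rewarded for Watson-Crick complementarity.

    ``pairs`` lists (i, j) with i < j; an antiparallel stem has consecutive
    i ascending while j descends (constant i + j).  ``strength`` scales the
    Watson-Crick reward; wobble (G·T) pairing gets half strength when
    ``wobble`` is on.
    """

    pairs: list[tuple[int, int]]
    strength: float = 3.0
    wobble: bool = True

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"stem pair ({i},{j}) must have i < j")
            if i in seen or j in seen:
                raise ValueError(f"position reused within one stem: ({i},{j})")
            seen.update((i, j))

    def coupling_matrix(self) -> np.ndarray:
        J = self.strength * WC_MATRIX
        if self.wobble:
            J = J + 0.5 * self.strength * WOBBLE_MATRIX
        return J


def antiparallel_stem(start_i: int, start_j: int, length: int,
                      strength: float = 3.0, wobble: bool = True) -> StemSpec:
    """Helix of ``length`` pairs: (start_i + t, start_j - t)."""
    pairs = [(start_i + t, start_j - t) for t in range(length)]
    return StemSpec(pairs=pairs, strength=strength, wobble=wobble)


def make_stem_model(n: int, stems: list[StemSpec],
                    h: np.ndarray | None = None) -> PairwiseCouplingModel:
    """Coupling model with Watson-Crick rewards at each planted pair."""
    couplings: dict[tuple[int, int], np.ndarray] = {}
    for stem in stems:
        J = stem.coupling_matrix()
        for i, j in stem.pairs:
            if j >= n:
                raise ValueError(f"stem pair ({i},{j}) outside sequence of length {n}")
            if (i, j) in couplings:
                raise ValueError(f"pair ({i},{j}) assigned by two stems")
            couplings[(i, j)] = J.copy()
    if h is None:
        h = np.zeros((n, 4))
    return PairwiseCouplingModel(h, couplings, model_id="stem")


def make_motif_model(n: int, pwm: np.ndarray, placement: int,
                     strength: float = 2.0,
                     h: np.ndarray | None = None) -> PairwiseCouplingModel:
    """Dense mutual couplings among the motif positions.

    Each motif position gets a preference vector from the PWM's log-enrichment
    over uniform, centered and normalized to unit Euclidean norm; the coupling
    between positions i and j is the outer product of their preference vectors
    scaled by ``strength / (L - 1)``, so every in-motif mutation perturbs
    every other in-motif position — the mechanism behind on-diagonal
    dependency blocks at bound motifs — while the total conditional logit
    swing at any position stays of order ``strength`` regardless of motif
    length (keeping probabilities away from saturation).
    """
    pwm = np.asarray(pwm, dtype=float)
    L = pwm.shape[0]
    if L < 2:
        raise ValueError("motif length must be >= 2")
    if placement + L > n:
        raise ValueError("motif does not fit in sequence")
    if pwm.shape != (L, 4) or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm must be L x 4 with rows summing to 1")
    w = np.log2(np.clip(pwm, 1e-6, None) / 0.25)
    w -= w.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    w = np.divide(w, norms, out=np.zeros_like(w), where=norms > 0)
    couplings = {}
    for a in range(L):
        for b in range(a + 1, L):
            i, j = placement + a, placement + b
            couplings[(i, j)] = (strength / (L - 1)) * np.outer(w[a], w[b])
    if h is None:
        h = np.zeros((n, 4))
    return PairwiseCouplingModel(h, couplings, model_id="motif")


@dataclass
class DuplicationConfig:
    """Study conditions for the artificial-duplication experiment.

    Random 100-nt backgrounds carry two copies of a short duplicate
    (lengths 2–20), forward or inverted, at non-overlapping random offsets.
    """

    n_sequences: int = 10
    background_length: int = 100
    duplicate_length: int = 10
    orientation: str = "forward"  # or "inverted"
    coupling_strength: float = 3.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self):
        if self.orientation not in ("forward", "inverted"):
            raise ValueError("orientation must be 'forward' or 'inverted'")
        if not 2 <= self.duplicate_length <= self.background_length // 2:
            raise ValueError("duplicate must fit twice in the background")


@dataclass
class DuplicationSet:
    sequences: list[str]
    placements: list[dict] = field(default_factory=list)
    models: list[PairwiseCouplingModel] = field(default_factory=list)


def make_duplication_set(config: DuplicationConfig) -> DuplicationSet:
    """Generate duplicated sequences plus companion coupling models.

    Each companion model couples position t of copy 1 to its partner in
    copy 2 (same order for forward duplications, reversed for inverted) with
    an identity reward (forward) or complementarity reward (inverted), so
    its dependency map shows the corresponding (anti)parallel diagonal.
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.background_length, config.duplicate_length
    comp = np.asarray(config.base_composition, dtype=float)
    comp = comp / comp.sum()
    ident = config.coupling_strength * np.eye(4)
    inv = config.coupling_strength * WC_MATRIX
    out = DuplicationSet(sequences=[])
    for s in range(config.n_sequences):
        background = rng.choice(4, size=n, p=comp)
        rng.shuffle(background)
        dup = rng.integers(0, 4, size=L)
        for _ in range(config.max_retries):
            s1, s2 = sorted(rng.integers(0, n - L + 1, size=2))
            if s1 + L <= s2:
                break
        else:
            raise RuntimeError("could not place non-overlapping duplicate copies")
        seq = background.copy()
        seq[s1:s1 + L] = dup
        if config.orientation == "forward":
            seq[s2:s2 + L] = dup
            couplings = {(s1 + t, s2 + t): ident.copy() for t in range(L)}
        else:
            rc = 3 - dup[::-1]  # A<->T, C<->G under the ACGT encoding
            seq[s2:s2 + L] = rc
            couplings = {
                (s1 + t, s2 + L - 1 - t): inv.copy() for t in range(L)
            }
        out.sequences.append("".join(ALPHABET[b] for b in seq))
        out.placements.append(
            {
                "seq_id": f"dup{s}",
                "start1": int(s1),
                "start2": int(s2),
                "length": L,
                "orientation": config.orientation,
            }
        )
        out.models.append(
            PairwiseCouplingModel(np.zeros((n, 4)), couplings, model_id="duplication")
        )
    return out


def random_coupling_model(rng: np.random.Generator, n: int,
                          n_couplings: int = 3, field_scale: float = 0.5,
                          coupling_scale: float = 1.5) -> PairwiseCouplingModel:
    """Random fields + random couplings on distinct pairs; oracle-test fodder."""
    h = field_scale * rng.standard_normal((n, 4))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(pairs), size=min(n_couplings, len(pairs)), replace=False)
    couplings = {
        pairs[c]: coupling_scale * rng.standard_normal((4, 4)) for c in chosen
    }
    return PairwiseCouplingModel(h, couplings, model_id="random")


def random_sequence(rng: np.random.Generator, n: int,
                    composition=(0.25, 0.25, 0.25, 0.25)) -> str:
    comp = np.asarray(composition, dtype=float)
    comp = comp / comp.sum()
    return "".join(ALPHABET[b] for b in rng.choice(4, size=n, p=comp))
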