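"""Brute-force reference computations, written independently of depcore.

These functions recompute dependencies and conditionals from first
principles (literal per-pair substitution, full-joint enumeration) and are
deliberately kept free of any shared odds/log helper with
:mod:`nucdep.depcore`, so they can serve as its oracle.
"""

from __future__ import annotations

import math

import numpy as np

from .models import ALPHABET, NucleotideModel
from .synthetic import PairwiseCouplingModel


def _odds(p: float, eps: float = 1e-9) -> float:
    p = min(max(p, eps), 1.0 - eps)
    return p / (1.0 - p)


def brute_force_variant_dependency(
    model: NucleotideModel, seq: str, i: int, k_alt: str, j: int,
    eps: float = 1e-9,
) -> float:
    """e_{i,j,k_alt}: literal evaluation of the dependency definition."""
    if i == j:
        raise ValueError("self-dependencies are undefined")
    if seq[i] == k_alt:
        raise ValueError("k_alt must differ from the reference base")
    p_ref = model.predict(seq)[j]
    alt_seq = seq[:i] + k_alt + seq[i + 1:]
    p_alt = model.predict(alt_seq)[j]
    best = 0.0
    for k in range(4):
        ratio = _odds(float(p_alt[k]), eps) / _odds(float(p_ref[k]), eps)
        best = max(best, abs(math.log2(ratio)))
    return best


def brute_force_dependency(
    model: NucleotideModel, seq: str, i: int, j: int, eps: float = 1e-9
) -> float:
    """e_{i,j}: max over the three alternative query bases."""
    if i == j:
        raise ValueError("self-dependencies are undefined")
    return max(
        brute_force_variant_dependency(model, seq, i, alt, j, eps)
        for alt in ALPHABET
        if alt != seq[i]
    )


def brute_force_map(model: NucleotideModel, seq: str,
                    eps: float = 1e-9) -> np.ndarray:
    """Full dependency map by repeated literal per-pair evaluation."""
    n = len(seq)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = brute_force_dependency(model, seq, i, j, eps)
    return out


def enumeration_conditionals(model: PairwiseCouplingModel, seq: str) -> np.ndarray:
    """Exact conditionals via full-joint enumeration over all 4^N sequences.

    Independent route to the model's closed-form ``predict``: conditions the
    enumerated joint on all residues but one.
    """
    n = model.length
    grids, energies = model.all_sequences_energies()
    energies = energies - energies.max()
    weights = np.exp(energies)
    idx = np.array([ALPHABET.index(b) for b in seq])
    out = np.empty((n, 4))
    for j in range(n):
        rest = np.delete(np.arange(n), j)
        match = np.all(grids[:, rest] == idx[rest], axis=1)
        w = np.array([weights[match & (grids[:, j] == b)].sum() for b in range(4)])
        out[j] = w / w.sum()
    return out
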