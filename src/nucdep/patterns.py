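"""Pattern detectors over dependency maps.

Motif instances show up as dense blocks along the map diagonal; RNA stems
and inverted duplications as antiparallel diagonals (runs of cells with
constant i + j); forward duplications as parallel diagonals.  Detection is
deliberately simple and transparent: a quantile-based block score for
motifs, mean-centered 5x5 diagonal filters plus thresholding for stems,
with standard evaluation helpers (AUROC, precision, bootstrap CIs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from sklearn.metrics import roc_auc_score

from .depcore import DependencyMap, symmetrize_max


def _as_matrix(m) -> np.ndarray:
    return m.e if isinstance(m, DependencyMap) else np.asarray(m, dtype=float)


# ---------------------------------------------------------------------------
# block score
# ---------------------------------------------------------------------------


@dataclass
class BlockScoreTrack:
    scores: np.ndarray
    span: int
    quartile: float


def block_score(m, span: int = 6, quartile: float = 0.25,
                include_diagonal: bool = False,
                sliding: bool = True) -> BlockScoreTrack:
    """Per-nucleotide block score: quantile of dependencies in 6-nt spans.

    For every window of ``span`` consecutive positions, collect all
    query-target dependencies within the window (the diagonal is excluded by
    default: span^2 - span values) and take the ``quartile`` quantile with
    linear interpolation between order statistics.  The per-nucleotide score
    is the maximum over windows containing the nucleotide.  ``sliding=False``
    tiles the windows instead (anchored at position 0).
    """
    e = _as_matrix(m)
    n = e.shape[0]
    if span < 2:
        raise ValueError("span must be >= 2")
    if n < span:
        raise ValueError(f"map size {n} smaller than span {span}")
    starts = range(0, n - span + 1) if sliding else range(0, n - span + 1, span)
    scores = np.full(n, np.nan)
    for s in starts:
        window = e[s:s + span, s:s + span]
        if include_diagonal:
            vals = window.ravel()
            vals = vals[~np.isnan(vals)]
        else:
            vals = window[~np.eye(span, dtype=bool)]
        w_score = float(np.quantile(vals, quartile))
        sl = slice(s, s + span)
        scores[sl] = np.fmax(scores[sl], w_score)
    return BlockScoreTrack(scores=scores, span=span, quartile=quartile)


# ---------------------------------------------------------------------------
# diagonal filters and stem calling
# ---------------------------------------------------------------------------


@dataclass
class DiagonalFilter:
    """Mean-centered (anti)diagonal matched filter.

    Ones on the (anti)diagonal of a size x size zero matrix, then the global
    mean (1/size) subtracted from every cell so the response to any constant
    patch is exactly zero.
    """

    weights: np.ndarray
    size: int
    orientation: str


def build_diagonal_filter(size: int = 5,
                          orientation: str = "antiparallel") -> DiagonalFilter:
    if size < 3 or size % 2 == 0:
        raise ValueError("filter size must be odd and >= 3")
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError("orientation must be 'parallel' or 'antiparallel'")
    w = np.eye(size)
    if orientation == "antiparallel":
        w = np.fliplr(w)
    w -= w.mean()
    return DiagonalFilter(weights=w, size=size, orientation=orientation)


@dataclass
class ResponseGrid:
    """Valid-region filter response; ``offset`` maps response indices back to
    map coordinates: response[r, c] is the window centered at
    (r + offset, c + offset)."""

    values: np.ndarray
    offset: int
    orientation: str


def convolve_map(m, f: DiagonalFilter,
                 symmetrized: bool = False) -> ResponseGrid:
    """Cross-correlate the map with a diagonal filter (valid region only).

    Diagonal NaN sentinels are treated as zero — conservative, since zero
    cells cannot push a window over the stem-calling threshold.
    """
    e = _as_matrix(m)
    if symmetrized:
        e = symmetrize_max(e)
    if e.shape[0] < f.size or e.shape[1] < f.size:
        raise ValueError("map smaller than filter")
    filled = np.nan_to_num(e, nan=0.0)
    response = signal.correlate2d(filled, f.weights, mode="valid")
    return ResponseGrid(values=response, offset=f.size // 2,
                        orientation=f.orientation)


@dataclass
class StemCallResult:
    hits: list[tuple[int, int, float]]
    antidiagonal_ids: list[int]
    n_stems: int
    is_candidate: bool
    threshold: float


def call_stems(response: ResponseGrid, threshold: float = 25.0,
               min_support: int = 3, min_stems: int = 2) -> StemCallResult:
    """Threshold an antiparallel-filter response and group hits into stems.

    Cells below ``threshold`` are zeroed; surviving cells are grouped by
    i + j of their window centers (in map coordinates); every antidiagonal
    supported by at least ``min_support`` survivors counts as one candidate
    stem, and a map is a structure candidate when it carries at least
    ``min_stems`` stems.
    """
    if response.orientation != "antiparallel":
        raise ValueError("stem calling expects an antiparallel-filter response")
    vals = response.values
    off = response.offset
    rows, cols = np.nonzero(vals >= threshold)
    hits = [
        (int(r + off), int(c + off), float(vals[r, c]))
        for r, c in zip(rows, cols)
    ]
    support: dict[int, int] = {}
    for r, c, _ in hits:
        support[r + c] = support.get(r + c, 0) + 1
    ids = sorted(k for k, v in support.items() if v >= min_support)
    return StemCallResult(
        hits=hits,
        antidiagonal_ids=ids,
        n_stems=len(ids),
        is_candidate=len(ids) >= min_stems,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# pair scoring and evaluation
# ---------------------------------------------------------------------------


def pair_contact_scores(m) -> list[tuple[int, int, float]]:
    """One score per unordered position pair: max of the two map entries."""
    sym = symmetrize_max(_as_matrix(m))
    n = sym.shape[0]
    return [(i, j, float(sym[i, j])) for i in range(n) for j in range(i + 1, n)]


def auroc(scores, labels) -> float:
    """Rank-based AUROC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def precision_at_threshold(scores, labels, t: float) -> float:
    """TP / (TP + FP) among pairs scoring at or above ``t`` (NaN if none)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    called = scores >= t
    if not called.any():
        return float("nan")
    return float(labels[called].mean())


def bootstrap_correlation_ci(x, y, n_boot: int = 100,
                             seed: int | np.random.Generator = 0
                             ) -> tuple[float, float, float]:
    """Pearson r with a ±2-bootstrap-SD confidence interval.

    Resamples (x, y) pairs with replacement ``n_boot`` times and reports
    (r, r - 2·sd, r + 2·sd) with sd the standard deviation of bootstrap r's.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    r = float(stats.pearsonr(x, y).statistic)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boots[b] = r
        else:
            boots[b] = stats.pearsonr(xb, yb).statistic
    sd = float(np.std(boots))
    return r, r - 2 * sd, r + 2 * sd
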