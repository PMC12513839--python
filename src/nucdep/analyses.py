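"""Higher-level statistical procedures on dependency maps.

Covers the splice-site analyses (donor-acceptor dependencies with decoy and
matched-distance negatives, splice-outlier scoring with a near-diagonal
guard), the artificial-duplication diagonal profile, genome tiling with
distance sampling, the power-law fit of dependency versus distance with
residual periodicity, and genomic region categorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .depcore import DependencyMap, dependency_map
from .models import NucleotideModel

DEFAULT_DEPENDENCY_FLOOR = 1e-3


def _as_matrix(m) -> np.ndarray:
    return m.e if isinstance(m, DependencyMap) else np.asarray(m, dtype=float)


# ---------------------------------------------------------------------------
# splice-site statistics
# ---------------------------------------------------------------------------


@dataclass
class SpliceAnnotation:
    """Intron with its splice-site dinucleotides, 0-based half-open.

    ``donor_start`` indexes the first base of the (usually GT) donor
    dinucleotide; ``acceptor_start`` the first base of the (usually AG)
    acceptor.  The intron interval spans donor through acceptor inclusive.
    """

    donor_start: int
    acceptor_start: int
    intron: tuple[int, int]

    def __post_init__(self):
        if self.donor_start >= self.acceptor_start:
            raise ValueError("donor must lie 5' of the acceptor")

    @property
    def donor_positions(self) -> tuple[int, int]:
        return (self.donor_start, self.donor_start + 1)

    @property
    def acceptor_positions(self) -> tuple[int, int]:
        return (self.acceptor_start, self.acceptor_start + 1)

    @property
    def distance(self) -> int:
        return self.acceptor_start - self.donor_start


def _site_pair_mean(e: np.ndarray, site_a, site_b,
                    both_orientations: bool) -> float:
    cells = [e[p, q] for p in site_a for q in site_b]
    if both_orientations:
        cells += [e[q, p] for p in site_a for q in site_b]
    return float(np.nanmean(cells))


def donor_acceptor_dependency(m, ann: SpliceAnnotation,
                              both_orientations: bool = True) -> float:
    """Mean dependency between every donor and acceptor nucleotide."""
    e = _as_matrix(m)
    donor = ann.donor_positions
    acceptor = ann.acceptor_positions
    if set(donor) & set(acceptor):
        raise ValueError("donor and acceptor dinucleotides overlap")
    for p in (*donor, *acceptor):
        if not 0 <= p < e.shape[0]:
            raise ValueError(f"splice position {p} outside map")
    return _site_pair_mean(e, donor, acceptor, both_orientations)


def decoy_acceptor_dependencies(m, ann: SpliceAnnotation, intron_seq: str,
                                both_orientations: bool = True) -> list[float]:
    """Donor-to-decoy statistics for every intronic AG that is not the acceptor.

    ``intron_seq`` is the sequence of the intron interval; AG dinucleotides
    whose map coordinates coincide with the annotated acceptor are skipped.
    """
    e = _as_matrix(m)
    start = ann.intron[0]
    out = []
    for off in range(len(intron_seq) - 1):
        if intron_seq[off:off + 2] != "AG":
            continue
        pos = start + off
        if pos == ann.acceptor_start:
            continue
        decoy = (pos, pos + 1)
        if set(decoy) & set(ann.donor_positions):
            continue
        if decoy[1] >= e.shape[0]:
            continue
        out.append(_site_pair_mean(e, ann.donor_positions, decoy,
                                   both_orientations))
    return out


def matched_distance_background(m, ann: SpliceAnnotation, n: int = 4,
                                rng: int | np.random.Generator = 0
                                ) -> list[float]:
    """Random dependencies at exactly the donor-acceptor spacing.

    Samples ``n`` map entries (p, p + d) at the annotated spacing d, in a
    random orientation, excluding any pair touching the donor or acceptor
    dinucleotides themselves.  Sampling is without replacement; if fewer
    eligible pairs exist than requested, it falls back to sampling with
    replacement.
    """
    e = _as_matrix(m)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = ann.distance
    excluded = set(ann.donor_positions) | set(ann.acceptor_positions)
    eligible = [
        p for p in range(e.shape[0] - d)
        if p not in excluded and (p + d) not in excluded
    ]
    if not eligible:
        raise ValueError("no eligible pairs at the donor-acceptor spacing")
    replace = len(eligible) < n
    starts = rng.choice(eligible, size=n, replace=replace)
    orientations = rng.integers(0, 2, size=n)
    return [
        float(e[p, p + d] if o == 0 else e[p + d, p])
        for p, o in zip(starts, orientations)
    ]


def splice_outlier_score(m, variant_pos: int, junction_start: int,
                         min_dist: int = 5, both_orientations: bool = True
                         ) -> tuple[float, float] | None:
    """(foreground, background) for a variant against a splice dinucleotide.

    Foreground: mean map value at the intersection of the variant position
    and the junction dinucleotide.  Background: mean over all map entries at
    the same query-target spacing.  Variants closer than ``min_dist`` to the
    junction are excluded (returns None) to avoid near-diagonal
    self-interaction values.
    """
    e = _as_matrix(m)
    n = e.shape[0]
    junction = (junction_start, junction_start + 1)
    d = abs(variant_pos - junction_start)
    if d < min_dist:
        return None
    cells = [e[variant_pos, q] for q in junction]
    if both_orientations:
        cells += [e[q, variant_pos] for q in junction]
    foreground = float(np.nanmean(cells))
    rows, cols = np.indices(e.shape)
    at_distance = np.abs(rows - cols) == d
    background = float(np.nanmean(e[at_distance]))
    return foreground, background


# ---------------------------------------------------------------------------
# duplication profile
# ---------------------------------------------------------------------------


def duplication_pair_positions(start1: int, start2: int, length: int,
                               orientation: str) -> list[tuple[int, int]]:
    """Map position t of copy 1 to its partner in copy 2.

    Forward copies pair in the same order (a parallel diagonal); inverted
    copies pair in reverse order (an antiparallel diagonal).
    """
    if orientation == "forward":
        return [(start1 + t, start2 + t) for t in range(length)]
    if orientation == "inverted":
        return [(start1 + t, start2 + length - 1 - t) for t in range(length)]
    raise ValueError("orientation must be 'forward' or 'inverted'")


def duplication_dependency_profile(maps, placements) -> pd.DataFrame:
    """Mean dependency along each duplication diagonal, aggregated.

    ``maps`` is a sequence of dependency maps (one per sequence) and
    ``placements`` the matching records from the duplication generator.
    Returns one row per (length, orientation) with the mean of per-sequence
    diagonal means and a 95% normal-approximation CI across sequences.
    """
    rows = []
    for m, placement in zip(maps, placements):
        e = _as_matrix(m)
        pairs = duplication_pair_positions(
            placement["start1"], placement["start2"],
            placement["length"], placement["orientation"],
        )
        for a, b in pairs:
            if not (0 <= a < e.shape[0] and 0 <= b < e.shape[0]):
                raise ValueError(f"placement cell ({a},{b}) outside map")
        vals = [np.nanmean([e[a, b], e[b, a]]) for a, b in pairs]
        rows.append(
            {
                "seq_id": placement.get("seq_id", ""),
                "length": placement["length"],
                "orientation": placement["orientation"],
                "mean_dependency": float(np.mean(vals)),
            }
        )
    per_seq = pd.DataFrame(rows)
    grouped = per_seq.groupby(["length", "orientation"])["mean_dependency"]
    out = grouped.agg(["mean", "count", "sem"]).reset_index()
    out["ci_lower"] = out["mean"] - 1.96 * out["sem"].fillna(0.0)
    out["ci_upper"] = out["mean"] + 1.96 * out["sem"].fillna(0.0)
    return out.rename(columns={"mean": "mean_dependency", "count": "n_sequences"})


# ---------------------------------------------------------------------------
# genome tiling, power law, residual periodicity
# ---------------------------------------------------------------------------


@dataclass
class DistanceSample:
    """Sampled (distance, dependency) records from tiled dependency maps."""

    records: pd.DataFrame  # columns: distance, dependency[, region]
    floor: float = DEFAULT_DEPENDENCY_FLOOR

    @property
    def distances(self) -> np.ndarray:
        return self.records["distance"].to_numpy()

    @property
    def dependencies(self) -> np.ndarray:
        return self.records["dependency"].to_numpy()


def tile_dependency_samples(
    model: NucleotideModel, seq: str, window: int = 1000, stride: int = 500,
    max_dist: int = 500, n_sample: int = 1000,
    floor: float = DEFAULT_DEPENDENCY_FLOOR,
    rng: int | np.random.Generator = 0,
) -> DistanceSample:
    """Tile a long sequence with square dependency maps and sample distances.

    Square maps of ``window`` positions are computed every ``stride``
    positions (final partial window dropped); entries mapping to the same
    genomic (i, j) from overlapping tiles are averaged first, then
    ``n_sample`` entries are drawn per tile (seeded, without replacement)
    among pairs at most ``max_dist`` apart, and values at or below ``floor``
    are dropped.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    if window > model.max_context:
        raise ValueError("window exceeds model context")
    offsets = list(range(0, n - window + 1, stride))
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for off in offsets:
        tile = dependency_map(model, seq[off:off + window]).e
        qs, ts = np.nonzero(~np.isnan(tile))
        keep = np.abs(qs - ts) <= max_dist
        for q, t in zip(qs[keep], ts[keep]):
            key = (off + int(q), off + int(t))
            sums[key] = sums.get(key, 0.0) + float(tile[q, t])
            counts[key] = counts.get(key, 0) + 1
    averaged = {k: sums[k] / counts[k] for k in sums}
    rows = []
    for off in offsets:
        keys = [
            k for k in averaged
            if off <= k[0] < off + window and off <= k[1] < off + window
        ]
        take = min(n_sample, len(keys))
        chosen = rng.choice(len(keys), size=take, replace=False)
        for c in chosen:
            gi, gj = keys[c]
            val = averaged[(gi, gj)]
            if val > floor:
                rows.append({"distance": abs(gi - gj), "dependency": val})
    records = pd.DataFrame(rows, columns=["distance", "dependency"])
    return DistanceSample(records=records, floor=floor)


@dataclass
class PowerLawFit:
    """Log10-log10 OLS of dependency against distance.

    ``decay_per_tenfold`` is the percentage drop in dependency per tenfold
    distance increase, (1 - 10^slope) * 100; ``scaling_constant`` is the
    exponentiated intercept, i.e. the fitted dependency at distance 1.
    """

    slope: float
    intercept: float
    n_points: int
    residuals: np.ndarray = field(repr=False)
    distances: np.ndarray = field(repr=False)

    @property
    def decay_per_tenfold(self) -> float:
        return (1.0 - 10.0 ** self.slope) * 100.0

    @property
    def scaling_constant(self) -> float:
        return 10.0 ** self.intercept


def fit_power_law(sample: DistanceSample) -> PowerLawFit:
    """Ordinary least squares on (log10 distance, log10 dependency)."""
    d = sample.distances.astype(float)
    y = sample.dependencies.astype(float)
    if len(d) < 10:
        raise ValueError("need at least 10 points")
    if np.any(d < 1) or np.any(y <= 0):
        raise ValueError("distances must be >= 1 and dependencies > 0")
    log_d = np.log10(d)
    log_y = np.log10(y)
    if len(np.unique(log_d)) < 2:
        raise ValueError("need at least 2 distinct distances")
    fit = stats.linregress(log_d, log_y)
    residuals = log_y - (fit.intercept + fit.slope * log_d)
    return PowerLawFit(slope=float(fit.slope), intercept=float(fit.intercept),
                       n_points=len(d), residuals=residuals, distances=d)


def simulate_power_law_sample(
    n: int = 10_000, decay_per_tenfold: float = 78.0,
    scaling_constant: float = 0.1, noise_sd: float = 0.3,
    max_dist: int = 500, rng: int | np.random.Generator = 0,
) -> DistanceSample:
    """Synthetic (distance, dependency) draws from a noisy power law.

    Distances are uniform on [1, max_dist]; log10 dependencies get additive
    Gaussian noise of ``noise_sd``.  Used to validate parameter recovery.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    slope = np.log10(1.0 - decay_per_tenfold / 100.0)
    d = rng.integers(1, max_dist + 1, size=n).astype(float)
    log_y = (np.log10(scaling_constant) + slope * np.log10(d)
             + noise_sd * rng.standard_normal(n))
    return DistanceSample(
        records=pd.DataFrame({"distance": d.astype(int), "dependency": 10.0 ** log_y}),
        floor=0.0,
    )


def residual_profile(fit: PowerLawFit, sample: DistanceSample) -> pd.DataFrame:
    """Median power-law residual per integer distance, with mod-3 class.

    Positive medians flag distances with systematically stronger
    dependencies than the global power law predicts (e.g. codon-periodic
    spacings or the nucleosome repeat length).
    """
    df = pd.DataFrame({
        "distance": sample.distances.astype(int),
        "residual": fit.residuals,
    })
    out = (df.groupby("distance")["residual"].median()
           .reset_index()
           .rename(columns={"residual": "median_residual"}))
    out["mod3"] = out["distance"] % 3
    return out


# ---------------------------------------------------------------------------
# region categorization
# ---------------------------------------------------------------------------

STRUCTURED_RNA_TYPES = {
    "tRNA", "tRNA_pseudogene", "rRNA", "snRNA", "ribozyme", "SRP_RNA",
    "snoRNA", "RNase_P_RNA", "RNase_MRP_RNA",
}
PROTEIN_CODING_TYPES = {
    "five_prime_utr", "three_prime_utr", "intron", "CDS",
    "pseudogene_with_CDS",
}
INTERGENIC_TYPES = {"transposable_element", "pseudogene"}

MITOCHONDRIAL_SEQIDS = {"chrM", "chrMT", "MT", "Mito", "mito", "mitochondrion"}


def compartment(seqid: str) -> str:
    """'mitochondrial' or 'nuclear' from the sequence/chromosome name."""
    return "mitochondrial" if seqid in MITOCHONDRIAL_SEQIDS else "nuclear"


def label_regions(intervals, features) -> list[str]:
    """Categorize intervals by overlapping annotation feature types.

    ``intervals``: (seqid, start, end) records, 0-based half-open.
    ``features``: records with seqid, type, start, end attributes or keys.
    Precedence: structured_RNA > protein_coding_gene > intergenic; intervals
    overlapping no informative feature are intergenic.
    """
    def get(f, name):
        return f[name] if isinstance(f, dict) else getattr(f, name)

    labels = []
    for seqid, start, end in intervals:
        cats = set()
        for f in features:
            if get(f, "seqid") != seqid:
                continue
            if get(f, "end") <= start or get(f, "start") >= end:
                continue
            ftype = get(f, "type")
            if ftype in STRUCTURED_RNA_TYPES:
                cats.add("structured_RNA")
            elif ftype in PROTEIN_CODING_TYPES:
                cats.add("protein_coding_gene")
            elif ftype in INTERGENIC_TYPES:
                cats.add("intergenic")
        if "structured_RNA" in cats:
            labels.append("structured_RNA")
        elif "protein_coding_gene" in cats:
            labels.append("protein_coding_gene")
        else:
            labels.append("intergenic")
    return labels
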