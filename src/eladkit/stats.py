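"""Cross-cutting statistics: feature×landmark contingency tests, border
enrichment, target-gene set dynamics, and FRAP recovery normalization.

The contingency test asks whether a genomic feature (peaks, eLADs,
cLADs, expression, ATAC) is enriched or depleted in bins belonging to an
architectural landmark (A compartment, B compartment, TAD border).  The
effect size is the natural-log odds ratio with a Haldane–Anscombe ½
correction applied only when a zero cell would make it infinite; the
p-value is the two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .genome import GenomeModel
from .hic import TadPartition
from .signal import PeakSet

__all__ = [
    "ContingencyResult",
    "DynamicsSummary",
    "binarize_feature",
    "feature_landmark_log_odds",
    "border_enrichment_pvalue",
    "timepoint_dynamics",
    "de_target_overlap",
    "frap_normalize",
]


@dataclass(frozen=True)
class ContingencyResult:
    feature: str
    landmark: str
    a: int  # feature+ in landmark
    b: int  # feature+ out of landmark
    c: int  # feature- in landmark
    d: int  # feature- out of landmark
    log_odds: float
    p_value: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value out of range")
        if not math.isfinite(self.log_odds):
            raise ValueError("log-odds must be finite")

    @property
    def n_bins(self) -> int:
        return self.a + self.b + self.c + self.d


def binarize_feature(
    intervals: dict[str, np.ndarray],
    chrom: str,
    n_bins: int,
    resolution: int,
    min_fraction: float = 0.0,
) -> np.ndarray:
    """Boolean per-bin presence of a feature (any-overlap by default).

    With ``min_fraction > 0`` a bin counts as feature-positive only if at
    least that fraction of the bin is covered.
    """
    present = np.zeros(n_bins, dtype=bool)
    cov = np.zeros(n_bins)
    for s, e in intervals.get(chrom, ()):
        lo, hi = int(s) // resolution, (int(e) - 1) // resolution
        for b in range(max(lo, 0), min(hi + 1, n_bins)):
            ov = min(e, (b + 1) * resolution) - max(s, b * resolution)
            cov[b] += max(ov, 0)
    if min_fraction > 0:
        present = cov / resolution >= min_fraction
    else:
        present = cov > 0
    return present


def feature_landmark_log_odds(
    feature_bins: np.ndarray,
    landmark_bins: np.ndarray,
    evaluated: np.ndarray | None = None,
    feature: str = "feature",
    landmark: str = "landmark",
) -> ContingencyResult:
    """2×2 feature-presence × landmark-membership test over a bin grid.

    ``feature_bins`` and ``landmark_bins`` are boolean vectors on the same
    grid; ``evaluated`` (default all) restricts to unmasked bins.
    """
    f = np.asarray(feature_bins, dtype=bool)
    l = np.asarray(landmark_bins, dtype=bool)
    if f.shape != l.shape:
        raise ValueError("feature and landmark grids differ")
    ok = np.ones_like(f) if evaluated is None else np.asarray(evaluated, dtype=bool)
    f, l = f[ok], l[ok]
    if not l.any() or l.all():
        raise ValueError("landmark must be a proper, non-empty subset of evaluated bins")
    a = int(np.sum(f & l))
    b = int(np.sum(f & ~l))
    c = int(np.sum(~f & l))
    d = int(np.sum(~f & ~l))
    if min(a, b, c, d) == 0:
        log_odds = math.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
    else:
        log_odds = math.log(a * d / (b * c))
    _, p = sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(feature, landmark, a, b, c, d, log_odds, float(min(max(p, 5e-324), 1.0)))


def _border_intervals(partition: TadPartition, border_span: int = 1) -> list[tuple[int, int]]:
    res = partition.resolution
    out = []
    for b in partition.border_bins():
        out.append((max(b - border_span, 0) * res, (b + border_span + 1) * res))
    return out


def border_enrichment_pvalue(
    peaks: PeakSet,
    partition: TadPartition,
    genome: GenomeModel,
    method: str = "binomial",
    border_span: int = 1,
    n_permutations: int = 10_000,
    seed: int = 0,
):
    """Are lamin B1 peaks over-represented at TAD borders?

    binomial: one-sided tail of the observed peak-in-border count with
    success probability = the border-bp fraction of the chromosome (an
    approximation that ignores peak width, stated in the docs).
    permutation: peaks re-placed uniformly preserving their lengths.
    Returns (p_value, fold_enrichment, observed, n_peaks).
    """
    chrom = partition.chrom
    length = genome.chrom_length(chrom)
    borders = _border_intervals(partition, border_span)
    border_bp = sum(min(e, length) - s for s, e in borders)
    p0 = border_bp / length
    ivs = peaks.intervals(chrom)
    n = len(ivs)
    if n == 0:
        return 1.0, 0.0, 0, 0
    obs = int(
        sum(
            any(s < be and bs < e for bs, be in borders)
            for s, e in ivs
        )
    )
    fold = (obs / n) / p0 if p0 > 0 else float("inf")
    if method == "binomial":
        p = float(sp_stats.binom.sf(obs - 1, n, p0))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        lengths = ivs[:, 1] - ivs[:, 0]
        bstarts = np.asarray([s for s, _ in borders])
        bends = np.asarray([e for _, e in borders])
        hits = 0
        for _ in range(n_permutations):
            starts = rng.integers(0, np.maximum(length - lengths, 1))
            ends = starts + lengths
            k = 0
            for s, e in zip(starts, ends):
                if np.any((s < bends) & (bstarts < e)):
                    k += 1
            if k >= obs:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, fold, obs, n


@dataclass
class DynamicsSummary:
    """Set algebra over per-condition target-gene sets (3 conditions)."""

    conditions: list[str]
    venn: dict[str, int]           # region key like '110' → count
    union_size: int
    maintained: int                # in every condition
    changed: int                   # union minus full intersection
    maintained_fraction: float
    changed_fraction: float
    maintained_pct: int            # rounded, presentation form
    changed_pct: int

    def __post_init__(self):
        if sum(self.venn.values()) != self.union_size:
            raise ValueError("Venn regions must sum to the union size")
        if self.maintained + self.changed != self.union_size:
            raise ValueError("maintained + changed must equal the union size")


def timepoint_dynamics(target_sets: dict[str, set]) -> DynamicsSummary:
    """Maintained/changed accounting across time-point target sets."""
    conds = list(target_sets)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    sets = [set(target_sets[c]) for c in conds]
    union = set().union(*sets)
    inter = set.intersection(*sets)
    venn: dict[str, int] = {}
    for gene_mask in range(1, 2 ** len(conds)):
        key = format(gene_mask, f"0{len(conds)}b")
        region = set(union)
        for i, bit in enumerate(key):
            region &= sets[i] if bit == "1" else (union - sets[i])
        venn[key] = len(region)
    maintained, changed = len(inter), len(union) - len(inter)
    mf = maintained / len(union) if union else 0.0
    cf = changed / len(union) if union else 0.0
    return DynamicsSummary(
        conds, venn, len(union), maintained, changed, mf, cf,
        int(round(100 * mf)), int(round(100 * cf)),
    )


def de_target_overlap(de_genes: set, targets: set):
    """Overlap of DE genes with lamin B1 target genes.

    Returns (overlap count, % of targets that are DE, % of DE that are
    targets, empty-targets flag); percentages are exact fractions × 100.
    """
    overlap = len(set(de_genes) & set(targets))
    empty = len(targets) == 0
    pct_targets_de = 0.0 if empty else 100.0 * overlap / len(targets)
    pct_de_targets = 0.0 if len(de_genes) == 0 else 100.0 * overlap / len(de_genes)
    return overlap, pct_targets_de, pct_de_targets, empty


def frap_normalize(roi_b, roi_bg, roi_nb, pb_roi_b, pb_roi_bg, pb_roi_nb):
    """Double-normalized FRAP recovery.

    [(ROI_b − ROI_bg)/(ROI_nb − ROI_bg)] /
    [(pbROI_b − pbROI_bg)/(pbROI_nb − pbROI_bg)]

    where b = bleached, bg = background, nb = non-bleached ROI and the
    pb terms are pre-bleach intensities.  Accepts scalars or per-frame
    arrays; scale-invariant in the common intensity unit.
    """
    roi_b = np.asarray(roi_b, dtype=float)
    roi_bg = np.asarray(roi_bg, dtype=float)
    roi_nb = np.asarray(roi_nb, dtype=float)
    denom1 = roi_nb - roi_bg
    if np.any(denom1 == 0):
        raise ZeroDivisionError("ROI_nb equals ROI_bg: zero denominator")
    denom2 = np.asarray(pb_roi_nb, dtype=float) - np.asarray(pb_roi_bg, dtype=float)
    if np.any(denom2 == 0):
        raise ZeroDivisionError("pbROI_nb equals pbROI_bg: zero denominator")
    pre = (np.asarray(pb_roi_b, dtype=float) - pb_roi_bg) / denom2
    if np.any(pre == 0):
        raise ZeroDivisionError("pre-bleach ratio is zero: cannot normalize")
    post = (roi_b - roi_bg) / denom1
    result = post / pre
    return float(result) if result.ndim == 0 else result
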