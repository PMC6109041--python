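"""Hi-C architecture: matrix balancing, A/B compartments, TAD borders.

Compartments follow the standard observed/expected → correlation →
leading-eigenvector construction at 100-kb resolution, oriented so that
positive PC1 (the A compartment) is the gene-dense state.  TAD borders
are local minima of an insulation score — the mean balanced contact in a
``window × window`` square straddling each bin, log2-normalized by the
chromosome-wide mean — with a prominence filter; border strength is the
prominence normalized to [0, 10] per chromosome (the strongest border on
a chromosome scores 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .signal import PeakSet

__all__ = [
    "ContactMatrix",
    "CompartmentProfile",
    "TadPartition",
    "balance_matrix",
    "compartment_pc1",
    "classify_bin_changes",
    "insulation",
    "call_borders",
    "match_borders",
    "border_peak_occupancy",
]


@dataclass
class ContactMatrix:
    """Square symmetric cis contact matrix for one chromosome."""

    chrom: str
    resolution: int
    matrix: np.ndarray
    mask: np.ndarray | None = None  # True = masked (low coverage)
    balanced: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.n_bins
        if self.matrix.ndim != 2 or self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("contact counts must be non-negative")
        tol = 0 if not self.balanced else 1e-8 * max(self.matrix.max(), 1.0)
        if np.abs(self.matrix - self.matrix.T).max() > tol:
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def balance_matrix(
    m: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 500,
    mask_percentile: float = 2.0,
) -> ContactMatrix:
    """Iterative proportional fitting (ICE-style) to uniform row sums.

    Bins whose raw marginal falls below the ``mask_percentile``-th
    percentile of positive marginals (or is zero) are masked and excluded.
    """
    mat = m.matrix.copy()
    marg = mat.sum(axis=1)
    positive = marg[marg > 0]
    cutoff = np.percentile(positive, mask_percentile) if len(positive) else 0.0
    mask = (marg <= 0) | (marg < cutoff) | m.mask
    mat[mask, :] = 0.0
    mat[:, mask] = 0.0
    live = ~mask
    if live.sum() < 2:
        raise ValueError("too few unmasked bins to balance")
    for _ in range(max_iter):
        s = mat[np.ix_(live, live)].sum(axis=1)
        s = s / s.mean()
        resid = np.abs(s - 1.0).max()
        if resid < tol:
            return ContactMatrix(m.chrom, m.resolution, mat, mask, balanced=True)
        b = np.ones(m.n_bins)
        b[live] = np.sqrt(s)
        mat = mat / np.outer(b, b)
    raise RuntimeError(f"balancing did not converge: residual {resid:.3g} after {max_iter} iterations")


@dataclass
class CompartmentProfile:
    chrom: str
    resolution: int
    pc1: np.ndarray          # NaN at masked bins
    labels: np.ndarray       # 'A', 'B', or '' at masked bins
    covariate_name: str = "gene_density"
    orientation_corr: float = float("nan")

    def __post_init__(self):
        ok = ~np.isnan(self.pc1)
        if not np.all((self.labels[ok] == "A") == (self.pc1[ok] > 0)):
            raise ValueError("label A must correspond to PC1 > 0")


def compartment_pc1(
    m: ContactMatrix,
    orientation_covariate: np.ndarray,
    covariate_name: str = "gene_density",
) -> CompartmentProfile:
    """Leading eigenvector of the O/E Pearson correlation matrix.

    The sign is flipped if PC1 anti-correlates with the orientation
    covariate, so the A compartment (PC1 > 0) is the covariate-rich
    (gene-dense, active) state.
    """
    if not m.balanced:
        m = balance_matrix(m)
    live = ~m.mask
    if live.sum() < 10:
        raise ValueError("need at least 10 unmasked bins")
    sub = m.matrix[np.ix_(live, live)]
    n = sub.shape[0]
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    expected = np.array([sub[d == k].mean() for k in range(n)])
    expected[expected == 0] = np.nan
    oe = sub / expected[d]
    oe[np.isnan(oe)] = 1.0
    if np.allclose(oe.std(axis=0), 0):
        raise ValueError("degenerate observed/expected matrix")
    corr = np.corrcoef(oe)
    if np.any(~np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    cov = np.asarray(orientation_covariate, dtype=float)[live]
    if np.std(cov) == 0 or np.std(v) == 0:
        raise ValueError("cannot orient PC1: constant covariate or eigenvector")
    r = float(stats.pearsonr(v, cov)[0])
    if r < 0:
        v, r = -v, -r
    pc1 = np.full(m.n_bins, np.nan)
    pc1[live] = v
    labels = np.where(np.isnan(pc1), "", np.where(pc1 > 0, "A", "B")).astype("U1")
    return CompartmentProfile(m.chrom, m.resolution, pc1, labels,
                              covariate_name, r)


def classify_bin_changes(
    p1: CompartmentProfile, p2: CompartmentProfile, min_abs_pc1: float = 0.0
):
    """Per-bin compartment change calls between two profiles.

    Labels: 'stable', 'AtoB', 'BtoA', or 'masked'; a change needs a sign
    flip with |PC1| ≥ ``min_abs_pc1`` in both profiles.
    """
    if (p1.resolution != p2.resolution or p1.chrom != p2.chrom
            or len(p1.pc1) != len(p2.pc1)):
        raise ValueError("profiles are on different grids")
    out = np.full(len(p1.pc1), "stable", dtype="U6")
    masked = np.isnan(p1.pc1) | np.isnan(p2.pc1)
    out[masked] = "masked"
    strong = (np.abs(p1.pc1) >= min_abs_pc1) & (np.abs(p2.pc1) >= min_abs_pc1)
    a_to_b = (p1.pc1 > 0) & (p2.pc1 < 0) & strong & ~masked
    b_to_a = (p1.pc1 < 0) & (p2.pc1 > 0) & strong & ~masked
    out[a_to_b] = "AtoB"
    out[b_to_a] = "BtoA"
    counts = {"AtoB": int(a_to_b.sum()), "BtoA": int(b_to_a.sum())}
    return out, counts


def insulation(m: ContactMatrix, window: int = 5) -> np.ndarray:
    """Per-bin insulation score (log2 of square mean over chromosome mean).

    score(i) averages the balanced contacts in the ``window × window``
    square linking the ``window`` bins upstream of *i* to the ``window``
    bins downstream.  Bins within ``window`` of an edge, and masked
    bins, get NaN.
    """
    if window < 1:
        raise ValueError("window must be ≥ 1")
    if not m.balanced:
        m = balance_matrix(m)
    n = m.n_bins
    raw = np.full(n, np.nan)
    live = ~m.mask
    for i in range(window, n - window):
        if not live[i]:
            continue
        rows = np.arange(i - window, i)
        cols = np.arange(i + 1, i + window + 1)
        ok = np.ix_(rows[live[rows]], cols[live[cols]])
        block = m.matrix[ok]
        if block.size:
            raw[i] = block.mean()
    valid = raw[np.isfinite(raw) & (raw > 0)]
    if len(valid) == 0:
        return raw
    with np.errstate(divide="ignore"):
        score = np.log2(raw / valid.mean())
    score[~np.isfinite(score)] = np.nan
    return score


@dataclass
class TadPartition:
    chrom: str
    resolution: int
    insulation: np.ndarray
    borders: list[tuple[int, float]] = field(default_factory=list)  # (bin, strength 0-10)
    prominences: np.ndarray = field(default_factory=lambda: np.empty(0))
    window: int = 5

    def __post_init__(self):
        bins = [b for b, _ in self.borders]
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("border bins must be strictly increasing")
        if any(not (0 <= s <= 10) for _, s in self.borders):
            raise ValueError("border strength must lie in [0, 10]")

    def border_bins(self) -> np.ndarray:
        return np.asarray([b for b, _ in self.borders], dtype=np.int64)


def call_borders(
    ins: np.ndarray,
    prominence_min: float = 0.5,
    chrom: str = "chr",
    resolution: int = 40_000,
    window: int = 5,
) -> TadPartition:
    """Borders = local insulation minima with prominence ≥ ``prominence_min``.

    Strength is 10 × prominence / (max prominence on the chromosome), so
    the strongest border always scores 10; NaN (edge or masked) bins can
    never become borders.
    """
    ins = np.asarray(ins, dtype=float)
    finite = np.flatnonzero(np.isfinite(ins))
    bins: list[int] = []
    proms: list[float] = []
    if len(finite) >= 3:
        lo, hi = finite[0], finite[-1]
        # interior masked bins (low-coverage bins often sit exactly at
        # boundaries) are bridged by linear interpolation for minimum
        # detection; a border is then snapped off any masked bin onto its
        # lower unmasked neighbour, so masked bins never become borders.
        filled = np.interp(np.arange(lo, hi + 1), finite, ins[finite])
        peaks, props = sps.find_peaks(-filled, prominence=prominence_min)
        best: dict[int, float] = {}
        for p, prom in zip(peaks + lo, props["prominences"]):
            b = int(p)
            if not np.isfinite(ins[b]):
                nb = [k for k in (b - 1, b + 1) if 0 <= k < len(ins) and np.isfinite(ins[k])]
                if not nb:
                    continue
                b = min(nb, key=lambda k: ins[k])
            best[b] = max(best.get(b, 0.0), float(prom))
        bins = sorted(best)
        proms = [best[b] for b in bins]
    proms_arr = np.asarray(proms)
    if len(proms_arr):
        strengths = 10.0 * (proms_arr / proms_arr.max())
    else:
        strengths = proms_arr
    borders = [(int(b), float(s)) for b, s in zip(bins, strengths)]
    return TadPartition(chrom, resolution, ins, borders, proms_arr, window)


def match_borders(partitions: list[TadPartition], tol: int = 2):
    """Cross-condition border conservation by greedy positional matching.

    All borders are pooled, sorted by bin (ties to the lower condition
    index), and clustered greedily: a cluster seeds at the smallest
    unassigned border and absorbs every border within ``tol`` bins of
    the seed.  A cluster is conserved when all conditions contribute;
    conserved fraction = conserved clusters / total clusters.
    """
    if len({p.resolution for p in partitions}) > 1:
        raise ValueError("partitions must share a resolution")
    pooled = sorted(
        (b, ci) for ci, p in enumerate(partitions) for b in p.border_bins()
    )
    clusters: list[list[tuple[int, int]]] = []
    used = [False] * len(pooled)
    for k, (b, ci) in enumerate(pooled):
        if used[k]:
            continue
        cluster = [(b, ci)]
        used[k] = True
        for k2 in range(k + 1, len(pooled)):
            if used[k2]:
                continue
            b2, c2 = pooled[k2]
            if b2 - b <= tol:
                cluster.append((b2, c2))
                used[k2] = True
            else:
                break
        clusters.append(cluster)
    n_cond = len(partitions)
    conserved = [c for c in clusters if len({ci for _, ci in c}) == n_cond]
    frac = len(conserved) / len(clusters) if clusters else 0.0
    conserved_bins = [min(b for b, _ in c) for c in conserved]
    return conserved_bins, frac, clusters


def border_peak_occupancy(
    partition: TadPartition, peaks: PeakSet, border_span: int = 1
):
    """Peak counts per border interval (border bin ± ``border_span`` bins).

    Returns the per-border counts and a histogram over {0, 1, 2, ≥3}.
    """
    res = partition.resolution
    counts = []
    ivs = peaks.intervals(partition.chrom)
    for b in partition.border_bins():
        lo = max(b - border_span, 0) * res
        hi = (b + border_span + 1) * res
        if len(ivs):
            k = int(np.sum((ivs[:, 0] < hi) & (ivs[:, 1] > lo)))
        else:
            k = 0
        counts.append(k)
    hist = {"0": 0, "1": 0, "2": 0, ">=3": 0}
    for k in counts:
        hist[str(k) if k < 3 else ">=3"] += 1
    return counts, hist
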