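"""Coordinate frame: chromosomes, genes, cLADs, and interval arithmetic.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package.  Interval sets are stored per chromosome as ``(n, 2)`` integer
arrays sorted by start; the helpers here implement the exact base-pair
arithmetic (merge, intersect, total length) the rest of the pipeline
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gene",
    "GenomeModel",
    "SyntheticTruth",
    "as_interval_array",
    "merge_intervals",
    "intersect_intervals",
    "total_length",
    "intersect_length",
]


def as_interval_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (n, 2) int64 array."""
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (start, end) pairs")
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("interval end must exceed start")
    return arr


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals into a disjoint set."""
    arr = as_interval_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Base-pair-exact intersection of two merged interval sets (sweep line)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_interval_array(out) if out else np.empty((0, 2), dtype=np.int64)


def total_length(intervals: np.ndarray) -> int:
    arr = merge_intervals(intervals)
    if len(arr) == 0:
        return 0
    return int(np.sum(arr[:, 1] - arr[:, 0]))


def intersect_length(a: np.ndarray, b: np.ndarray) -> int:
    return total_length(intersect_intervals(a, b)) if len(a) and len(b) else 0


@dataclass(frozen=True)
class Gene:
    """A gene body with its strand-resolved transcription start site."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"TSS of {self.id} outside gene body")


@dataclass
class GenomeModel:
    """Chromosome sizes, gene annotation, and constitutive-LAD intervals.

    ``clads`` maps chromosome name to an (n, 2) array of merged intervals.
    Genes are kept sorted by (chrom, start).
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)
    clads: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        sizes = dict(self.chromosomes)
        if any(l <= 0 for l in sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.id))
        for g in self.genes:
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > sizes[g.chrom]:
                raise ValueError(f"gene {g.id} outside chromosome bounds")
        self.clads = {c: merge_intervals(v) for c, v in self.clads.items() if len(v)}
        for c, arr in self.clads.items():
            if c not in sizes:
                raise ValueError(f"cLADs on unknown chromosome {c}")
            if len(arr) and (arr[0, 0] < 0 or arr[-1, 1] > sizes[c]):
                raise ValueError(f"cLAD outside chromosome {c} bounds")

    def chrom_length(self, name: str) -> int:
        for c, l in self.chromosomes:
            if c == name:
                return l
        raise KeyError(name)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene_density(self, chrom: str, bin_size: int) -> np.ndarray:
        """TSS count per fixed-size bin; orientation covariate for PC1."""
        n = -(-self.chrom_length(chrom) // bin_size)
        dens = np.zeros(n)
        for g in self.genes_on(chrom):
            dens[g.tss // bin_size] += 1
        return dens


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside a simulated genome.

    All genomic coordinates are bp; compartment block edges and TAD
    boundaries fall on multiples of ``block_unit`` so that both the
    compartment (100 kb) and TAD (40 kb) analysis grids align with them.
    """

    conditions: list[str]
    # condition -> chrom -> (n, 2) disjoint intervals
    planted_elads: dict[str, dict[str, np.ndarray]]
    # condition -> chrom -> list of (start, end, label) with label in {A, B}
    compartment_blocks: dict[str, dict[str, list[tuple[int, int, str]]]]
    # condition -> chrom -> sorted bp positions of internal TAD boundaries
    tad_boundaries: dict[str, dict[str, np.ndarray]]
    # condition -> gene id -> bool (TSS inside a planted eLAD)
    gene_lamin_status: dict[str, dict[str, bool]]
    # condition -> set of differentially expressed gene ids
    de_genes: dict[str, set]
    block_unit: int = 200_000

    def __post_init__(self):
        for cond in self.conditions:
            for chrom, arr in self.planted_elads[cond].items():
                m = merge_intervals(arr)
                if len(m) != len(arr):
                    raise ValueError(f"planted eLADs overlap in {cond}/{chrom}")
            for chrom, b in self.tad_boundaries[cond].items():
                b = np.asarray(b)
                if len(b) > 1 and np.any(np.diff(b) <= 0):
                    raise ValueError("TAD boundaries must be strictly increasing")

    def compartment_labels(self, condition: str, chrom: str, resolution: int) -> np.ndarray:
        """Per-bin A/B label at ``resolution``; errors if edges misalign."""
        blocks = self.compartment_blocks[condition][chrom]
        for s, e, _ in blocks:
            if s % resolution or e % resolution:
                raise ValueError(
                    f"resolution {resolution} incompatible with compartment grid"
                )
        n = blocks[-1][1] // resolution
        labels = np.empty(n, dtype="U1")
        for s, e, lab in blocks:
            labels[s // resolution : e // resolution] = lab
        return labels

    def boundary_bins(self, condition: str, chrom: str, resolution: int) -> np.ndarray:
        b = np.asarray(self.tad_boundaries[condition][chrom])
        if np.any(b % resolution):
            raise ValueError(f"resolution {resolution} incompatible with TAD grid")
        return (b // resolution).astype(np.int64)
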