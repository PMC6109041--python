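"""Synthetic genomes, ChIP/control tracks, expression, and Hi-C matrices.

The generator plants the structures the analysis is meant to recover:

* gene-poor, AT-rich constitutive LAD blocks in the inactive (B)
  compartment;
* gene-rich euchromatin lamin B1 domains (eLADs, mean size 0.34 Mb),
  placed preferentially (3:1) in the active (A) compartment and only
  partially retained between the three conditions (default retention
  0.28);
* within each planted eLAD, punctate lamin B1 "sites" — short blocks of
  elevated ChIP rate separated by 1-kb gaps — mirroring the TSS-centred
  site structure that domain calling then re-clusters;
* a checkerboard A/B compartment profile and block TADs whose edges fall
  on multiples of 200 kb so both the 100-kb compartment grid and the
  40-kb TAD grid align with the truth.

Count noise is Poisson everywhere (an optional overdispersion multiplier
turns it into gamma-Poisson); all draws come from one
``numpy.random.default_rng(seed)`` stream so identical (config, seed)
give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Gene, GenomeModel, SyntheticTruth, merge_intervals

__all__ = [
    "SimulationConfig",
    "PackingError",
    "simulate_genome",
    "simulate_chip_tracks",
    "simulate_expression",
    "simulate_hic",
    "simulate_sequence",
]

BLOCK_UNIT = 200_000  # lcm of the 40-kb TAD and 100-kb compartment grids


class PackingError(ValueError):
    """Raised when requested domains cannot be placed without overlap."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted world.

    Defaults describe one 20-Mb test chromosome carrying ~16 eLADs of
    mean size 0.34 Mb (≈27% coverage, between the 25.9–40.1% range of
    real eLAD sets), 20% cLAD coverage, and three conditions with a
    domain-retention fraction of 0.28 between them.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 20_000_000),)
    n_genes: int = 800
    gene_mean_length: int = 25_000
    clad_fraction: float = 0.20
    clad_mean_size: int = 1_000_000
    n_elads: int = 16
    elad_mean_size: int = 340_000
    elad_size_cv: float = 0.5
    # planted domains keep this much clear space between them so the
    # gap-chaining definition (default max_gap 100 kb) can tell them
    # apart even when a single boundary site lands mid-gap
    elad_min_separation: int = 220_000
    conditions: tuple[str, ...] = ("untreated", "tgfb_8h", "tgfb_24h")
    retention: float = 0.28
    compartment_block_range: tuple[int, int] = (1_000_000, 2_200_000)
    tad_size_range: tuple[int, int] = (400_000, 1_200_000)
    n_compartment_flips: int = 2
    boundary_keep: float = 0.8
    de_fraction: float = 0.3
    block_unit: int = BLOCK_UNIT

    def __post_init__(self):
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < 0 or self.n_elads < 0:
            raise ValueError("counts must be non-negative")
        for _, length in self.chromosomes:
            elad_bp = self.n_elads * self.elad_mean_size / max(len(self.chromosomes), 1)
            if self.clad_fraction + elad_bp / length > 1:
                raise PackingError(
                    "cLAD fraction plus planted eLAD fraction exceeds chromosome size"
                )


def _subtract(regions, occupied):
    """Free sub-runs of ``regions`` after removing ``occupied`` intervals."""
    free = []
    occ = sorted(tuple(iv) for iv in occupied)
    for s0, e0 in regions:
        pos = s0
        for s, e in occ:
            if e <= pos or s >= e0:
                continue
            if s > pos:
                free.append((pos, min(s, e0)))
            pos = max(pos, e)
            if pos >= e0:
                break
        if pos < e0:
            free.append((pos, e0))
    return free


def _place_nonoverlapping(rng, sizes, length, forbidden, allowed=None, margin=0):
    """Place intervals of the given sizes without overlap, avoiding
    ``forbidden`` and staying inside ``allowed`` regions (whole genome if
    None).  Each start is drawn uniformly over all feasible positions in
    the remaining free runs; larger domains are placed first to limit
    fragmentation, and truly impossible packings raise rather than
    silently truncating."""
    placed: list[tuple[int, int]] = []
    occupied = [tuple(iv) for iv in forbidden]
    base = [tuple(iv) for iv in allowed] if allowed is not None else [(0, length)]
    for size in sorted((int(s) for s in sizes), reverse=True):
        grown = [(s - margin, e + margin) for s, e in occupied]
        free = [iv for iv in _subtract(base, grown) if iv[1] - iv[0] >= size]
        if not free:
            raise PackingError(f"no free run can hold a {size}-bp domain")
        weights = np.array([e - s - size + 1 for s, e in free], dtype=float)
        run = free[rng.choice(len(free), p=weights / weights.sum())]
        start = int(rng.integers(run[0], run[1] - size + 1))
        placed.append((start, start + size))
        occupied.append((start, start + size))
    placed.sort()
    return placed


def _place_weighted(rng, sizes, length, forbidden, preferred, margin=0, w_pref=3.0):
    """Place non-overlapping domains with start positions weighted
    ``w_pref``:1 towards ``preferred`` regions (the condition's A
    compartment), anywhere else allowed.  Same margin/failure semantics
    as :func:`_place_nonoverlapping`."""
    placed: list[tuple[int, int]] = []
    occupied = [tuple(iv) for iv in forbidden]
    pref = sorted(tuple(iv) for iv in preferred)
    for size in sorted((int(s) for s in sizes), reverse=True):
        grown = [(s - margin, e + margin) for s, e in occupied]
        free = [iv for iv in _subtract([(0, length)], grown) if iv[1] - iv[0] >= size]
        if not free:
            raise PackingError(f"no free run can hold a {size}-bp domain")
        # candidate start segments, split at preferred-region boundaries
        segments: list[tuple[int, int, float]] = []
        for s, e in free:
            cuts = sorted({s, e - size + 1}
                          | {p for ps, pe in pref for p in (ps, pe)
                             if s < p < e - size + 1})
            for a, b in zip(cuts, cuts[1:]):
                in_pref = any(ps <= a < pe for ps, pe in pref)
                segments.append((a, b, (w_pref if in_pref else 1.0) * (b - a)))
        w = np.array([seg[2] for seg in segments])
        a, b, _ = segments[rng.choice(len(segments), p=w / w.sum())]
        start = int(rng.integers(a, b))
        placed.append((start, start + size))
        occupied.append((start, start + size))
    placed.sort()
    return placed


def _domain_sizes(rng, n, mean, cv):
    if n == 0:
        return np.empty(0, dtype=np.int64)
    shape = 1.0 / cv**2
    sizes = rng.gamma(shape, mean / shape, size=n)
    return np.maximum(sizes.astype(np.int64), 20_000)


def simulate_genome(config: SimulationConfig, seed: int):
    """Build a :class:`GenomeModel` plus its :class:`SyntheticTruth`.

    Construction order per chromosome: compartment checkerboard → cLADs
    (inside B blocks) → per-condition planted eLADs (weighted towards
    that condition's A blocks, clear of cLADs, mutually separated) →
    genes (weighted towards eLADs, away from cLADs) → TAD boundaries →
    gene lamin status and DE sets.
    """
    rng = np.random.default_rng(seed)
    conds = list(config.conditions)
    unit = config.block_unit
    clads: dict[str, np.ndarray] = {}
    elads: dict[str, dict[str, np.ndarray]] = {c: {} for c in conds}
    blocks: dict[str, dict[str, list[tuple[int, int, str]]]] = {c: {} for c in conds}
    bounds: dict[str, dict[str, np.ndarray]] = {c: {} for c in conds}
    genes: list[Gene] = []

    n_chrom = len(config.chromosomes)
    for ci, (chrom, length) in enumerate(config.chromosomes):
        aligned = (length // unit) * unit
        # -- compartment checkerboard (block edges on the 200-kb unit grid)
        lo, hi = config.compartment_block_range
        choices = np.arange(max(lo // unit, 1), hi // unit + 1) * unit
        edges = [0]
        while edges[-1] < aligned:
            edges.append(min(edges[-1] + int(rng.choice(choices)), aligned))
        start_a = bool(rng.integers(2))
        base_blocks = [
            (edges[i], edges[i + 1], "A" if (i % 2 == 0) == start_a else "B")
            for i in range(len(edges) - 1)
        ]
        # progressive per-condition flips relative to the base labels
        flip_order = rng.permutation(len(base_blocks))
        cond_blocks = {conds[0]: base_blocks}
        for t, cond in enumerate(conds[1:], start=1):
            flipped = set(flip_order[: t * config.n_compartment_flips].tolist())
            cond_blocks[cond] = [
                (s, e, ("B" if lab == "A" else "A") if i in flipped else lab)
                for i, (s, e, lab) in enumerate(base_blocks)
            ]
        for cond in conds:
            blocks[cond][chrom] = cond_blocks[cond]

        def regions(cond, want):
            return [(s, e) for s, e, lab in cond_blocks[cond] if lab == want]

        # -- cLADs: gene-poor heterochromatin inside B blocks
        n_clads = max(int(round(config.clad_fraction * length / config.clad_mean_size)), 0)
        clad_sizes = _domain_sizes(rng, n_clads, config.clad_mean_size, 0.3)
        b_space = regions(conds[0], "B")
        clad_list = _place_nonoverlapping(rng, clad_sizes, length, [], allowed=b_space)
        clads[chrom] = merge_intervals(clad_list) if clad_list else np.empty((0, 2), np.int64)

        # -- planted eLADs: per condition, inside that condition's A blocks,
        #    partially retained from the base condition
        n_here = config.n_elads // n_chrom + (1 if ci < config.n_elads % n_chrom else 0)
        base_sizes = _domain_sizes(rng, n_here, config.elad_mean_size, config.elad_size_cv)
        base = _place_weighted(
            rng, base_sizes, length, clad_list, regions(conds[0], "A"),
            margin=config.elad_min_separation,
        )
        elads[conds[0]][chrom] = np.asarray(base, np.int64).reshape(-1, 2)
        for cond in conds[1:]:
            keep = [iv for iv in base if rng.random() < config.retention]
            n_new = n_here - len(keep)
            new_sizes = _domain_sizes(rng, n_new, config.elad_mean_size, config.elad_size_cv)
            forbidden = list(clad_list) + keep
            new = _place_weighted(
                rng, new_sizes, length, forbidden, regions(cond, "A"),
                margin=config.elad_min_separation,
            )
            alld = sorted(keep + new)
            elads[cond][chrom] = np.asarray(alld, np.int64).reshape(-1, 2)

        # -- genes, weighted towards the eLAD union and away from cLADs
        n_genes_here = config.n_genes // n_chrom + (1 if ci < config.n_genes % n_chrom else 0)
        union = merge_intervals(np.vstack([elads[c][chrom] for c in conds]))
        gene_ivs: list[tuple[int, int]] = []
        tries = 0
        while len(gene_ivs) < n_genes_here and tries < 200 * n_genes_here:
            tries += 1
            glen = max(int(rng.lognormal(np.log(config.gene_mean_length), 0.6)), 1000)
            if glen >= length:
                continue
            start = int(rng.integers(0, length - glen))
            mid = start + glen // 2
            in_clad = any(s <= mid < e for s, e in clads[chrom])
            in_elad = any(s <= mid < e for s, e in union)
            w = 0.1 if in_clad else (3.0 if in_elad else 1.0)
            if rng.random() > w / 3.0:
                continue
            if any(start < e and start + glen > s for s, e in gene_ivs):
                continue
            gene_ivs.append((start, start + glen))
        if len(gene_ivs) < n_genes_here:
            raise PackingError(f"could not place {n_genes_here} genes on {chrom}")
        gene_ivs.sort()
        for k, (s, e) in enumerate(gene_ivs):
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{chrom}_{k:04d}"
            genes.append(Gene(gid, chrom, s, e, strand, s if strand == "+" else e - 1))

        # -- TAD boundaries on the unit grid.  Compartment block edges are
        # always boundaries (TADs nest within compartments, so an A/B
        # transition is also an insulation break); additional boundaries
        # fill in the blocks and are only partially conserved between
        # conditions.
        lo_t, hi_t = config.tad_size_range
        t_choices = np.arange(max(lo_t // unit, 1), hi_t // unit + 1) * unit
        comp_edges = [e for e in edges[1:-1]]
        fillers = []
        for bs, be, _ in base_blocks:
            pos = bs
            while True:
                pos += int(rng.choice(t_choices))
                if pos > be - lo_t:  # keep every TAD at least lo_t wide
                    break
                fillers.append(pos)
        bounds[conds[0]][chrom] = np.asarray(sorted(comp_edges + fillers), np.int64)
        for cond in conds[1:]:
            kept = [b for b in fillers if rng.random() < config.boundary_keep]
            bounds[cond][chrom] = np.asarray(sorted(comp_edges + kept), np.int64)

    genome = GenomeModel(list(config.chromosomes), genes, clads)
    status = {
        cond: {
            g.id: any(
                s <= g.tss < e for s, e in elads[cond].get(g.chrom, ())
            )
            for g in genes
        }
        for cond in conds
    }
    de: dict[str, set] = {}
    for cond in conds[1:]:
        picked = set()
        for g in genes:
            p = 0.5 if status[cond][g.id] != status[conds[0]][g.id] else 0.25
            p *= config.de_fraction / 0.3
            if rng.random() < min(p, 1.0):
                picked.add(g.id)
        de[cond] = picked
    truth = SyntheticTruth(
        conditions=conds,
        planted_elads=elads,
        compartment_blocks=blocks,
        tad_boundaries=bounds,
        gene_lamin_status=status,
        de_genes=de,
        block_unit=unit,
    )
    return genome, truth


def _site_coverage(domains: np.ndarray, length: int, bin_size: int,
                   site_block: int, site_gap: int) -> np.ndarray:
    """Fraction of each bin covered by punctate site blocks tiled through
    the planted domains (``site_block`` bp on / ``site_gap`` bp off)."""
    n = -(-length // bin_size)
    cov = np.zeros(n)
    period = site_block + site_gap
    for s, e in domains:
        pos = int(s)
        while pos < e:
            b_end = min(pos + site_block, int(e))
            first, last = pos // bin_size, (b_end - 1) // bin_size
            for b in range(first, min(last + 1, n)):
                lo = max(pos, b * bin_size)
                hi = min(b_end, (b + 1) * bin_size)
                cov[b] += max(hi - lo, 0) / bin_size
            pos += period
    return np.minimum(cov, 1.0)


def simulate_chip_tracks(
    genome: GenomeModel,
    truth: SyntheticTruth,
    condition: str,
    depth: int = 1_000_000,
    enrichment: float = 4.0,
    bin_size: int = 1000,
    seed: int = 0,
    site_block: int = 6000,
    site_gap: int = 1000,
    tss_bump: float = 0.5,
    border_site_fraction: float = 0.5,
    overdispersion: float | None = None,
    mappability: dict[str, np.ndarray] | None = None,
):
    """Poisson ChIP and IgG-control tracks for one condition.

    The per-bin ChIP rate is uniform background times a multiplier that
    equals ``m = (enrichment-1)/f + 1`` inside site blocks (where
    ``f = site_block/(site_block+site_gap)`` is their coverage of a
    planted domain) so that the *mean* signal inside planted eLADs is
    ``enrichment``-fold the outside mean.  Lamin-positive TSSs get an
    additive bump and a fraction of TAD boundaries carry a border site;
    both scale with ``enrichment - 1`` so ``enrichment=1`` is an exact
    null (ChIP rate ≡ control rate).  Totals are scaled to ``depth``.
    """
    from .signal import SignalTrack

    if enrichment < 1:
        raise ValueError("enrichment must be ≥ 1")
    rng = np.random.default_rng(seed)
    if depth == 0:
        warnings.warn("depth is 0: returning all-zero tracks")
        zeros = {
            c: np.zeros(-(-l // bin_size)) for c, l in genome.chromosomes
        }
        z = SignalTrack(bin_size, {k: v.copy() for k, v in zeros.items()})
        return z, SignalTrack(bin_size, zeros)

    f = site_block / (site_block + site_gap)
    m = (enrichment - 1.0) / f + 1.0
    mult: dict[str, np.ndarray] = {}
    base: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        n = -(-length // bin_size)
        cov = _site_coverage(
            truth.planted_elads[condition].get(chrom, np.empty((0, 2), np.int64)),
            length, bin_size, site_block, site_gap,
        )
        mu = 1.0 + cov * (m - 1.0)
        for g in genome.genes_on(chrom):
            if truth.gene_lamin_status[condition][g.id]:
                lo = max((g.tss - 1000) // bin_size, 0)
                hi = min((g.tss + 1000 - 1) // bin_size + 1, n)
                mu[lo:hi] += (enrichment - 1.0) * tss_bump
        for b in truth.tad_boundaries[condition].get(chrom, ()):
            if rng.random() < border_site_fraction:
                lo = max((int(b) - 2000) // bin_size, 0)
                hi = min((int(b) + 2000 - 1) // bin_size + 1, n)
                mu[lo:hi] = np.maximum(mu[lo:hi], m)
        w = np.ones(n)
        if mappability is not None and chrom in mappability:
            w = np.asarray(mappability[chrom], dtype=float)
            if len(w) != n:
                raise ValueError("mappability grid mismatch")
        mult[chrom] = mu * w
        base[chrom] = w

    tot_mu = sum(v.sum() for v in mult.values())
    tot_w = sum(v.sum() for v in base.values())
    chip_data, ctrl_data = {}, {}
    for chrom, _ in genome.chromosomes:
        lam_chip = mult[chrom] / tot_mu * depth
        lam_ctrl = base[chrom] / tot_w * depth
        if overdispersion:
            lam_chip = rng.gamma(1.0 / overdispersion, overdispersion * lam_chip)
            lam_ctrl = rng.gamma(1.0 / overdispersion, overdispersion * lam_ctrl)
        chip_data[chrom] = rng.poisson(lam_chip).astype(float)
        ctrl_data[chrom] = rng.poisson(lam_ctrl).astype(float)
    return SignalTrack(bin_size, chip_data), SignalTrack(bin_size, ctrl_data)


def simulate_expression(
    genome: GenomeModel,
    truth: SyntheticTruth,
    seed: int = 0,
    base_log_fpkm: float = 0.0,
    shift: float = 2.0,
    sigma: float = 1.0,
    silent_fraction: float = 0.2,
) -> pd.DataFrame:
    """Log-normal FPKM table, one ``fpkm_<condition>`` column per condition.

    Lamin-positive genes get a ``shift`` higher log-location; a random
    ``silent_fraction`` of genes is set to exactly 0 per condition.
    """
    rng = np.random.default_rng(seed)
    ids = [g.id for g in genome.genes]
    out = {}
    for cond in truth.conditions:
        status = np.array([truth.gene_lamin_status[cond][i] for i in ids])
        loc = base_log_fpkm + shift * status.astype(float)
        vals = np.exp(rng.normal(loc, sigma))
        silent = rng.random(len(ids)) < silent_fraction
        vals[silent] = 0.0
        out[f"fpkm_{cond}"] = vals
    return pd.DataFrame(out, index=pd.Index(ids, name="gene_id"))


def simulate_hic(
    genome: GenomeModel,
    truth: SyntheticTruth,
    condition: str,
    resolution: int,
    seed: int = 0,
    chrom: str | None = None,
    compartment_strength: float = 1.6,
    tad_strength: float = 2.0,
    total_reads: int = 1_000_000,
    alpha: float = 1.0,
    noise: bool = True,
    visibility_sd: float = 0.2,
    dropout_fraction: float = 0.02,
):
    """Cis contact matrix: power-law decay × compartment × TAD factors.

    ``expected[i, j] = (1+|i-j|)^-alpha``, multiplied by
    ``compartment_strength`` when bins share an A/B label and by
    ``tad_strength`` when they fall in the same TAD, scaled to
    ``total_reads`` and Poisson-sampled symmetrically (``noise=False``
    returns the expected matrix itself, the noise-free limit).

    When ``noise`` is on, each bin also gets a multiplicative
    "visibility" (log-normal, sd ``visibility_sd``) and a
    ``dropout_fraction`` of bins are near-invisible — the coverage
    heterogeneity real maps show, which matrix balancing removes and the
    low-marginal mask is meant to catch.
    """
    from .hic import ContactMatrix

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    chrom = chrom or genome.chromosomes[0][0]
    labels = truth.compartment_labels(condition, chrom, resolution)  # may raise
    bbins = truth.boundary_bins(condition, chrom, resolution)
    n = len(labels)
    rng = np.random.default_rng(seed)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    expected = (1.0 + d) ** (-alpha)
    same = labels[:, None] == labels[None, :]
    expected *= np.where(same, compartment_strength, 1.0)
    tad_id = np.searchsorted(bbins, np.arange(n), side="right")
    expected *= np.where(tad_id[:, None] == tad_id[None, :], tad_strength, 1.0)
    expected *= total_reads / expected.sum()
    if not noise:
        mat = expected
    else:
        vis = rng.lognormal(0.0, visibility_sd, n)
        drop = rng.random(n) < dropout_fraction
        vis[drop] *= 0.05
        lam = expected * np.outer(vis, vis)
        lam *= total_reads / lam.sum()
        upper = rng.poisson(np.triu(lam)).astype(float)
        mat = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution, matrix=mat)


def simulate_sequence(
    genome: GenomeModel,
    truth: SyntheticTruth,
    seed: int = 0,
    condition: str | None = None,
    gc_background: float = 0.42,
    gc_elad: float = 0.55,
    gc_clad: float = 0.35,
) -> dict[str, str]:
    """Random genome sequence: CG-rich inside planted eLADs, AT-rich in
    cLADs — the composition contrast seen between eLADs and cLADs."""
    rng = np.random.default_rng(seed)
    condition = condition or truth.conditions[0]
    seqs = {}
    for chrom, length in genome.chromosomes:
        gc = np.full(length, gc_background)
        for s, e in truth.planted_elads[condition].get(chrom, ()):
            gc[s:e] = gc_elad
        for s, e in genome.clads.get(chrom, ()):
            gc[s:e] = gc_clad
        u = rng.random(length)
        is_gc = u < gc
        u2 = rng.random(length)
        letters = np.where(is_gc, np.where(u2 < 0.5, "G", "C"),
                           np.where(u2 < 0.5, "A", "T"))
        seqs[chrom] = letters.astype("S1").tobytes().decode("ascii")
    return seqs
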