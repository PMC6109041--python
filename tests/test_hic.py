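"""Matrix balancing, compartment PC1, insulation, borders, occupancy."""

import numpy as np
import pytest

from eladkit.hic import (
    ContactMatrix,
    TadPartition,
    balance_matrix,
    border_peak_occupancy,
    call_borders,
    classify_bin_changes,
    compartment_pc1,
    insulation,
    match_borders,
)
from eladkit.signal import Peak, PeakSet
from eladkit.simulate import simulate_hic


def _sym(rng, n, scale=50.0):
    a = rng.uniform(1, scale, (n, n))
    return (a + a.T) / 2


class TestBalance:
    def test_uniform_matrix_is_fixed_point(self):
        m = ContactMatrix("chr1", 1000, np.full((30, 30), 4.0))
        b = balance_matrix(m, mask_percentile=0)
        live = ~b.mask
        assert np.allclose(b.matrix[np.ix_(live, live)], 4.0, rtol=1e-5)

    def test_row_sums_equalize(self, rng):
        m = ContactMatrix("chr1", 1000, _sym(rng, 50))
        b = balance_matrix(m, tol=1e-8)
        live = ~b.mask
        sums = b.matrix[np.ix_(live, live)].sum(axis=1)
        assert np.abs(sums / sums.mean() - 1).max() < 1e-6
        assert np.allclose(b.matrix, b.matrix.T)

    def test_zero_row_is_masked(self, rng):
        mat = _sym(rng, 20)
        mat[5, :] = 0
        mat[:, 5] = 0
        b = balance_matrix(ContactMatrix("chr1", 1000, mat))
        assert b.mask[5]

    def test_asymmetric_rejected(self):
        mat = np.ones((5, 5))
        mat[0, 1] = 3
        with pytest.raises(ValueError):
            ContactMatrix("chr1", 1000, mat)


def _checkerboard_expected(labels, boost=2.0, n_reads=1e6):
    n = len(labels)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = (1.0 + d) ** -1.0
    same = labels[:, None] == labels[None, :]
    exp = exp * np.where(same, boost, 1.0)
    return exp * (n_reads / exp.sum())


class TestCompartments:
    labels = np.array(list("AAAAABBBBBAAAAABBBBB") * 2)

    def test_noise_free_checkerboard_recovered_exactly(self):
        m = ContactMatrix("chr1", 100_000, _checkerboard_expected(self.labels))
        dens = (self.labels == "A").astype(float)  # A bins gene-dense
        prof = compartment_pc1(balance_matrix(m, mask_percentile=0), dens)
        ok = ~np.isnan(prof.pc1)
        assert np.array_equal(prof.labels[ok], self.labels[ok])

    def test_orientation_covariate_flip_flips_labels(self):
        m = ContactMatrix("chr1", 100_000, _checkerboard_expected(self.labels))
        dens = (self.labels == "A").astype(float)
        p1 = compartment_pc1(balance_matrix(m, mask_percentile=0), dens)
        p2 = compartment_pc1(balance_matrix(m, mask_percentile=0), 1.0 - dens)
        ok = ~np.isnan(p1.pc1)
        assert np.all((p1.labels[ok] == "A") == (p2.labels[ok] == "B"))

    def test_recovery_on_simulated_matrix(self, world):
        genome, truth = world
        m = simulate_hic(genome, truth, "untreated", 100_000, seed=2)
        dens = genome.gene_density("chr1", 100_000)[: m.n_bins]
        prof = compartment_pc1(balance_matrix(m), dens)
        planted = truth.compartment_labels("untreated", "chr1", 100_000)
        ok = ~np.isnan(prof.pc1)
        assert np.mean(prof.labels[ok] == planted[ok]) >= 0.95


class TestBinChanges:
    def _profile(self, pc1):
        from eladkit.hic import CompartmentProfile

        pc1 = np.asarray(pc1, float)
        labels = np.where(np.isnan(pc1), "",
                          np.where(pc1 > 0, "A", "B")).astype("U1")
        return CompartmentProfile("chr1", 100_000, pc1, labels)

    def test_identical_profiles_all_stable(self):
        p = self._profile([0.5, -0.5, 0.3])
        _, counts = classify_bin_changes(p, p)
        assert counts == {"AtoB": 0, "BtoA": 0}

    def test_single_flip(self):
        p1 = self._profile([0.5, -0.5, 0.3])
        p2 = self._profile([-0.5, -0.5, 0.3])
        calls, counts = classify_bin_changes(p1, p2)
        assert counts == {"AtoB": 1, "BtoA": 0}
        assert calls[0] == "AtoB"

    def test_random_vectors_match_elementwise_oracle(self, rng):
        v1 = rng.normal(size=30)
        v2 = rng.normal(size=30)
        p1, p2 = self._profile(v1), self._profile(v2)
        calls, counts = classify_bin_changes(p1, p2)
        exp_ab = int(np.sum((v1 > 0) & (v2 < 0)))
        exp_ba = int(np.sum((v1 < 0) & (v2 > 0)))
        assert counts == {"AtoB": exp_ab, "BtoA": exp_ba}

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError):
            classify_bin_changes(self._profile([0.1] * 5), self._profile([0.1] * 6))


class TestInsulation:
    def test_uniform_matrix_scores_zero(self):
        m = balance_matrix(ContactMatrix("chr1", 1000, np.full((40, 40), 5.0)),
                           mask_percentile=0)
        ins = insulation(m, window=5)
        valid = ~np.isnan(ins)
        assert np.allclose(ins[valid], 0.0, atol=1e-9)
        assert np.isnan(ins[:5]).all() and np.isnan(ins[-5:]).all()

    def test_two_block_matrix_minimum_at_boundary(self):
        mat = np.full((20, 20), 1e-3)
        mat[:10, :10] = 10.0
        mat[10:, 10:] = 10.0
        m = ContactMatrix("chr1", 1000, mat, balanced=True)
        ins = insulation(m, window=3)
        valid_bins = np.flatnonzero(~np.isnan(ins))
        assert ins[valid_bins].argmin() + valid_bins[0] in (9, 10)


class TestBorders:
    def test_monotone_vector_has_no_borders(self):
        part = call_borders(np.linspace(0, -2, 30), 0.5)
        assert part.borders == []

    def test_single_minimum_gets_strength_ten(self):
        v = np.zeros(30)
        v[14] = -2.0
        part = call_borders(v, 0.5)
        assert [b for b, _ in part.borders] == [14]
        assert part.borders[0][1] == 10.0

    def test_recovery_and_strength_monotonicity(self, world):
        genome, truth = world
        proms = []
        for strength in (1.5, 2.0, 3.0):
            m = simulate_hic(genome, truth, "untreated", 40_000, seed=6,
                             tad_strength=strength)
            ins = insulation(balance_matrix(m), 5)
            part = call_borders(ins, 0.5, "chr1", 40_000)
            called = part.border_bins()
            planted = truth.boundary_bins("untreated", "chr1", 40_000)
            recall = np.mean([np.abs(called - b).min() <= 1 for b in planted])
            precision = np.mean([np.abs(planted - b).min() <= 1 for b in called])
            if strength == 2.0:
                assert recall >= 0.9 and precision >= 0.9
            hit = [max(p for b, p in zip(called, part.prominences)
                       if abs(b - t) <= 1)
                   for t in planted if np.abs(called - t).min() <= 1]
            proms.append(np.mean(hit))
        assert proms[0] < proms[1] < proms[2]


class TestMatchBorders:
    def _part(self, bins):
        n = (max(bins) + 5) if bins else 10
        ins = np.zeros(n)
        return TadPartition("chr1", 40_000, ins,
                            [(b, 5.0) for b in sorted(bins)])

    def test_identical_partitions_fully_conserved(self):
        parts = [self._part([5, 15, 25]) for _ in range(3)]
        _, frac, _ = match_borders(parts, tol=2)
        assert frac == 1.0

    def test_shifted_beyond_tolerance_not_conserved(self):
        parts = [self._part([5, 15, 25]), self._part([8, 18, 28])]
        _, frac, _ = match_borders(parts, tol=2)
        assert frac == 0.0

    def test_random_sets_match_greedy_oracle(self, rng):
        for _ in range(10):
            sets = [sorted(rng.choice(100, rng.integers(3, 12), replace=False))
                    for _ in range(3)]
            parts = [self._part(list(s)) for s in sets]
            conserved, frac, clusters = match_borders(parts, tol=2)
            # independent re-derivation of the greedy seed clustering
            pooled = sorted((b, ci) for ci, s in enumerate(sets) for b in s)
            oracle_clusters = []
            remaining = list(pooled)
            while remaining:
                seed_b, _ = remaining[0]
                cluster = [x for x in remaining if x[0] - seed_b <= 2]
                oracle_clusters.append(cluster)
                remaining = [x for x in remaining if x not in cluster]
            n_cons = sum(1 for c in oracle_clusters
                         if {ci for _, ci in c} == {0, 1, 2})
            assert len(clusters) == len(oracle_clusters)
            assert len(conserved) == n_cons


class TestOccupancy:
    def _part(self):
        return TadPartition("chr1", 40_000, np.zeros(100),
                            [(10, 5.0), (50, 7.0), (90, 3.0)])

    def test_no_peaks_all_zero(self):
        counts, hist = border_peak_occupancy(self._part(), PeakSet("c", []))
        assert counts == [0, 0, 0]
        assert hist == {"0": 3, "1": 0, "2": 0, ">=3": 0}

    def test_single_peak_in_one_border(self):
        peaks = PeakSet("c", [Peak("chr1", 10 * 40_000, 10 * 40_000 + 500, 1, 2)])
        counts, hist = border_peak_occupancy(self._part(), peaks)
        assert counts == [1, 0, 0]
        assert hist["1"] == 1

    def test_random_peaks_match_quadratic_oracle(self, rng):
        part = self._part()
        starts = np.sort(rng.choice(np.arange(0, 3_990_000, 7000), 60,
                                    replace=False))
        peaks = PeakSet("c", [Peak("chr1", int(s), int(s) + 5000, 1, 2)
                              for s in starts])
        counts, _ = border_peak_occupancy(part, peaks, border_span=1)
        for (b, _), got in zip(part.borders, counts):
            lo, hi = (b - 1) * 40_000, (b + 2) * 40_000
            expected = sum(1 for s in starts if s < hi and s + 5000 > lo)
            assert got == expected
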