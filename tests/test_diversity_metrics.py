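import itertools

import numpy as np
import pytest

from upcycle import diversity_metrics as dm
from upcycle import genome_sim as gs


def _flat_map(n_loci, length=100.0, n_chrom=1):
    per = n_loci // n_chrom
    chrom = np.repeat(np.arange(n_chrom, dtype=np.int32), per)
    cm = np.tile(np.linspace(0.0, length, per), n_chrom)
    return gs.GeneticMap(chrom, cm, np.ones(chrom.size, bool), np.zeros(chrom.size, bool), n_chrom, length)


class TestWindows:
    def test_window_scheme_validation(self):
        with pytest.raises(ValueError):
            dm.WindowScheme(window_snps=0)
        with pytest.raises(ValueError):
            dm.WindowScheme(step_fraction=0.0)
        assert dm.WindowScheme().step_snps == 9  # round(0.2 * 44)

    def test_windows_stay_within_chromosomes(self):
        gmap = _flat_map(200, n_chrom=2)
        wins = dm.build_windows(gmap, dm.WindowScheme(window_snps=44, step_fraction=0.2))
        for w in wins:
            assert len(np.unique(gmap.chrom[w])) == 1

    def test_direct_sum_example(self):
        gmap = _flat_map(2)
        vals = dm.window_haplotype_ebvs(np.array([[1, 1]]), gmap, np.array([1.0, -1.0]), dm.WindowScheme(2, 1.0))
        assert vals[0, 0] == 0.0

    def test_zero_effects(self):
        gmap = _flat_map(88)
        haps = np.random.default_rng(0).integers(0, 2, (5, 88))
        vals = dm.window_haplotype_ebvs(haps, gmap, np.zeros(88), dm.WindowScheme())
        assert np.allclose(vals, 0.0)

    def test_tiling_windows_sum_to_genome_score(self, rng):
        gmap = _flat_map(120, n_chrom=2)
        haps = rng.integers(0, 2, (7, 120))
        eff = rng.standard_normal(120)
        scheme = dm.WindowScheme(window_snps=20, step_fraction=1.0)  # non-overlapping tiling
        vals = dm.window_haplotype_ebvs(haps, gmap, eff, scheme)
        assert np.allclose(vals.sum(axis=1), haps @ eff)


class TestBeneficialDonors:
    def _toy(self, rng, n_cand=4, n_elite=3, L=60):
        gmap = _flat_map(L)
        cand = rng.integers(0, 2, (n_cand, 2, L)).astype(np.uint8)
        elite = rng.integers(0, 2, (n_elite * 2, L)).astype(np.uint8)
        eff = rng.standard_normal(L)
        return gmap, cand, elite, eff

    def test_dominated_candidate_gains_zero(self, rng):
        gmap = _flat_map(40)
        elite = np.ones((2, 40), np.uint8)
        cand = np.zeros((1, 2, 40), np.uint8)
        eff = np.abs(rng.standard_normal(40))  # all-ones elite dominates
        chosen, gains = dm.select_donors_beneficial(cand, [7], [0], elite, eff, gmap, dm.WindowScheme(10, 1.0), 1)
        assert chosen == [7] and gains[0] == 0.0

    def test_single_improving_window(self):
        gmap = _flat_map(20)
        scheme = dm.WindowScheme(10, 1.0)  # two windows
        eff = np.ones(20)
        elite = np.zeros((2, 20), np.uint8)
        elite[:, :10] = 1  # elite max: window0 = 10, window1 = 0
        cand = np.zeros((2, 2, 20), np.uint8)
        cand[1, 0, 10:13] = 1  # candidate 11 improves window1 by 3
        chosen, gains = dm.select_donors_beneficial(cand, [10, 11], [0, 0], elite, eff, gmap, scheme, 1)
        assert chosen == [11] and gains[0] == pytest.approx(3.0)

    def test_greedy_matches_exhaustive_two_donors(self, rng):
        gmap, cand, elite, eff = self._toy(rng, n_cand=6)
        scheme = dm.WindowScheme(12, 0.5)
        wins = dm.build_windows(gmap, scheme)
        elite_vals = dm.window_haplotype_ebvs(elite, gmap, eff, windows=wins)
        cand_vals = dm.window_haplotype_ebvs(cand.reshape(12, -1), gmap, eff, windows=wins)
        cand_best = np.maximum(cand_vals[0::2], cand_vals[1::2])
        base = elite_vals.max(axis=0)

        def total(pair):
            return np.maximum(base, np.maximum(cand_best[pair[0]], cand_best[pair[1]])).sum()

        best_pair_score = max(total(p) for p in itertools.combinations(range(6), 2))
        chosen, gains = dm.select_donors_beneficial(cand, list(range(6)), [0] * 6, elite, eff, gmap, scheme, 2)
        assert base.sum() + sum(gains) == pytest.approx(best_pair_score)


class TestUniqueHaplotypes:
    def test_distinct_string_count(self):
        gmap = _flat_map(2, length=0.9)
        alleles = np.array([[[0, 0], [0, 1]], [[0, 1], [1, 1]]], np.uint8)
        panel = gs.HaplotypePanel(alleles, np.zeros_like(alleles, np.int32), np.arange(2))
        total, per = dm.count_unique_haplotypes(panel, gmap)
        assert total == 3

    def test_identical_haplotypes_one_per_segment(self, rng):
        gmap = _flat_map(50)
        hap = rng.integers(0, 2, 50).astype(np.uint8)
        alleles = np.broadcast_to(hap, (2, 4, 50)).copy()
        panel = gs.HaplotypePanel(alleles, np.zeros_like(alleles, np.int32), np.arange(4))
        total, per = dm.count_unique_haplotypes(panel, gmap, warn_empty=False)
        assert total == (per > 0).sum()
        assert set(per[per > 0]) == {1}

    def test_chip_count_never_exceeds_all_loci_count(self, rng):
        gmap = _flat_map(80)
        gmap.chip_mask[::2] = False  # chip = subset of loci
        alleles = rng.integers(0, 2, (2, 10, 80)).astype(np.uint8)
        panel = gs.HaplotypePanel(alleles, np.zeros_like(alleles, np.int32), np.arange(10))
        t_all, _ = dm.count_unique_haplotypes(panel, gmap, use_all_loci=True, warn_empty=False)
        t_chip, _ = dm.count_unique_haplotypes(panel, gmap, use_all_loci=False, warn_empty=False)
        assert t_chip <= t_all

    def test_adding_animal_never_decreases_count(self, rng):
        gmap = _flat_map(60)
        alleles = rng.integers(0, 2, (2, 8, 60)).astype(np.uint8)
        panel = gs.HaplotypePanel(alleles, np.zeros_like(alleles, np.int32), np.arange(8))
        t_small, _ = dm.count_unique_haplotypes(panel, gmap, rows=np.arange(5), warn_empty=False)
        t_large, _ = dm.count_unique_haplotypes(panel, gmap, rows=np.arange(6), warn_empty=False)
        assert t_large >= t_small

    def test_greedy_selection_and_oracle(self, rng):
        gmap = _flat_map(30)
        elite = rng.integers(0, 2, (6, 30)).astype(np.uint8)
        cand = rng.integers(0, 2, (5, 2, 30)).astype(np.uint8)
        cand[0] = elite[:2]  # candidate 0 adds nothing
        chosen, gains = dm.select_donors_unique(cand[:1], [3], [0], elite, gmap, 1)
        assert gains[0] == 0

        segs = [idx for _, _, idx in dm._segment_slices(gmap, gmap.chip_idx, 1.0) if idx.size]

        def added(subset):
            seen = [set(dm._hap_keys(elite, idx).tolist()) for idx in segs]
            g = 0
            for k in subset:
                for s, idx in enumerate(segs):
                    for h in range(2):
                        key = dm._hap_keys(cand[k][None, h], idx).tolist()[0]
                        if key not in seen[s]:
                            g += 1
                            seen[s].add(key)
            return g

        best = max(added(list(p)) for p in itertools.combinations(range(5), 2))
        chosen, gains = dm.select_donors_unique(cand, list(range(5)), [0] * 5, elite, gmap, 2)
        assert sum(gains) == best

    def test_novelty_ranking(self):
        gmap = _flat_map(4, length=0.5)  # single segment of 4 loci
        elite = np.zeros((4, 4), np.uint8)
        c_one = np.zeros((1, 2, 4), np.uint8); c_one[0, 0] = [1, 0, 0, 0]
        c_two = np.zeros((1, 2, 4), np.uint8)
        c_two[0, 0] = [1, 1, 0, 0]; c_two[0, 1] = [0, 1, 1, 0]
        cand = np.concatenate([c_one, c_two])
        chosen, gains = dm.select_donors_unique(cand, [1, 2], [0, 0], elite, gmap, 1)
        assert chosen == [2] and gains[0] == 2


class TestSegmentKinship:
    def _map_linspace(self, L=201, length=100.0):
        return _flat_map(L, length=length)

    def test_constructed_single_run(self):
        """One 10 cM identical run (21 SNPs) on one of four haplotype pairs of
        a 100 cM genome gives kinship 0.1/4 = 0.025."""
        gmap = self._map_linspace()
        rng = np.random.default_rng(5)
        b = rng.integers(0, 2, (1, 2, 201)).astype(np.uint8)
        a = (1 - b).astype(np.uint8)
        a[0, 0, 60:81] = b[0, 0, 60:81]  # exactly 10 cM, 21 SNPs
        spec = dm.SegmentKinshipSpec(4.0, 20)
        f = dm.segment_ibd_kinship_cross(a, b, gmap, spec)
        assert f[0, 0] == pytest.approx(0.025)

    def test_self_kinship_of_homozygote(self):
        gmap = self._map_linspace()
        hap = np.random.default_rng(0).integers(0, 2, 201).astype(np.uint8)
        a = np.stack([np.stack([hap, hap])])
        f = dm.segment_ibd_kinship(a, gmap)
        assert f[0, 0] == pytest.approx(1.0)

    def test_unrelated_animals_zero(self):
        gmap = self._map_linspace()
        a = np.zeros((1, 2, 201), np.uint8)
        b = np.tile(np.arange(201) % 2, (1, 2, 1)).astype(np.uint8)  # alternating
        f = dm.segment_ibd_kinship_cross(a, b, gmap)
        assert f[0, 0] == 0.0

    def test_matrix_symmetric_and_bounded(self, rng):
        gmap = self._map_linspace(101)
        haps = rng.integers(0, 2, (6, 2, 101)).astype(np.uint8)
        f = dm.segment_ibd_kinship(haps, gmap, dm.SegmentKinshipSpec(2.0, 3))
        assert np.allclose(f, f.T)
        assert f.min() >= 0.0 and f.max() <= 1.0 + 1e-12

    def test_numba_and_numpy_paths_agree(self, rng):
        gmap = _flat_map(150, n_chrom=3)
        a = rng.integers(0, 2, (5, 2, 150)).astype(np.uint8)
        b = rng.integers(0, 2, (4, 2, 150)).astype(np.uint8)
        a[0] = b[1]
        spec = dm.SegmentKinshipSpec(3.0, 4)
        f_np = dm.segment_ibd_kinship_cross(a, b, gmap, spec, use_numba=False)
        f_nb = dm.segment_ibd_kinship_cross(a, b, gmap, spec, use_numba=True)
        assert np.allclose(f_np, f_nb)

    def test_low_kinship_ranking(self, rng):
        gmap = self._map_linspace()
        elite = rng.integers(0, 2, (4, 2, 201)).astype(np.uint8)
        clone = elite[0][None]
        stranger = (1 - elite[0])[None] * 0 + np.tile(np.arange(201) % 2, (1, 2, 1)).astype(np.uint8)
        others = rng.integers(0, 2, (3, 2, 201)).astype(np.uint8)
        cand = np.concatenate([clone, stranger, others])
        f = dm.segment_ibd_kinship_cross(cand, elite, gmap)
        order = np.lexsort((np.arange(5), np.zeros(5), f.mean(1)))
        chosen, scores = dm.select_donors_low_kinship(cand, np.arange(5), np.zeros(5, int), elite, gmap, n_donors=5)
        assert chosen == [int(i) for i in np.arange(5)[order]]
        assert chosen[-1] == 0  # the clone ranks last
        assert scores[0] == pytest.approx(f.mean(1).min())

    def test_empty_elite_rejected(self, rng):
        gmap = self._map_linspace(51)
        cand = rng.integers(0, 2, (2, 2, 51)).astype(np.uint8)
        with pytest.raises(ValueError, match="empty elite"):
            dm.select_donors_low_kinship(cand, [0, 1], [0, 0], np.zeros((0, 2, 51), np.uint8), gmap)


class TestSummaryStatistics:
    def test_genic_variance_examples(self):
        assert dm.genic_variance([0.5], [1.0]) == pytest.approx(0.5)
        assert dm.genic_variance([0.0, 1.0], [2.0, 3.0]) == 0.0
        p = np.array([0.1, 0.3, 0.7])
        a = np.array([1.0, 2.0, 0.5])
        assert dm.genic_variance(p, a) == pytest.approx(dm.genic_variance(1 - p, a))
        with pytest.raises(ValueError):
            dm.genic_variance([0.5, 0.5], [1.0])

    def _trait_panel(self, freqs):
        L = len(freqs)
        gmap = _flat_map(L)
        gmap.qtl_mask[:] = True
        gmap.chip_mask[:] = False
        alleles = np.zeros((2, 4, L), np.uint8)
        for j, p in enumerate(freqs):
            k = int(round(p * 8))
            alleles.reshape(8, L)[:k, j] = 1
        panel = gs.HaplotypePanel(alleles, np.zeros_like(alleles, np.int32), np.arange(4))
        return gmap, panel

    def test_selection_limit(self):
        gmap, panel = self._trait_panel([0.5, 0.25, 0.0])
        trait = gs.TraitArchitecture(
            np.array([1.0, 2.0, 5.0]), np.ones(3, np.uint8), 0.3, 1.0, 1.0, gmap.qtl_idx
        )
        # QTL 3's beneficial allele is absent: limit = 2*1 + 2*2
        assert dm.selection_limit(panel, trait) == pytest.approx(6.0)
        assert dm.selection_limit(panel, trait) >= trait.tbv(panel).max()

    def test_true_ibd_founder_conventions(self):
        gmap = _flat_map(10)
        alleles = np.zeros((2, 2, 10), np.uint8)
        labels = np.arange(4, dtype=np.int32).reshape(2, 2)[:, :, None] * np.ones(10, np.int32)
        panel = gs.HaplotypePanel(alleles, labels, np.arange(2))
        f = dm.true_ibd_kinship(panel, gmap)
        assert f[0, 0] == pytest.approx(0.5)  # non-inbred founder self-kinship
        assert f[0, 1] == pytest.approx(0.0)  # distinct founders

    def test_full_sib_expectation(self, toy_map, rng):
        """Founder-IBD kinship of full sibs averages 0.25 over meioses."""
        L = toy_map.n_loci
        alleles = rng.integers(0, 2, (2, 2, L)).astype(np.uint8)
        labels = np.arange(4, dtype=np.int32).reshape(2, 2)[:, :, None] * np.ones(L, np.int32)
        vals = []
        for _ in range(300):
            # gametes 0,1 from the sire (row 0), 2,3 from the dam (row 1)
            _, gl = gs.gametes_batch(alleles, labels, np.array([0, 0, 1, 1]), toy_map, rng)
            sib_labels = np.stack([np.stack([gl[0], gl[1]]), np.stack([gl[2], gl[3]])])
            sibs = gs.HaplotypePanel(np.zeros((2, 2, L), np.uint8), sib_labels, np.arange(2))
            vals.append(dm.true_ibd_kinship(sibs, toy_map)[0, 1])
        assert np.mean(vals) == pytest.approx(0.25, abs=0.02)

    def test_mean_kinship_equals_matrix_mean(self, toy_map, rng):
        alleles = rng.integers(0, 2, (2, 5, toy_map.n_loci)).astype(np.uint8)
        labels = rng.integers(0, 6, (2, 5, 1)) * np.ones(toy_map.n_loci, np.int32)
        panel = gs.HaplotypePanel(alleles, labels.astype(np.int32), np.arange(5))
        f = dm.true_ibd_kinship(panel, toy_map)
        assert dm.mean_true_ibd_kinship(panel, toy_map) == pytest.approx(f.mean())

    def test_genic_variance_decays_under_drift(self, rng):
        gmap = _flat_map(60)
        eff = np.abs(rng.standard_normal(60))
        finals = []
        N = 20
        for _ in range(30):
            alleles = (rng.random((2, N, 60)) < 0.5).astype(np.uint8)
            labels = np.zeros_like(alleles, np.int32)
            v0 = dm.genic_variance(alleles.mean((0, 1)), eff)
            for _ in range(4):
                sires = rng.integers(0, N, N)
                dams = (sires + 1 + rng.integers(0, N - 1, N)) % N
                g1, _ = gs.gametes_batch(alleles, labels, sires, gmap, rng)
                g2, _ = gs.gametes_batch(alleles, labels, dams, gmap, rng)
                alleles = np.stack([g1, g2])
            finals.append(dm.genic_variance(alleles.mean((0, 1)), eff) / v0)
        assert np.mean(finals) < 1.0


class TestTheoryUtilities:
    def test_retention_examples(self):
        assert dm.allele_retention_probability(0.5, 1e6, 10, 1) == pytest.approx(1.0)
        assert dm.allele_retention_probability(0.05, 50, 1, 1) == pytest.approx(1 - 0.95 ** 100, rel=1e-6)
        # the printed formula gives ~0.069 for the 45-locus worked case
        assert dm.allele_retention_probability(0.05, 50, 10, 45) == pytest.approx(0.0694, abs=0.001)
        with pytest.raises(ValueError):
            dm.allele_retention_probability(0.0, 50, 1, 1)

    def test_backcross_kinship(self):
        assert dm.expected_backcross_kinship(0.15, 0.21, 4) == pytest.approx(0.20625)
        assert dm.expected_backcross_kinship(0.3, 0.3, 7) == pytest.approx(0.3)
        assert dm.expected_backcross_kinship(0.0, 0.4, 60) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            dm.expected_backcross_kinship(-0.1, 0.5, 2)

    def test_inbreeding_identities(self):
        assert dm.delta_f(50) == pytest.approx(0.01)
        assert dm.inbreeding_after(50, 1) == pytest.approx(0.01)
        assert dm.elite_genome_fraction(4) == pytest.approx(0.9375)
        assert dm.elite_genome_fraction(1) == pytest.approx(0.5)
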