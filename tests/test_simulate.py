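"""Gamete dropping, founder models, truth tracks and parent phasing."""

import numpy as np
import pytest
from scipy import stats

from lineorigin import (
    GeneticMap,
    SimConfig,
    default_marker_map,
    drop_gamete,
    phase_parent,
    read_truth,
    simulate_cross,
    write_truth,
)
from lineorigin.emission import transmissible_alleles
from lineorigin.simulate import write_phase
from tests.conftest import make_pedigree


class TestDropGamete:
    MAP = default_marker_map(200, 451.0)

    def test_zero_length_chromosome_never_recombines(self):
        gmap = GeneticMap(["m"], [0.0], length_cM=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert drop_gamete(np.zeros((2, 1), dtype=np.int8), gmap, rng).crossovers.size == 0

    def test_mean_crossovers_equals_length_in_morgans(self):
        # 451 cM chromosome: Poisson mean 4.51 per meiosis
        rng = np.random.default_rng(42)
        haps = np.zeros((2, 200), dtype=np.int8)
        counts = [drop_gamete(haps, self.MAP, rng).crossovers.size for _ in range(10_000)]
        se = np.sqrt(4.51 / 10_000)
        assert abs(np.mean(counts) - 4.51) < 3 * se

    def test_identical_haplotypes_transmit_unchanged(self):
        rng = np.random.default_rng(1)
        hap = rng.integers(0, 2, 200).astype(np.int8)
        g = drop_gamete(np.stack([hap, hap]), self.MAP, rng)
        np.testing.assert_array_equal(g.alleles, hap)

    def test_alleles_follow_crossover_track(self):
        rng = np.random.default_rng(2)
        haps = np.stack([np.zeros(200, dtype=np.int8), np.ones(200, dtype=np.int8)])
        g = drop_gamete(haps, self.MAP, rng)
        np.testing.assert_array_equal(g.alleles, g.haplotype_at(self.MAP.positions_cM))


class TestFounderModel:
    def test_degenerate_frequencies_make_every_marker_fully_informative(self):
        ped = make_pedigree(2)
        gmap = default_marker_map(50, 49.0)
        freqs = np.zeros((2, 50))
        freqs[1] = 1.0
        sim = simulate_cross(SimConfig(gmap=gmap, pedigree=ped, seed=3, allele_freqs=freqs))
        for f1 in ped.f1():
            gp1, gp2 = ped.grandparents_by_line(f1.id)
            for j in range(50):
                s1, s2 = transmissible_alleles(
                    int(sim.genotypes.row(f1.id)[j]),
                    int(sim.genotypes.row(gp1.id)[j]),
                    int(sim.genotypes.row(gp2.id)[j]),
                )
                assert s1 == frozenset({0}) and s2 == frozenset({1})

    def test_equal_frequencies_never_fully_informative(self):
        # identical degenerate frequencies in both lines: no line contrast
        ped = make_pedigree(2)
        gmap = default_marker_map(50, 49.0)
        freqs = np.ones((2, 50))
        sim = simulate_cross(SimConfig(gmap=gmap, pedigree=ped, seed=4, allele_freqs=freqs))
        f1 = ped.f1()[0]
        gp1, gp2 = ped.grandparents_by_line(f1.id)
        for j in range(50):
            s1, s2 = transmissible_alleles(
                int(sim.genotypes.row(f1.id)[j]),
                int(sim.genotypes.row(gp1.id)[j]),
                int(sim.genotypes.row(gp2.id)[j]),
            )
            assert s1 == s2  # both haplotypes carry allele 1: no contrast

    def test_fully_informative_fraction_matches_integration_oracle(self):
        # oracle: enumerate founder allele/transmission configurations and
        # integrate over the U(0,1) frequency in each line numerically
        from itertools import product

        nodes, weights = np.polynomial.legendre.leggauss(40)
        p_nodes = 0.5 * (nodes + 1)
        w = 0.5 * weights

        def informative_prob(p, q):
            total = 0.0
            for x1, x2, y1, y2, c1, c2 in product((0, 1), repeat=6):
                t1 = (x1, x2)[c1]  # allele transmitted by the line-1 founder
                t2 = (y1, y2)[c2]
                if t1 == t2:
                    continue  # F1 homozygous: sets equal
                if x1 != x2 and y1 != y2:
                    continue  # both founders het: phase unresolvable
                prob = (
                    (p if x1 else 1 - p) * (p if x2 else 1 - p)
                    * (q if y1 else 1 - q) * (q if y2 else 1 - q) * 0.25
                )
                total += prob
            return total

        expected = sum(
            wi * wj * informative_prob(pi, qj)
            for pi, wi in zip(p_nodes, w)
            for qj, wj in zip(p_nodes, w)
        )

        n = 20_000
        ped = make_pedigree(2)
        sim = simulate_cross(SimConfig(gmap=default_marker_map(n, 451.0), pedigree=ped, seed=5))
        f1 = ped.f1()[0]
        gp1, gp2 = ped.grandparents_by_line(f1.id)
        count = 0
        for j in range(n):
            s1, s2 = transmissible_alleles(
                int(sim.genotypes.row(f1.id)[j]),
                int(sim.genotypes.row(gp1.id)[j]),
                int(sim.genotypes.row(gp2.id)[j]),
            )
            if len(s1) == 1 and len(s2) == 1 and s1 != s2:
                count += 1
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(count / n - expected) < 4 * se


@pytest.fixture(scope="module")
def sim():
    return simulate_cross(
        SimConfig(gmap=default_marker_map(120, 119.0), pedigree=make_pedigree(30), seed=6)
    )


class TestSimulateCross:

    def test_seeded_determinism_is_byte_identical(self, sim, tmp_path):
        again = simulate_cross(sim.config)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        from lineorigin import write_genotypes

        write_genotypes(sim.genotypes, a)
        write_genotypes(again.genotypes, b)
        assert a.read_bytes() == b.read_bytes()
        ta, tb = tmp_path / "ta.tsv", tmp_path / "tb.tsv"
        write_truth(sim.truth, ta)
        write_truth(again.truth, tb)
        assert ta.read_bytes() == tb.read_bytes()

    def test_all_genotypes_mendelian_consistent(self, sim):
        ped = sim.config.pedigree
        for f2 in ped.f2():
            g = sim.genotypes.row(f2.id)
            gs = sim.genotypes.row(f2.sire)
            gd = sim.genotypes.row(f2.dam)
            for child, sire, dam in zip(g, gs, gd):
                child_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(child)]
                sire_all = {0: {0}, 1: {0, 1}, 2: {1}}[int(sire)]
                dam_all = {0: {0}, 1: {0, 1}, 2: {1}}[int(dam)]
                assert any(
                    a in dam_all and b in sire_all
                    for a, b in (child_alleles, child_alleles[::-1])
                )

    def test_truth_consistent_with_stored_crossovers(self, sim):
        rng = np.random.default_rng(8)
        queries = rng.uniform(0, sim.config.gmap.length_cM, 1000)
        for (ind, hap), entry in list(sim.truth.entries.items())[:10]:
            got = sim.truth.origin_at(ind, hap, queries)
            # independent re-derivation: parity of crossovers left of the query
            for q, o in zip(queries, got):
                flips = int((entry.crossovers < q).sum())
                expect = entry.start_line if flips % 2 == 0 else 3 - entry.start_line
                assert o == expect

    def test_truth_round_trip(self, sim, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(sim.truth, path)
        again = read_truth(path)
        assert set(again.entries) == set(sim.truth.entries)
        for key, entry in sim.truth.entries.items():
            assert again[key].start_line == entry.start_line
            np.testing.assert_allclose(again[key].crossovers, entry.crossovers, atol=1e-9)

    def test_genotype_matches_truth_and_phase(self, sim):
        # F2 allele = the allele its parent carries on the haplotype of the
        # true line origin, at every marker: genotype, truth and parental
        # phase must all agree
        ped = sim.config.pedigree
        pos = sim.config.gmap.positions_cM
        for f2 in ped.f2()[:5]:
            mat_origin = sim.truth.origin_at(f2.id, "maternal", pos)
            pat_origin = sim.truth.origin_at(f2.id, "paternal", pos)
            dam_phase = sim.parental_phase[f2.dam]
            sire_phase = sim.parental_phase[f2.sire]
            mat_allele = dam_phase[np.arange(pos.size), mat_origin - 1]
            pat_allele = sire_phase[np.arange(pos.size), pat_origin - 1]
            np.testing.assert_array_equal(mat_allele + pat_allele, sim.genotypes.row(f2.id))

    def test_error_and_missing_rates_apply(self):
        cfg = SimConfig(
            gmap=default_marker_map(200, 100.0),
            pedigree=make_pedigree(20),
            seed=9,
            missing_rate=0.1,
            error_rate=0.0,
        )
        sim = simulate_cross(cfg)
        frac = (sim.genotypes.codes == -1).mean()
        assert 0.05 < frac < 0.15


class TestDistributions:
    def test_crossover_positions_uniform(self):
        gmap = default_marker_map(10, 451.0)
        rng = np.random.default_rng(10)
        haps = np.zeros((2, 10), dtype=np.int8)
        pos = np.concatenate(
            [drop_gamete(haps, gmap, rng).crossovers for _ in range(3000)]
        )
        stat = stats.kstest(pos, "uniform", args=(0, 451.0))
        assert stat.pvalue > 1e-3


class TestPhaseParent:
    def test_homozygous_and_anchored_markers_resolve_in_step_one(self):
        ped = make_pedigree(20)
        gmap = default_marker_map(40, 20.0)
        freqs = np.tile(np.array([[0.0], [0.5]]), (1, 40))  # line 1 fixed for 0
        sim = simulate_cross(SimConfig(gmap=gmap, pedigree=ped, seed=11, allele_freqs=freqs))
        phase = phase_parent("S0", ped, sim.genotypes, gmap)
        het = sim.genotypes.row("S0") == 1
        # line-1 founder homozygous everywhere: every het marker is forced
        assert np.all(phase.resolved[het])
        assert np.all(np.isinf(phase.support[het]))

    @staticmethod
    def _cis_fixture(offspring_bc_missing=False):
        """Hand-built cross where only offspring linkage can phase b and c.

        Marker a is phase-forced (founders homozygous for opposite
        alleles); markers b and c sit 0.1 cM apart with both founders
        heterozygous.  The sire's true haplotypes are (0,1,1) on line 1 and
        (1,0,0) on line 2; offspring receive one haplotype unrecombined
        from the sire and all-0 alleles from their dams.
        """
        from lineorigin.pedigree_io import GenotypeMatrix

        ped = make_pedigree(20, n_sires=1, n_dams=2)
        gmap = GeneticMap(["a", "b", "c"], [0.0, 10.0, 10.1], length_cM=20.0)
        rows = {
            "A1": [0, 1, 1],  # line-1 founder: hom 0 at a, het at b, c
            "B1": [2, 1, 1],  # line-2 founder: hom 1 at a, het at b, c
            "A2": [0, 0, 0],
            "B2": [0, 0, 0],
            "S0": [1, 1, 1],
            "D0": [0, 0, 0],
            "D1": [0, 0, 0],
        }
        for k in range(20):
            from_line1 = k % 2 == 0
            g = [0, 1, 1] if from_line1 else [1, 0, 0]  # sire hap + dam 0s
            if offspring_bc_missing:
                g = [g[0], -1, -1]
            rows[f"X{k:04d}"] = g
        codes = np.array([rows[i] for i in ped.ids()], dtype=np.int8)
        geno = GenotypeMatrix(ped.ids(), gmap.marker_ids, codes)
        truth_line1 = np.array([[0, 1], [1, 0], [1, 0]])  # (line1, line2) alleles
        return ped, gmap, geno, truth_line1

    def test_cis_phase_recovered_from_offspring(self):
        ped, gmap, geno, truth = self._cis_fixture()
        phase = phase_parent("S0", ped, geno, gmap)
        assert phase.resolved.all()
        np.testing.assert_array_equal(phase.as_array(), truth)
        assert np.isinf(phase.support[0])  # a: forced by founders
        assert np.isfinite(phase.support[1]) and phase.support[1] > 0

    def test_uninformative_offspring_leave_marker_unresolved(self):
        ped, gmap, geno, _ = self._cis_fixture(offspring_bc_missing=True)
        phase = phase_parent("S0", ped, geno, gmap)
        assert phase.resolved[0] and not phase.resolved[1] and not phase.resolved[2]

    def test_phase_recovery_rate_on_dense_simulation(self):
        # dense heterozygous markers, 25 offspring: >= 99% of the resolved
        # markers must carry the true phase
        ped = make_pedigree(25, n_sires=1, n_dams=2)
        gmap = default_marker_map(300, 60.0)
        sim = simulate_cross(SimConfig(gmap=gmap, pedigree=ped, seed=17))
        correct = total = 0
        phase = phase_parent("S0", ped, sim.genotypes, gmap)
        truth = sim.parental_phase["S0"]
        mask = phase.resolved
        total += int(mask.sum())
        correct += int((phase.allele_line1[mask] == truth[mask, 0]).sum())
        assert total > 100
        assert correct / total >= 0.99

    def test_parent_without_offspring_rejected(self):
        ped = make_pedigree(4, n_sires=2, n_dams=2)
        gmap = default_marker_map(10, 9.0)
        sim = simulate_cross(SimConfig(gmap=gmap, pedigree=ped, seed=19))
        # S1 gets offspring only when n_f2 > 1 (round robin); drop them
        from lineorigin.pedigree_io import Individual, Pedigree

        keep = [i for i in ped if not (i.generation == "F2" and i.sire == "S1")]
        ped2 = Pedigree(
            [Individual(i.id, i.sire, i.dam, i.sex, i.line) for i in keep]
        )
        from lineorigin.errors import InputError

        with pytest.raises(InputError, match="offspring"):
            phase_parent("S1", ped2, sim.genotypes, gmap)

    def test_phase_file_written_deterministically(self, tmp_path):
        sim = simulate_cross(
            SimConfig(gmap=default_marker_map(10, 9.0), pedigree=make_pedigree(4), seed=21)
        )
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_phase(sim.parental_phase, sim.config.gmap.marker_ids, a)
        write_phase(sim.parental_phase, sim.config.gmap.marker_ids, b)
        assert a.read_bytes() == b.read_bytes()
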