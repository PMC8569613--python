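import itertools

import numpy as np
import pandas as pd
import pytest

from polycross import simulate as sim
from polycross.genotype import compute_ga_table, gamete_dosage_set


class TestGeneticMap:
    def test_default_map_invariants(self):
        gmap = sim.build_genetic_map(np.random.default_rng(0))
        assert gmap.n_chromosomes == 8
        assert 4800 <= gmap.n_markers <= 7200
        for L, pos, cen in zip(gmap.lengths, gmap.positions, gmap.centromeres):
            assert 90 <= L <= 120
            assert 600 <= pos.size <= 900
            assert 10 <= cen <= 50
            assert np.diff(pos).min() >= 0.1 - 1e-9

    def test_two_marker_chromosome_respects_spacing(self):
        gmap = sim.build_genetic_map(
            np.random.default_rng(1),
            n_chromosomes=1,
            length_range=(10, 10),
            markers_per_chrom_range=(2, 2),
        )
        assert np.diff(gmap.positions[0]).min() >= 0.1 - 1e-9

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="cannot fit"):
            sim.build_genetic_map(
                np.random.default_rng(2),
                n_chromosomes=1,
                length_range=(10, 10),
                markers_per_chrom_range=(200, 200),
            )


class TestSimulateParent:
    def test_point_mass_profiles(self, tiny_map, rng):
        p0 = sim.simulate_parent(tiny_map, [1, 0, 0, 0, 0], 4, rng)
        assert (p0.dosage == 0).all()
        p4 = sim.simulate_parent(tiny_map, [0, 0, 0, 0, 1], 4, rng)
        assert (p4.dosage == 4).all()

    def test_uniform_rates_multinomial(self):
        rng = np.random.default_rng(3)
        gmap = sim.build_genetic_map(
            rng, n_chromosomes=1, length_range=(100, 100),
            markers_per_chrom_range=(900, 900),
        )
        # 10 independent parents -> 9000 marker draws
        counts = np.zeros(5)
        for _ in range(10):
            p = sim.simulate_parent(gmap, [0.2] * 5, 4, rng)
            counts += np.bincount(p.dosage, minlength=5)
        n = counts.sum()
        sigma = np.sqrt(0.2 * 0.8 / n)
        assert np.abs(counts / n - 0.2).max() < 3 * sigma

    def test_rate_vector_length_mismatch(self, tiny_map, rng):
        with pytest.raises(ValueError, match="length"):
            sim.simulate_parent(tiny_map, [0.5, 0.5], 4, rng)


class TestMakeGamete:
    def test_homozygous_markers_conserved(self, tiny_map, rng):
        parent = sim.simulate_parent(tiny_map, [0.3, 0, 0, 0, 0.7], 4, rng)
        for _ in range(5):
            g = sim.make_gamete(parent, tiny_map, rng)
            assert g.shape == (2, tiny_map.n_markers)
            dos = g.sum(axis=0)
            assert np.array_equal(dos[parent.dosage == 0], np.zeros((parent.dosage == 0).sum()))
            assert np.array_equal(dos[parent.dosage == 4], np.full((parent.dosage == 4).sum(), 2))

    @pytest.mark.parametrize("ploidy", [4, 6])
    def test_gamete_dosage_range_matches_enumeration(self, tiny_map, ploidy):
        """Observed gamete dosages equal the brute-force set of all
        (p choose p/2) chromosome subsets, for every parental dosage."""
        rng = np.random.default_rng(9)
        half = ploidy // 2
        for d in range(ploidy + 1):
            parent = sim.simulate_parent(
                tiny_map, np.eye(ploidy + 1)[d], ploidy, rng
            )
            observed = set()
            for _ in range(80):
                observed |= set(sim.make_gamete(parent, tiny_map, rng).sum(axis=0).tolist())
            haplo = [1] * d + [0] * (ploidy - d)
            brute = {sum(c) for c in itertools.combinations(haplo, half)}
            assert observed == brute == gamete_dosage_set(d, ploidy)

    def test_recombination_matches_haldane(self):
        """Two markers 0.1 cM apart: recombinant fraction ~ (1-e^(-2d))/2.

        A diploid heterozygote phased in coupling (haplotypes 11 / 00) makes
        every transmitted chromatid informative, so the observed switch rate
        is the map's recombination fraction.
        """
        gmap = sim.GeneticMap((10.0,), (np.array([5.0, 5.1]),), (5.0,))
        rng = np.random.default_rng(12)
        parent = sim.PhasedParent(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        n, rec = 100_000, 0
        for _ in range(n):
            g = sim.make_gamete(parent, gmap, rng)
            rec += int(g[0, 0] != g[0, 1])
        d = 0.1 / 100
        expected = (1 - np.exp(-2 * d)) / 2
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 3 * sigma


class TestCross:
    def test_nulliplex_parents_give_nulliplex_progeny(self, tiny_map, rng):
        p = sim.simulate_parent(tiny_map, [1, 0, 0, 0, 0], 4, rng)
        prog = sim.cross(p, p, 5, tiny_map, rng)
        assert (prog.to_numpy() == 0).all()

    def test_selfing_fixed_at_parent_nulliplex_markers(self, tiny_map, rng):
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        prog = sim.cross(p1, p1, 10, tiny_map, rng).to_numpy()
        nul = p1.dosage == 0
        assert (prog[:, nul] == 0).all()

    def test_nulliplex_by_simplex_progeny_in_0_1(self, tiny_map, rng):
        p0 = sim.simulate_parent(tiny_map, [1, 0, 0, 0, 0], 4, rng)
        p1 = sim.simulate_parent(tiny_map, [0, 1, 0, 0, 0], 4, rng)
        prog = sim.cross(p0, p1, 10, tiny_map, rng).to_numpy()
        assert set(np.unique(prog)) <= {0.0, 1.0}

    def test_ploidy_mismatch_raises(self, tiny_map, rng):
        p4 = sim.simulate_parent(tiny_map, [1, 0, 0, 0, 0], 4, rng)
        p6 = sim.simulate_parent(tiny_map, [1, 0, 0, 0, 0, 0, 0], 6, rng)
        with pytest.raises(ValueError, match="ploidy"):
            sim.cross(p4, p6, 1, tiny_map, rng)


class TestNoise:
    def test_error_rate_zero_is_identity(self, small_matrix, rng):
        out = sim.inject_errors(small_matrix, 0.0, rng)
        pd.testing.assert_frame_equal(out.data, small_matrix.data)

    def test_error_fraction_binomial(self, tiny_map):
        rng = np.random.default_rng(21)
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        p2 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P2"), 4, rng)
        spec = sim.ScenarioSpec(counts={"HP": 200}, error_rate=0.0, missing_range=(0, 0))
        matrix, _ = sim.build_population(spec, tiny_map, {"P1": p1, "P2": p2}, rng)
        noisy = sim.inject_errors(matrix, 0.05, rng)
        prog = matrix.progeny_ids
        changed = (noisy.data.loc[prog] != matrix.data.loc[prog]).to_numpy().mean()
        cells = len(prog) * matrix.n_markers
        assert abs(changed - 0.05) < 3 * np.sqrt(0.05 * 0.95 / cells)
        # parents untouched
        pd.testing.assert_frame_equal(
            noisy.data.loc[["P1", "P2"]], matrix.data.loc[["P1", "P2"]]
        )

    def test_error_never_reproduces_own_value(self, tiny_map):
        rng = np.random.default_rng(22)
        df = pd.DataFrame(
            np.full((6, 50), 2.0), index=[f"i{k}" for k in range(6)],
            columns=[f"m{j}" for j in range(50)],
        )
        from polycross.io_core import DosageMatrix

        mat = DosageMatrix(df, 4, "i0", "i1")
        noisy = sim.inject_errors(mat, 0.5, rng)
        vals = noisy.data.loc[mat.progeny_ids].to_numpy()
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0, 3.0, 4.0}
        assert (vals != 2.0).any()

    def test_missing_range_zero_is_identity(self, small_matrix, rng):
        out = sim.inject_missing(small_matrix, (0.0, 0.0), rng)
        pd.testing.assert_frame_equal(out.data, small_matrix.data)

    def test_missing_per_marker_bounded_and_mean(self, tiny_map):
        rng = np.random.default_rng(23)
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        p2 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P2"), 4, rng)
        spec = sim.ScenarioSpec(counts={"HP": 100}, error_rate=0.0, missing_range=(0, 0))
        matrix, _ = sim.build_population(spec, tiny_map, {"P1": p1, "P2": p2}, rng)
        out = sim.inject_missing(matrix, (0.01, 0.05), rng)
        frac = out.data.loc[matrix.progeny_ids].isna().mean(axis=0)
        n = len(matrix.progeny_ids)
        assert (frac <= 0.05 + 1 / n + 1e-12).all()
        assert abs(frac.mean() - 0.03) < 0.01

    @pytest.mark.parametrize("bad", [(-0.1, 0.2), (0.5, 0.2), (0.2, 1.0)])
    def test_invalid_missing_interval(self, small_matrix, rng, bad):
        with pytest.raises(ValueError, match="missing range"):
            sim.inject_missing(small_matrix, bad, rng)


class TestBuildPopulation:
    def test_worked_example_composition(self, worked_example):
        matrix, truth = worked_example
        assert matrix.n_individuals == 202
        assert matrix.n_markers == 2758
        assert truth.labels.value_counts().to_dict() == {
            "HP": 150, "AC_P1": 10, "SP_P1": 10, "HS": 20, "FC": 10
        }
        assert set(truth.origin[truth.labels == "HS"].unique()) == {"P1xP3", "P1xP4"}

    def test_all_hybrid_scenario(self, tiny_map, rng):
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        p2 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P2"), 4, rng)
        matrix, truth = sim.build_population(
            sim.ScenarioSpec(counts={"HP": 5}), tiny_map, {"P1": p1, "P2": p2}, rng
        )
        assert (truth.labels == "HP").all()
        truth.validate_against(matrix)

    def test_missing_required_parent_raises(self, tiny_map, rng):
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        p2 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P2"), 4, rng)
        with pytest.raises(ValueError, match="P3"):
            sim.build_population(
                sim.ScenarioSpec(counts={"HP": 2, "HS1": 2}),
                tiny_map, {"P1": p1, "P2": p2}, rng,
            )

    def test_clone_equals_parent_before_noise(self, tiny_map, rng):
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        assert np.array_equal(sim.clone(p1), p1.dosage.astype(float))

    def test_seed_determinism(self, tiny_map):
        def run(seed):
            rng = np.random.default_rng(seed)
            p = {
                q: sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, q), 4, rng)
                for q in ("P1", "P2", "P3", "P4")
            }
            spec = sim.ScenarioSpec(counts={"HP": 10, "AC_P1": 2, "FC": 3})
            return sim.build_population(spec, tiny_map, p, rng)

        m1, t1 = run(99)
        m2, t2 = run(99)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        assert t1.labels.equals(t2.labels)

    def test_dosage_conservation_links_to_ga3(self, clean_population):
        """Error-free true hybrids carry only Mendelian-expected dosages."""
        matrix, _, _, _ = clean_population
        table = compute_ga_table(matrix)
        assert (table.scores["ga3"] == 0.0).all()


class TestBenchmarkScenario:
    def test_composition_bounds(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            spec = sim.benchmark_scenario(rng)
            c = spec.total - spec.counts["HP"]
            assert 1 <= c <= 50
            assert spec.total == 200
            assert set(spec.counts) <= {"HP", "AC_P1", "SP_P1", "HS1", "HS2", "FC"}


class TestSubsample:
    def test_full_sample_is_permutation_equivalent(self, small_matrix, rng):
        out = sim.subsample_markers(small_matrix, 3, rng)
        assert sorted(out.marker_ids) == sorted(small_matrix.marker_ids)
        pd.testing.assert_frame_equal(
            out.data[small_matrix.marker_ids], small_matrix.data
        )

    def test_single_marker_valid(self, small_matrix, rng):
        out = sim.subsample_markers(small_matrix, 1, rng)
        assert out.n_markers == 1

    def test_oversample_raises(self, small_matrix, rng):
        with pytest.raises(ValueError, match="sample"):
            sim.subsample_markers(small_matrix, 10, rng)

    def test_subsample_map_consistent_with_parents(self, tiny_map, rng):
        p1 = sim.simulate_parent(tiny_map, sim.default_dosage_rates(4, "P1"), 4, rng)
        sub_map, sub_parents = sim.subsample_map(tiny_map, {"P1": p1}, 10, rng)
        assert sub_map.n_markers == 10
        assert sub_parents["P1"].n_markers == 10
        # surviving markers keep their dosages (match by map position;
        # marker ids are renumbered on the subsetted map)
        full = dict(zip(tiny_map.positions[0], p1.dosage))
        sub = dict(zip(sub_map.positions[0], sub_parents["P1"].dosage))
        assert set(sub) <= set(full)
        assert all(full[pos] == d for pos, d in sub.items())
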