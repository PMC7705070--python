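"""Pairwise distance matrices and the fraction-discriminable statistic."""

import numpy as np
import pandas as pd
import pytest

from floravision import (
    DistanceMatrix,
    fraction_discriminable,
    pairwise_distances,
    render_archetype,
    simulate_population,
    study_means,
    summarize_study,
)
from floravision.synthetic_flora import FlowerArchetype, ParameterJitter

from conftest import make_dataset


def matrix_from_pairs(pair_values, n):
    """Build a DistanceMatrix from upper-triangle values (row-major)."""
    d = np.zeros((n, n))
    d[np.triu_indices(n, k=1)] = pair_values
    d = d + d.T
    return DistanceMatrix("p1", "bee", tuple(f"f{i}" for i in range(n)), d)


class TestPairwiseDistances:
    def test_identical_spectra_zero_off_diagonal(self, grid, bee, illuminant):
        refl = np.interp(grid, [300, 450, 700], [0.1, 0.7, 0.1])
        ds = make_dataset({"a": refl, "b": refl.copy()}, grid)
        dm = pairwise_distances(ds, "p1", bee, illuminant)
        assert dm.pair_values() == pytest.approx([0.0], abs=1e-14)

    def test_fifteen_flowers_give_105_pairs(self, gaussian_archetype, bee, illuminant):
        frag = simulate_population(
            gaussian_archetype, ParameterJitter(center_sd=5), n=15, seed=7
        )
        dm = pairwise_distances(frag, "pop1", bee, illuminant)
        assert dm.pair_values().size == 105

    def test_flower_order_does_not_change_distance_multiset(self, grid, bee, illuminant):
        rng = np.random.default_rng(3)
        values = {f"f{i}": rng.uniform(0, 1, grid.size) for i in range(5)}
        ds = make_dataset(values, grid)
        shuffled = ds.subset(["f3", "f0", "f4", "f1", "f2"])
        d1 = np.sort(pairwise_distances(ds, "p1", bee, illuminant).pair_values())
        d2 = np.sort(pairwise_distances(shuffled, "p1", bee, illuminant).pair_values())
        np.testing.assert_allclose(d1, d2, atol=1e-14)


class TestFractionDiscriminable:
    def test_constructed_six_pair_example(self):
        dm = matrix_from_pairs([0.05, 0.12, 0.12, 0.05, 0.20, 0.02], 4)
        pv = fraction_discriminable(dm, threshold=0.11)
        # brute-force count over the six listed pairs: 0.12, 0.12, 0.20 exceed
        assert pv.n_pairs == 6
        assert pv.n_discriminable == 3
        assert pv.fraction_discriminable == pytest.approx(0.5)

    def test_tie_at_threshold_is_indiscriminable(self):
        dm = matrix_from_pairs([0.11], 2)
        assert fraction_discriminable(dm, 0.11).n_discriminable == 0

    def test_threshold_bounds(self):
        dm = matrix_from_pairs([0.3, 0.5, 0.7], 3)
        assert fraction_discriminable(dm, 0.8).fraction_discriminable == 0.0
        assert fraction_discriminable(dm, 1e-12).fraction_discriminable == 1.0

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        dm = matrix_from_pairs(rng.uniform(0, 2, 28), 8)
        fracs = [
            fraction_discriminable(dm, t).fraction_discriminable
            for t in np.linspace(0.01, 2.0, 25)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_duplicate_flower_cannot_increase_fraction(self, grid, bee, illuminant):
        rng = np.random.default_rng(11)
        values = {f"f{i}": rng.uniform(0, 0.8, grid.size) for i in range(4)}
        ds = make_dataset(values, grid)
        base = fraction_discriminable(
            pairwise_distances(ds, "p1", bee, illuminant), bee.threshold
        )
        values["f0_dup"] = values["f0"].copy()
        with_dup = fraction_discriminable(
            pairwise_distances(make_dataset(values, grid), "p1", bee, illuminant),
            bee.threshold,
        )
        assert with_dup.fraction_discriminable <= base.fraction_discriminable

    def test_exhaustive_double_loop_oracle_small_populations(self, bee, bird_vs, illuminant):
        from floravision.colorspaces import color_point, hexagon_distance, rnl_distance
        from floravision.visual_systems import quantum_catches

        rng = np.random.default_rng(19)
        arch = FlowerArchetype("gaussian_peak", 480, 45, 0.6)
        for rep in range(20):
            n = int(rng.integers(2, 9))
            frag = simulate_population(
                arch, ParameterJitter(8, 4, 0.08, 0.01), n, seed=int(rng.integers(2**31))
            )
            for v in (bee, bird_vs):
                dm = pairwise_distances(frag, "pop1", v, illuminant)
                got = fraction_discriminable(dm, v.threshold)
                # independent double loop over flowers
                flowers = list(frag.spectra)
                count = total = 0
                for i in range(len(flowers)):
                    for j in range(i + 1, len(flowers)):
                        qa = quantum_catches(frag.spectra[flowers[i]], v, illuminant)
                        qb = quantum_catches(frag.spectra[flowers[j]], v, illuminant)
                        if v.model == "hexagon":
                            dist = hexagon_distance(color_point(qa, v), color_point(qb, v))
                        else:
                            dist = rnl_distance(qa, qb, v)
                        total += 1
                        count += dist > v.threshold
                assert got.n_pairs == total
                assert got.n_discriminable == count


class TestSummarizeStudy:
    @pytest.fixture()
    def two_species_dataset(self, grid):
        rng = np.random.default_rng(23)
        frames, spectra = [], {}
        # sp1 has two populations, sp2 only one -> its SE must be NaN
        for pop, sp, system in [("sp1_p1", "sp1", "Bee"), ("sp1_p2", "sp1", "Bee"), ("sp2_p1", "sp2", "Bird")]:
            ds = make_dataset(
                {f"{pop}_f{i}": rng.uniform(0, 1, grid.size) for i in range(4)},
                grid, population=pop, species=sp, system=system,
            )
            spectra.update(ds.spectra)
            frames.append(ds.metadata)
        from floravision import SpectralDataset

        return SpectralDataset(spectra, pd.concat(frames, ignore_index=True))

    def test_single_population_species_has_no_se(self, two_species_dataset, bee, illuminant):
        pop, species = summarize_study(two_species_dataset, [bee], illuminant)
        sp1 = species[species.species_code == "sp1"].iloc[0]
        sp2 = species[species.species_code == "sp2"].iloc[0]
        assert np.isfinite(sp1.se_fraction)
        assert np.isnan(sp2.se_fraction)

    def test_zero_jitter_study_all_fractions_zero(self, gaussian_archetype, bee, bird_vs, illuminant):
        frag = simulate_population(gaussian_archetype, ParameterJitter(), 5, seed=1)
        pop, _ = summarize_study(frag, [bee, bird_vs], illuminant)
        assert (pop.fraction_discriminable == 0).all()

    def test_study_means_match_independent_groupby(self, two_species_dataset, bee, bird_vs, illuminant):
        pop, species = summarize_study(two_species_dataset, [bee, bird_vs], illuminant)
        means = study_means(pop, species)
        for viewer in ("bee", "bird_VS"):
            rows = pop[pop.viewer == viewer]
            expect_pop = rows.fraction_discriminable.sum() / len(rows)
            sp_means = [
                g.fraction_discriminable.mean() for _, g in rows.groupby("species_code")
            ]
            expect_sp = sum(sp_means) / len(sp_means)
            got = means[means.viewer == viewer].iloc[0]
            assert got.across_populations == pytest.approx(expect_pop)
            assert got.across_species == pytest.approx(expect_sp)
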