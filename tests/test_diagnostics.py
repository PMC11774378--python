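"""Tests for the diagnostic statistics (psi, LOPO, out-of-range, fits)."""

import itertools

import numpy as np
import pytest

import qfasa as q
from conftest import make_library, make_matrix


class TestPsi:
    def test_all_singleton_groups_give_zero(self, rng):
        x = rng.dirichlet(np.ones(5), size=4)
        lib = make_library(x, ["a", "b", "c", "d"])
        res = q.psi(lib, "aitchison")
        assert res.psi == 0.0 and res.within_sum == 0.0

    @pytest.mark.parametrize("measure", ["kullback_leibler", "aitchison"])
    def test_matches_all_pairs_enumeration(self, measure, rng):
        n = 12
        x = rng.dirichlet(np.ones(6), size=n)
        labels = ["g1"] * 4 + ["g2"] * 5 + ["g3"] * 3
        lib = make_library(x, labels)
        res = q.psi(lib, measure)
        dist = q.kl_distance if measure == "kullback_leibler" else (
            q.aitchison_distance
        )
        within = between = 0.0
        for i, j in itertools.combinations(range(n), 2):
            d = dist(x[i], x[j])
            if labels[i] == labels[j]:
                within += d
            else:
                between += d
        assert res.within_sum == pytest.approx(within, abs=1e-10)
        assert res.between_sum == pytest.approx(between, abs=1e-10)
        assert res.psi == pytest.approx(within / (within + between),
                                        abs=1e-12)
        assert 0.0 <= res.psi <= 1.0

    def test_two_by_two_toy_library(self):
        x = np.array(
            [[0.6, 0.4], [0.7, 0.3], [0.2, 0.8], [0.3, 0.7]]
        )
        lib = make_library(x, ["a", "a", "b", "b"])
        res = q.psi(lib, "aitchison")
        d = q.aitchison_distance
        within = d(x[0], x[1]) + d(x[2], x[3])
        between = sum(
            d(x[i], x[j]) for i in (0, 1) for j in (2, 3)
        )
        assert res.psi == pytest.approx(within / (within + between),
                                        abs=1e-12)

    def test_decreases_with_group_separation(self):
        psis = []
        for sep in [0.2, 0.5, 1.0, 1.8, 3.0]:
            spec = q.SimulationSpec(
                G=4, K=8, n_per_group=6, n_predators=2,
                within_spread=0.15, separation=sep, seed=2,
            )
            lib = q.simulate_prey_library(spec)
            psis.append(q.psi(lib, "aitchison").psi)
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_identical_signatures_fail(self):
        lib = make_library([[0.5, 0.5], [0.5, 0.5]], ["a", "b"])
        with pytest.raises(ValueError, match="undefined"):
            q.psi(lib, "aitchison")


class TestLopo:
    def _cfg(self, space="prey", distance="aitchison", k=6):
        return q.MethodConfig("fixed_cc", space, distance, "normalize",
                              [f"fa_{j}" for j in range(k)])

    def test_perfectly_separated_groups_give_identity(self, rng):
        # internally identical, mutually distinct signatures
        bases = rng.dirichlet(np.ones(6), size=3)
        x = np.repeat(bases, 3, axis=0)
        lib = make_library(x, [g for g in "abc" for _ in range(3)])
        res = q.lopo(lib, np.ones(6), self._cfg())
        np.testing.assert_allclose(res.attribution, np.eye(3), atol=1e-6)
        assert res.total == pytest.approx(3.0, abs=1e-6)
        np.testing.assert_allclose(res.attribution.sum(axis=1), 1.0,
                                   atol=1e-6)

    @pytest.mark.parametrize("space", ["prey", "predator"])
    def test_well_separated_synthetic_groups(self, space):
        spec = q.SimulationSpec(
            G=3, K=8, n_per_group=6, n_predators=2,
            within_spread=0.05, separation=1.5, cc_spread=0.2, seed=4,
        )
        lib = q.simulate_prey_library(spec)
        cc = q.simulate_cc(spec)
        cfg = q.MethodConfig("fixed_cc", space, "aitchison", "normalize",
                             lib.signatures.fa_names)
        res = q.lopo(lib, cc, cfg)
        assert np.all(np.diag(res.attribution) >= 0.9)
        np.testing.assert_allclose(res.attribution.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_duplicating_members_changes_attribution_little(self, rng):
        # Exact invariance under duplication cannot hold: the held-out
        # signature's duplicate stays in the group and pulls the
        # leave-one-out mean toward it.  The effect is O(1/n), so with
        # moderately sized groups the attributions nearly coincide.
        x = np.vstack([
            rng.dirichlet([30, 10, 10, 10, 10], size=12),
            rng.dirichlet([10, 30, 10, 10, 10], size=12),
        ])
        labels = ["a"] * 12 + ["b"] * 12
        lib = make_library(x, labels)
        doubled = make_library(
            np.vstack([x, x]), labels + labels,
            ids=[f"s{i}" for i in range(48)],
        )
        r1 = q.lopo(lib, np.ones(5), self._cfg(k=5))
        r2 = q.lopo(doubled, np.ones(5), self._cfg(k=5))
        np.testing.assert_allclose(r1.attribution, r2.attribution,
                                   atol=0.05)

    def test_singleton_group_fails_with_group_name(self, rng):
        lib = make_library(rng.dirichlet(np.ones(4), size=3),
                           ["a", "a", "lonely"])
        with pytest.raises(ValueError, match="lonely"):
            q.lopo(lib, np.ones(4), self._cfg(k=4))


class TestOutOfRange:
    def _means(self, arr):
        arr = np.asarray(arr, float)
        return q.GroupMeans(
            [f"g{i}" for i in range(arr.shape[0])],
            [f"fa_{j}" for j in range(arr.shape[1])], arr,
            [1] * arr.shape[0],
        )

    def _cfg(self, space, k):
        return q.MethodConfig("fixed_cc", space, "aitchison", "normalize",
                              [f"fa_{j}" for j in range(k)])

    def test_predator_at_group_mean_is_inside(self):
        means = self._means([[0.4, 0.6], [0.6, 0.4]])
        pred = make_matrix([[0.4, 0.6]])
        assert q.out_of_range_proportion(
            pred, means, np.ones(2), self._cfg("predator", 2)
        ) == 0.0

    def test_fully_outside_predator(self):
        means = self._means([[0.4, 0.6], [0.6, 0.4]])
        pred = make_matrix([[0.7, 0.3]])
        assert q.out_of_range_proportion(
            pred, means, np.ones(2), self._cfg("predator", 2)
        ) == 1.0

    def test_convex_combinations_are_inside(self, rng):
        means = self._means(rng.dirichlet(np.ones(5), size=3))
        Pi = rng.dirichlet(np.ones(3), size=10)
        pred = make_matrix(Pi @ means.means)
        assert q.out_of_range_proportion(
            pred, means, np.ones(5), self._cfg("predator", 5)
        ) == 0.0

    def test_prey_space_transforms_predators(self, rng):
        # predators built inside the hull *after* CC inversion
        means = self._means(rng.dirichlet(np.ones(5), size=3))
        c = np.linspace(0.5, 2.0, 5)
        Pi = rng.dirichlet(np.ones(3), size=10)
        pred = make_matrix(q.to_predator_space(Pi @ means.means, c))
        assert q.out_of_range_proportion(
            pred, means, c, self._cfg("prey", 5)
        ) == 0.0


class TestFitDistances:
    def test_recomputation_matches_stored_objectives(
        self, small_library, small_cc, small_predators
    ):
        predators, truth = small_predators
        cfg = q.MethodConfig("fixed_cc", "prey", "kullback_leibler",
                             "normalize", predators.fa_names)
        table = q.estimate_all(predators, small_library, small_cc, cfg)
        means = q.prey_group_means(small_library)
        fd = q.fit_distances(predators, table, means, small_cc, cfg)
        np.testing.assert_allclose(fd, table.objectives, atol=1e-10)

    def test_sum_equals_joint_objective(
        self, small_library, small_cc, small_predators
    ):
        predators, truth = small_predators
        cfg = q.MethodConfig("fixed_cc", "predator", "aitchison",
                             "normalize", predators.fa_names)
        table = q.estimate_all(predators, small_library, small_cc, cfg)
        means = q.prey_group_means(small_library)
        fd = q.fit_distances(predators, table, means, small_cc, cfg)
        joint = q.joint_objective(table, small_cc, predators, means)
        assert fd.sum() == pytest.approx(joint, abs=1e-10)


class TestCompareMethods:
    def _table(self, Pi, labels=None):
        labels = labels or [f"g{j}" for j in range(Pi.shape[1])]
        return q.DietTable(
            [q.DietEstimate(i, p, 0.0, True, 1) for i, p in enumerate(Pi)],
            labels,
        )

    def test_self_comparison_gives_unit_correlations(self, rng):
        Pi = rng.dirichlet(np.ones(3), size=20)
        a = self._table(Pi)
        corr, share = q.compare_methods(a, self._table(Pi.copy()),
                                        fit_a=np.ones(20),
                                        fit_b=np.ones(20))
        assert np.allclose(corr.to_numpy(), 1.0)
        assert share == 0.0

    def test_independent_estimates_decorrelate(self, rng):
        a = self._table(rng.dirichlet(np.ones(4), size=400))
        b = self._table(rng.dirichlet(np.ones(4), size=400))
        corr, _ = q.compare_methods(a, b)
        assert np.all(np.abs(corr.to_numpy()) < 0.2)

    def test_zero_variance_species_reported_as_nan(self):
        Pi = np.tile([0.5, 0.5], (5, 1))
        corr, _ = q.compare_methods(self._table(Pi), self._table(Pi))
        assert corr.isna().all()

    def test_mismatched_predators_rejected(self, rng):
        a = self._table(rng.dirichlet(np.ones(3), size=4))
        b = self._table(rng.dirichlet(np.ones(3), size=5))
        with pytest.raises(ValueError, match="different predators"):
            q.compare_methods(a, b)
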