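import itertools
import math

import numpy as np
import pytest

from epiwalk import (
    EvolutionParams,
    GenotypeFitnessMap,
    TrajectoryDistribution,
    edge_marginals,
    fixation_probability,
    prediction_overlap,
    theta,
    trajectory_probabilities,
)
from epiwalk.trajectories import NoAccessibleTrajectoriesError


class TestFixationProbability:
    def test_neutral_limit_is_one_over_N(self):
        p = EvolutionParams(N=1000)
        assert fixation_probability(1.0, 1.0, p) == pytest.approx(1e-3, rel=1e-9)

    def test_lethal_destination_is_zero(self):
        p = EvolutionParams(N=1e4)
        assert fixation_probability(1.0, 0.0, p) == 0.0
        assert fixation_probability(1.0, -0.5, p) == 0.0

    def test_lethal_background_raises(self):
        with pytest.raises(ValueError, match="lethal"):
            fixation_probability(0.0, 1.0, EvolutionParams(N=100))

    def test_closed_form_beneficial(self):
        # s = 0.1, N = 1e4: pi = (1 - e^-0.1) / (1 - e^-1000)
        p = EvolutionParams(N=1e4)
        expected = (1.0 - np.exp(-0.1)) / (1.0 - np.exp(-1000.0))
        assert fixation_probability(1.0, 1.1, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_destination_fitness(self):
        p = EvolutionParams(N=1e4)
        w = np.linspace(0.998, 1.2, 30)  # below this, pi underflows doubles
        pis = [fixation_probability(1.0, wi, p) for wi in w]
        assert np.all(np.diff(pis) > 0)

    def test_continuous_at_neutrality(self):
        p = EvolutionParams(N=1000)
        lo = fixation_probability(1.0, 1.0 - 1e-9, p)
        hi = fixation_probability(1.0, 1.0 + 1e-9, p)
        assert lo == pytest.approx(1e-3, rel=1e-5)
        assert hi == pytest.approx(1e-3, rel=1e-5)

    def test_large_N_limits(self):
        p = EvolutionParams(N=1e12)
        s = 0.2
        assert fixation_probability(1.0, 1.2, p) == pytest.approx(
            1.0 - np.exp(-s), abs=1e-9
        )
        assert fixation_probability(1.0, 0.8, p) == pytest.approx(0.0, abs=1e-9)

    def test_population_must_exceed_one(self):
        with pytest.raises(ValueError):
            EvolutionParams(N=1.0)


class TestTrajectoryProbabilities:
    def test_symmetric_two_site_map_splits_evenly(self, additive_map_2s):
        d = trajectory_probabilities(additive_map_2s, EvolutionParams(N=1e4), 2)
        assert set(d.trajectories) == {(0, 1), (1, 0)}
        np.testing.assert_allclose(d.probabilities, 0.5, atol=1e-12)

    def test_deleterious_first_step_suppressed_at_large_N(self):
        # site 1 alone is deleterious, so trajectory (1, 0) needs a fitness
        # valley and becomes unreachable as N grows
        m = GenotypeFitnessMap(
            n_sites=2, fitness_mean=np.array([1.0, 0.9, 1.2, 1.3])
        )
        d = trajectory_probabilities(m, EvolutionParams(N=1e6), 2)
        probs = d.as_dict()
        assert probs[(0, 1)] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("length", [1, 2, 3, 4])
    def test_counts_and_normalization(self, length, noisy_map_4s):
        d = trajectory_probabilities(noisy_map_4s, EvolutionParams(), length)
        expected_n = math.factorial(4) // math.factorial(4 - length)
        assert len(d.trajectories) == expected_n
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(d.probabilities >= 0)
        assert all(len(set(t)) == len(t) for t in d.trajectories)

    def test_site_relabeling_equivariance(self, noisy_map_4s):
        # swapping two sites permutes trajectories but not their probabilities
        L = 4
        perm = [1, 0, 2, 3]
        relabeled = np.empty_like(noisy_map_4s.fitness_mean)
        for i in range(2**L):
            bits = format(i, f"0{L}b")
            j = int("".join(bits[perm.index(k)] for k in range(L)), 2)
            relabeled[j] = noisy_map_4s.fitness_mean[i]
        m2 = noisy_map_4s.with_means(relabeled)
        d1 = trajectory_probabilities(noisy_map_4s, EvolutionParams(), 4).as_dict()
        d2 = trajectory_probabilities(m2, EvolutionParams(), 4).as_dict()
        for traj, p in d1.items():
            relabeled_traj = tuple(perm[s] for s in traj)
            assert d2[relabeled_traj] == pytest.approx(p, rel=1e-9)

    def test_all_lethal_raises_diagnostic(self):
        m = GenotypeFitnessMap(
            n_sites=2, fitness_mean=np.array([1.0, -1.0, -1.0, 1.5])
        )
        with pytest.raises(NoAccessibleTrajectoriesError):
            trajectory_probabilities(m, EvolutionParams(N=1e4), 2)

    def test_dead_ancestor_raises(self):
        m = GenotypeFitnessMap(n_sites=1, fitness_mean=np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="ancestral"):
            trajectory_probabilities(m, EvolutionParams(N=100), 1)


class TestTheta:
    def _uniform(self, L, length):
        trajs = list(itertools.permutations(range(L), length))
        return TrajectoryDistribution(
            n_sites=L,
            length=length,
            trajectories=trajs,
            probabilities=np.full(len(trajs), 1.0 / len(trajs)),
        )

    def _point_mass(self, L, traj):
        trajs = list(itertools.permutations(range(L), len(traj)))
        p = np.zeros(len(trajs))
        p[trajs.index(traj)] = 1.0
        return TrajectoryDistribution(
            n_sites=L, length=len(traj), trajectories=trajs, probabilities=p
        )

    def test_self_distance_zero(self, noisy_map_4s):
        d = trajectory_probabilities(noisy_map_4s, EvolutionParams(), 4)
        assert theta(d, d) == 0.0

    def test_disjoint_supports_give_one(self):
        a = self._point_mass(3, (0, 1, 2))
        b = self._point_mass(3, (2, 1, 0))
        assert theta(a, b) == pytest.approx(1.0)

    def test_metric_properties(self):
        rng = np.random.default_rng(8)
        trajs = list(itertools.permutations(range(3), 3))
        dists = []
        for _ in range(3):
            p = rng.dirichlet(np.ones(len(trajs)))
            dists.append(
                TrajectoryDistribution(3, 3, trajs, p)
            )
        a, b, c = dists
        assert theta(a, b) == pytest.approx(theta(b, a))
        assert theta(a, a) == 0.0
        assert theta(a, c) <= theta(a, b) + theta(b, c) + 1e-12
        assert 0.0 <= theta(a, b) <= 1.0

    def test_squared_variant(self):
        a = self._point_mass(2, (0, 1))
        b = self._point_mass(2, (1, 0))
        assert theta(a, b, variant="sq") == pytest.approx(2.0)
        with pytest.raises(ValueError):
            theta(a, b, variant="cubed")

    def test_mismatched_lengths_raise(self):
        a = self._uniform(3, 2)
        b = self._uniform(3, 3)
        with pytest.raises(ValueError):
            theta(a, b)


class TestPredictionOverlap:
    def test_full_order_is_perfect_for_all_lengths(self, noisy_map_4s):
        for k in range(1, 5):
            assert prediction_overlap(noisy_map_4s, 4, k) == pytest.approx(
                100.0, abs=1e-6
            )

    def test_first_move_predicted_perfectly_by_first_order(self, noisy_map_4s):
        # local first-order coefficients are the exact single-mutant effects
        assert prediction_overlap(noisy_map_4s, 1, 1) == pytest.approx(100.0, abs=1e-4)


class TestEdgeMarginals:
    def test_point_mass_marks_its_edges(self):
        trajs = list(itertools.permutations(range(3), 3))
        p = np.zeros(len(trajs))
        p[trajs.index((0, 1, 2))] = 1.0
        d = TrajectoryDistribution(3, 3, trajs, p)
        m = GenotypeFitnessMap(n_sites=3, fitness_mean=np.ones(8))
        edges, visits = edge_marginals(d, m)
        used = edges[edges.probability > 0]
        assert set(zip(used["from"], used["to"])) == {
            ("000", "100"),
            ("100", "110"),
            ("110", "111"),
        }
        np.testing.assert_allclose(used.probability, 1.0)

    def test_ancestral_outflow_sums_to_one(self, noisy_map_4s):
        d = trajectory_probabilities(noisy_map_4s, EvolutionParams(), 4)
        edges, visits = edge_marginals(d, noisy_map_4s)
        out = edges[edges["from"] == "0000"].probability.sum()
        assert out == pytest.approx(1.0, abs=1e-12)
        assert visits[0] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_distribution_first_step_marginals(self):
        trajs = list(itertools.permutations(range(3), 3))
        d = TrajectoryDistribution(3, 3, trajs, np.full(6, 1 / 6))
        m = GenotypeFitnessMap(n_sites=3, fitness_mean=np.ones(8))
        edges, _ = edge_marginals(d, m)
        first = edges[edges["from"] == "000"]
        np.testing.assert_allclose(first.probability, 1 / 3)
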