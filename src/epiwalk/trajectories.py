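"""Adaptive-walk trajectory probabilities under strong selection, weak mutation.

In the SSWM regime a population occupies a single genotype and evolves by a
series of isolated fixation events, so a forward trajectory is an ordered
sequence of distinct sites mutating 0 -> 1 away from the ancestral genotype.
The probability of fixing a mutant of relative fitness ``w_to`` in a
background of fitness ``w_from`` follows the classic haploid fixation form

    pi = (1 - exp(-s)) / (1 - exp(-N * s)),      s = w_to / w_from - 1,

with population size ``N`` and the analytic limit ``1/N`` at ``s = 0``.  A
trajectory's unnormalized weight is the product of its step fixation
probabilities; probabilities are normalized across all enumerated trajectories
of the same length (competing trajectories of equal step count).

Divergence between two trajectory distributions is the total-variation
distance ``theta = 0.5 * sum |p_a - p_b|``: 0 when the distributions are
identical, 1 when their supports are disjoint, and the fraction of trajectory
probability density shifted in between.  A squared-difference variant
(``sum (p_a - p_b)**2``) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .decomposition import EpistasisRemover
from .map_io import GenotypeFitnessMap, index_to_genotype

__all__ = [
    "EvolutionParams",
    "TrajectoryDistribution",
    "NoAccessibleTrajectoriesError",
    "fixation_probability",
    "trajectory_probabilities",
    "theta",
    "prediction_overlap",
    "edge_marginals",
]


class NoAccessibleTrajectoriesError(RuntimeError):
    """Every enumerated trajectory has zero fixation weight."""


@dataclass(frozen=True)
class EvolutionParams:
    """SSWM model parameters.

    N:
        Population size; must exceed 1.  Default 1e6, a large asexual
        population in which even mildly deleterious steps are effectively
        inaccessible.
    lethal_threshold:
        Fitness at or below which a genotype is inviable; fixation probability
        into it is 0.
    """

    N: float = 1e6
    lethal_threshold: float = 0.0

    def __post_init__(self):
        if not self.N > 1:
            raise ValueError(f"population size N must exceed 1, got {self.N}")


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(-x)) for x > 0, numerically stable at both ends."""
    with np.errstate(divide="ignore"):
        return np.where(
            x > np.log(2), np.log1p(-np.exp(-x)), np.log(-np.expm1(-x))
        )


def _log_fixation_array(w_from, w_to, params: EvolutionParams) -> np.ndarray:
    """Vectorized log fixation probability; -inf into lethal genotypes.

    Computed entirely in log space so that strongly deleterious steps (whose
    probabilities underflow any float) keep finite log-weights; exact zeros
    arise only for lethal destination genotypes.
    """
    w_from = np.asarray(w_from, dtype=float)
    w_to = np.asarray(w_to, dtype=float)
    N = params.N
    dead_to = w_to <= params.lethal_threshold
    safe_from = np.where(w_from > params.lethal_threshold, w_from, 1.0)
    s = np.where(dead_to, 1.0, w_to / safe_from - 1.0)  # dummy where lethal
    neutral = np.isclose(s, 0.0, atol=1e-14)
    su = np.where(neutral, 1.0, np.abs(s))  # dummy where neutral
    # s > 0: log pi = g(s) - g(N s) with g(x) = log(1 - e^-x)
    # s < 0: log pi = (N - 1) s + g(-s) - g(-N s)
    logpi = np.where(
        s > 0,
        _log1mexp(su) - _log1mexp(N * su),
        (N - 1.0) * (-su) + _log1mexp(su) - _log1mexp(N * su),
    )
    logpi = np.where(neutral, -np.log(N), logpi)
    logpi = np.where(dead_to, -np.inf, logpi)
    return np.minimum(logpi, 0.0)


def _fixation_array(w_from, w_to, params: EvolutionParams) -> np.ndarray:
    """Vectorized fixation probability in [0, 1]; 0 into lethal genotypes."""
    return np.exp(_log_fixation_array(w_from, w_to, params))


def fixation_probability(w_from: float, w_to: float, params: EvolutionParams) -> float:
    """Probability that a ``w_to`` mutant fixes in a ``w_from`` background."""
    if w_from <= params.lethal_threshold:
        raise ValueError(
            f"background fitness {w_from:g} is at or below the lethal "
            f"threshold {params.lethal_threshold:g}: no population to evolve"
        )
    return float(_fixation_array(w_from, w_to, params))


def _path_indices(n_sites: int, paths: np.ndarray) -> np.ndarray:
    """Genotype indices visited along each path, shape (n_paths, k + 1)."""
    bit_values = 2 ** (n_sites - 1 - paths)
    idx = np.zeros((paths.shape[0], paths.shape[1] + 1), dtype=int)
    idx[:, 1:] = np.cumsum(bit_values, axis=1)
    return idx


@dataclass
class TrajectoryDistribution:
    """Normalized probabilities over ordered forward mutational paths."""

    n_sites: int
    length: int
    trajectories: list[tuple[int, ...]]
    probabilities: np.ndarray

    def as_dict(self) -> dict[tuple[int, ...], float]:
        return dict(zip(self.trajectories, self.probabilities))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trajectory": ["-".join(map(str, t)) for t in self.trajectories],
                "length": self.length,
                "probability": self.probabilities,
            }
        )


def trajectory_probabilities(
    gmap: GenotypeFitnessMap, params: EvolutionParams, length: int | None = None
) -> TrajectoryDistribution:
    """Probabilities of all ordered forward paths of ``length`` distinct steps.

    Enumerates every ordered sequence of ``length`` distinct sites mutating
    away from the ancestral genotype (``L!/(L-length)!`` paths), weights each
    by the product of its step fixation probabilities (accumulated in log
    space), and normalizes over the enumeration.
    """
    L = gmap.n_sites
    if length is None:
        length = L
    if not 1 <= length <= L:
        raise ValueError(f"length must be in [1, {L}], got {length}")
    if gmap.fitness_mean[0] <= params.lethal_threshold:
        raise ValueError("ancestral genotype is at or below the lethal threshold")

    paths = np.array(list(permutations(range(L), length)), dtype=int)
    idx = _path_indices(L, paths)
    f = gmap.fitness_mean
    logpi = _log_fixation_array(f[idx[:, :-1]], f[idx[:, 1:]], params)
    logw = np.sum(logpi, axis=1)
    if np.all(np.isneginf(logw)):
        raise NoAccessibleTrajectoriesError(
            f"no accessible {length}-step trajectories: all fixation weights are zero"
        )
    probs = np.exp(logw - logsumexp(logw))
    probs /= probs.sum()
    return TrajectoryDistribution(
        n_sites=L,
        length=length,
        trajectories=[tuple(p) for p in paths],
        probabilities=probs,
    )


def theta(
    d_a: TrajectoryDistribution, d_b: TrajectoryDistribution, variant: str = "tv"
) -> float:
    """Divergence between two aligned trajectory distributions.

    ``variant="tv"`` (default) is the total-variation distance
    ``0.5 * sum |p_a - p_b|`` in [0, 1]; ``variant="sq"`` is the raw sum of
    squared differences, for sensitivity analysis.
    """
    if d_a.n_sites != d_b.n_sites or d_a.length != d_b.length:
        raise ValueError("trajectory distributions differ in L or length")
    if d_a.trajectories == d_b.trajectories:
        pa, pb = d_a.probabilities, d_b.probabilities
    else:
        lookup = d_b.as_dict()
        if set(d_a.trajectories) != set(lookup):
            raise ValueError("trajectory sets do not match")
        pa = d_a.probabilities
        pb = np.array([lookup[t] for t in d_a.trajectories])
    diff = pa - pb
    if variant == "tv":
        return float(0.5 * np.abs(diff).sum())
    if variant == "sq":
        return float(np.sum(diff**2))
    raise ValueError(f"unknown theta variant {variant!r}")


def prediction_overlap(
    gmap: GenotypeFitnessMap,
    max_order: int,
    length: int,
    params: EvolutionParams | None = None,
) -> float:
    """Percent overlap between k-step trajectories of the true map and a map
    truncated in the ancestral-referenced (local) basis.

    Measures how well fitness measured on low-order mutants of the ancestor
    predicts where evolution actually goes: 100 * (1 - theta) between the
    ``length``-step distributions, from 0 (disjoint) to 100 (identical).
    """
    params = params or EvolutionParams()
    tmap = EpistasisRemover(basis="local").fit(gmap).truncated_map(max_order)
    d_true = trajectory_probabilities(gmap, params, length)
    d_trunc = trajectory_probabilities(tmap, params, length)
    return 100.0 * (1.0 - theta(d_true, d_trunc))


def edge_marginals(
    d: TrajectoryDistribution, gmap: GenotypeFitnessMap
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-edge traversal probability and per-genotype visit probability.

    Returns a frame with columns (from, to, site, probability) for every edge
    traversed with positive probability, and an array over all genotypes with
    the summed probability of trajectories visiting each one (the ancestral
    genotype always has visit probability 1).
    """
    L = d.n_sites
    paths = np.array(d.trajectories, dtype=int)
    idx = _path_indices(L, paths)
    edge_prob: dict[tuple[int, int, int], float] = {}
    visit = np.zeros(2**L)
    visited_mask = np.zeros((len(paths), 2**L), dtype=bool)
    for step in range(d.length):
        frm, to = idx[:, step], idx[:, step + 1]
        for i in range(len(paths)):
            key = (int(frm[i]), int(to[i]), int(paths[i, step]))
            edge_prob[key] = edge_prob.get(key, 0.0) + float(d.probabilities[i])
    for col in range(idx.shape[1]):
        visited_mask[np.arange(len(paths)), idx[:, col]] = True
    visit = visited_mask.T @ d.probabilities
    frame = pd.DataFrame(
        [
            {
                "from": index_to_genotype(f, L),
                "to": index_to_genotype(t, L),
                "site": s,
                "probability": p,
            }
            for (f, t, s), p in sorted(edge_prob.items())
        ]
    )
    return frame, visit
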