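"""Propagating measurement uncertainty into the variance-partition and
trajectory-divergence statistics.

The experimental maps carry per-genotype measurement noise, and an epistasis
model soaks noise up as apparent interaction terms.  Two resampling schemes
quantify this:

* **pseudoreplicates** — maps whose fitness values are Gaussian draws around
  the measured means with the measured uncertainty; each is pushed through the
  complete pipeline (additive fit, scale refit, decomposition, truncation,
  trajectories) to yield a (phi, theta) sample per epistatic order.  The
  spread gives confidence intervals.
* **null maps** — the source map truncated *below* the order under test, with
  the original measurement uncertainty re-attached.  Pseudoreplicates of the
  null map contain no true epistasis at that order, so their (phi, theta)
  distribution shows what noise alone produces.  The p-value of an order is
  the upper-tail percentile of the experimental theta mode on the null theta
  distribution.

When replicate measurements are available the per-genotype sampling width is
the standard error of the mean; otherwise the raw std is used.  Zero widths
are floored at 1e-6 of the map's fitness range (with a warning) so sampling
stays non-degenerate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .decomposition import EpistasisRemover
from .map_io import GenotypeFitnessMap
from .trajectories import EvolutionParams, theta, trajectory_probabilities

__all__ = [
    "ResampleDistribution",
    "sampling_std",
    "sample_pseudoreplicates",
    "experimental_distribution",
    "null_distribution",
    "p_value",
    "estimate_mode",
    "confidence_interval",
]

logger = logging.getLogger(__name__)

_STD_FLOOR_FRAC = 1e-6


class DegenerateUncertaintyError(ValueError):
    """All sampling widths are zero and the floor is disabled."""


@dataclass
class ResampleDistribution:
    """Paired (phi, theta) samples for one epistatic order."""

    order: int
    source: str  # "experimental" or "null"
    phi: np.ndarray
    theta: np.ndarray
    seed: int
    n_failed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.phi)

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.phi, self.theta))


def sampling_std(gmap: GenotypeFitnessMap, std_floor: str | float | None = "auto") -> np.ndarray:
    """Per-genotype Gaussian sampling width for pseudoreplicate draws.

    Standard error of the mean when replicates are present, raw std
    otherwise.  ``std_floor="auto"`` floors zero widths at 1e-6 of the
    fitness range; a float sets the floor directly; ``None`` disables it
    (raising if every width is zero).
    """
    if gmap.fitness_replicates is not None:
        counts = np.array([len(r) for r in gmap.fitness_replicates])
        sd = gmap.fitness_std / np.sqrt(counts)
    else:
        sd = gmap.fitness_std.copy()
    if std_floor is None:
        if np.all(sd == 0):
            raise DegenerateUncertaintyError(
                "all sampling widths are zero and no floor is set"
            )
        return sd
    floor = (
        _STD_FLOOR_FRAC * max(np.ptp(gmap.fitness_mean), 1e-12)
        if std_floor == "auto"
        else float(std_floor)
    )
    n_floored = int(np.sum(sd < floor))
    if n_floored:
        warnings.warn(
            f"{n_floored} genotype(s) had sampling std below the floor "
            f"{floor:g}; floored",
            stacklevel=2,
        )
    return np.maximum(sd, floor)


def sample_pseudoreplicates(
    gmap: GenotypeFitnessMap,
    n: int,
    seed: int,
    std_floor: str | float | None = "auto",
    sigma: np.ndarray | None = None,
):
    """Yield ``n`` pseudoreplicate maps, deterministically for a given seed.

    Each pseudoreplicate's fitness means are independent Gaussian draws
    centered on the source means with width ``sigma`` (default: the source
    map's :func:`sampling_std`).  Source stds are carried over unchanged.
    """
    sigma = sampling_std(gmap, std_floor) if sigma is None else np.asarray(sigma)
    rng = np.random.default_rng(seed)
    for i in range(n):
        means = rng.normal(gmap.fitness_mean, sigma)
        yield gmap.with_means(means, name=f"{gmap.name}|pseudo{i}")


# scale-fit objective tolerance inside the resampling loop: looser than the
# point-estimate default because per-fit precision (phi to ~1e-4, theta to
# ~2e-3) is far below resampling spread, and flat-ridge fits are ~3x faster
_RESAMPLE_FTOL = 1e-8


def _phi_theta_one(
    pmap: GenotypeFitnessMap, order: int, params: EvolutionParams
) -> tuple[float, float]:
    """Full-pipeline (phi, theta) of one map at one order (global basis)."""
    rem = EpistasisRemover(basis="global", ftol=_RESAMPLE_FTOL).fit(pmap)
    phi_val = rem.phi(order)
    d_lo = trajectory_probabilities(rem.truncated_map(order - 1), params)
    d_hi = trajectory_probabilities(rem.truncated_map(order), params)
    return phi_val, theta(d_lo, d_hi)


def _resample(
    base_map: GenotypeFitnessMap,
    sigma: np.ndarray,
    order: int,
    n: int,
    seed: int,
    params: EvolutionParams,
    source: str,
) -> ResampleDistribution:
    phis, thetas, n_failed = [], [], 0
    for pmap in sample_pseudoreplicates(base_map, n, seed, sigma=sigma):
        try:
            ph, th = _phi_theta_one(pmap, order, params)
        except Exception as exc:  # refit or trajectory failure: log and skip
            n_failed += 1
            logger.warning("pseudoreplicate skipped (%s): %s", type(exc).__name__, exc)
            continue
        phis.append(ph)
        thetas.append(th)
    return ResampleDistribution(
        order=order,
        source=source,
        phi=np.array(phis),
        theta=np.array(thetas),
        seed=seed,
        n_failed=n_failed,
    )


def experimental_distribution(
    gmap: GenotypeFitnessMap,
    order: int,
    n: int,
    seed: int,
    params: EvolutionParams | None = None,
    std_floor: str | float | None = "auto",
) -> ResampleDistribution:
    """(phi, theta) samples at ``order`` from pseudoreplicates of the map.

    theta is measured between the maps truncated at ``order - 1`` and
    ``order`` (full-length trajectories, global basis), with the scale refit
    for every pseudoreplicate.
    """
    if not 2 <= order <= gmap.n_sites:
        raise ValueError(f"order must be in [2, {gmap.n_sites}], got {order}")
    params = params or EvolutionParams()
    sigma = sampling_std(gmap, std_floor)
    return _resample(gmap, sigma, order, n, seed, params, "experimental")


def null_distribution(
    gmap: GenotypeFitnessMap,
    order: int,
    n: int,
    seed: int,
    params: EvolutionParams | None = None,
    std_floor: str | float | None = "auto",
) -> ResampleDistribution:
    """(phi, theta) samples from a noise-only null at ``order``.

    The null map is the source truncated to ``order - 1`` — no epistasis at
    the tested order — with the source map's measurement uncertainty
    re-attached, so any apparent order-``order`` signal in its
    pseudoreplicates arises from noise alone.
    """
    if not 2 <= order <= gmap.n_sites:
        raise ValueError(f"order must be in [2, {gmap.n_sites}], got {order}")
    params = params or EvolutionParams()
    sigma = sampling_std(gmap, std_floor)
    null_map = EpistasisRemover(basis="global").fit(gmap).truncated_map(order - 1)
    null_map = null_map.with_means(null_map.fitness_mean, fitness_std=gmap.fitness_std)
    return _resample(null_map, sigma, order, n, seed, params, "null")


def estimate_mode(samples: np.ndarray, method: str = "kde") -> float:
    """Mode of a continuous sample.

    ``"kde"``: Gaussian kernel density (Silverman bandwidth), argmax on a
    512-point grid over the sample range.  ``"hist"``: midpoint of the fullest
    of sqrt(n) histogram bins.  Degenerate (near-constant) samples return
    their mean.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample")
    if np.ptp(samples) < 1e-12:
        return float(samples.mean())
    if method == "kde":
        try:
            kde = gaussian_kde(samples, bw_method="silverman")
            grid = np.linspace(samples.min(), samples.max(), 512)
            return float(grid[np.argmax(kde(grid))])
        except np.linalg.LinAlgError:
            method = "hist"
    if method == "hist":
        nbins = max(int(np.sqrt(samples.size)), 1)
        counts, edges = np.histogram(samples, bins=nbins)
        i = int(np.argmax(counts))
        return float(0.5 * (edges[i] + edges[i + 1]))
    raise ValueError(f"unknown mode method {method!r}")


def p_value(
    experimental: ResampleDistribution,
    null: ResampleDistribution,
    mode_method: str = "kde",
) -> float:
    """Upper-tail percentile of the experimental theta mode on the null.

    The fraction of null theta samples at or above the mode of the
    experimental theta distribution; 0 means the mode exceeds every null
    sample (effectively p < 1/n_null).
    """
    if experimental.order != null.order:
        raise ValueError(
            f"order mismatch: experimental {experimental.order} vs null {null.order}"
        )
    if experimental.n_samples == 0 or null.n_samples == 0:
        raise ValueError("empty resample distribution")
    mode = estimate_mode(experimental.theta, method=mode_method)
    return float(np.mean(null.theta >= mode))


def confidence_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a sample."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(samples, alpha)), float(np.quantile(samples, 1.0 - alpha))
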