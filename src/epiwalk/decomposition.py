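"""Epistatic decomposition of linearized fitness and order truncation.

A complete map's linearized fitness vector ``F_linear`` (length ``2**L``,
canonical genotype order) is written exactly as ``F_linear = X @ beta`` where
``X`` is a square design matrix over all site subsets and ``beta`` the vector
of epistatic coefficients, one per subset, grouped by ascending interaction
order (empty set, singletons, pairs, ..., the full set).

Two encodings of ``X`` are supported:

* ``global`` — Walsh/Hadamard basis: each allele is encoded -1 (ancestral) or
  +1 (derived), the column for subset S is the product over S.  The reference
  state is the geometric center of the map, coefficients are
  background-averaged interactions, and ``X.T @ X = 2**L * I`` so the solve is
  the analytic ``X.T / 2**L``.
* ``local`` — 0/1 encoding relative to the ancestral genotype; coefficients
  measure effects in the ancestral background (the "biochemical" model).

Removing epistasis above a chosen order is: fit the additive model and the
power-transform scale, linearize, decompose, zero the high-order coefficients,
recompose, and map the truncated linear fitness back through the forward scale.
:class:`EpistasisRemover` performs the fit once and serves truncations at any
order; module-level functions are thin wrappers over it.

The per-order variance-partition statistic phi(i) = rho_i**2 - rho_(i-1)**2 is
the extra fraction of linearized-fitness variance explained when order-i
coefficients enter the model, where rho_x**2 is the squared Pearson
correlation between ``F_linear`` and the order-x truncated model.  rho_0 is
defined as 0 (correlation against a constant is undefined), so phi(1) is the
variance explained by the additive model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from .map_io import GenotypeFitnessMap, genotype_matrix
from .scale import PowerTransform, fit_additive, transform

__all__ = [
    "DesignMatrix",
    "EpistasisCoefficients",
    "EpistasisRemover",
    "build_design_matrix",
    "decompose",
    "truncate",
    "recompose",
    "truncated_map",
    "phi",
    "phi_profile",
    "phi_from_linear",
]

_MAX_SITES = 12  # enumeration bound: 2**12 x 2**12 dense design


def _site_subsets(n_sites: int) -> list[tuple[int, ...]]:
    """All site subsets grouped by ascending order, lexicographic within."""
    subsets: list[tuple[int, ...]] = []
    for k in range(n_sites + 1):
        subsets.extend(combinations(range(n_sites), k))
    return subsets


@dataclass
class DesignMatrix:
    """Square design matrix over all site subsets in canonical order."""

    basis: str
    n_sites: int
    subsets: list[tuple[int, ...]]
    matrix: np.ndarray

    @property
    def orders(self) -> np.ndarray:
        return np.array([len(s) for s in self.subsets])


@dataclass
class EpistasisCoefficients:
    """Epistatic coefficients ``beta``, one per site subset."""

    basis: str
    n_sites: int
    subsets: list[tuple[int, ...]]
    beta: np.ndarray

    @property
    def orders(self) -> np.ndarray:
        return np.array([len(s) for s in self.subsets])

    def of_order(self, k: int) -> np.ndarray:
        return self.beta[self.orders == k]


def build_design_matrix(n_sites: int, basis: str = "global") -> DesignMatrix:
    """Construct the global (Walsh/Hadamard, -1/+1) or local (0/1) design."""
    if not 1 <= n_sites <= _MAX_SITES:
        raise ValueError(f"n_sites must be in [1, {_MAX_SITES}], got {n_sites}")
    if basis not in ("global", "local"):
        raise ValueError(f"basis must be 'global' or 'local', got {basis!r}")
    x = genotype_matrix(n_sites)
    enc = 2.0 * x - 1.0 if basis == "global" else x
    subsets = _site_subsets(n_sites)
    n = 2**n_sites
    X = np.empty((n, n))
    for col, S in enumerate(subsets):
        X[:, col] = enc[:, S].prod(axis=1) if S else 1.0
    return DesignMatrix(basis=basis, n_sites=n_sites, subsets=subsets, matrix=X)


def decompose(f_linear: np.ndarray, design: DesignMatrix) -> EpistasisCoefficients:
    """Solve ``beta = X^-1 @ F_linear`` exactly.

    The global basis uses the analytic inverse ``X.T / 2**L``; the local basis
    a direct solve.
    """
    f = np.asarray(f_linear, dtype=float)
    if f.shape != (2**design.n_sites,):
        raise ValueError(
            f"fitness vector has shape {f.shape}, expected ({2**design.n_sites},)"
        )
    if design.basis == "global":
        beta = design.matrix.T @ f / 2**design.n_sites
    else:
        beta = np.linalg.solve(design.matrix, f)
    return EpistasisCoefficients(
        basis=design.basis, n_sites=design.n_sites, subsets=design.subsets, beta=beta
    )


def truncate(coeffs: EpistasisCoefficients, max_order: int) -> EpistasisCoefficients:
    """Zero all coefficients of order greater than ``max_order``."""
    if not 0 <= max_order <= coeffs.n_sites:
        raise ValueError(
            f"max_order must be in [0, {coeffs.n_sites}], got {max_order}"
        )
    beta = coeffs.beta.copy()
    beta[coeffs.orders > max_order] = 0.0
    return replace(coeffs, beta=beta)


def recompose(coeffs: EpistasisCoefficients, design: DesignMatrix) -> np.ndarray:
    """``F_linear = X @ beta`` in canonical genotype order."""
    if coeffs.basis != design.basis or coeffs.n_sites != design.n_sites:
        raise ValueError(
            f"coefficients ({coeffs.basis}, L={coeffs.n_sites}) do not match "
            f"design ({design.basis}, L={design.n_sites})"
        )
    return design.matrix @ coeffs.beta


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either vector is constant."""
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


class EpistasisRemover(BaseEstimator):
    """Fit the scale-removal + decomposition pipeline once; truncate at will.

    Parameters
    ----------
    basis:
        ``"global"`` (Walsh/Hadamard, background-averaged) or ``"local"``
        (ancestral-referenced).  The variance partition is conventionally
        computed on the global basis; the local basis serves the
        predict-from-the-ancestor analysis.
    lam_bounds:
        Passed to :class:`~epiwalk.scale.PowerTransform`.

    Fitted attributes
    -----------------
    additive_ : AdditiveFit
    scale_ : PowerTransform
    f_linear_ : linearized observed fitness
    design_ : DesignMatrix
    coefficients_ : EpistasisCoefficients
    n_clipped_ : genotypes clipped to the domain floor during back-transforms
    """

    def __init__(self, basis: str = "global", lam_bounds=(1e-6, 10.0), ftol=1e-10):
        self.basis = basis
        self.lam_bounds = lam_bounds
        self.ftol = ftol

    def fit(self, gmap: GenotypeFitnessMap):
        self.map_ = gmap
        self.additive_ = fit_additive(gmap)
        self.scale_ = PowerTransform(lam_bounds=self.lam_bounds, ftol=self.ftol).fit(
            self.additive_.additive_fitness, gmap.fitness_mean
        )
        p = self.scale_.params_
        edge = p.lam * p.GM ** (p.lam - 1.0) * (gmap.fitness_mean - p.B) + 1.0
        self.n_clipped_ = int(np.sum(edge <= 0))
        self.f_linear_ = self.scale_.linearize(gmap.fitness_mean, clip=True)
        self.design_ = build_design_matrix(gmap.n_sites, self.basis)
        self.coefficients_ = decompose(self.f_linear_, self.design_)
        return self

    # -- truncation ----------------------------------------------------------

    def linear_truncation(self, max_order: int) -> np.ndarray:
        """Truncated model fitness on the linear scale."""
        return recompose(truncate(self.coefficients_, max_order), self.design_)

    def truncated_fitness(self, max_order: int) -> np.ndarray:
        """Truncated fitness back on the original (possibly nonlinear) scale."""
        f_lin = self.linear_truncation(max_order)
        self.n_clipped_ += int(np.sum(f_lin + self.scale_.A_ <= 0))
        return self.scale_.transform(f_lin, clip=True)

    def truncated_map(self, max_order: int) -> GenotypeFitnessMap:
        """Map with epistasis above ``max_order`` removed, stds copied."""
        name = f"{self.map_.name}|trunc<={max_order}({self.basis})"
        return self.map_.with_means(self.truncated_fitness(max_order), name=name)

    # -- variance partition --------------------------------------------------

    def rho_squared(self, order: int) -> float:
        if order == 0:
            return 0.0
        return _squared_pearson(self.f_linear_, self.linear_truncation(order))

    def phi(self, order: int) -> float:
        if not 1 <= order <= self.map_.n_sites:
            raise ValueError(f"order must be in [1, {self.map_.n_sites}], got {order}")
        return self.rho_squared(order) - self.rho_squared(order - 1)

    def phi_profile(self) -> np.ndarray:
        """phi for orders 1..L."""
        rho = [self.rho_squared(k) for k in range(self.map_.n_sites + 1)]
        return np.diff(rho)


# -- functional wrappers -----------------------------------------------------


def truncated_map(
    gmap: GenotypeFitnessMap, max_order: int, basis: str = "global"
) -> GenotypeFitnessMap:
    """Run the full removal protocol and return the truncated map."""
    return EpistasisRemover(basis=basis).fit(gmap).truncated_map(max_order)


def phi(gmap: GenotypeFitnessMap, order: int, basis: str = "global") -> float:
    """Extra variance fraction explained by order-``order`` coefficients."""
    return EpistasisRemover(basis=basis).fit(gmap).phi(order)


def phi_profile(gmap: GenotypeFitnessMap, basis: str = "global") -> np.ndarray:
    """phi for every order 1..L of a map (one shared scale fit)."""
    return EpistasisRemover(basis=basis).fit(gmap).phi_profile()


def phi_from_linear(f_linear: np.ndarray, basis: str = "global") -> np.ndarray:
    """Variance partition of an already-linear fitness vector (no scale fit).

    Used by synthetic-data oracles where the linear-scale truth is known:
    with the orthogonal global basis the partition equals each order's share
    of Var(F_linear) exactly.
    """
    f = np.asarray(f_linear, dtype=float)
    L = int(np.log2(f.size))
    design = build_design_matrix(L, basis)
    coeffs = decompose(f, design)
    rho = [0.0] + [
        _squared_pearson(f, recompose(truncate(coeffs, k), design))
        for k in range(1, L + 1)
    ]
    return np.diff(rho)
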