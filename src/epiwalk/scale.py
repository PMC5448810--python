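"""Additive model and power-transform scale for genotype-fitness maps.

Observed fitness often combines on a nonlinear scale: mutational effects may
multiply rather than add, and failing to remove that global curvature inflates
apparent epistasis.  The scale model used here is a power transform linking the
additive expectation ``F_add`` to the observed fitness ``F_obs``::

    F_obs = ((F_add + A)**lam - 1) / (lam * GM**(lam - 1)) + B

where ``A`` and ``B`` are translation constants, ``lam`` is the shape
parameter, and ``GM`` is the geometric mean of ``F_add + A`` (a deterministic
function of ``A`` and the additive fit, not a free parameter).  ``lam = 1``
reduces the transform to an affine map; ``lam != 1`` bends it monotonically.

Removing the scale ("linearizing") applies the inverse transform to the
observed fitness, leaving a map on which a linear epistasis decomposition is
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression

from .map_io import GenotypeFitnessMap, genotype_matrix

__all__ = [
    "AdditiveFit",
    "AdditiveFitnessModel",
    "PowerTransformParams",
    "PowerTransform",
    "PowerFitError",
    "ScaleDomainError",
    "fit_additive",
    "fit_power_transform",
    "transform",
    "linearize",
]


class ScaleDomainError(ValueError):
    """A value lies outside the domain of the (inverse) power transform."""


class PowerFitError(RuntimeError):
    """Power-transform optimizer failed to converge.

    Carries the best parameters found so far in ``params`` and the scipy
    result object in ``result``.
    """

    def __init__(self, message, params=None, result=None):
        super().__init__(message)
        self.params = params
        self.result = result


# -- additive model ----------------------------------------------------------


@dataclass
class AdditiveFit:
    """Least-squares additive model of a map.

    ``mean_effects[j]`` is the average effect of mutation j across all
    backgrounds; ``additive_fitness`` the per-genotype prediction
    ``intercept + sum_j mean_effects[j] * x_ij``.
    """

    intercept: float
    mean_effects: np.ndarray
    additive_fitness: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.mean_effects)


class AdditiveFitnessModel(RegressorMixin, BaseEstimator):
    """Ordinary least-squares fit of per-site average mutational effects.

    X is the ``n x L`` 0/1 mutation-indicator matrix, y the fitness vector.
    Fitted attributes: ``effects_`` (per-site average effect), ``intercept_``.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        reg = LinearRegression().fit(X, y)
        self.effects_ = reg.coef_.copy()
        self.intercept_ = float(reg.intercept_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.effects_ + self.intercept_


def fit_additive(gmap: GenotypeFitnessMap) -> AdditiveFit:
    """Fit the additive model to a complete map's mean fitness values."""
    X = genotype_matrix(gmap.n_sites)
    model = AdditiveFitnessModel().fit(X, gmap.fitness_mean)
    return AdditiveFit(
        intercept=model.intercept_,
        mean_effects=model.effects_,
        additive_fitness=model.predict(X),
    )


# -- power transform ---------------------------------------------------------


@dataclass
class PowerTransformParams:
    """Fitted scale parameters. ``GM`` is the geometric mean of ``F_add + A``."""

    lam: float
    A: float
    B: float
    GM: float

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "A": self.A, "B": self.B, "GM": self.GM}

    @classmethod
    def from_dict(cls, d: dict) -> "PowerTransformParams":
        return cls(lam=d.get("lambda", d.get("lam")), A=d["A"], B=d["B"], GM=d["GM"])


def transform(values, params: PowerTransformParams, clip: bool = False) -> np.ndarray:
    """Forward power transform: additive/linear scale -> observed scale.

    With ``clip=True`` a non-positive base ``values + A`` is clipped to a tiny
    positive floor instead of raising (used when back-transforming truncated
    fitness that strays outside the fitted domain; callers count the clips).
    """
    v = np.asarray(values, dtype=float)
    base = v + params.A
    if np.any(base <= 0):
        if not clip:
            bad = int(np.flatnonzero(base <= 0)[0])
            raise ScaleDomainError(
                f"value {v.flat[bad]:g} at position {bad} gives non-positive "
                f"base {base.flat[bad]:g} under A={params.A:g}"
            )
        base = np.maximum(base, 1e-9)
    return (base**params.lam - 1.0) / (params.lam * params.GM ** (params.lam - 1.0)) + params.B


def linearize(values, params: PowerTransformParams, clip: bool = False) -> np.ndarray:
    """Inverse power transform: observed scale -> linear (additive) scale.

    With ``clip=True`` an observed value below the transform's infimum (whose
    bracketed base is non-positive) is clipped to a tiny positive base — the
    domain edge maps to ``-A``, so a marginal overshoot lands near there —
    instead of raising.  Callers count the clips.
    """
    v = np.asarray(values, dtype=float)
    base = params.lam * params.GM ** (params.lam - 1.0) * (v - params.B) + 1.0
    if np.any(base <= 0):
        if not clip:
            bad = int(np.flatnonzero(base <= 0)[0])
            raise ScaleDomainError(
                f"value {v.flat[bad]:g} at position {bad} gives non-positive "
                f"base {base.flat[bad]:g}; cannot linearize"
            )
        base = np.maximum(base, 1e-9)
    return base ** (1.0 / params.lam) - params.A


class PowerTransform(BaseEstimator):
    """Bounded nonlinear least-squares fit of the power-transform scale.

    Parameters
    ----------
    lam_bounds:
        Bounds for the shape parameter; the lower bound stays positive so the
        transform is strictly increasing on its domain.
    ftol:
        Convergence tolerance on the objective.

    Fitted attributes: ``lam_``, ``A_``, ``B_``, ``GM_``, ``rss_``,
    ``params_`` (a :class:`PowerTransformParams`).  The fit is deterministic:
    fixed initialization (``lam=1``, small positive base shift, ``B=0``) and no
    randomness.
    """

    def __init__(self, lam_bounds=(1e-6, 10.0), ftol=1e-10, max_nfev=20_000):
        self.lam_bounds = lam_bounds
        self.ftol = ftol
        self.max_nfev = max_nfev

    def fit(self, f_add, f_obs):
        f_add = np.asarray(f_add, dtype=float)
        f_obs = np.asarray(f_obs, dtype=float)
        fmin = f_add.min()
        span = max(np.ptp(f_add), 1.0)

        def residuals(p):
            lam, A, B = p
            base = f_add + A
            gm = np.exp(np.mean(np.log(base)))
            pred = (base**lam - 1.0) / (lam * gm ** (lam - 1.0)) + B
            return pred - f_obs

        def jacobian(p):
            lam, A, _ = p
            base = f_add + A
            log_base = np.log(base)
            gm = np.exp(np.mean(log_base))
            powered = base**lam
            denom = lam * gm ** (lam - 1.0)
            num = powered - 1.0
            # d(denom)/dlam and d(denom)/dA; gm depends on A through the mean log
            dgm_dA = gm * np.mean(1.0 / base)
            ddenom_dlam = gm ** (lam - 1.0) * (1.0 + lam * np.log(gm))
            ddenom_dA = lam * (lam - 1.0) * gm ** (lam - 2.0) * dgm_dA
            J = np.empty((f_add.size, 3))
            J[:, 0] = (powered * log_base * denom - num * ddenom_dlam) / denom**2
            J[:, 1] = (lam * base ** (lam - 1.0) * denom - num * ddenom_dA) / denom**2
            J[:, 2] = 1.0
            return J

        a_lower = -fmin + 1e-9 * span
        x0 = np.array([1.0, max(-fmin + 1e-3 * span, 1e-6), 0.0])
        x0[1] = max(x0[1], a_lower * (1 + 1e-6) + 1e-12)
        res = least_squares(
            residuals,
            x0,
            jac=jacobian,
            bounds=([self.lam_bounds[0], a_lower, -np.inf],
                    [self.lam_bounds[1], np.inf, np.inf]),
            ftol=self.ftol,
            xtol=self.ftol,
            gtol=self.ftol,
            x_scale="jac",
            max_nfev=self.max_nfev,
        )
        lam, A, B = res.x
        gm = float(np.exp(np.mean(np.log(f_add + A))))
        params = PowerTransformParams(lam=float(lam), A=float(A), B=float(B), GM=gm)
        if res.status <= 0:
            raise PowerFitError(
                f"power-transform fit did not converge: {res.message}",
                params=params,
                result=res,
            )
        self.lam_ = params.lam
        self.A_ = params.A
        self.B_ = params.B
        self.GM_ = params.GM
        self.rss_ = float(np.sum(res.fun**2))
        self.params_ = params
        self.result_ = res
        return self

    def transform(self, values, clip: bool = False) -> np.ndarray:
        return transform(values, self.params_, clip=clip)

    def linearize(self, values, clip: bool = False) -> np.ndarray:
        return linearize(values, self.params_, clip=clip)

    # alias so the estimator composes with sklearn-style pipelines
    inverse_transform = linearize


def fit_power_transform(add: AdditiveFit, gmap: GenotypeFitnessMap, **kwargs) -> PowerTransform:
    """Fit the scale linking an additive fit to a map's observed fitness."""
    return PowerTransform(**kwargs).fit(add.additive_fitness, gmap.fitness_mean)
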