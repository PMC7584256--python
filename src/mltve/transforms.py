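"""Differentiable variable transformations with derivative bookkeeping.

Effect decomposition on an additive model consumes both the transformed
predictor blocks f(x) and their first derivatives f'(x); every transform here
therefore evaluates values *and* exact first derivatives at arbitrary points.
Analytic derivatives are used for identity/log/polynomial/truncation and for
the natural cubic spline (piecewise-polynomial differentiation); user-supplied
transforms without a derivative function fall back to central finite
differences with step 1e-6 x the local scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = ["TransformSpec", "Transform", "make_transform"]


@dataclass(frozen=True)
class TransformSpec:
    """Declarative description of a transformation.

    Parameters
    ----------
    kind
        One of ``identity``, ``log``, ``polynomial``, ``ns`` (natural cubic
        spline), ``truncation`` (two-piece hinge), ``indicator`` (reference
        coding of a categorical), ``user``.
    degree
        Polynomial degree (``polynomial`` only).
    df
        Basis dimension for ``ns``; interior knots are placed at quantiles.
    knots
        Explicit interior knots for ``ns`` (overrides ``df``).
    threshold
        Change point for ``truncation``: columns min(x, t) and max(x - t, 0).
    reference
        Reference level for ``indicator``; defaults to the first sorted level.
    value_fn, derivative_fn
        Callables for ``user`` transforms, mapping an array to an (n, c) basis.
    """

    kind: str
    degree: Optional[int] = None
    df: Optional[int] = None
    knots: Optional[Sequence[float]] = None
    threshold: Optional[float] = None
    reference: Optional[object] = None
    value_fn: Optional[Callable] = None
    derivative_fn: Optional[Callable] = None

    _KINDS = ("identity", "log", "polynomial", "ns", "truncation", "indicator", "user")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ConfigurationError(f"unknown transform kind {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "polynomial" and (self.degree is None or self.degree < 1):
            raise ConfigurationError("polynomial transform requires degree >= 1")
        if self.kind == "ns" and self.knots is None and (self.df is None or self.df < 1):
            raise ConfigurationError("natural cubic spline requires df >= 1 or explicit knots")
        if self.kind == "truncation" and self.threshold is None:
            raise ConfigurationError("truncation transform requires a threshold")
        if self.kind == "user" and self.value_fn is None:
            raise ConfigurationError("user transform requires value_fn")


class Transform:
    """A fitted transformation: evaluates basis values and first derivatives.

    Subclasses fix ``n_columns`` at construction; ``values`` and
    ``derivatives`` return (n, n_columns) arrays of identical shape and
    column order.
    """

    n_columns: int
    spec: TransformSpec

    def values(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def derivatives(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def column_names(self, var: str) -> list[str]:
        if self.n_columns == 1:
            return [var]
        return [f"{var}.{i + 1}" for i in range(self.n_columns)]

    @staticmethod
    def _as2d(a) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return a.reshape(-1, 1) if a.ndim == 1 else a


class IdentityTransform(Transform):
    n_columns = 1

    def __init__(self, spec: TransformSpec):
        self.spec = spec

    def values(self, x):
        return self._as2d(x).copy()

    def derivatives(self, x):
        return np.ones((np.asarray(x).size, 1))


class LogTransform(Transform):
    n_columns = 1

    def __init__(self, spec: TransformSpec):
        self.spec = spec

    def values(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            bad = int(np.flatnonzero(x <= 0)[0])
            raise DomainError(f"log transform requires positive values; offending row {bad} (value {x.ravel()[bad]})")
        return self._as2d(np.log(x))

    def derivatives(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise DomainError("log transform derivative requires positive values")
        return self._as2d(1.0 / x)


class PolynomialTransform(Transform):
    """Raw polynomial basis (x, x^2, ..., x^degree), no intercept column."""

    def __init__(self, spec: TransformSpec):
        self.spec = spec
        self.degree = int(spec.degree)
        self.n_columns = self.degree

    def values(self, x):
        x = np.asarray(x, dtype=float).ravel()
        return np.column_stack([x ** p for p in range(1, self.degree + 1)])

    def derivatives(self, x):
        x = np.asarray(x, dtype=float).ravel()
        return np.column_stack([p * x ** (p - 1) for p in range(1, self.degree + 1)])


class TruncationTransform(Transform):
    """Two-piece hinge pair around a change point t: (min(x, t), max(x - t, 0)).

    The fitted curve is continuous piecewise-linear with a slope change at t;
    at exactly x = t the derivative is taken from the left piece, i.e. (1, 0).
    """

    n_columns = 2

    def __init__(self, spec: TransformSpec):
        self.spec = spec
        self.t = float(spec.threshold)

    def values(self, x):
        x = np.asarray(x, dtype=float).ravel()
        return np.column_stack([np.minimum(x, self.t), np.maximum(x - self.t, 0.0)])

    def derivatives(self, x):
        x = np.asarray(x, dtype=float).ravel()
        below = x <= self.t
        return np.column_stack([below.astype(float), (~below).astype(float)])


class NaturalCubicSplineTransform(Transform):
    """Natural cubic spline basis in the truncated-power formulation.

    ``df`` basis columns (no intercept) use df - 1 interior knots at the
    quantiles of the fit data, with boundary knots at the data min/max. The
    basis is linear beyond the boundary knots; derivatives are the exact
    piecewise-polynomial derivatives.
    """

    def __init__(self, spec: TransformSpec, fit_values: np.ndarray):
        self.spec = spec
        x = np.asarray(fit_values, dtype=float).ravel()
        if spec.knots is not None:
            interior = np.sort(np.asarray(spec.knots, dtype=float))
        else:
            n_int = int(spec.df) - 1
            if n_int > 0:
                qs = np.linspace(0, 1, n_int + 2)[1:-1]
                interior = np.quantile(x, qs)
            else:
                interior = np.empty(0)
        self.knots = np.concatenate([[x.min()], interior, [x.max()]])
        if np.unique(self.knots).size != self.knots.size:
            raise ConfigurationError("natural cubic spline knots are not distinct; reduce df")
        self.n_columns = self.knots.size - 1

    def _d(self, x, k, deriv):
        # d_k(x) = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k)
        xiK = self.knots[-1]
        num = (
            np.maximum(x - self.knots[k], 0.0) ** 3 - np.maximum(x - xiK, 0.0) ** 3
            if not deriv
            else 3 * np.maximum(x - self.knots[k], 0.0) ** 2 - 3 * np.maximum(x - xiK, 0.0) ** 2
        )
        return num / (xiK - self.knots[k])

    def _basis(self, x, deriv):
        x = np.asarray(x, dtype=float).ravel()
        cols = [np.ones_like(x) if deriv else x]
        K = self.knots.size
        dKm1 = self._d(x, K - 2, deriv)
        for k in range(K - 2):
            cols.append(self._d(x, k, deriv) - dKm1)
        return np.column_stack(cols[: self.n_columns])

    def values(self, x):
        return self._basis(x, deriv=False)

    def derivatives(self, x):
        return self._basis(x, deriv=True)


class IndicatorTransform(Transform):
    """Reference coding of a categorical: k levels -> k-1 zero/one indicators."""

    def __init__(self, spec: TransformSpec, fit_values):
        self.spec = spec
        levels = sorted(set(np.asarray(fit_values).ravel().tolist()))
        if len(levels) < 2:
            raise ConfigurationError("indicator transform requires at least 2 distinct levels")
        ref = spec.reference if spec.reference is not None else levels[0]
        if ref not in levels:
            raise ConfigurationError(f"reference level {ref!r} not among observed levels {levels}")
        self.reference = ref
        self.levels = [l for l in levels if l != ref]
        self.n_columns = len(self.levels)

    def values(self, x):
        x = np.asarray(x).ravel()
        return np.column_stack([(x == lvl).astype(float) for lvl in self.levels])

    def derivatives(self, x):
        # categorical: no continuous derivative; effects use unit-step differences
        return np.zeros((np.asarray(x).size, self.n_columns))

    def column_names(self, var):
        return [f"{var}[{lvl}]" for lvl in self.levels]


class UserTransform(Transform):
    def __init__(self, spec: TransformSpec, fit_values):
        self.spec = spec
        probe = self._as2d(spec.value_fn(np.asarray(fit_values, dtype=float).ravel()[:1]))
        self.n_columns = probe.shape[1]

    def values(self, x):
        return self._as2d(self.spec.value_fn(np.asarray(x, dtype=float).ravel()))

    def derivatives(self, x):
        x = np.asarray(x, dtype=float).ravel()
        if self.spec.derivative_fn is not None:
            return self._as2d(self.spec.derivative_fn(x))
        h = 1e-6 * np.maximum(np.abs(x), 1.0)
        return (self.values(x + h) - self.values(x - h)) / (2 * h)[:, None]


def make_transform(spec: TransformSpec, fit_values) -> Transform:
    """Fit a transform to data (knot placement, level discovery) and return it.

    ``fit_values`` supplies knot-placement data for splines and the level set
    for indicators; for ``log`` it is checked for positivity up front.
    """
    fit_values = np.asarray(fit_values)
    if spec.kind == "identity":
        return IdentityTransform(spec)
    if spec.kind == "log":
        t = LogTransform(spec)
        t.values(fit_values.astype(float))  # domain check at fit time
        return t
    if spec.kind == "polynomial":
        return PolynomialTransform(spec)
    if spec.kind == "ns":
        return NaturalCubicSplineTransform(spec, fit_values)
    if spec.kind == "truncation":
        return TruncationTransform(spec)
    if spec.kind == "indicator":
        return IndicatorTransform(spec, fit_values)
    if spec.kind == "user":
        return UserTransform(spec, fit_values)
    raise ConfigurationError(f"unknown transform kind {spec.kind!r}")  # pragma: no cover
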