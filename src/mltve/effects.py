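"""Total, direct and indirect effect decomposition on a fitted model system.

Effects are defined as changing rates of the expected outcome in the
exposure: the derivative for a continuous exposure, the unit-step difference
quotient (f(x + u*) - f(x)) / u* with minimum unit u* for a discrete one. On
the additive model system they have closed forms:

level-1 exposure x, per record (i, j):

    DE1(x)    = b1' f1e'(x)
    IE1_k(x)  = [a_k' f1ke1'(x) . (dg^-1/deta)(eta_ijk)] * [b3k' f3k'(m_ijk)]
    TE1(x)    = DE1(x) + sum_k IE1_k(x)

level-2 exposure x, per group j:

    DE2(x)    = b2' f2e'(x)
    IE22_l(x) = [a_l' f2le'(x) . (dg^-1/deta)(eta_jl)] * [b4l' f4l'(m_jl)]
    IE21_k(x) = [a_k' f2ke1'(x)] * E_i[(dg^-1/deta)(eta_ijk) . b3k' f3k'(m_ijk)]
    TE2(x)    = DE2(x) + sum_k IE21_k(x) + sum_l IE22_l(x)

where a are the exposure coefficients of the third-variable models, b the
outcome-model coefficients, f' the transformation derivatives (or unit-step
differences), and the link inverse-derivative is evaluated at the fitted
linear predictor. Only level-1 third-variables carry level-1 exposure
effects. Averaging is over level-1 records (level 1) or unweighted over
groups (level 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .exceptions import ConfigurationError, MltveError
from .models import ModelSystem
from .transforms import Transform

logger = logging.getLogger(__name__)

RELATIVE_EFFECT_ATE_FLOOR = 1e-12


@dataclass(frozen=True)
class ExposureStep:
    """How the difference quotient is taken for one exposure.

    ``continuous`` uses the exact derivative (the u -> 0 limit); ``discrete``
    uses the unit-step difference with minimum unit ``u_star`` (1 for binary
    or categorical exposures).
    """

    exposure: str
    kind: str = "continuous"  # or "discrete"
    u_star: float = 1.0

    def __post_init__(self):
        if self.kind not in ("continuous", "discrete"):
            raise ConfigurationError(f"exposure step kind must be continuous|discrete, got {self.kind!r}")


def default_step(system: ModelSystem, exposure: str) -> ExposureStep:
    kind = "discrete" if system.dataset.is_binary(exposure) else "continuous"
    return ExposureStep(exposure, kind)


def _delta(transform: Transform, x: np.ndarray, step: ExposureStep) -> np.ndarray:
    """f'(x) for continuous exposures, (f(x+u*) - f(x))/u* for discrete ones."""
    x = np.asarray(x, dtype=float)
    if step.kind == "continuous":
        return transform.derivatives(x)
    u = step.u_star
    return (transform.values(x + u) - transform.values(x)) / u


@dataclass
class EffectCurves:
    """Per-record (level 1) or per-group (level 2) effect components.

    ``te = de + sum(ie.values())`` element-wise by construction of the
    decomposition; the identity is checked at construction.
    """

    level: int
    exposure: str
    eval_points: np.ndarray
    de: np.ndarray
    ie: Dict[str, np.ndarray]
    te: np.ndarray = field(init=False)

    def __post_init__(self):
        self.te = self.de + (np.sum(list(self.ie.values()), axis=0) if self.ie else 0.0)
        for comp in (self.de, *self.ie.values()):
            if comp.shape != self.eval_points.shape:
                raise MltveError("effect component length mismatch")


@dataclass
class EffectSummary:
    """Averaged effects: ATE = ADE + sum AIE; relative = component / ATE."""

    level: int
    exposure: str
    ate: float
    ade: float
    aie: Dict[str, float]
    relative_effects: Optional[Dict[str, float]]  # None when |ATE| ~ 0


def _mediator_model(system: ModelSystem, name: str):
    try:
        return system.mediator_models[name]
    except KeyError:
        raise MltveError(f"internal consistency error: no fitted model for third-variable {name!r}")


def level1_effects(system: ModelSystem, exposure: str, step: Optional[ExposureStep] = None) -> EffectCurves:
    """Effects of a level-1 exposure, one value per level-1 record.

    Only level-1 third-variables contribute indirect paths.
    """
    ds = system.dataset
    if exposure not in ds.roles.exposures_l1:
        raise ConfigurationError(f"{exposure!r} is not a declared level-1 exposure")
    step = step or default_step(system, exposure)
    x = ds.column(exposure).astype(float)
    out = system.outcome_model

    de = _delta(system.design.outcome["f1e"][exposure].transform, x, step) @ out.coefficients[exposure]
    ie = {}
    for k in ds.roles.mediators_l1:
        mm = _mediator_model(system, k)
        a = _delta(system.design.mediator[k]["f1ke1"][exposure].transform, x, step) \
            @ mm.exposure_coefficients[exposure]
        link_fac = mm.link.inverse_derivative(mm.fitted_linear_predictor)
        b = system.design.outcome["f3k"][k].derivs @ out.coefficients[k]
        ie[k] = a * link_fac * b
    return EffectCurves(level=1, exposure=exposure, eval_points=x, de=de, ie=ie)


def level2_effects(system: ModelSystem, exposure: str, step: Optional[ExposureStep] = None) -> EffectCurves:
    """Effects of a level-2 exposure, one value per group.

    Level-2 third-variables contribute through their group-level models
    (IE22); level-1 third-variables contribute with the outcome-side factor
    averaged over the group's records (IE21).
    """
    ds = system.dataset
    if exposure not in ds.roles.exposures_l2:
        raise ConfigurationError(f"{exposure!r} is not a declared level-2 exposure")
    step = step or default_step(system, exposure)
    x = ds.group_level(exposure).astype(float)
    gf = ds.group_first
    out = system.outcome_model

    de = _delta(system.design.outcome["f2e"][exposure].transform, x, step) @ out.coefficients[exposure]
    ie = {}
    for l in ds.roles.mediators_l2:
        mm = _mediator_model(system, l)
        a = _delta(system.design.mediator[l]["f2le"][exposure].transform, x, step) \
            @ mm.exposure_coefficients[exposure]
        link_fac = mm.link.inverse_derivative(mm.fitted_linear_predictor)  # per group
        b = (system.design.outcome["f4l"][l].derivs @ out.coefficients[l])[gf]
        ie[l] = a * link_fac * b
    for k in ds.roles.mediators_l1:
        mm = _mediator_model(system, k)
        a = _delta(system.design.mediator[k]["f2ke1"][exposure].transform, x, step) \
            @ mm.exposure_coefficients[exposure]
        inner = mm.link.inverse_derivative(mm.fitted_linear_predictor) \
            * (system.design.outcome["f3k"][k].derivs @ out.coefficients[k])
        inner_mean = np.bincount(ds.group_codes, weights=inner, minlength=ds.n_groups) / ds.group_sizes
        ie[k] = a * inner_mean
    return EffectCurves(level=2, exposure=exposure, eval_points=x, de=de, ie=ie)


def average_effects(curves: EffectCurves) -> EffectSummary:
    """Average over level-1 records (level 1) or unweighted over groups."""
    ate = float(np.mean(curves.te))
    ade = float(np.mean(curves.de))
    aie = {k: float(np.mean(v)) for k, v in curves.ie.items()}
    if abs(ate) < RELATIVE_EFFECT_ATE_FLOOR:
        rel = None
    else:
        rel = {"de": ade / ate, **{k: v / ate for k, v in aie.items()}}
    return EffectSummary(curves.level, curves.exposure, ate, ade, aie, rel)


def effect_grid(system: ModelSystem, exposure: str, grid, step: Optional[ExposureStep] = None) -> EffectCurves:
    """Evaluate effect-vs-exposure curves on a supplied grid.

    Record-dependent factors that do not depend on the exposure value (the
    outcome-side derivative of each third-variable, and the other predictors'
    contribution to a logistic third-variable's linear predictor) are
    averaged over the observed data, so for identity links the grid curves
    coincide with the closed-form curves.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ConfigurationError("effect grid is empty")
    ds = system.dataset
    if exposure in ds.roles.exposures_l1:
        level, x_obs = 1, ds.column(exposure).astype(float)
    elif exposure in ds.roles.exposures_l2:
        level, x_obs = 2, ds.group_level(exposure).astype(float)
    else:
        raise ConfigurationError(f"{exposure!r} is not a declared exposure")
    if grid.min() < x_obs.min() or grid.max() > x_obs.max():
        logger.warning("effect grid for %r extends beyond the observed range [%g, %g]",
                       exposure, x_obs.min(), x_obs.max())
    step = step or default_step(system, exposure)
    out = system.outcome_model

    eblock = "f1e" if level == 1 else "f2e"
    de = _delta(system.design.outcome[eblock][exposure].transform, grid, step) @ out.coefficients[exposure]

    ie = {}
    mediators = ds.roles.mediators_l1 if level == 1 else (ds.roles.mediators_l2 + ds.roles.mediators_l1)
    for k in mediators:
        mm = _mediator_model(system, k)
        mblock = {1: "f1ke1", 2: "f2ke1" if mm.level == 1 else "f2le"}[level]
        tr = system.design.mediator[k][mblock][exposure].transform
        a = _delta(tr, grid, step) @ mm.exposure_coefficients[exposure]
        if mm.level == 1:
            b = float(np.mean(system.design.outcome["f3k"][k].derivs @ out.coefficients[k]))
        else:
            b = float(np.mean((system.design.outcome["f4l"][k].derivs @ out.coefficients[k])[ds.group_first]))
        if mm.link.name == "identity":
            link_fac = np.ones_like(grid)
        else:
            # linear predictor on the grid: swap in the exposure's own
            # contribution, keep everything else at its observed average
            contrib_obs = tr.values(x_obs) @ mm.exposure_coefficients[exposure]
            base = float(np.mean(mm.fitted_linear_predictor)) - float(np.mean(contrib_obs))
            eta_grid = base + tr.values(grid) @ mm.exposure_coefficients[exposure]
            link_fac = mm.link.inverse_derivative(eta_grid)
        ie[k] = a * link_fac * b
    return EffectCurves(level=level, exposure=exposure, eval_points=grid, de=de, ie=ie)


# ---------------------------------------------------------------------------
# flat summaries (shared by the bootstrap and the CLI)

def component_key(level: int, comp: str, mediator: Optional[str], exposure: str, multi: bool) -> str:
    """Component names follow the convention te1/de1/ie1, te2/de2/ie2.1/ie2.2,
    with the third-variable after a colon and the exposure appended only when
    several exposures share a level."""
    key = comp if mediator is None else f"{comp}:{mediator}"
    return f"{key}@{exposure}" if multi else key


def system_effect_summaries(system: ModelSystem) -> Dict[str, float]:
    """Flat {component key: averaged effect} over all exposures at both levels."""
    ds = system.dataset
    out: Dict[str, float] = {}
    multi1 = len(ds.roles.exposures_l1) > 1
    for e in ds.roles.exposures_l1:
        s = average_effects(level1_effects(system, e))
        out[component_key(1, "te1", None, e, multi1)] = s.ate
        out[component_key(1, "de1", None, e, multi1)] = s.ade
        for m, v in s.aie.items():
            out[component_key(1, "ie1", m, e, multi1)] = v
    multi2 = len(ds.roles.exposures_l2) > 1
    for e in ds.roles.exposures_l2:
        s = average_effects(level2_effects(system, e))
        out[component_key(2, "te2", None, e, multi2)] = s.ate
        out[component_key(2, "de2", None, e, multi2)] = s.ade
        for m, v in s.aie.items():
            comp = "ie2.1" if system.mediator_models[m].level == 1 else "ie2.2"
            out[component_key(2, comp, m, e, multi2)] = v
    return out
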