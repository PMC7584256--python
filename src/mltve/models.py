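"""The three-layer generalized additive mixed-model system.

Layer 1 — level-2 third-variable models: single-level GLMs of each group-level
third-variable on the transformed level-2 exposures (one record per group).

Layer 2 — level-1 third-variable models: random-intercept models of each
level-1 third-variable on the transformed level-1 and level-2 exposures
(linear mixed model for an identity link, adaptive-quadrature logistic GLMM
for a binary third-variable).

Layer 3 — the outcome model: a random-intercept model of Y on all transformed
exposures and third-variables plus covariates. The outcome link is identity
(continuous Y); the link abstraction is carried so other links can be added.

Effect decomposition only needs coefficients, link derivatives and fitted
linear predictors, which every fitted layer exposes uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional

import numpy as np
import statsmodels.api as sm

from ._glmm import fit_logistic_glmm
from ._lmm import fit_random_intercept_lm
from .exceptions import ConfigurationError, ConvergenceError, ValidationError
from .hierdata import HierarchicalDataset, PreparedDesign, prepare_design
from scipy.special import expit

__all__ = [
    "LinkFunction", "IDENTITY_LINK", "LOGIT_LINK",
    "FittedMediatorModel", "FittedOutcomeModel", "ModelSystem",
    "fit_level2_mediator", "fit_level1_mediator", "fit_outcome", "fit_system",
]


@dataclass(frozen=True)
class LinkFunction:
    """g maps the mean to the linear predictor; the effect formulas consume
    d g^-1 / d eta evaluated at the fitted linear predictor."""

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    inverse_derivative: Callable[[np.ndarray], np.ndarray]


IDENTITY_LINK = LinkFunction(
    "identity", forward=lambda mu: mu, inverse=lambda eta: eta,
    inverse_derivative=lambda eta: np.ones_like(np.asarray(eta, dtype=float)),
)
LOGIT_LINK = LinkFunction(
    "logit",
    forward=lambda mu: np.log(mu / (1 - mu)),
    inverse=expit,
    inverse_derivative=lambda eta: expit(eta) * (1 - expit(eta)),
)


@dataclass
class FittedMediatorModel:
    target: str
    level: int  # 1 or 2
    link: LinkFunction
    intercept: float
    # exposure -> coefficient vector over that exposure's basis columns
    exposure_coefficients: Dict[str, np.ndarray]
    fitted_linear_predictor: np.ndarray  # per record (level 1) or per group (level 2)
    random_intercept_variance: Optional[float] = None  # level-1 targets only
    residual_variance: Optional[float] = None
    boundary: bool = False
    standard_errors: Optional[Dict[str, np.ndarray]] = None

    @property
    def fitted_mean(self):
        return self.link.inverse(self.fitted_linear_predictor)


@dataclass
class FittedOutcomeModel:
    intercept: float
    # variable -> coefficient vector over its basis columns (exposures and mediators)
    coefficients: Dict[str, np.ndarray]
    covariate_coefficients: Dict[str, float]
    random_intercept_variance: float
    residual_variance: float
    link: LinkFunction
    fitted_linear_predictor: np.ndarray
    boundary: bool = False
    standard_errors: Optional[Dict[str, np.ndarray]] = None


@dataclass
class ModelSystem:
    design: PreparedDesign
    mediator_models: Dict[str, FittedMediatorModel]
    outcome_model: FittedOutcomeModel
    convergence_report: Dict[str, dict] = field(default_factory=dict)

    @property
    def dataset(self) -> HierarchicalDataset:
        return self.design.dataset


def _stack(blocks: Mapping[str, "object"]):
    """Column-stack TransformedVar blocks; returns (matrix, names, slices per var)."""
    mats, names, slices, start = [], [], {}, 0
    for var, tv in blocks.items():
        mats.append(tv.values)
        names += tv.names
        slices[var] = slice(start, start + tv.values.shape[1])
        start += tv.values.shape[1]
    if not mats:
        return np.empty((0, 0)), names, slices
    return np.column_stack(mats), names, slices


def fit_level2_mediator(design: PreparedDesign, mediator: str, link: LinkFunction) -> FittedMediatorModel:
    """Single-level GLM of a group-level third-variable on transformed level-2
    exposures, one record per group (no random effects at the top level)."""
    ds = design.dataset
    if mediator not in ds.roles.mediators_l2:
        raise ConfigurationError(f"{mediator!r} is not a declared level-2 third-variable")
    if ds.n_groups < 2:
        raise ValidationError("level-2 model needs at least 2 groups")
    m = ds.group_level(mediator).astype(float)
    Xfull, names, slices = _stack(design.mediator[mediator]["f2le"])
    X = sm.add_constant(Xfull[ds.group_first], has_constant="add")

    if link.name == "identity":
        fam = sm.families.Gaussian()
    elif link.name == "logit":
        if np.ptp(m) == 0:
            raise ConvergenceError(f"level-2 third-variable {mediator!r} is constant: separation")
        fam = sm.families.Binomial()
    else:  # pragma: no cover
        raise ConfigurationError(f"unsupported mediator link {link.name!r}")
    try:
        res = sm.GLM(m, X, family=fam).fit()
    except Exception as e:
        raise ConvergenceError(f"level-2 model for {mediator!r} failed: {e}") from e
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 50:
        raise ConvergenceError(f"level-2 model for {mediator!r}: separation or divergence")

    coefs = {var: res.params[1:][sl] for var, sl in slices.items()}
    eta = X @ res.params
    resid_var = float(res.scale) if link.name == "identity" else None
    return FittedMediatorModel(
        target=mediator, level=2, link=link, intercept=float(res.params[0]),
        exposure_coefficients=coefs, fitted_linear_predictor=eta,
        residual_variance=resid_var,
        standard_errors={var: res.bse[1:][sl] for var, sl in slices.items()},
    )


def fit_level1_mediator(design: PreparedDesign, mediator: str, link: LinkFunction) -> FittedMediatorModel:
    """Random-intercept model of a level-1 third-variable on transformed
    level-1 and level-2 exposures (LMM for identity, AGHQ GLMM for logit)."""
    ds = design.dataset
    if mediator not in ds.roles.mediators_l1:
        raise ConfigurationError(f"{mediator!r} is not a declared level-1 third-variable")
    m = ds.column(mediator).astype(float)
    blocks = design.mediator[mediator]
    X1, n1, s1 = _stack(blocks["f1ke1"])
    X2, n2, s2 = _stack(blocks["f2ke1"])
    parts = [np.ones((ds.n_records, 1))] + [b for b in (X1, X2) if b.size]
    X = np.column_stack(parts)
    names = ["(intercept)"] + n1 + n2
    offset = 1
    slices = {}
    for var, sl in s1.items():
        slices[var] = slice(sl.start + offset, sl.stop + offset)
    for var, sl in s2.items():
        slices[var] = slice(sl.start + offset + X1.shape[1], sl.stop + offset + X1.shape[1])

    if link.name == "identity":
        fit = fit_random_intercept_lm(m, X, ds.group_codes, ds.n_groups, colnames=names)
        return FittedMediatorModel(
            target=mediator, level=1, link=link, intercept=float(fit.beta[0]),
            exposure_coefficients={v: fit.beta[sl] for v, sl in slices.items()},
            fitted_linear_predictor=fit.linear_predictor,
            random_intercept_variance=fit.sigma2_b, residual_variance=fit.sigma2_e,
            boundary=fit.boundary,
            standard_errors={v: fit.se[sl] for v, sl in slices.items()},
        )
    if link.name == "logit":
        fit = fit_logistic_glmm(m, X, ds.group_codes, ds.n_groups)
        if not fit.converged:
            raise ConvergenceError(f"logistic GLMM for {mediator!r} did not converge")
        return FittedMediatorModel(
            target=mediator, level=1, link=link, intercept=float(fit.beta[0]),
            exposure_coefficients={v: fit.beta[sl] for v, sl in slices.items()},
            fitted_linear_predictor=fit.linear_predictor,
            random_intercept_variance=fit.sigma2_b, boundary=fit.boundary,
        )
    raise ConfigurationError(f"unsupported mediator link {link.name!r}")  # pragma: no cover


def fit_outcome(design: PreparedDesign) -> FittedOutcomeModel:
    """Random-intercept model of Y on all transformed exposures and
    third-variables plus covariates (identity link)."""
    ds = design.dataset
    y = ds.column(ds.roles.outcome).astype(float)
    mats, names, slices = [np.ones((ds.n_records, 1))], ["(intercept)"], {}
    start = 1
    for block in ("f1e", "f2e", "f3k", "f4l"):
        for var, tv in design.outcome[block].items():
            mats.append(tv.values)
            names += tv.names
            slices[var] = slice(start, start + tv.values.shape[1])
            start += tv.values.shape[1]
    cov_slices = {}
    for z in ds.roles.covariates:
        mats.append(ds.column(z).astype(float)[:, None])
        names.append(z)
        cov_slices[z] = start
        start += 1
    X = np.column_stack(mats)
    fit = fit_random_intercept_lm(y, X, ds.group_codes, ds.n_groups, colnames=names)
    return FittedOutcomeModel(
        intercept=float(fit.beta[0]),
        coefficients={v: fit.beta[sl] for v, sl in slices.items()},
        covariate_coefficients={z: float(fit.beta[i]) for z, i in cov_slices.items()},
        random_intercept_variance=fit.sigma2_b, residual_variance=fit.sigma2_e,
        link=IDENTITY_LINK, fitted_linear_predictor=fit.linear_predictor,
        boundary=fit.boundary,
        standard_errors={v: fit.se[sl] for v, sl in slices.items()},
    )


def default_links(dataset: HierarchicalDataset) -> Dict[str, LinkFunction]:
    """Binary third-variables get logit, everything else identity."""
    out = {}
    for m in dataset.roles.mediators_l1 + dataset.roles.mediators_l2:
        out[m] = LOGIT_LINK if dataset.is_binary(m) else IDENTITY_LINK
    return out


def fit_system(
    dataset: HierarchicalDataset,
    transform_config: Optional[Mapping] = None,
    *,
    links: Optional[Mapping[str, LinkFunction]] = None,
    frozen_transforms: Optional[Mapping] = None,
) -> ModelSystem:
    """Prepare the design, fit every third-variable model and the outcome
    model, and assemble the system.

    Path legibility is structural: level-2 third-variable models contain only
    level-2 exposures, so a level-1 exposure can never route through a
    level-2 third-variable.
    """
    design = prepare_design(dataset, transform_config, frozen_transforms=frozen_transforms)
    links = {**default_links(dataset), **(links or {})}
    report: Dict[str, dict] = {}
    mediators: Dict[str, FittedMediatorModel] = {}

    for m in dataset.roles.mediators_l1:
        try:
            fit = fit_level1_mediator(design, m, links[m])
        except Exception as e:
            e.add_note(f"while fitting the level-1 third-variable model for {m!r}")
            raise
        mediators[m] = fit
        report[f"mediator:{m}"] = {
            "converged": True, "boundary": fit.boundary,
            "notes": ["random-intercept variance at the zero boundary"] if fit.boundary else [],
        }
    for m in dataset.roles.mediators_l2:
        try:
            fit = fit_level2_mediator(design, m, links[m])
        except Exception as e:
            e.add_note(f"while fitting the level-2 third-variable model for {m!r}")
            raise
        mediators[m] = fit
        report[f"mediator:{m}"] = {"converged": True, "boundary": False, "notes": []}
    if dataset.roles.exposures_l1 and dataset.roles.mediators_l2:
        report["legibility"] = {
            "converged": True, "boundary": False,
            "notes": [
                f"level-2 third-variables {list(dataset.roles.mediators_l2)} carry no "
                "paths from level-1 exposures (level-1 effects use level-1 paths only)"
            ],
        }
    try:
        outcome = fit_outcome(design)
    except Exception as e:
        e.add_note("while fitting the outcome model")
        raise
    report["outcome"] = {
        "converged": True, "boundary": outcome.boundary,
        "notes": ["random-intercept variance at the zero boundary"] if outcome.boundary else [],
    }
    return ModelSystem(design, mediators, outcome, report)
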