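"""Synthetic-data generators and the operating-characteristics harness.

Study 1 is a 2 -> 1 -> 1 design extended with variables at both levels: a
binary level-1 exposure and a standard-normal level-2 exposure, a binary
level-2 third-variable generated through a logit model, a continuous level-1
third-variable and a Gaussian outcome, all with random intercepts at level 2:

    logit P(m2_j = 1) = 0.8 x2_j
    m1_ij = u0_j + 0.8 x2_j + 0.8 x1_ij + e0_ij,   u0 ~ N(0, .5), e0 ~ N(0, 1)
    y_ij  = u1_j + b1 x1 + b2 x2 + b3 m1 + b4 m2 + e1_ij,
            u1 ~ N(0, v2), e1 ~ N(0, v1), v2 = v1 / 5  (ICC = 1/6)

Study 2 adds nonlinearity: a quadratic exposure term in the third-variable
model and a log-transformed level-2 exposure effect on the outcome:

    m_ij = u0_j1 + 1.2 x1^2 + 1.2 x1 + gamma x2_j + e1_ij
    y_ij = u0_j + 0.98 x1 + 0.98 log(x2_j) + 0.98 m_ij + e_ij

with x1 ~ N(0, .5), x2 ~ chi-square(2), e1 ~ N(0, 1), e ~ N(0, 2),
u0_j1 ~ N(0, .5), u0_j ~ N(0, .4). This design targets a constant level-2
indirect effect of 1.176 = 1.2 x 0.98, which requires the level-2 exposure
to enter the third-variable model; the generator therefore carries the
gamma x2 term (gamma = 1.2 by default, gamma = 0 removes the path).

All normal parameters are (mean, variance). ``true_effects`` evaluates the
closed-form decomposition at the generating coefficients, so the full
pipeline can be checked against analytic truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, MltveError
from .hierdata import HierarchicalDataset, Roles, prepare_design
from .models import (IDENTITY_LINK, LOGIT_LINK, FittedMediatorModel,
                     FittedOutcomeModel, ModelSystem)
from .transforms import TransformSpec

SIM1_ROLES = Roles(
    group="g", outcome="y",
    exposures_l1=("x1",), exposures_l2=("x2",),
    mediators_l1=("m1",), mediators_l2=("m2",),
)
SIM2_ROLES = Roles(
    group="g", outcome="y",
    exposures_l1=("x1",), exposures_l2=("x2",),
    mediators_l1=("m",),
)


@dataclass(frozen=True)
class Sim1Config:
    total_n: int = 600
    n_per_group: int = 20
    beta1: float = 0.39
    beta2: float = 0.39
    beta3: float = 0.59
    beta4: float = 0.59
    v1: float = 1.0
    v2: Optional[float] = None  # defaults to v1 / 5 (ICC = 1/6)
    mediator_intercept_var: float = 0.5
    seed: Optional[int] = None

    @property
    def n_groups(self) -> int:
        if self.total_n % self.n_per_group:
            raise ConfigurationError(
                f"total_n ({self.total_n}) must be divisible by n_per_group ({self.n_per_group})")
        return self.total_n // self.n_per_group

    @property
    def outcome_group_var(self) -> float:
        return self.v1 / 5 if self.v2 is None else self.v2


@dataclass(frozen=True)
class Sim2Config:
    n_groups: int = 30
    n_per_group: int = 20
    gamma: float = 1.2            # level-2 exposure -> third-variable path
    b_direct_l1: float = 0.98
    b_direct_l2: float = 0.98     # coefficient on log(x2) in the outcome
    b_mediator: float = 0.98
    a_linear: float = 1.2         # coefficient on x1 in the third-variable model
    a_quadratic: float = 1.2      # coefficient on x1^2
    seed: Optional[int] = None


SimConfig = Union[Sim1Config, Sim2Config]


def gen_sim1(config: Sim1Config, rng=None) -> HierarchicalDataset:
    """Generate one study-1 dataset."""
    J, n = config.n_groups, config.n_per_group
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    N = J * n
    g = np.repeat(np.arange(J), n)
    x1 = rng.binomial(1, 0.5, N).astype(float)
    x2g = rng.standard_normal(J)
    m2g = rng.binomial(1, expit(0.8 * x2g)).astype(float)
    u0 = rng.normal(0, np.sqrt(config.mediator_intercept_var), J)
    m1 = u0[g] + 0.8 * x2g[g] + 0.8 * x1 + rng.standard_normal(N)
    u1 = rng.normal(0, np.sqrt(config.outcome_group_var), J)
    y = (u1[g] + config.beta1 * x1 + config.beta2 * x2g[g]
         + config.beta3 * m1 + config.beta4 * m2g[g]
         + rng.normal(0, np.sqrt(config.v1), N))
    df = pd.DataFrame({"g": g, "y": y, "x1": x1, "x2": x2g[g], "m1": m1, "m2": m2g[g]})
    return HierarchicalDataset(df, SIM1_ROLES)


def gen_sim2(config: Sim2Config, rng=None) -> HierarchicalDataset:
    """Generate one study-2 dataset (nonlinear third-variable model)."""
    J, n = config.n_groups, config.n_per_group
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    N = J * n
    g = np.repeat(np.arange(J), n)
    x1 = rng.normal(0, np.sqrt(0.5), N)
    x2g = rng.chisquare(2, J)
    u0j1 = rng.normal(0, np.sqrt(0.5), J)
    m = (u0j1[g] + config.a_quadratic * x1**2 + config.a_linear * x1
         + config.gamma * x2g[g] + rng.standard_normal(N))
    u0j = rng.normal(0, np.sqrt(0.4), J)
    y = (u0j[g] + config.b_direct_l1 * x1 + config.b_direct_l2 * np.log(x2g[g])
         + config.b_mediator * m + rng.normal(0, np.sqrt(2.0), N))
    df = pd.DataFrame({"g": g, "y": y, "x1": x1, "x2": x2g[g], "m": m})
    return HierarchicalDataset(df, SIM2_ROLES)


def sim2_transforms() -> Dict[str, dict]:
    """Transform config matching the study-2 generating model: quadratic x1
    in the third-variable model, log x2 in the outcome model."""
    return {
        "x1": {"mediator": TransformSpec("polynomial", degree=2),
               "outcome": TransformSpec("identity")},
        "x2": {"mediator": TransformSpec("identity"),
               "outcome": TransformSpec("log")},
    }


def generate(config: SimConfig, rng=None) -> HierarchicalDataset:
    return gen_sim1(config, rng) if isinstance(config, Sim1Config) else gen_sim2(config, rng)


def transforms_for(config: SimConfig):
    return None if isinstance(config, Sim1Config) else sim2_transforms()


# ---------------------------------------------------------------------------
# analytic truth

def true_system(config: SimConfig, dataset: Optional[HierarchicalDataset] = None) -> ModelSystem:
    """A model system carrying the *generating* coefficients.

    Running the effect decomposition on this system yields the true effect
    curves and averages implied by the generating equations, evaluated at the
    given dataset's exposure values (a freshly generated probe dataset by
    default). Fitted linear predictors hold random intercepts at zero, i.e.
    the population-level model.
    """
    if dataset is None:
        dataset = generate(replace(config, seed=config.seed if config.seed is not None else 12345))
    design = prepare_design(dataset, transforms_for(config))
    ds = dataset
    if isinstance(config, Sim1Config):
        m1 = FittedMediatorModel(
            target="m1", level=1, link=IDENTITY_LINK, intercept=0.0,
            exposure_coefficients={"x1": np.array([0.8]), "x2": np.array([0.8])},
            fitted_linear_predictor=0.8 * ds.column("x2") + 0.8 * ds.column("x1"),
            random_intercept_variance=config.mediator_intercept_var, residual_variance=1.0,
        )
        m2 = FittedMediatorModel(
            target="m2", level=2, link=LOGIT_LINK, intercept=0.0,
            exposure_coefficients={"x2": np.array([0.8])},
            fitted_linear_predictor=0.8 * ds.group_level("x2"),
        )
        outcome = FittedOutcomeModel(
            intercept=0.0,
            coefficients={"x1": np.array([config.beta1]), "x2": np.array([config.beta2]),
                          "m1": np.array([config.beta3]), "m2": np.array([config.beta4])},
            covariate_coefficients={}, random_intercept_variance=config.outcome_group_var,
            residual_variance=config.v1, link=IDENTITY_LINK,
            fitted_linear_predictor=np.zeros(ds.n_records),
        )
        return ModelSystem(design, {"m1": m1, "m2": m2}, outcome, {})
    x1 = ds.column("x1")
    med = FittedMediatorModel(
        target="m", level=1, link=IDENTITY_LINK, intercept=0.0,
        exposure_coefficients={"x1": np.array([config.a_linear, config.a_quadratic]),
                               "x2": np.array([config.gamma])},
        fitted_linear_predictor=(config.a_quadratic * x1**2 + config.a_linear * x1
                                 + config.gamma * ds.column("x2")),
        random_intercept_variance=0.5, residual_variance=1.0,
    )
    outcome = FittedOutcomeModel(
        intercept=0.0,
        coefficients={"x1": np.array([config.b_direct_l1]), "x2": np.array([config.b_direct_l2]),
                      "m": np.array([config.b_mediator])},
        covariate_coefficients={}, random_intercept_variance=0.4, residual_variance=2.0,
        link=IDENTITY_LINK, fitted_linear_predictor=np.zeros(ds.n_records),
    )
    return ModelSystem(design, {"m": med}, outcome, {})


def _gauss_hermite_expectation(f, n_nodes: int = 80):
    """E[f(Z)] for Z ~ N(0, 1) by Gauss-Hermite quadrature."""
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    return float(np.sum(w * f(np.sqrt(2.0) * z)) / np.sqrt(np.pi))


def true_effects(config: SimConfig) -> Dict[str, float]:
    """Averaged true effects under the generating model.

    Point-independent components come straight from the decomposition applied
    to the generating coefficients; the study-1 level-2 indirect effect
    through the binary third-variable averages 0.8 logistic'(0.8 x) b4 over
    the standard-normal exposure distribution by quadrature. For study 2 the
    level-2 direct effect is the curve 0.98/x whose population average over a
    chi-square(2) exposure does not exist; those averages are reported NaN
    (the curves remain available through ``true_system``/``effect_grid``).
    """
    if isinstance(config, Sim1Config):
        ie1 = 0.8 * config.beta3
        ie22 = config.beta4 * _gauss_hermite_expectation(
            lambda x: 0.8 * expit(0.8 * x) * (1 - expit(0.8 * x)))
        return {
            "te1": config.beta1 + ie1,
            "de1": config.beta1,
            "ie1:m1": ie1,
            "te2": config.beta2 + ie1 + ie22,
            "de2": config.beta2,
            "ie2.1:m1": ie1,
            "ie2.2:m2": ie22,
        }
    # study 2: evaluate the decomposition at the true coefficients; the x1
    # average is taken over its N(0, .5) distribution (the derivative term
    # 2 a_q x1 averages to zero)
    de1 = config.b_direct_l1
    ie1_avg = config.b_mediator * config.a_linear
    ie21 = config.gamma * config.b_mediator
    return {
        "te1": de1 + ie1_avg,
        "de1": de1,
        "ie1:m": ie1_avg,
        "te2": np.nan,
        "de2": np.nan,  # the curve 0.98/x has no finite chi-square(2) average
        "ie2.1:m": ie21,
    }


# ---------------------------------------------------------------------------
# sensitivity / specificity harness

@dataclass
class OperatingCharacteristics:
    """Per component: the proportion of replicates whose interval excludes 0.

    The proportion is a sensitivity when the component's true value is
    nonzero and one-minus-specificity when it is zero.
    """

    table: pd.DataFrame  # component, proportion, label, n_effective
    config: SimConfig
    n_replicates: int


def run_operating_study(
    config: SimConfig,
    n_replicates: int = 20,
    B: int = 100,
    seed: int = 0,
    level: float = 0.95,
) -> OperatingCharacteristics:
    """Generate -> fit -> bootstrap -> interval, tallied over replicates."""
    from .bootstrap import bootstrap_effects, percentile_ci

    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    truth = true_effects(config)
    ints = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    counts: Dict[str, int] = {}
    n_ok = 0
    for r in range(n_replicates):
        data = generate(config, rng=np.random.default_rng(int(ints[2 * r])))
        try:
            res = bootstrap_effects(data, transforms_for(config), B=B,
                                    seed=int(ints[2 * r + 1]) % 2**31)
            ci = percentile_ci(res, level)
        except MltveError:
            continue
        n_ok += 1
        excl = (ci["lower"] > 0) | (ci["upper"] < 0)
        for comp, flag in excl.items():
            counts[comp] = counts.get(comp, 0) + int(flag)
    if n_ok == 0:
        raise MltveError("every operating-study replicate failed to fit")
    rows = []
    for comp, c in counts.items():
        tv = truth.get(comp, np.nan)
        nonzero = bool(np.isnan(tv) or abs(tv) > 1e-12)  # NaN: truth is a nonzero curve
        rows.append({
            "component": comp,
            "proportion": c / n_ok,
            "label": "sensitivity" if nonzero else "one_minus_specificity",
            "n_effective": n_ok,
        })
    return OperatingCharacteristics(pd.DataFrame(rows), config, n_replicates)
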