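"""Two-level data model: ingestion, validation, aggregation and design preparation.

A :class:`HierarchicalDataset` is a flat level-1 table with a group identifier
and a role map declaring which columns are the outcome, the level-1/level-2
exposures, the level-1/level-2 third-variables (mediators/confounders) and
optional covariates. Level-2 columns must be constant within each group.

:func:`prepare_design` evaluates the configured transformations and their
first derivatives at the observed data, producing the predictor blocks of the
three-layer model system:

* ``f1e`` / ``f2e`` — level-1 / level-2 exposures in the outcome model,
* ``f3k`` / ``f4l`` — level-1 / level-2 mediators in the outcome model,
* per level-1 mediator: ``f1ke1`` / ``f2ke1`` — exposures in its model,
* per level-2 mediator: ``f2le`` — level-2 exposures in its model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, ValidationError
from .transforms import Transform, TransformSpec, make_transform

logger = logging.getLogger(__name__)

IDENTITY = TransformSpec("identity")


@dataclass(frozen=True)
class Roles:
    """Normalized variable-role map."""

    group: str
    outcome: str
    exposures_l1: tuple = ()
    exposures_l2: tuple = ()
    mediators_l1: tuple = ()
    mediators_l2: tuple = ()
    covariates: tuple = ()

    @classmethod
    def from_mapping(cls, roles: Mapping, group_col: Optional[str] = None) -> "Roles":
        def _tup(section, key):
            v = (roles.get(section) or {}).get(key, []) if isinstance(roles.get(section), Mapping) else []
            if isinstance(v, str):
                v = [v]
            return tuple(v)

        group = group_col or roles.get("group")
        if group is None:
            raise ConfigurationError("role map must name a group column")
        outcome = roles.get("outcome")
        if outcome is None:
            raise ConfigurationError("role map must name an outcome column")
        cov = roles.get("covariates", []) or []
        if isinstance(cov, str):
            cov = [cov]
        return cls(
            group=group,
            outcome=outcome,
            exposures_l1=_tup("exposures", "level1"),
            exposures_l2=_tup("exposures", "level2"),
            mediators_l1=_tup("mediators", "level1"),
            mediators_l2=_tup("mediators", "level2"),
            covariates=tuple(cov),
        )

    @property
    def level1_vars(self):
        return self.exposures_l1 + self.mediators_l1

    @property
    def level2_vars(self):
        return self.exposures_l2 + self.mediators_l2

    @property
    def required(self):
        return (self.outcome,) + self.exposures_l1 + self.exposures_l2 + \
            self.mediators_l1 + self.mediators_l2 + self.covariates


class HierarchicalDataset:
    """Validated two-level table.

    Rows are sorted so each group is contiguous; ``group_codes`` maps rows to
    0-based group indices, ``group_sizes`` gives n_j per group and
    ``group_first`` the row index of each group's first record (used to read
    level-2 variables once per group).
    """

    def __init__(self, df: pd.DataFrame, roles: Union[Roles, Mapping], *, validate: bool = True):
        if not isinstance(roles, Roles):
            roles = Roles.from_mapping(roles)
        self.roles = roles
        missing = [c for c in (roles.group,) + roles.required if c not in df.columns]
        if missing:
            raise ConfigurationError(f"columns not found in input: {missing}")

        df = df.loc[:, [roles.group, *dict.fromkeys(roles.required)]]
        n0 = len(df)
        df = df.dropna()
        if len(df) < n0:
            logger.info("dropped %d rows with missing required fields", n0 - len(df))
        # stable sort keeps within-group record order; groups become contiguous
        df = df.sort_values(roles.group, kind="stable").reset_index(drop=True)
        self.df = df

        codes, self.group_labels = pd.factorize(df[roles.group], sort=True)
        self.group_codes = codes.astype(np.intp)
        self.group_sizes = np.bincount(self.group_codes, minlength=len(self.group_labels))
        self.group_first = np.searchsorted(self.group_codes, np.arange(len(self.group_labels)))

        if validate:
            self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self):
        if self.n_groups < 2:
            raise ValidationError(f"at least 2 groups are required, found {self.n_groups}")
        if len(self.df) < 3:
            raise ValidationError(f"at least 3 records are required, found {len(self.df)}")
        for col in self.roles.level2_vars:
            nun = self.df.groupby(self.group_codes, sort=False)[col].nunique()
            bad = nun[nun > 1]
            if len(bad):
                g = self.group_labels[bad.index[0]]
                raise ValidationError(f"level-2 column {col!r} varies within group {g!r}")
        y = self.df[self.roles.outcome].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValidationError(f"outcome {self.roles.outcome!r} has zero variance")

    # -- accessors --------------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def group_level(self, name: str) -> np.ndarray:
        """One value per group for a level-2 column."""
        return self.df[name].to_numpy()[self.group_first]

    def level_of(self, var: str) -> int:
        if var in self.roles.level1_vars or var == self.roles.outcome:
            return 1
        if var in self.roles.level2_vars:
            return 2
        raise ConfigurationError(f"unknown variable {var!r}")

    def is_binary(self, var: str) -> bool:
        vals = np.unique(self.df[var].to_numpy())
        return set(np.asarray(vals).tolist()) <= {0, 1, 0.0, 1.0}


def load_dataset(path, roles: Mapping, group_col: Optional[str] = None) -> HierarchicalDataset:
    """Read a CSV with a header row and return a validated dataset.

    ``roles`` follows the config layout: keys ``group``, ``outcome``,
    ``exposures.level1/level2``, ``mediators.level1/level2``, ``covariates``.
    """
    df = pd.read_csv(path)
    return HierarchicalDataset(df, Roles.from_mapping(roles, group_col))


def aggregate_level1(dataset: HierarchicalDataset, var: str, stat: str = "mean") -> pd.Series:
    """Aggregate a level-1 column within groups and broadcast back to rows.

    The result is a valid level-2 variable (constant within group). Only the
    mean is supported, matching the usual definition of an aggregated
    third-variable.
    """
    if var not in dataset.df.columns:
        raise ConfigurationError(f"unknown variable {var!r}")
    if stat != "mean":
        raise ConfigurationError(f"unsupported aggregation {stat!r}; only 'mean'")
    x = dataset.df[var].to_numpy(dtype=float)
    sums = np.bincount(dataset.group_codes, weights=x, minlength=dataset.n_groups)
    means = sums / dataset.group_sizes
    return pd.Series(means[dataset.group_codes], index=dataset.df.index, name=f"{var}.mean")


def dichotomize(var: pd.Series, reference=None):
    """Reference-code a categorical column into k-1 zero/one indicators.

    Returns ``(indicators, reference_level)``; row sums are 0 (reference) or 1.
    """
    levels = sorted(pd.unique(var).tolist())
    if len(levels) < 2:
        raise ValidationError(f"column {var.name!r} is constant; cannot dichotomize")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ConfigurationError(f"reference level {ref!r} not observed in {var.name!r}")
    cols = {f"{var.name}[{lvl}]": (var == lvl).astype(int) for lvl in levels if lvl != ref}
    return pd.DataFrame(cols, index=var.index), ref


@dataclass
class TransformedVar:
    """One source variable's fitted transform plus its evaluated blocks."""

    var: str
    transform: Transform
    values: np.ndarray  # (n, c)
    derivs: np.ndarray  # (n, c)
    names: List[str]


@dataclass
class PreparedDesign:
    """All transformed predictor blocks of the model system, with derivatives.

    ``outcome`` maps block name (f1e/f2e/f3k/f4l) -> {var: TransformedVar};
    ``mediator`` maps mediator name -> {block name -> {var: TransformedVar}}.
    All blocks are evaluated at level-1 rows; level-2 models collapse them via
    ``dataset.group_first``.
    """

    dataset: HierarchicalDataset
    outcome: Dict[str, Dict[str, TransformedVar]]
    mediator: Dict[str, Dict[str, Dict[str, TransformedVar]]]
    transforms: Dict[tuple, Transform] = field(default_factory=dict)

    @property
    def column_map(self):
        out = []
        for block, tvs in self.outcome.items():
            for var, tv in tvs.items():
                out += [(f"outcome/{block}", var, nm) for nm in tv.names]
        for med, blocks in self.mediator.items():
            for block, tvs in blocks.items():
                for var, tv in tvs.items():
                    out += [(f"{med}/{block}", var, nm) for nm in tv.names]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Audit export: value columns plus derivative columns suffixed __d."""
        cols = {}
        for block, var, tv, j, nm in self._iter_cols():
            cols[f"{block}:{nm}"] = tv.values[:, j]
            cols[f"{block}:{nm}__d"] = tv.derivs[:, j]
        return pd.DataFrame(cols, index=self.dataset.df.index)

    def _iter_cols(self):
        for block, tvs in self.outcome.items():
            for var, tv in tvs.items():
                for j, nm in enumerate(tv.names):
                    yield f"outcome/{block}", var, tv, j, nm
        for med, blocks in self.mediator.items():
            for block, tvs in blocks.items():
                for var, tv in tvs.items():
                    for j, nm in enumerate(tv.names):
                        yield f"{med}/{block}", var, tv, j, nm


def _resolve_spec(config, var: str, context: str) -> TransformSpec:
    """Context is 'outcome' or 'mediator'; unconfigured variables are identity."""
    entry = (config or {}).get(var)
    if entry is None:
        return IDENTITY
    if isinstance(entry, TransformSpec):
        return entry
    if isinstance(entry, Mapping):
        return entry.get(context, IDENTITY)
    raise ConfigurationError(f"transform config for {var!r} must be a TransformSpec or a context mapping")


def _fit_eval(dataset, var, spec, frozen, key) -> TransformedVar:
    x = dataset.column(var)
    try:
        if frozen is not None and key in frozen:
            tr = frozen[key]
        else:
            tr = make_transform(spec, x)
        vals = tr.values(x)
        ders = tr.derivatives(x)
    except DomainError as e:
        raise DomainError(f"transform of {var!r}: {e}") from e
    return TransformedVar(var, tr, vals, ders, tr.column_names(var))


def prepare_design(
    dataset: HierarchicalDataset,
    transform_config: Optional[Mapping] = None,
    *,
    frozen_transforms: Optional[Mapping] = None,
) -> PreparedDesign:
    """Evaluate every transformed predictor block and its derivative block.

    ``transform_config`` maps variable -> TransformSpec, or variable ->
    ``{"outcome": spec, "mediator": spec}`` when an exposure needs different
    transformations in the outcome and mediator models. Unconfigured
    variables are identity. ``frozen_transforms`` (keyed like
    ``PreparedDesign.transforms``) reuses already-fitted transforms, so that
    data-dependent pieces such as spline knots stay fixed across bootstrap
    replicates.
    """
    r = dataset.roles
    for var in transform_config or {}:
        if var not in r.required:
            raise ConfigurationError(f"transform configured for unknown variable {var!r}")

    transforms: Dict[tuple, Transform] = {}

    def block(vars_, context):
        out = {}
        for v in vars_:
            key = (v, context)
            tv = _fit_eval(dataset, v, _resolve_spec(transform_config, v, context), frozen_transforms, key)
            transforms[key] = tv.transform
            out[v] = tv
        return out

    outcome = {
        "f1e": block(r.exposures_l1, "outcome"),
        "f2e": block(r.exposures_l2, "outcome"),
        "f3k": block(r.mediators_l1, "outcome"),
        "f4l": block(r.mediators_l2, "outcome"),
    }
    mediator: Dict[str, Dict[str, Dict[str, TransformedVar]]] = {}
    for k in r.mediators_l1:
        mediator[k] = {
            "f1ke1": block(r.exposures_l1, "mediator"),
            "f2ke1": block(r.exposures_l2, "mediator"),
        }
    for l in r.mediators_l2:
        mediator[l] = {"f2le": block(r.exposures_l2, "mediator")}

    return PreparedDesign(dataset, outcome, mediator, transforms)
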