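"""Cluster bootstrap: resample records within groups, refit, re-decompose.

Every group is kept; within group j, n_j records are drawn with replacement
from that group's own records, so group sizes and all level-2 variables are
preserved exactly. Each resample is refitted (with transformation fits such
as spline knots frozen from the original data, keeping the estimand fixed)
and the effect decomposition recomputed; percentile intervals and bootstrap
standard errors come from the replicate distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .effects import system_effect_summaries
from .exceptions import InferenceError, MltveError
from .hierdata import HierarchicalDataset
from .models import ModelSystem, fit_system

logger = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.2


def resample_within_groups(dataset: HierarchicalDataset, rng) -> HierarchicalDataset:
    """One cluster-bootstrap resample: all groups kept, records drawn with
    replacement within each group, sizes n_j preserved."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    gc = dataset.group_codes
    sizes = dataset.group_sizes
    # per slot, a uniform draw from that slot's own group
    u = rng.random(dataset.n_records)
    pick = dataset.group_first[gc] + np.floor(u * sizes[gc]).astype(np.intp)
    df = dataset.df.take(pick).reset_index(drop=True)
    return HierarchicalDataset(df, dataset.roles, validate=False)


@dataclass
class BootstrapResult:
    """Converged replicate effect summaries plus the original-data estimates."""

    replicates: pd.DataFrame           # one row per converged replicate
    point_estimates: Dict[str, float]  # original-data component values
    B: int
    seed: int
    failures: List[str] = field(default_factory=list)
    system: Optional[ModelSystem] = None

    @property
    def n_converged(self) -> int:
        return len(self.replicates)

    @property
    def degenerate(self) -> bool:
        return self.n_converged < 2


def bootstrap_effects(
    dataset: HierarchicalDataset,
    transform_config: Optional[Mapping] = None,
    B: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Run B resample -> refit -> effects cycles.

    Per-replicate random streams are spawned from the master seed, so any
    subset of replicates is reproducible independently of execution order.
    Replicates whose refit fails are dropped and logged, never replaced; more
    than 20% failures aborts with advice to re-specify the model.
    """
    if B < 1:
        raise InferenceError("B must be >= 1")
    system0 = fit_system(dataset, transform_config)
    point = system_effect_summaries(system0)
    frozen = system0.design.transforms

    children = np.random.SeedSequence(seed).spawn(B)
    rows, failures = [], []
    for b in range(B):
        rng = np.random.default_rng(children[b])
        ds_b = resample_within_groups(dataset, rng)
        try:
            sys_b = fit_system(dataset=ds_b, transform_config=transform_config,
                               frozen_transforms=frozen)
            rows.append(system_effect_summaries(sys_b))
        except MltveError as e:
            failures.append(f"replicate {b}: {e}")
    if len(failures) > MAX_FAILURE_FRACTION * B:
        raise InferenceError(
            f"{len(failures)}/{B} bootstrap replicates failed to fit; "
            "consider re-specifying the model (fewer terms or transformations)"
        )
    for msg in failures:
        logger.warning("bootstrap %s", msg)
    replicates = pd.DataFrame(rows, columns=list(point)) if rows else pd.DataFrame(columns=list(point))
    result = BootstrapResult(replicates, point, B, seed, failures, system0)
    if result.degenerate:
        logger.warning("fewer than 2 converged replicates; intervals are degenerate")
    return result


def percentile_ci(result: BootstrapResult, level: float = 0.95) -> pd.DataFrame:
    """Percentile confidence intervals and bootstrap SEs per component.

    Quantiles use linear interpolation of the order statistics.
    """
    if not 0 < level < 1:
        raise InferenceError(f"confidence level must be in (0, 1), got {level}")
    if result.n_converged < 2:
        raise InferenceError("need at least 2 converged replicates for intervals")
    alpha = (1 - level) / 2
    reps = result.replicates.to_numpy()
    lower = np.quantile(reps, alpha, axis=0, method="linear")
    upper = np.quantile(reps, 1 - alpha, axis=0, method="linear")
    se = reps.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "estimate": [result.point_estimates[c] for c in result.replicates.columns],
            "lower": lower,
            "upper": upper,
            "se": se,
        },
        index=result.replicates.columns,
    )


def summarize(result: BootstrapResult, level: float = 0.95) -> pd.DataFrame:
    """Tidy effect table: one row per component with estimate, CI, SE and a
    significance flag (interval excludes 0). With fewer than 2 converged
    replicates the intervals collapse to the point estimate and are flagged
    degenerate."""
    if result.n_converged >= 2:
        ci = percentile_ci(result, level)
        degenerate = False
    else:
        est = pd.Series(result.point_estimates)
        ci = pd.DataFrame({"estimate": est, "lower": est, "upper": est, "se": np.nan})
        degenerate = True
    rows = []
    for comp, r in ci.iterrows():
        level_no = 2 if comp.startswith(("te2", "de2", "ie2")) else 1
        mediator = comp.split(":", 1)[1].split("@", 1)[0] if ":" in comp else ""
        rows.append(
            {
                "component": comp,
                "level": level_no,
                "mediator": mediator,
                "estimate": r["estimate"],
                "lower": r["lower"],
                "upper": r["upper"],
                "se": r["se"],
                "significant": bool(r["lower"] > 0 or r["upper"] < 0) and not degenerate,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def summary_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def summary_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["mediator"] = df["mediator"].astype(str)
    for c in ("estimate", "lower", "upper", "se"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("significant", "degenerate"):
        df[c] = df[c].astype(str).str.lower().eq("true")
    return df
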