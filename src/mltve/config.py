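"""Run configuration: YAML round-trip, validation, transform parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, Mapping, Optional

import yaml

from .exceptions import ConfigurationError
from .hierdata import Roles
from .transforms import TransformSpec

_SPEC_KEYS = {"kind", "degree", "df", "knots", "threshold", "reference"}


def parse_transform_spec(entry: Mapping) -> TransformSpec:
    if "kind" not in entry:
        raise ConfigurationError(f"transform entry {entry!r} lacks a 'kind'")
    unknown = set(entry) - _SPEC_KEYS
    if unknown:
        raise ConfigurationError(f"unknown transform keys {sorted(unknown)} in {entry!r}")
    return TransformSpec(**entry)


def parse_transforms(raw: Optional[Mapping]) -> Optional[Dict]:
    """Raw YAML transforms -> {var: TransformSpec | {context: TransformSpec}}."""
    if not raw:
        return None
    out: Dict = {}
    for var, entry in raw.items():
        if "kind" in entry:
            out[var] = parse_transform_spec(entry)
        else:
            ctxs = set(entry) - {"outcome", "mediator"}
            if ctxs:
                raise ConfigurationError(
                    f"transform contexts for {var!r} must be 'outcome'/'mediator', got {sorted(ctxs)}")
            out[var] = {ctx: parse_transform_spec(spec) for ctx, spec in entry.items()}
    return out


@dataclass
class RunConfig:
    """Everything one analysis run needs; round-trips losslessly through YAML."""

    input: str
    roles: dict
    transforms: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=lambda: {"B": 500, "level": 0.95, "seed": 0})
    verbosity: str = "info"

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        unknown = set(raw) - {"input", "roles", "transforms", "bootstrap", "verbosity"}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "input" not in raw or "roles" not in raw:
            raise ConfigurationError("config must provide 'input' and 'roles'")
        cfg = cls(
            input=raw["input"],
            roles=raw["roles"],
            transforms=raw.get("transforms") or {},
            bootstrap={**{"B": 500, "level": 0.95, "seed": 0}, **(raw.get("bootstrap") or {})},
            verbosity=raw.get("verbosity", "info"),
        )
        cfg.parsed_roles()  # fail fast on malformed roles
        parse_transforms(cfg.transforms)
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def parsed_roles(self) -> Roles:
        return Roles.from_mapping(self.roles)

    def parsed_transforms(self):
        return parse_transforms(self.transforms)

    def validate_columns(self, columns) -> None:
        cols = set(columns)
        r = self.parsed_roles()
        missing = [c for c in (r.group,) + r.required if c not in cols]
        missing += [v for v in self.transforms if v not in cols and v not in missing]
        if missing:
            raise ConfigurationError(f"columns not found in input: {missing}")
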