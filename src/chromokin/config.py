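"""Run configuration: flat key-value files with dotted namespaces.

A config file is YAML restricted to scalars, with keys either dotted
(``geometry.b850_radius: 26``) or nested one level (``geometry: {...}``).
Recognized namespaces: ``geometry``, ``exciton``, ``kinetics``, ``sweep``
and top-level ``seed`` / ``outdir``.  Every override is validated against
the target dataclass before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .excitons import ExcitonParameters
from .geometry import GeometryConfig
from .kinetics import KineticParameters
from .sweep import FootprintAreas

__all__ = ["RunConfig", "load_config", "flatten"]

_NAMESPACES = ("geometry", "exciton", "kinetics", "sweep")


def flatten(mapping: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    """Collapse nested mappings into dotted keys."""
    out: dict[str, Any] = {}
    for key, value in mapping.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, Mapping):
            out.update(flatten(value, prefix=f"{dotted}."))
        else:
            out[dotted] = value
    return out


@dataclass
class RunConfig:
    """Validated configuration for the full pipeline."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    exciton: ExcitonParameters = field(default_factory=ExcitonParameters)
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    areas: FootprintAreas = field(default_factory=FootprintAreas)
    seed: int = 0
    intensities: tuple[float, ...] = tuple(float(x) for x in (1, 3, 10, 30, 100, 300, 1000))
    sweep_intensity: float = 10.0
    nb_range: tuple[int, int] = (1, 30)
    nl_range: tuple[int, int] = (1, 30)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        flat = flatten(mapping)
        groups: dict[str, dict[str, Any]] = {ns: {} for ns in _NAMESPACES}
        top: dict[str, Any] = {}
        for key, value in flat.items():
            if "." in key:
                ns, _, rest = key.partition(".")
                if ns not in groups or "." in rest:
                    raise ValueError(f"unknown config key {key!r}")
                groups[ns][rest] = value
            else:
                top[key] = value
        seed = int(top.pop("seed", 0))
        geometry_kwargs = dict(groups["geometry"])
        geometry_kwargs.setdefault("seed", seed)
        sweep_kwargs = dict(groups["sweep"])
        intensities = tuple(float(x) for x in top.pop("intensities", cls().intensities))
        sweep_intensity = float(sweep_kwargs.pop("intensity", 10.0))
        nb_range = tuple(int(x) for x in sweep_kwargs.pop("nb_range", (1, 30)))
        nl_range = tuple(int(x) for x in sweep_kwargs.pop("nl_range", (1, 30)))
        if top:
            raise ValueError(f"unknown top-level config keys: {sorted(top)}")
        return cls(
            geometry=GeometryConfig.from_mapping(geometry_kwargs),
            exciton=ExcitonParameters().with_overrides(**groups["exciton"]),
            kinetics=KineticParameters.from_mapping(groups["kinetics"]),
            areas=FootprintAreas(**sweep_kwargs),
            seed=seed,
            intensities=intensities,
            sweep_intensity=sweep_intensity,
            nb_range=nb_range,  # type: ignore[arg-type]
            nl_range=nl_range,  # type: ignore[arg-type]
        )


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValueError("config file must contain a key-value mapping")
    return RunConfig.from_mapping(data)
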