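"""Declarative run configuration (TOML) with strict validation.

A run is described by four optional TOML tables -- ``[model]``,
``[tissue]``, ``[integration]`` and ``[scenario]`` -- whose keys map onto
:class:`~pancfate.model.ModelParams`, the lattice geometry, the integrator
settings and the protocol choice.  Unknown tables or keys are rejected by
name, and every run writes a fully-resolved copy of its configuration
(``config.resolved``, JSON) next to its outputs so results can be
reproduced bit-identically from the artefacts alone.

An empty file resolves to the reference parameter set and the development
scenario defaults.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tomllib
from dataclasses import dataclass, field

from .model import ModelParams
from . import scenarios
from .scenarios import ScenarioSpec

__all__ = ["RunConfig", "load_config", "SCENARIO_NAMES"]

SCENARIO_NAMES = (
    "development",
    "conversion_stab",
    "conversion_both",
    "inhibition_only",
    "recovery",
    "density_sweep",
    "shape_sweep",
)

_TISSUE_KEYS = {"topology": str, "width": int, "height": int, "density": (int, float),
                "boundary": str, "mask": str}
_INTEGRATION_KEYS = {"dt": (int, float), "t_end": (int, float), "seed": int,
                     "noise_on": bool, "record_every": int}
_SCENARIO_KEYS = {"name": str, "replicates": int, "t_rec": (int, float),
                  "burn_in": (int, float), "keep_trajectories": bool}


@dataclass
class RunConfig:
    """Fully-resolved configuration of one run."""

    model: ModelParams = field(default_factory=ModelParams)
    tissue: dict = field(default_factory=dict)
    integration: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        """Plain-dict form with all defaults filled in (for provenance)."""
        spec = self.to_spec()
        return {
            "model": dataclasses.asdict(spec.params),
            "tissue": {
                "topology": self.tissue.get("topology", "hex_lattice"),
                "width": spec.width,
                "height": spec.height,
                "density": spec.density,
                "boundary": spec.boundary,
                "mask": self.tissue.get("mask"),
            },
            "integration": {
                "dt": spec.dt,
                "t_end": spec.t_end,
                "seed": spec.seed,
                "noise_on": bool(spec.params.eta_x or spec.params.eta_y),
                "record_every": spec.record_every,
            },
            "scenario": {
                "name": spec.name,
                "replicates": spec.replicates,
                "t_rec": spec.t_rec,
                "burn_in": spec.burn_in,
                "schedule": [[t, dict(ov)] for t, ov in spec.schedule],
            },
        }

    def save_resolved(self, out_dir: str) -> str:
        path = os.path.join(out_dir, "config.resolved")
        with open(path, "w") as fh:
            json.dump(self.resolved(), fh, indent=2)
            fh.write("\n")
        return path

    def to_spec(self) -> ScenarioSpec:
        """Build the ScenarioSpec this configuration describes."""
        name = self.scenario.get("name", "development")
        if name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario name {name!r}")
        params = self.model
        integ = dict(self.integration)
        if not integ.pop("noise_on", True):
            params = params.replace(eta_x=0.0, eta_y=0.0)

        overrides: dict = {"params": params}
        for key in ("width", "height", "density", "boundary"):
            if key in self.tissue:
                overrides[key] = self.tissue[key]
        if self.tissue.get("mask"):
            from .tissue import load_mask

            overrides["mask"] = load_mask(
                self.tissue["mask"], boundary=self.tissue.get("boundary", "periodic")
            )
        for src, dst in (("dt", "dt"), ("t_end", "t_end"), ("seed", "seed"),
                         ("record_every", "record_every")):
            if src in integ:
                overrides[dst] = integ[src]
        for key in ("replicates", "burn_in", "keep_trajectories"):
            if key in self.scenario:
                overrides[key] = self.scenario[key]

        if name == "development":
            return scenarios.development_spec(**overrides)
        if name in ("conversion_stab", "conversion_both", "inhibition_only"):
            variant = {"conversion_stab": "stab", "conversion_both": "both",
                       "inhibition_only": "inhibition"}[name]
            return scenarios.conversion_spec(variant, **overrides)
        if name == "recovery":
            t_rec = self.scenario.get("t_rec")
            if t_rec is None:
                raise ValueError("scenario key 't_rec' is required for recovery")
            return scenarios.recovery_spec(t_rec, **overrides)
        # sweeps: the spec object carries the shared settings; densities /
        # b values / masks are provided at call time (CLI flags)
        return ScenarioSpec(name=name, init="adult").with_(**overrides)


def _check_keys(section: str, table: dict, allowed: dict) -> None:
    for key, value in table.items():
        if key not in allowed:
            raise ValueError(f"unknown key {key!r} in [{section}]")
        expected = allowed[key]
        if expected is bool:
            ok = isinstance(value, bool)
        else:
            types = expected if isinstance(expected, tuple) else (expected,)
            ok = isinstance(value, types) and not isinstance(value, bool)
        if not ok:
            raise ValueError(f"key {key!r} in [{section}] has invalid type {type(value).__name__}")


def load_config(path: str | None) -> RunConfig:
    """Parse and validate a TOML run configuration.

    ``None`` or an empty file yields the full defaults.  Unknown keys,
    type mismatches and out-of-range values raise ``ValueError`` naming
    the offending key.
    """
    raw: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    for section in raw:
        if section not in ("model", "tissue", "integration", "scenario"):
            raise ValueError(f"unknown configuration table [{section}]")

    model_tab = raw.get("model", {})
    param_fields = {f.name for f in dataclasses.fields(ModelParams)}
    for key in model_tab:
        if key not in param_fields:
            raise ValueError(f"unknown key {key!r} in [model]")
    try:
        model = ModelParams(**model_tab)
    except ValueError as exc:
        raise ValueError(f"invalid [model] value: {exc}") from None

    tissue_tab = dict(raw.get("tissue", {}))
    _check_keys("tissue", tissue_tab, _TISSUE_KEYS)
    if "density" in tissue_tab and not 0 <= tissue_tab["density"] <= 1:
        raise ValueError("key 'density' in [tissue] must lie in [0, 1]")
    if "topology" in tissue_tab and tissue_tab["topology"] not in ("hex_lattice", "triangle3"):
        raise ValueError("key 'topology' in [tissue] must be 'hex_lattice' or 'triangle3'")

    integ_tab = dict(raw.get("integration", {}))
    _check_keys("integration", integ_tab, _INTEGRATION_KEYS)
    if "dt" in integ_tab and integ_tab["dt"] <= 0:
        raise ValueError("key 'dt' in [integration] must be > 0")
    if "record_every" in integ_tab and integ_tab["record_every"] < 1:
        raise ValueError("key 'record_every' in [integration] must be >= 1")

    scen_tab = dict(raw.get("scenario", {}))
    _check_keys("scenario", scen_tab, _SCENARIO_KEYS)
    if "name" in scen_tab and scen_tab["name"] not in SCENARIO_NAMES:
        raise ValueError(f"key 'name' in [scenario]: unknown scenario {scen_tab['name']!r}")
    if "replicates" in scen_tab and scen_tab["replicates"] < 1:
        raise ValueError("key 'replicates' in [scenario] must be >= 1")

    return RunConfig(model=model, tissue=tissue_tab, integration=integ_tab, scenario=scen_tab)
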