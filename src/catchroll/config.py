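"""YAML configuration, canonical fixtures and run serialization.

A run is fully described by a small YAML file with sections ``bond:``,
``flow:``, ``kinematics:``, ``cluster:``, ``grids:`` and ``mc:``; every
omitted key falls back to the reference parameter set (see
:mod:`catchroll.params`).  Named fixtures provide the canonical
configurations used throughout the examples and tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .params import BondParams, EdgeKinematics, FlowCell

__all__ = ["RunConfig", "fixture", "load_config", "save_config"]


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grids: forces (pN), speeds (μm/s), shear rates (1/s)."""

    f_min: float = 0.0
    f_max: float = 50.0
    n_f: int = 201
    vc_min: float = 1.0e-2
    vc_max: float = 1.0e4
    n_vc: int = 200
    gamma_min: float = 1.0
    gamma_max: float = 400.0
    n_gamma: int = 160

    def force_grid(self) -> np.ndarray:
        return np.linspace(self.f_min, self.f_max, self.n_f)

    def speed_grid(self) -> np.ndarray:
        return np.geomspace(self.vc_min, self.vc_max, self.n_vc)

    def shear_grid(self) -> np.ndarray:
        return np.linspace(self.gamma_min, self.gamma_max, self.n_gamma)


@dataclass(frozen=True)
class MCSpec:
    """Monte Carlo controls."""

    seed: int = 2020
    n_samples: int = 10_000


@dataclass(frozen=True)
class RunConfig:
    bond: BondParams = field(default_factory=BondParams)
    flow: FlowCell = field(default_factory=FlowCell)
    kinematics: EdgeKinematics = field(
        default_factory=lambda: EdgeKinematics(vc=1.0)
    )
    Nt: int = 10
    grids: GridSpec = field(default_factory=GridSpec)
    mc: MCSpec = field(default_factory=MCSpec)

    def to_dict(self) -> dict[str, Any]:
        return {
            "bond": dataclasses.asdict(self.bond),
            "flow": dataclasses.asdict(self.flow),
            "kinematics": dataclasses.asdict(self.kinematics),
            "cluster": {"Nt": self.Nt},
            "grids": dataclasses.asdict(self.grids),
            "mc": dataclasses.asdict(self.mc),
        }

    def digest(self) -> str:
        """Short stable hash of the full parameter set."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTION_TYPES = {
    "bond": BondParams,
    "flow": FlowCell,
    "kinematics": EdgeKinematics,
    "grids": GridSpec,
    "mc": MCSpec,
}


def _build_section(cls, overrides: dict[str, Any], section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )
    try:
        return cls(**overrides)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid value in config section {section!r}: {exc}") from exc


def config_from_dict(raw: dict[str, Any] | None) -> RunConfig:
    raw = dict(raw or {})
    cluster = raw.pop("cluster", {}) or {}
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(
            f"unknown config section(s) {sorted(unknown)}; "
            f"valid sections: {sorted(_SECTION_TYPES) + ['cluster']}"
        )
    sections = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTION_TYPES.items()
    }
    nt = cluster.get("Nt", 10)
    extra = set(cluster) - {"Nt"}
    if extra:
        raise ValueError(f"unknown key(s) {sorted(extra)} in config section 'cluster'")
    return RunConfig(
        bond=sections["bond"],
        flow=sections["flow"],
        kinematics=sections["kinematics"],
        Nt=nt,
        grids=sections["grids"],
        mc=sections["mc"],
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; omitted keys take reference defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (lossless round-trip)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def fixture(name: str) -> RunConfig:
    """Canonical parameter sets.

    * ``default_catch`` — reference parameters with the calibrated
      two-pathway constants (calibrated, not reference values).
    * ``default_slip``  — same, Bell off-rate with the shared f_beta.
    * ``no_adhesion``   — total bond density set to zero; the steady
      state is free rolling v = Rγ at every shear rate.
    """
    if name == "default_catch":
        return RunConfig()
    if name == "default_slip":
        return dataclasses.replace(RunConfig(), bond=BondParams().comparison_slip())
    if name == "no_adhesion":
        base = RunConfig()
        return dataclasses.replace(
            base,
            kinematics=dataclasses.replace(base.kinematics, xi_all=0.0),
        )
    raise ValueError(
        f"unknown fixture {name!r}; choose from "
        "'default_catch', 'default_slip', 'no_adhesion'"
    )
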