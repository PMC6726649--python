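"""Configuration loading, validation and delimited-text output writers.

A run configuration is a YAML document merged over the packaged defaults;
unknown keys are rejected with their dotted path.  Every table written by
the tool carries a comment header recording the tool version, the seed and
a hash of the resolved configuration, so any run can be reproduced from its
outputs.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abm import SimConfig
from .network import NetworkSpec
from .secretion import AbundanceTable, RateSet

__all__ = [
    "RunConfig",
    "load_config",
    "default_config_dict",
    "write_table",
    "read_table",
    "write_diagram",
    "write_graph_edges",
    "read_graph_edges",
]


def default_config_dict() -> dict:
    """The packaged default configuration as a plain dict."""
    text = (
        importlib.resources.files("macpol").joinpath("data/defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


def _merge(defaults, override, path=""):
    if override is None:
        return defaults
    if not isinstance(defaults, dict):
        return override
    if not isinstance(override, dict):
        raise ValueError(f"config key {path or '<root>'}: expected a mapping")
    out = dict(defaults)
    for key, value in override.items():
        dotted = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ValueError(f"unknown config key: {dotted}")
        out[key] = _merge(defaults[key], value, dotted)
    return out


@dataclass
class RunConfig:
    """A resolved run configuration with typed accessors."""

    data: dict

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def scenario(self) -> str | None:
        return self.data["scenario"]

    def network(self) -> NetworkSpec:
        n = self.data["network"]
        return NetworkSpec(
            act_weights=np.array(n["act_weights"]),
            inh_weights=np.array(n["inh_weights"]),
            stim_act_weights=np.array(n["stim_act_weights"]),
            stim_inh_weights=np.array(n["stim_inh_weights"]),
            act_offsets=np.array(n["act_offsets"]),
            inh_offsets=np.array(n["inh_offsets"]),
            steepness=np.array(n["sigma"]),
            rate_scale=np.array(n["gamma"]),
        )

    def rates(self) -> RateSet:
        return RateSet(**{k: float(v) for k, v in self.data["rates"].items()})

    def abundances(self) -> AbundanceTable:
        return AbundanceTable(**{k: float(v) for k, v in self.data["abundances"].items()})

    def sim(self, **overrides) -> SimConfig:
        s = dict(self.data["simulation"])
        kappa = s.pop("kappa")
        thresholds = tuple(self.data["bifurcation"]["thresholds"])
        cfg = SimConfig(
            seed=self.seed,
            kappa=None if kappa is None else float(kappa),
            thresholds=thresholds,
            **s,
        )
        return cfg.replace(**overrides) if overrides else cfg

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Merge a YAML config file (and/or an override dict) over the defaults.

    Raises ``ValueError`` naming the offending dotted key for unknown keys,
    and propagates the domain objects' validation errors for bad values.
    """
    data = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        data = _merge(data, user)
    if overrides:
        data = _merge(data, overrides)
    cfg = RunConfig(data=data)
    # eagerly validate the typed sections so errors surface at load time
    cfg.network()
    cfg.rates()
    cfg.abundances()
    cfg.sim()
    return cfg


def _header(meta: dict | None) -> str:
    lines = [f"# macpol {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as comma-delimited text with a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_diagram(diagram, path: str | Path, meta: dict | None = None) -> None:
    """Flatten a bifurcation diagram into a delimited table.

    Columns: swept parameter value, the three node states, stability flag,
    max eigenvalue real part and the branch index; folds are written next to
    it as ``<stem>_folds<suffix>``.
    """
    rows = []
    for bi, br in enumerate(diagram.branches):
        for value, eq in br.samples:
            rows.append(
                (
                    value,
                    eq.state[0],
                    eq.state[1],
                    eq.state[2],
                    int(eq.stable),
                    eq.eigenvalue_max_real,
                    bi,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[diagram.param_name, "NFkB", "STAT1", "STAT6", "stable", "eig_max_real", "branch"],
    )
    meta = dict(meta or {})
    meta["fixed_stimuli"] = diagram.fixed_stimuli.as_array().tolist()
    write_table(df, path, meta)
    path = Path(path)
    folds = pd.DataFrame(
        [
            (f.param_name, f.param_value, f.state[0], f.state[1], f.state[2])
            for f in diagram.folds
        ],
        columns=["param", "value", "NFkB", "STAT1", "STAT6"],
    )
    write_table(folds, path.with_name(path.stem + "_folds" + path.suffix), meta)


def write_graph_edges(graph, path: str | Path, meta: dict | None = None) -> None:
    """Write a reachability graph as an edge list (plus isolated nodes)."""
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append(
            (
                "".join(l[0] for l in u),
                "".join(l[0] for l in v),
                ";".join(data.get("stimuli", [])),
                ";".join(data.get("conditions", [])),
            )
        )
    df = pd.DataFrame(rows, columns=["source", "target", "stimuli", "conditions"])
    meta = dict(meta or {})
    meta["nodes"] = ",".join(sorted("".join(l[0] for l in n) for n in graph.nodes))
    write_table(df, path, meta)


def read_graph_edges(path: str | Path) -> pd.DataFrame:
    return read_table(path).fillna("")
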