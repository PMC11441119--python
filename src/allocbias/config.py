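"""Study configuration files (YAML) and shipped fixture configs.

A config file encodes one :class:`~allocbias.montecarlo.StudyConfig`::

    name: table3_m2
    N: 32
    m: 2
    alpha: 0.05
    corr: identity              # or {exchangeable: 0.5}, or an m x m matrix
    nu: 0.1                     # eta_k = nu * effect size
    effect_size: 1.024          # scalar (homogeneous) or list of m values
    procedure: sidak            # or all_or_none
    r: 100000
    seed: 20240930
    rps:
      - {name: CR}
      - {name: BSD, b: 3}
      - {name: MP, b: 3}
      - {name: PBR, block_size: 4}
      - {name: RAR}
      - {name: EBC, p: 0.67}
      - {name: CHEN, p: 0.67, b: 2}

The bias policy may alternatively be given directly as ``eta: [..]``.
Fixture configs for the shipped study settings live in
``allocbias/configs`` and can be loaded by name with
:func:`load_fixture_config`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .biasing import BiasPolicy
from .error_rates import TrialDesign
from .exceptions import ConfigurationError
from .montecarlo import StudyConfig
from .randomization import RPSpec

__all__ = ["parse_config", "load_config", "load_fixture_config",
           "fixture_config_names"]


def _parse_corr(spec, m: int):
    if spec is None or spec == "identity":
        return None
    if isinstance(spec, dict) and set(spec) == {"exchangeable"}:
        rho = float(spec["exchangeable"])
        corr = np.full((m, m), rho)
        np.fill_diagonal(corr, 1.0)
        return corr
    corr = np.asarray(spec, dtype=float)
    if corr.shape != (m, m):
        raise ConfigurationError(f"corr must be {m}x{m}, got shape {corr.shape}")
    return corr


def _parse_policy(raw: dict, m: int) -> BiasPolicy:
    if "eta" in raw:
        eta = np.atleast_1d(np.asarray(raw["eta"], dtype=float))
        if eta.size == 1:
            eta = np.full(m, eta[0])
        return BiasPolicy(eta)
    if "nu" not in raw:
        raise ConfigurationError("config needs either 'eta' or 'nu' + effect sizes")
    e = raw.get("effect_sizes", raw.get("effect_size"))
    if e is None:
        raise ConfigurationError("'nu' requires 'effect_size' or 'effect_sizes'")
    e = np.atleast_1d(np.asarray(e, dtype=float))
    if e.size == 1:
        e = np.full(m, e[0])
    if e.size != m:
        raise ConfigurationError(f"effect sizes must have length {m}")
    return BiasPolicy.from_effect_sizes(float(raw["nu"]), e)


def parse_config(raw: dict) -> StudyConfig:
    """Build a :class:`StudyConfig` from a parsed YAML mapping."""
    try:
        m = int(raw["m"])
        design = TrialDesign(
            N=int(raw["N"]), m=m, alpha=float(raw.get("alpha", 0.05)),
            sigma=raw.get("sigma"), corr=_parse_corr(raw.get("corr"), m),
        )
        policy = _parse_policy(raw, m)
        rps = tuple(RPSpec(**entry) for entry in raw["rps"])
        return StudyConfig(
            design=design, policy=policy, rps=rps,
            procedure=raw["procedure"], r=int(raw["r"]),
            seed=int(raw["seed"]), name=str(raw.get("name", "")),
        )
    except KeyError as exc:
        raise ConfigurationError(f"config is missing required key {exc}") from exc


def load_config(path: str | Path) -> StudyConfig:
    """Load a study configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    cfg = parse_config(raw)
    if not cfg.name:
        object.__setattr__(cfg, "name", Path(path).stem)
    return cfg


def fixture_config_names() -> list[str]:
    """Names of the shipped study-setting configs."""
    pkg = resources.files("allocbias") / "configs"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_fixture_config(name: str) -> StudyConfig:
    """Load a shipped config by name, e.g. ``table3_m2``."""
    pkg = resources.files("allocbias") / "configs" / f"{name}.yaml"
    if not pkg.is_file():
        raise ConfigurationError(
            f"unknown fixture config {name!r}; available: "
            f"{', '.join(fixture_config_names())}"
        )
    raw = yaml.safe_load(pkg.read_text())
    raw.setdefault("name", name)
    return parse_config(raw)
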