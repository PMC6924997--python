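"""Run configuration: a serialisable description of a full analysis.

A :class:`RunConfig` bundles the simulator block, the basis block, the
reconstruction scheme and the quantification settings; a run is
reproducible from the RunConfig alone (it includes the seed).  Configs are
read from YAML mappings; validation errors name the offending field path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import SimConfig

__all__ = ["BasisConfig", "SchemeConfig", "QuantConfig", "RunConfig", "load_run_config"]


@dataclass(frozen=True)
class BasisConfig:
    k: int = 8
    exponent: float | None = None  # None -> k - 1
    kind: str = "cosine"  # cosine | delta | bimodal
    alpha: float = 0.5  # mixing weight of the bimodal transform

    def to_dict(self) -> dict:
        return {"k": self.k, "exponent": self.exponent, "kind": self.kind,
                "alpha": self.alpha}


@dataclass(frozen=True)
class SchemeConfig:
    kind: str = "fixed_model"  # fixed_model | kfold
    n_folds: int | None = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_folds": self.n_folds}


@dataclass(frozen=True)
class QuantConfig:
    n_repeats: int = 100
    baseline_subtract: bool = False

    def to_dict(self) -> dict:
        return {"n_repeats": self.n_repeats,
                "baseline_subtract": self.baseline_subtract}


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    basis: BasisConfig = field(default_factory=BasisConfig)
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "basis": self.basis.to_dict(),
            "scheme": self.scheme.to_dict(),
            "quant": self.quant.to_dict(),
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }


_SIM_FIELDS = {
    "n_voxels": int,
    "n_neurons_per_voxel": int,
    "orientations": list,
    "n_trials_per_cell": int,
    "gains": list,
    "noise_sd": (int, float),
    "tuning_sd_range": list,
    "amplitude_range": list,
    "seed": int,
    "period": (int, float),
}


def _check_type(path: str, value, expected) -> None:
    if not isinstance(value, expected):
        names = (
            expected.__name__
            if isinstance(expected, type)
            else "/".join(t.__name__ for t in expected)
        )
        raise ConfigError(f"{path}: expected {names}, got {type(value).__name__}")


def _build_sim(block: dict) -> SimConfig:
    if "seed" not in block:
        raise ConfigError("sim.seed: missing (a run must state its seed)")
    kwargs = {}
    for key, value in block.items():
        if key not in _SIM_FIELDS:
            raise ConfigError(f"sim.{key}: unknown field")
        _check_type(f"sim.{key}", value, _SIM_FIELDS[key])
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    try:
        return SimConfig(**kwargs)
    except Exception as exc:  # surface invariant violations with the block path
        raise ConfigError(f"sim: {exc}") from exc


def load_run_config(source) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file or mapping.

    Raises
    ------
    ConfigError
        Naming the field path of the first violation found.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except OSError as exc:
            raise ConfigError(f"cannot read config file {source}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file {source} is not valid YAML: {exc}") from exc
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    known = {"sim", "basis", "scheme", "quant", "output_dir", "log_level"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"{key}: unknown top-level section")

    sim = _build_sim(dict(raw.get("sim", {})))

    basis_raw = dict(raw.get("basis", {}))
    for key in basis_raw:
        if key not in {"k", "exponent", "kind", "alpha"}:
            raise ConfigError(f"basis.{key}: unknown field")
    if "kind" in basis_raw and basis_raw["kind"] not in ("cosine", "delta", "bimodal"):
        raise ConfigError(
            f"basis.kind: must be cosine, delta or bimodal, got {basis_raw['kind']!r}"
        )
    basis = BasisConfig(**basis_raw)

    scheme_raw = dict(raw.get("scheme", {}))
    for key in scheme_raw:
        if key not in {"kind", "n_folds"}:
            raise ConfigError(f"scheme.{key}: unknown field")
    if "kind" in scheme_raw and scheme_raw["kind"] not in ("fixed_model", "kfold"):
        raise ConfigError(
            f"scheme.kind: must be fixed_model or kfold, got {scheme_raw['kind']!r}"
        )
    scheme = SchemeConfig(**scheme_raw)
    if scheme.kind == "kfold" and scheme.n_folds is None:
        raise ConfigError("scheme.n_folds: required when scheme.kind is kfold")

    quant_raw = dict(raw.get("quant", {}))
    for key in quant_raw:
        if key not in {"n_repeats", "baseline_subtract"}:
            raise ConfigError(f"quant.{key}: unknown field")
    quant = QuantConfig(**quant_raw)
    if quant.n_repeats < 1:
        raise ConfigError(f"quant.n_repeats: must be >= 1, got {quant.n_repeats}")

    return RunConfig(
        sim=sim,
        basis=basis,
        scheme=scheme,
        quant=quant,
        output_dir=str(raw.get("output_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )
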