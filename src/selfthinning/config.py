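"""Run configuration: one flat YAML file drives the whole pipeline.

The file has optional nested blocks ``simulate`` (a
:class:`~selfthinning.synthetic.SimConfig`), ``priors``, ``mcmc``, plus
top-level keys ``input`` (CSV path), ``forms`` (list of model labels),
``sff`` (bool), ``outdir``, ``seed``, ``mortality_threshold``.  Exactly one
data source — ``input`` or ``simulate`` — must be present for a fit run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gibbs import MCMCConfig, ModelForm
from .priors import PriorSpec, default_priors
from .synthetic import SimConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """The run configuration is malformed."""


@dataclass
class RunConfig:
    input: str | None = None
    simulate: SimConfig | None = None
    forms: list[ModelForm] = field(default_factory=lambda: [ModelForm.M1, ModelForm.M2])
    priors: PriorSpec = field(default_factory=default_priors)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    sff: bool = False
    rmse_mode: str = "conditional"
    mortality_threshold: float = 0.10
    outdir: str = "selfthinning_out"
    seed: int = 0

    def require_source(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one data source required: set 'input' (CSV path) "
                "XOR a 'simulate' block"
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "forms": [f.value for f in self.forms],
            "priors": self.priors.to_dict(),
            "mcmc": self.mcmc.to_dict(),
            "sff": self.sff,
            "rmse_mode": self.rmse_mode,
            "mortality_threshold": self.mortality_threshold,
            "outdir": self.outdir,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        unknown = set(d) - {
            "input", "simulate", "forms", "priors", "mcmc", "sff",
            "rmse_mode", "mortality_threshold", "outdir", "seed",
        }
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls()
        cfg.input = d.get("input")
        if d.get("simulate") is not None:
            cfg.simulate = SimConfig.from_dict(d["simulate"])
        if "forms" in d:
            try:
                cfg.forms = [ModelForm(f) for f in d["forms"]]
            except ValueError as exc:
                raise ConfigError(str(exc)) from None
        if d.get("priors"):
            cfg.priors = PriorSpec.from_dict(d["priors"])
        if d.get("mcmc"):
            cfg.mcmc = MCMCConfig.from_dict(d["mcmc"])
        cfg.sff = bool(d.get("sff", cfg.sff))
        cfg.rmse_mode = d.get("rmse_mode", cfg.rmse_mode)
        cfg.mortality_threshold = float(d.get("mortality_threshold", cfg.mortality_threshold))
        cfg.outdir = d.get("outdir", cfg.outdir)
        cfg.seed = int(d.get("seed", cfg.seed))
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from None
        return cls.from_dict(raw or {})
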