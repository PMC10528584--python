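"""Model parameters: rate constants, pools, induction and readout settings.

Parameters are grouped in the same sections as the shipped YAML config
(``induction``, ``nhej``, ``hr``, ``ssa``, ``altej``, ``gammah2ax``,
``pools``, ``readout``, ``solver``).  Rate constants keep their conventional
symbols (K for NHEJ and the H2AX module, P for HR, Q for SSA, R for Alt-EJ);
reverse constants use an ``m`` infix, so ``Km1`` is the reverse of ``K1``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml


class ConfigurationError(ValueError):
    """A required parameter is missing or out of range."""


RATE_SECTIONS = ("nhej", "hr", "ssa", "altej", "gammah2ax")

#: Keys in ``gammah2ax`` that are not rate constants.
_GH2AX_OPTIONS = ("dephospho_coupling",)


@dataclass
class ModelParameters:
    """All tunable quantities of the repair model.

    ``rate(name)`` resolves a constant by symbol regardless of section;
    ``with_updates`` returns a modified copy and is the hook the calibration
    module uses to move free parameters.
    """

    induction: dict[str, float] = field(default_factory=dict)
    nhej: dict[str, float] = field(default_factory=dict)
    hr: dict[str, float] = field(default_factory=dict)
    ssa: dict[str, float] = field(default_factory=dict)
    altej: dict[str, float] = field(default_factory=dict)
    gammah2ax: dict[str, Any] = field(default_factory=dict)
    pools: dict[str, float] = field(default_factory=dict)
    readout: dict[str, float] = field(default_factory=dict)
    solver: dict[str, Any] = field(default_factory=dict)

    # -- access ---------------------------------------------------------
    def _rate_maps(self) -> Iterator[dict[str, float]]:
        for sec in RATE_SECTIONS:
            yield getattr(self, sec)

    def rate(self, name: str) -> float:
        for m in self._rate_maps():
            if name in m and name not in _GH2AX_OPTIONS:
                return float(m[name])
        raise ConfigurationError(f"missing rate constant {name!r}")

    def has_rate(self, name: str) -> bool:
        return any(name in m for m in self._rate_maps()) and name not in _GH2AX_OPTIONS

    @property
    def alpha(self) -> float:
        return float(self.induction["alpha"])

    @property
    def f_ir(self) -> float:
        return float(self.induction["f_ir"])

    @property
    def f_micro(self) -> float:
        return float(self.induction["f_micro"])

    @property
    def dephospho_coupling(self) -> str:
        return str(self.gammah2ax.get("dephospho_coupling", "flux"))

    def pool(self, species: str) -> float:
        return float(self.pools.get(species, 0.0))

    # -- mutation -------------------------------------------------------
    def _locate(self, name: str) -> tuple[str, str]:
        """Return (section, key) holding parameter ``name``."""
        if name in self.induction:
            return "induction", name
        for sec in RATE_SECTIONS:
            if name in getattr(self, sec):
                return sec, name
        if name.startswith("pool:"):
            key = name.split(":", 1)[1]
            if key in self.pools:
                return "pools", key
        if name in self.readout:
            return "readout", name
        raise ConfigurationError(f"unknown parameter {name!r}")

    def value(self, name: str) -> float:
        sec, key = self._locate(name)
        return float(getattr(self, sec)[key])

    def with_updates(self, updates: dict[str, float]) -> "ModelParameters":
        new = copy.deepcopy(self)
        for name, value in updates.items():
            sec, key = new._locate(name)
            getattr(new, sec)[key] = float(value)
        return new

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for key in ("alpha", "f_ir", "f_micro"):
            if key not in self.induction:
                raise ConfigurationError(f"missing induction parameter {key!r}")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if not 0.0 <= self.f_ir < 1.0:
            raise ConfigurationError("f_ir must lie in [0, 1)")
        if not 0.0 <= self.f_micro <= 1.0:
            raise ConfigurationError("f_micro must lie in [0, 1]")
        for sec in RATE_SECTIONS:
            for name, value in getattr(self, sec).items():
                if name in _GH2AX_OPTIONS:
                    continue
                if float(value) < 0:
                    raise ConfigurationError(f"rate constant {name!r} must be >= 0")
        for sp, value in self.pools.items():
            if float(value) < 0:
                raise ConfigurationError(f"initial pool {sp!r} must be >= 0")
        if self.dephospho_coupling not in ("flux", "stock"):
            raise ConfigurationError(
                "gammah2ax.dephospho_coupling must be 'flux' or 'stock'"
            )

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        kwargs = {
            sec: dict(data.get(sec, {}))
            for sec in (
                "induction",
                "nhej",
                "hr",
                "ssa",
                "altej",
                "gammah2ax",
                "pools",
                "readout",
                "solver",
            )
        }
        params = cls(**kwargs)
        params.validate()
        return params

    def to_dict(self) -> dict[str, Any]:
        return {
            "induction": dict(self.induction),
            "nhej": dict(self.nhej),
            "hr": dict(self.hr),
            "ssa": dict(self.ssa),
            "altej": dict(self.altej),
            "gammah2ax": dict(self.gammah2ax),
            "pools": dict(self.pools),
            "readout": dict(self.readout),
            "solver": dict(self.solver),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """Baseline parameter set shipped with the package."""
    text = resources.files("dsbrepair.data").joinpath("default_params.yaml").read_text()
    return ModelParameters.from_dict(yaml.safe_load(text))
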