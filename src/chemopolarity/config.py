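"""Run-configuration schema, validation and provenance.

A run configuration is a YAML document with sections ``model``,
``geometry``, ``stimulus``, ``protocol``, ``wound`` and ``output``.  All
physical quantities carry the units documented in
:class:`~chemopolarity.params.RateParameters` (membrane densities in
molecules/um^2, concentrations in uM, lengths in um, times in s; the wound
section uses mm and hours).  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import SHAPES
from .params import RateParameters, FeedbackToggles
from .solver import SimulationProtocol
from .wound import WoundParams

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Schema violation; carries one message per offending field."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass
class RunConfig:
    """Fully-resolved configuration for one scenario."""

    params: RateParameters = field(default_factory=RateParameters)
    toggles: FeedbackToggles = field(default_factory=FeedbackToggles)
    shape: str = "symmetric"
    h: float = 0.2
    n_membrane: int | None = None
    rfrac: float = 0.1
    rsteep: float = 0.1
    direction: int = +1
    protocol: SimulationProtocol = field(default_factory=SimulationProtocol)
    wound: WoundParams = field(default_factory=WoundParams)
    output_dir: str = "out"
    rate_laws: str = "mass_action_v1"
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "model": {"parameters": self.params.to_dict(),
                      "toggles": dataclasses.asdict(self.toggles),
                      "rate_laws": self.rate_laws},
            "geometry": {"shape": self.shape, "h": self.h,
                         "n_membrane": self.n_membrane},
            "stimulus": {"rfrac": self.rfrac, "rsteep": self.rsteep,
                         "direction": self.direction},
            "protocol": dataclasses.asdict(self.protocol),
            "wound": dataclasses.asdict(self.wound),
            "output": {"directory": self.output_dir},
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def _coerce(value, target_type):
    """Coerce YAML-1.1 scalars (e.g. '1.0e9' parsed as str) to numbers."""
    if target_type in ("float", "int", "bool") or \
            target_type in (float, int, bool):
        if isinstance(value, str):
            try:
                return float(value) if "." in value or "e" in value.lower() \
                    else int(value)
            except ValueError:
                return value
    return value


def _build_section(cls, data: dict, section: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    known = set(fields)
    unknown = set(data) - known
    for k in sorted(unknown):
        errors.append(f"{section}.{k}: unknown key")
    kwargs = {k: _coerce(v, fields[k].type) for k, v in data.items()
              if k in known}
    try:
        obj = cls(**kwargs)
        if hasattr(obj, "validate"):
            obj.validate()
        return obj
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def validate_config(doc: dict | str) -> RunConfig:
    """Validate a raw configuration (YAML text or mapping) into a RunConfig.

    Raises :class:`ConfigError` naming every offending field and its
    constraint.
    """
    if isinstance(doc, str):
        doc = yaml.safe_load(doc) or {}
    if not isinstance(doc, dict):
        raise ConfigError(["top level must be a mapping"])
    errors: list[str] = []
    known_sections = {"label", "model", "geometry", "stimulus", "protocol",
                      "wound", "output"}
    for k in sorted(set(doc) - known_sections):
        errors.append(f"{k}: unknown section")

    model = doc.get("model", {}) or {}
    params = _build_section(RateParameters, model.get("parameters", {}) or {},
                            "model.parameters", errors)
    toggles = _build_section(FeedbackToggles, model.get("toggles", {}) or {},
                             "model.toggles", errors)
    for k in sorted(set(model) - {"parameters", "toggles", "rate_laws"}):
        errors.append(f"model.{k}: unknown key")

    geo = doc.get("geometry", {}) or {}
    for k in sorted(set(geo) - {"shape", "h", "n_membrane"}):
        errors.append(f"geometry.{k}: unknown key")
    shape = geo.get("shape", "symmetric")
    if shape not in SHAPES:
        errors.append(f"geometry.shape: must be one of {SHAPES}")
    h = geo.get("h", 0.2)
    if not isinstance(h, (int, float)) or not 0 < h <= 0.5:
        errors.append("geometry.h: must lie in (0, 0.5] um")

    stim = doc.get("stimulus", {}) or {}
    for k in sorted(set(stim) - {"rfrac", "rsteep", "direction"}):
        errors.append(f"stimulus.{k}: unknown key")
    if "rfrac" not in stim:
        errors.append("stimulus.rfrac: required field is missing")
    rfrac = stim.get("rfrac", 0.1)
    rsteep = stim.get("rsteep", 0.0)
    direction = stim.get("direction", +1)
    if not isinstance(rfrac, (int, float)) or rfrac < 0:
        errors.append("stimulus.rfrac: must be >= 0")
    if not isinstance(rsteep, (int, float)) or abs(rsteep) >= 2:
        errors.append("stimulus.rsteep: |rsteep| must be < 2 so that the "
                      "receptor field stays non-negative")
    if direction not in (+1, -1):
        errors.append("stimulus.direction: must be +1 or -1")

    protocol = _build_section(SimulationProtocol, doc.get("protocol", {}) or {},
                              "protocol", errors)
    wound = _build_section(WoundParams, doc.get("wound", {}) or {},
                           "wound", errors)

    out = doc.get("output", {}) or {}
    for k in sorted(set(out) - {"directory"}):
        errors.append(f"output.{k}: unknown key")

    if errors:
        raise ConfigError(errors)
    return RunConfig(params=params, toggles=toggles, shape=shape, h=float(h),
                     n_membrane=geo.get("n_membrane"),
                     rfrac=float(rfrac), rsteep=float(rsteep),
                     direction=int(direction), protocol=protocol, wound=wound,
                     output_dir=str(out.get("directory", "out")),
                     rate_laws=str(model.get("rate_laws", "mass_action_v1")),
                     label=str(doc.get("label", "")))


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())


def write_provenance(cfg: RunConfig, out_dir) -> None:
    """Echo the exact resolved configuration into the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    from . import __version__
    (out / "provenance.txt").write_text(
        f"chemopolarity {__version__}\nrate_laws: {cfg.rate_laws}\n")
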