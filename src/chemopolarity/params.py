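"""Kinetic parameters, diffusivities and feedback toggles for the PLC/PKC network.

Conventions
-----------
Membrane species carry densities in molecules/um^2; cytosolic species carry
concentrations in uM.  Rate constants are "membrane-referred": a bimolecular
step between a membrane species and a cytosolic species has units
1/(uM s) and yields a flux in molecules/um^2/s when multiplied by a membrane
density and a near-membrane concentration.  1 uM = 602.214 molecules/um^3.

The three positive feedback loops are toggled independently:

* ``pfl1`` — phosphatidic acid (PA) stabilises the receptor–PLC complex,
  reducing its effective off-rate (off means ``K_PA = 0``, equivalently
  ``epsilon = 1``).
* ``pfl2`` — active PKC amplifies PLD-mediated PA synthesis through a Hill
  function (off means ``K_PLD = 0``, equivalently ``gamma = 1``).
* ``marcks`` — MARCKS sequesters PIP2 and is neutralised by PKC
  phosphorylation (off means total MARCKS is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import yaml

#: molecules per um^3 in a 1 uM solution
UM_TO_PER_UM3 = 602.214

MEMBRANE_SPECIES = ("e", "p", "d", "dp", "c_star", "c_inact", "m_free", "m_pip2")
CYTOSOL_SPECIES = ("E", "C", "M", "M_p")


@dataclass
class FeedbackToggles:
    """On/off switches for the three positive feedback loops."""

    pfl1: bool = True
    pfl2: bool = False
    marcks: bool = True


@dataclass
class RateParameters:
    """Every kinetic constant and diffusivity of the signaling network.

    Default values are the package's calibrated base case (see
    ``docs/methods.md`` for the calibration procedure): PFL 1 + MARCKS
    regulation, PFL 2 available but off by default.
    """

    # --- PLC recruitment (membrane-referred) ---
    k_on_e: float = 1.0          # 1/(uM s)
    k_off_e: float = 2.9         # 1/s, basal complex off-rate
    K_PA: float = 0.065          # um^2/molecule, PA-PLC equilibrium constant (PFL 1)
    epsilon: float = 0.017       # dimensionless escape probability in [0, 1]

    # --- PIP2 hydrolysis and basal turnover ---
    k_hyd: float = 0.0025        # um^2/(molecule s), bilinear hydrolysis k_hyd*e*p
    K_m_hyd: float = 0.0         # molecules/um^2; 0 disables hydrolysis saturation
    V_synth_p: float = 4.9       # molecules/um^2/s, basal PIP2 synthesis
    k_deg_p: float = 0.0098      # 1/s, basal turnover of free PIP2

    # --- DAG <-> PA interconversion, basal PA turnover, PLD source ---
    k_DAGK: float = 0.28         # 1/s, DAG kinase (DAG -> PA)
    k_PAP: float = 0.072         # 1/s, PA phosphatase (PA -> DAG)
    k_basal_dp: float = 0.0177   # 1/s, basal PA consumption
    V_synth_dp: float = 0.01     # molecules/um^2/s, basal PA synthesis by PLD
    gamma: float = 1.0           # dimensionless PFL 2 gain (>= 1)
    K_PLD: float = 0.0           # um^2/molecule, PFL 2 saturation constant
    n_hill: int = 2              # PFL 2 Hill coefficient (1 or 2)

    # --- PKC membrane cycle ---
    k_on_c: float = 0.21         # 1/(uM s) per (#/um^2) of DAG
    k_off_c: float = 0.10        # 1/s, active PKC dissociation
    k_dp_c: float = 0.05         # 1/s, c* -> c dephosphorylation
    k_rp_c: float = 0.05         # 1/s, c -> c* autophosphorylation
    k_rel_c: float = 0.05        # 1/s, c -> cytosol dissociation

    # --- MARCKS cycle ---
    k_ins_m: float = 2.4         # molecules/um^2/s per uM, membrane insertion
    k_ret_m: float = 0.051       # 1/s, membrane retrieval of free MARCKS
    k_on_mp: float = 0.018       # um^2/(molecule s), MARCKS-PIP2 capture
    k_off_mp: float = 0.154      # 1/s, MARCKS-PIP2 release
    k_pkc_m: float = 0.10        # um^2/(molecule s), phosphorylation by active PKC
    K_pkc_m: float = 52.0        # molecules/um^2; >0 selects the cooperative
                                 # multi-site phosphorylation law
                                 # k_pkc_m*c*^2/(K_pkc_m + c*) per MARCKS
    k_deph_M: float = 0.047      # 1/s, cytosolic MARCKS dephosphorylation

    # --- total pools (whole-cell, expressed as cytosolic-equivalent uM) ---
    E_total: float = 0.087       # uM, total PLC
    C_total: float = 0.138       # uM, total PKC
    M_total: float = 16.0        # uM, total MARCKS (0 when marcks toggle off)

    # --- diffusivities, um^2/s ---
    D_e: float = 0.05
    D_p: float = 1.0
    D_d: float = 0.5
    D_dp: float = 0.5
    D_c_star: float = 0.1
    D_c_inact: float = 0.1
    D_m_free: float = 1.0
    D_m_pip2: float = 6.8
    D_E: float = 30.0
    D_C: float = 30.0
    D_M: float = 2.8
    D_M_p: float = 2.8

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "n_hill":
                if v not in (1, 2):
                    raise ValueError(f"n_hill must be 1 or 2, got {v}")
                continue
            if not isinstance(v, (int, float)):
                raise TypeError(f"{f.name} must be numeric, got {type(v)}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.gamma < 1.0:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")

    def membrane_diffusivities(self) -> dict[str, float]:
        return {
            "e": self.D_e, "p": self.D_p, "d": self.D_d, "dp": self.D_dp,
            "c_star": self.D_c_star, "c_inact": self.D_c_inact,
            "m_free": self.D_m_free, "m_pip2": self.D_m_pip2,
        }

    def cytosol_diffusivities(self) -> dict[str, float]:
        return {"E": self.D_E, "C": self.D_C, "M": self.D_M, "M_p": self.D_M_p}

    def replace(self, **kwargs: float) -> "RateParameters":
        d = asdict(self)
        for k, v in kwargs.items():
            if k not in d:
                raise KeyError(f"unknown parameter {k!r}")
            d[k] = v
        out = RateParameters(**d)
        out.validate()
        return out

    def scaled(self, name: str, factor: float) -> "RateParameters":
        """Return a copy with one parameter multiplied by ``factor``."""
        return self.replace(**{name: getattr(self, name) * factor})

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RateParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        p = cls(**dict(data))
        p.validate()
        return p


def base_parameters() -> RateParameters:
    """The calibrated base-case parameter set (PFL 1 + MARCKS)."""
    p = RateParameters()
    p.validate()
    return p


def base_toggles() -> FeedbackToggles:
    return FeedbackToggles(pfl1=True, pfl2=False, marcks=True)


def effective_parameters(params: RateParameters, toggles: FeedbackToggles) -> RateParameters:
    """Apply toggle semantics to the raw parameter set.

    ``pfl1`` off forces ``K_PA = 0``; ``pfl2`` off forces ``K_PLD = 0``;
    ``marcks`` off zeroes the total MARCKS pool.
    """
    kwargs: dict[str, float] = {}
    if not toggles.pfl1:
        kwargs["K_PA"] = 0.0
    if not toggles.pfl2:
        kwargs["K_PLD"] = 0.0
    if not toggles.marcks:
        kwargs["M_total"] = 0.0
    return params.replace(**kwargs) if kwargs else params


def save_parameters(params: RateParameters, toggles: FeedbackToggles, path) -> None:
    doc = {"parameters": params.to_dict(),
           "toggles": {"pfl1": toggles.pfl1, "pfl2": toggles.pfl2,
                       "marcks": toggles.marcks}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path) -> tuple[RateParameters, FeedbackToggles]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = RateParameters.from_dict(doc.get("parameters", {}))
    tog = doc.get("toggles", {})
    toggles = FeedbackToggles(pfl1=bool(tog.get("pfl1", True)),
                              pfl2=bool(tog.get("pfl2", False)),
                              marcks=bool(tog.get("marcks", True)))
    return params, toggles
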