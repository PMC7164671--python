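"""Reaction rate laws of the PLC/PKC/PA signaling network.

The network (all fluxes in molecules/um^2/s, evaluated per membrane node):

* activated receptors recruit cytosolic PLC (``E``) into an active
  receptor–PLC complex ``e``; phosphatidic acid (``dp``) prolongs the
  complex lifetime (PFL 1);
* active PLC hydrolyses free PIP2 (``p``) into DAG (``d``); MARCKS-bound
  PIP2 (``m_pip2``) is protected from hydrolysis; PIP2 has basal
  synthesis/turnover;
* DAG and PA interconvert by pseudo-first-order reactions (DAG kinases and
  PA phosphatases); PA has a small basal PLD source amplified by active PKC
  through a Hill function (PFL 2) and a basal consumption;
* DAG recruits cytosolic PKC (``C``) into active ``c_star``; membrane PKC is
  dephosphorylated to an inactive membrane form ``c_inact`` which either
  autophosphorylates back or dissociates to the cytosol;
* cytosolic MARCKS (``M``) inserts into the membrane (``m_free``), captures
  PIP2 (``m_pip2``), and is phosphorylated by active PKC, which releases
  both MARCKS (to cytosolic ``M_p``) and PIP2; ``M_p`` is dephosphorylated
  in the cytosol.

The inactive membrane PKC is taken to retain its bound DAG; that DAG is
returned to the free pool when the inactive form dissociates, so the DAG
backbone is conserved through the PKC cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import (RateParameters, FeedbackToggles, MEMBRANE_SPECIES,
                     CYTOSOL_SPECIES)

__all__ = [
    "MembraneState", "CytosolState", "plc_net_recruitment", "pld_rate",
    "pip2_hydrolysis_rate", "lipid_interconversion", "pkc_cycle_rates",
    "marcks_cycle_rates", "reaction_terms", "HYDROLYSIS_LAWS",
]


@dataclass
class MembraneState:
    """Densities of the 8 membrane species (molecules/um^2) on the membrane mesh."""

    e: np.ndarray
    p: np.ndarray
    d: np.ndarray
    dp: np.ndarray
    c_star: np.ndarray
    c_inact: np.ndarray
    m_free: np.ndarray
    m_pip2: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "MembraneState":
        return cls(*[np.zeros(n) for _ in MEMBRANE_SPECIES])

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in MEMBRANE_SPECIES}

    @property
    def p_total(self) -> np.ndarray:
        """Total PIP2: free plus MARCKS-bound."""
        return self.p + self.m_pip2

    @property
    def m_total(self) -> np.ndarray:
        """Membrane-associated MARCKS."""
        return self.m_free + self.m_pip2

    @property
    def d_total(self) -> np.ndarray:
        """Total DAG: free plus PKC-bound (active and inactive forms)."""
        return self.d + self.c_star + self.c_inact


@dataclass
class CytosolState:
    """Concentrations of the 4 cytosolic species (uM) on the interior mesh."""

    E: np.ndarray
    C: np.ndarray
    M: np.ndarray
    M_p: np.ndarray

    @classmethod
    def uniform(cls, n: int, E: float, C: float, M: float, M_p: float) -> "CytosolState":
        return cls(np.full(n, E), np.full(n, C), np.full(n, M), np.full(n, M_p))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in CYTOSOL_SPECIES}


def _check_nonneg(**named) -> None:
    for name, value in named.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def plc_net_recruitment(r_local, e, E_surface, dp, params: RateParameters,
                        toggles: FeedbackToggles | None = None, *,
                        validate: bool = True):
    """Net rate of PLC recruitment to the activated-receptor complex.

    ``k_on_e (r - e) E|_S  -  k_off_e (1 + eps K_PA dp)/(1 + K_PA dp) e``.
    The bracketed factor is PFL 1: PA lowers the effective off-rate from
    ``k_off_e`` toward ``epsilon * k_off_e``.  With ``K_PA = 0`` or
    ``epsilon = 1`` the bracket is identically 1.
    """
    if validate:
        _check_nonneg(r_local=r_local, e=e, E_surface=E_surface, dp=dp)
        if np.any(np.asarray(e) > np.asarray(r_local) * (1 + 1e-12) + 1e-9):
            raise ValueError("e must not exceed the local activated-receptor density")
    K_PA = params.K_PA if (toggles is None or toggles.pfl1) else 0.0
    x = K_PA * np.asarray(dp, dtype=float)
    bracket = (1.0 + params.epsilon * x) / (1.0 + x)
    return params.k_on_e * (np.asarray(r_local) - np.asarray(e)) * np.asarray(E_surface) \
        - params.k_off_e * bracket * np.asarray(e)


def pld_rate(c_star, params: RateParameters,
             toggles: FeedbackToggles | None = None, *, validate: bool = True):
    """PLD-mediated PA synthesis rate, amplified by active PKC (PFL 2).

    ``V_synth_dp (1 + gamma (K_PLD c*)^n) / (1 + (K_PLD c*)^n)``, bounded in
    ``[V_synth_dp, gamma V_synth_dp]``.
    """
    if validate:
        _check_nonneg(c_star=c_star)
    K_PLD = params.K_PLD if (toggles is None or toggles.pfl2) else 0.0
    x = (K_PLD * np.maximum(np.asarray(c_star, dtype=float), 0.0)) ** params.n_hill
    return params.V_synth_dp * (1.0 + params.gamma * x) / (1.0 + x)


def _hydrolysis_bilinear(e, p, params: RateParameters):
    return params.k_hyd * np.asarray(e) * np.asarray(p)


def _hydrolysis_saturable(e, p, params: RateParameters):
    p = np.asarray(p, dtype=float)
    return params.k_hyd * np.asarray(e) * p / (1.0 + p / params.K_m_hyd)


#: registry of PIP2-hydrolysis rate laws; the key used in a run is recorded
#: in output metadata.
HYDROLYSIS_LAWS: dict[str, Callable] = {
    "bilinear": _hydrolysis_bilinear,
    "saturable": _hydrolysis_saturable,
}


def pip2_hydrolysis_rate(e, p, params: RateParameters, *, validate: bool = True):
    """DAG production by active PLC acting on free PIP2 only.

    Default is the bilinear law ``k_hyd e p``; setting ``K_m_hyd > 0``
    selects the saturable variant ``k_hyd e p / (1 + p/K_m_hyd)``.
    """
    if validate:
        _check_nonneg(e=e, p=p)
    law = HYDROLYSIS_LAWS["saturable" if params.K_m_hyd > 0 else "bilinear"]
    return law(e, p, params)


def lipid_interconversion(d, dp, params: RateParameters, *, validate: bool = True):
    """Pseudo-first-order DAG/PA fluxes.

    Returns ``(d->dp flux, dp->d flux, dp degradation flux)`` =
    ``(k_DAGK d, k_PAP dp, k_basal_dp dp)``.  At steady state with a
    negligible PLD source this gives the proportionality
    ``dp/d = k_DAGK / (k_PAP + k_basal_dp)``.
    """
    if validate:
        _check_nonneg(d=d, dp=dp)
    d = np.asarray(d, dtype=float)
    dp = np.asarray(dp, dtype=float)
    return params.k_DAGK * d, params.k_PAP * dp, params.k_basal_dp * dp


def pa_dag_ratio(params: RateParameters) -> float:
    """Predicted steady-state PA/DAG ratio ``k_DAGK / (k_PAP + k_basal_dp)``."""
    return params.k_DAGK / (params.k_PAP + params.k_basal_dp)


def pkc_cycle_rates(d, c_star, c_inact, C_surface, params: RateParameters, *,
                    validate: bool = True) -> dict[str, np.ndarray]:
    """Fluxes of the PKC membrane cycle.

    ``bind`` consumes free DAG and cytosolic PKC to create ``c_star``;
    ``unbind`` reverses it; ``deact`` converts ``c_star`` to the inactive
    membrane form; ``react`` autophosphorylates it back; ``release`` returns
    inactive PKC (and its DAG) to the cytosolic / free-DAG pools.
    """
    if validate:
        _check_nonneg(d=d, c_star=c_star, c_inact=c_inact, C_surface=C_surface)
    d = np.asarray(d, dtype=float)
    return {
        "bind": params.k_on_c * d * np.asarray(C_surface),
        "unbind": params.k_off_c * np.asarray(c_star),
        "deact": params.k_dp_c * np.asarray(c_star),
        "react": params.k_rp_c * np.asarray(c_inact),
        "release": params.k_rel_c * np.asarray(c_inact),
    }


def marcks_phosphorylation_rate(c_star, params: RateParameters):
    """Per-MARCKS phosphorylation rate constant (1/s) as a function of
    active PKC density.

    ``K_pkc_m = 0`` selects the bilinear law ``k_pkc_m c*``; ``K_pkc_m > 0``
    selects the cooperative law ``k_pkc_m c*^2/(K_pkc_m + c*)``, which is
    quadratic in active PKC below ``K_pkc_m`` and linear above.  The
    cooperative form reflects the requirement for multiple PKC
    phosphorylations of the MARCKS effector domain before it releases from
    the membrane.
    """
    c = np.maximum(np.asarray(c_star, dtype=float), 0.0)
    if params.K_pkc_m > 0:
        return params.k_pkc_m * c * c / (params.K_pkc_m + c)
    return params.k_pkc_m * c


def marcks_cycle_rates(m_free, m_pip2, p, c_star, M_surface,
                       params: RateParameters,
                       toggles: FeedbackToggles | None = None, *,
                       validate: bool = True) -> dict[str, np.ndarray]:
    """Fluxes of the MARCKS membrane cycle.

    ``insert``/``retrieve`` exchange cytosolic unphosphorylated MARCKS with
    the membrane; ``capture``/``release_p`` are PIP2 binding and release;
    ``phos_free``/``phos_bound`` are PKC-mediated phosphorylation of the two
    membrane forms (the bound form liberates its PIP2).  The same rate
    constant applies to both membrane forms.
    """
    if validate:
        _check_nonneg(m_free=m_free, m_pip2=m_pip2, p=p, c_star=c_star,
                      M_surface=M_surface)
    if toggles is not None and not toggles.marcks:
        z = np.zeros_like(np.asarray(m_free, dtype=float))
        return {k: z for k in ("insert", "retrieve", "capture", "release_p",
                               "phos_free", "phos_bound")}
    c_star = np.asarray(c_star, dtype=float)
    phos = marcks_phosphorylation_rate(c_star, params)
    return {
        "insert": params.k_ins_m * np.asarray(M_surface, dtype=float),
        "retrieve": params.k_ret_m * np.asarray(m_free, dtype=float),
        "capture": params.k_on_mp * np.asarray(m_free) * np.asarray(p),
        "release_p": params.k_off_mp * np.asarray(m_pip2, dtype=float),
        "phos_free": phos * np.asarray(m_free),
        "phos_bound": phos * np.asarray(m_pip2),
    }


def reaction_terms(mem: MembraneState, cyt_surface: CytosolState,
                   r_field: np.ndarray, params: RateParameters,
                   toggles: FeedbackToggles, *, validate: bool = False
                   ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Assemble source terms for all membrane species and boundary fluxes
    for all cytosolic species.

    ``cyt_surface`` holds the cytosolic concentrations evaluated at the
    membrane-adjacent voxels, one value per membrane node.  Returned
    membrane sources are in molecules/um^2/s; cytosolic boundary fluxes are
    in molecules/um^2/s, positive into the cytosol (the solver converts them
    to concentration fluxes).
    """
    n = len(mem.e)
    for name, arr in {**mem.as_dict(), **cyt_surface.as_dict()}.items():
        if len(arr) != n:
            raise ValueError(f"field {name!r} has length {len(arr)}, expected {n}")
    if len(np.atleast_1d(r_field)) != n:
        raise ValueError("receptor field length does not match membrane mesh")

    v_plc = plc_net_recruitment(r_field, mem.e, cyt_surface.E, mem.dp, params,
                                toggles, validate=validate)
    v_hyd = pip2_hydrolysis_rate(mem.e, mem.p, params, validate=validate)
    f_dagk, f_pap, f_bas = lipid_interconversion(mem.d, mem.dp, params,
                                                 validate=validate)
    v_pld = pld_rate(mem.c_star, params, toggles, validate=validate)
    pkc = pkc_cycle_rates(mem.d, mem.c_star, mem.c_inact, cyt_surface.C,
                          params, validate=validate)
    mar = marcks_cycle_rates(mem.m_free, mem.m_pip2, mem.p, mem.c_star,
                             cyt_surface.M, params, toggles, validate=validate)

    mem_src = {
        "e": v_plc,
        "p": (params.V_synth_p - params.k_deg_p * mem.p - v_hyd
              - mar["capture"] + mar["release_p"] + mar["phos_bound"]),
        "d": (v_hyd - f_dagk + f_pap
              - pkc["bind"] + pkc["unbind"] + pkc["release"]),
        "dp": f_dagk - f_pap - f_bas + v_pld,
        "c_star": pkc["bind"] - pkc["unbind"] - pkc["deact"] + pkc["react"],
        "c_inact": pkc["deact"] - pkc["react"] - pkc["release"],
        "m_free": (mar["insert"] - mar["retrieve"] - mar["capture"]
                   + mar["release_p"] - mar["phos_free"]),
        "m_pip2": mar["capture"] - mar["release_p"] - mar["phos_bound"],
    }
    cyt_flux = {
        "E": -v_plc,
        "C": -pkc["bind"] + pkc["unbind"] + pkc["release"],
        "M": -mar["insert"] + mar["retrieve"],
        "M_p": mar["phos_free"] + mar["phos_bound"],
    }
    return mem_src, cyt_flux


def cytosol_bulk_terms(cyt: CytosolState, params: RateParameters
                       ) -> dict[str, np.ndarray]:
    """Volumetric reactions in the cytosol (uM/s): MARCKS dephosphorylation."""
    deph = params.k_deph_M * cyt.M_p
    zero = np.zeros_like(deph)
    return {"E": zero, "C": zero, "M": deph, "M_p": -deph}
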