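"""Scenario generators: one-command configurations for the standard scenarios.

Each fixture returns the fully-specified :class:`RunConfig` list for one
standard experiment scenario: the five-steepness dose-response sweep,
diffusivity perturbations, the asymmetric-geometry runs, the DAG-kinase
fold-change comparison, the feedback-combination panels, and the
wound-invasion comparison.

The scenario protocols use the coarse production mesh (h = 0.2 um) with a
raised step cap; accuracy is carried by the error-controlled implicit
integrator (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

from .analysis import log_rfrac_grid
from .config import RunConfig
from .params import (RateParameters, FeedbackToggles, base_parameters,
                     base_toggles)
from .solver import SimulationProtocol
from .wound import WoundParams

__all__ = ["fixture", "FIXTURES", "scenario_protocol", "scenario_rfracs"]

#: sweep steepness values: uniform up to a 2-fold (67%) difference
SWEEP_RSTEEPS = (0.0, 0.03, 0.1, 0.3, 0.67)


def scenario_protocol(reverse: bool = True) -> SimulationProtocol:
    """Production protocol: 20,000 s per phase on the coarse-mesh setup."""
    return SimulationProtocol(duration_phase1=20000.0, reverse=reverse,
                              duration_phase2=20000.0, max_dt=200.0)


def scenario_rfracs(lo: float = 0.02, hi: float = 0.5,
                    per_decade: int = 10) -> list[float]:
    return log_rfrac_grid(lo, hi, per_decade)


def _base_cfg(label: str, **kw) -> RunConfig:
    cfg = RunConfig(params=base_parameters(), toggles=base_toggles(),
                    shape="symmetric", h=0.2, protocol=scenario_protocol(),
                    label=label)
    return dc_replace(cfg, **kw)


def _fig2_sweep() -> list[RunConfig]:
    """Dose-response sweeps at five steepness values, base feedbacks
    (PFL 1 + MARCKS), plus the MARCKS-off comparison at each steepness."""
    out = []
    for rsteep in SWEEP_RSTEEPS:
        out.append(_base_cfg(f"sweep_rsteep={rsteep}", rsteep=rsteep))
        out.append(_base_cfg(f"sweep_rsteep={rsteep}_no_marcks",
                             rsteep=rsteep,
                             toggles=FeedbackToggles(pfl1=True, pfl2=False,
                                                     marcks=False)))
    return out


def _fig3_diffusivity() -> list[RunConfig]:
    """Fold-changes of MARCKS cytosolic diffusivities (M, M_p) and of the
    membrane diffusivities of total PIP2 and membrane MARCKS carriers."""
    base = base_parameters()
    out = []
    for fold in (0.1, 0.3, 1.0, 3.0, 10.0):
        p = base.replace(D_M=base.D_M * fold, D_M_p=base.D_M_p * fold)
        out.append(_base_cfg(f"cyto_marcks_D_x{fold}", params=p))
    for fold in (0.3, 1.0, 3.0):
        p = base.replace(D_p=base.D_p * fold,
                         D_m_pip2=base.D_m_pip2 * fold,
                         D_m_free=base.D_m_free * fold)
        out.append(_base_cfg(f"membrane_pip2_D_x{fold}", params=p))
    return out


def _fig4_asymmetric() -> list[RunConfig]:
    """Back-blunted geometry: uniform stimulus plus gradients in both
    directions at each steepness."""
    out = [_base_cfg("asym_uniform", shape="back_blunted", rsteep=0.0)]
    for rsteep in (0.03, 0.1, 0.3, 0.67):
        out.append(_base_cfg(f"asym_rsteep={rsteep}_fwd",
                             shape="back_blunted", rsteep=rsteep,
                             direction=+1))
        out.append(_base_cfg(f"asym_rsteep={rsteep}_rev",
                             shape="back_blunted", rsteep=rsteep,
                             direction=-1))
    return out


def _fig5_dagk() -> list[RunConfig]:
    """DAG kinase rate constant at 0.3x, 1x and 3x, 10% steepness."""
    base = base_parameters()
    return [_base_cfg(f"k_DAGK_x{f}", params=base.scaled("k_DAGK", f))
            for f in (0.3, 1.0, 3.0)]


def _fig6_feedback_combos() -> list[RunConfig]:
    """Feedback-combination panels at 10% steepness.

    (a) PFL 2 + MARCKS, no PFL 1 (Hill n = 1 and n = 2 variants);
    (b) PFL 1 + PFL 2, no MARCKS; (c) all three feedbacks.
    PFL 2 strength is stated as the pair (K_PLD, gamma*V_synth_dp).
    """
    base = base_parameters()

    def pfl2_params(K_PLD: float, gainV: float, n: int) -> RateParameters:
        return base.replace(K_PLD=K_PLD, gamma=max(gainV / base.V_synth_dp,
                                                   1.0), n_hill=n)

    out = []
    for n in (1, 2):
        out.append(_base_cfg(
            f"pfl2_marcks_n{n}", params=pfl2_params(0.05, 10.0, n),
            toggles=FeedbackToggles(pfl1=False, pfl2=True, marcks=True)))
    out.append(_base_cfg(
        "pfl1_pfl2_no_marcks", params=pfl2_params(0.1, 10.0, 2),
        toggles=FeedbackToggles(pfl1=True, pfl2=True, marcks=False)))
    out.append(_base_cfg(
        "all_three", params=pfl2_params(0.1, 10.0, 2),
        toggles=FeedbackToggles(pfl1=True, pfl2=True, marcks=True)))
    return out


def _fig7_wound() -> list[RunConfig]:
    """10-day, 10-replicate wound invasion with and without chemotaxis."""
    out = []
    for chemo in (True, False):
        cfg = _base_cfg(f"wound_chemotaxis={'on' if chemo else 'off'}")
        cfg = dc_replace(cfg, wound=WoundParams(chemotaxis_enabled=chemo))
        out.append(cfg)
    return out


FIXTURES = {
    "fig2_sweep": _fig2_sweep,
    "fig3_diffusivity": _fig3_diffusivity,
    "fig4_asymmetric": _fig4_asymmetric,
    "fig5_dagk": _fig5_dagk,
    "fig6_feedback_combos": _fig6_feedback_combos,
    "fig7_wound": _fig7_wound,
}


def fixture(name: str) -> list[RunConfig]:
    """Return the configuration list for a named scenario."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(FIXTURES)}")
    return FIXTURES[name]()
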