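"""Polarization metrics, dose-response sweeps and phase-plane analysis.

The polarization readout is the front/back ratio of active PKC density at
steady state.  Sweeps over the midpoint receptor occupancy ``rfrac`` at
fixed gradient steepness ``rsteep`` map the dose-response window of the
gradient-sensing circuit; the width of that window (largest/smallest
polarized ``rfrac``) quantifies dose-response robustness.

The phase-plane construction reduces the membrane dynamics at one location
to two variables: membrane-recruited PLC (e) and total DAG
(d_tot = free + PKC-bound).  It assumes (i) diffusion of active PLC and
DAG-containing species is negligible against their reaction terms, and
(ii) PA is slaved to DAG through the interconversion steady state
``dp = lambda * d`` with ``lambda = k_DAGK/(k_PAP + k_basal_dp)``.  The
e-nullcline rises with d_tot through PFL 1 (flat when PFL 1 is off); the
d-nullcline is a straight line through the origin whose slope is inversely
proportional to the local free PIP2 density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .geometry import CellGeometry, StimulusSpec, build_cell_geometry
from .params import RateParameters, FeedbackToggles
from .network import pa_dag_ratio
from .solver import (SimulationProtocol, ProtocolResult, SimulationResult,
                     run_protocol)

__all__ = ["SweepConfig", "ResponseTable", "PhasePlane", "front_back_ratio",
           "dose_response_sweep", "polarization_span", "nullclines",
           "phase_planes_from_result", "perturbation_scan",
           "scale_lipid_parameters"]

#: steady front/back ratio above which a row counts as polarized.  The
#: reported sweeps separate near-1 rows from >=10 rows, so any cutoff in
#: between gives the same classification; 2 is recorded in run metadata and
#: configurable.
POLARIZATION_RATIO_THRESHOLD = 2.0


@dataclass
class SweepConfig:
    """Everything needed to run one dose-response sweep."""

    params: RateParameters
    toggles: FeedbackToggles
    shape: str = "symmetric"
    h: float = 0.2
    n_membrane: int | None = None
    direction: int = +1
    protocol: SimulationProtocol = field(default_factory=SimulationProtocol)
    ratio_threshold: float = POLARIZATION_RATIO_THRESHOLD

    def geometry(self) -> CellGeometry:
        return build_cell_geometry(self.shape, self.h, self.n_membrane)


@dataclass
class ResponseTable:
    """Sweep results keyed by (rsteep, rfrac)."""

    table: pd.DataFrame
    ratio_threshold: float = POLARIZATION_RATIO_THRESHOLD

    COLUMNS = ["rsteep", "rfrac", "pkc_front", "pkc_back",
               "pkc_front_min", "pkc_front_max", "pkc_back_min",
               "pkc_back_max", "outcome", "ratio", "locked", "error"]

    def steady_rows(self) -> pd.DataFrame:
        return self.table[self.table.outcome.isin(["unpolarized",
                                                   "steady_polarized",
                                                   "locked"])]

    def polarized_rows(self, include_oscillatory: bool = False) -> pd.DataFrame:
        rows = self.table[self.table.outcome.isin(["steady_polarized",
                                                   "locked"])]
        if include_oscillatory:
            osc = self.table[self.table.outcome == "oscillatory"].copy()
            with np.errstate(divide="ignore", invalid="ignore"):
                env_ratio = osc.pkc_front_max / osc.pkc_back_max
            osc = osc[env_ratio >= self.ratio_threshold]
            rows = pd.concat([rows, osc])
        return rows

    @property
    def max_steady_ratio(self) -> float:
        rows = self.steady_rows()
        return float(rows.ratio.max()) if len(rows) else np.nan

    @property
    def optimal_rfrac(self) -> float:
        """rfrac of the steady row attaining the maximum front/back ratio."""
        rows = self.steady_rows()
        if not len(rows) or rows.ratio.isna().all():
            return np.nan
        return float(rows.loc[rows.ratio.idxmax(), "rfrac"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def front_back_ratio(result: ProtocolResult | SimulationResult):
    """Steady front/back ratio of active PKC, or the oscillation envelope.

    For a steady phase returns a float (``inf`` if the back probe is zero);
    for an oscillatory phase returns the envelope dict instead.
    """
    phase = result.phase1 if isinstance(result, ProtocolResult) else result
    if phase.oscillatory:
        return {k: v for k, v in phase.envelope.items()
                if k.startswith("c_star")}
    f = phase.probes["c_star_front"][-1]
    b = phase.probes["c_star_back"][-1]
    if b <= 0:
        return np.inf
    return float(f / b)


def _row_from_result(rsteep: float, rfrac: float,
                     res: ProtocolResult, threshold: float) -> dict:
    ph = res.phase1
    env_f = ph.envelope["c_star_front"]
    env_b = ph.envelope["c_star_back"]
    row = {"rsteep": rsteep, "rfrac": rfrac,
           "pkc_front": ph.probes["c_star_front"][-1],
           "pkc_back": ph.probes["c_star_back"][-1],
           "pkc_front_min": env_f[0], "pkc_front_max": env_f[1],
           "pkc_back_min": env_b[0], "pkc_back_max": env_b[1],
           "locked": res.reversal_outcome == "locked", "error": ""}
    if ph.oscillatory:
        row.update(outcome="oscillatory", ratio=np.nan)
    else:
        ratio = front_back_ratio(res)
        if ratio >= threshold:
            outcome = "locked" if row["locked"] else "steady_polarized"
        else:
            outcome = "unpolarized"
        row.update(outcome=outcome, ratio=ratio)
    return row


def dose_response_sweep(rsteep: float, rfrac_list, config: SweepConfig
                        ) -> ResponseTable:
    """One ``run_protocol`` per rfrac; failures are recorded per-row."""
    rfrac_list = list(rfrac_list)
    if any(r <= 0 for r in rfrac_list) or \
            sorted(rfrac_list) != rfrac_list:
        raise ValueError("rfrac_list must be sorted and positive")
    geom = config.geometry()
    rows = []
    for rfrac in rfrac_list:
        stim = StimulusSpec(rfrac=rfrac, rsteep=rsteep,
                            direction=config.direction)
        try:
            res = run_protocol(geom, config.params, config.toggles, stim,
                               config.protocol)
            rows.append(_row_from_result(rsteep, rfrac, res,
                                         config.ratio_threshold))
        except Exception as exc:   # individual failures do not stop the sweep
            rows.append({"rsteep": rsteep, "rfrac": rfrac,
                         "outcome": "failed", "ratio": np.nan,
                         "locked": False, "error": str(exc),
                         "pkc_front": np.nan, "pkc_back": np.nan,
                         "pkc_front_min": np.nan, "pkc_front_max": np.nan,
                         "pkc_back_min": np.nan, "pkc_back_max": np.nan})
    df = pd.DataFrame(rows, columns=ResponseTable.COLUMNS)
    return ResponseTable(df, config.ratio_threshold)


def log_rfrac_grid(lo: float, hi: float, per_decade: int = 10) -> list[float]:
    """Logarithmic rfrac grid (the sweep axes are log-scaled)."""
    n = max(2, int(np.ceil(np.log10(hi / lo) * per_decade)) + 1)
    return list(np.geomspace(lo, hi, n))


def polarization_span(table: ResponseTable,
                      include_oscillatory: bool = False) -> float:
    """Largest/smallest polarized rfrac (dose-response robustness factor).

    Oscillatory rows are excluded by default; with
    ``include_oscillatory=True`` rows whose oscillation-envelope maxima show
    a front/back ratio above threshold widen the span.
    Returns NaN when no row is polarized.
    """
    rows = table.polarized_rows(include_oscillatory)
    if not len(rows):
        return np.nan
    return float(rows.rfrac.max() / rows.rfrac.min())


# ---------------------------------------------------------------------------
# phase plane
# ---------------------------------------------------------------------------

@dataclass
class PhasePlane:
    """d- and e-nullclines on the (d_tot, e) plane at one location."""

    d_grid: np.ndarray
    e_nullcline: np.ndarray
    d_nullcline: np.ndarray
    fixed_points: np.ndarray        # d_tot values of intersections
    location: str = ""
    r_local: float = np.nan
    p_free: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d_tot": self.d_grid,
                             "e_nullcline": self.e_nullcline,
                             "d_nullcline": self.d_nullcline})


def _pkc_partition(params: RateParameters, C_local: float) -> float:
    """d_tot / d_free under quasi-steady PKC cycling at concentration C."""
    k_off_eff = params.k_off_c + params.k_dp_c * params.k_rel_c / \
        max(params.k_rp_c + params.k_rel_c, 1e-300)
    alpha = params.k_on_c * C_local / max(k_off_eff, 1e-300)
    beta = params.k_dp_c / max(params.k_rp_c + params.k_rel_c, 1e-300)
    return 1.0 + alpha * (1.0 + beta)


def nullclines(d_grid, r_local: float, E_cytosol: float, p_free: float,
               params: RateParameters, C_cytosol: float | None = None,
               location: str = "") -> PhasePlane:
    """Construct the e- and d-nullclines at one membrane location.

    ``d_grid`` is total DAG (free + PKC-bound).  PA is slaved to free DAG
    via ``dp = lambda d``; the e-nullcline solves the PLC recruitment
    balance for e, and the d-nullcline balances hydrolysis production
    against first-order consumption of the DAG backbone
    (``e = k_basal_dp lambda d / (k_hyd p)``), a line through the origin
    with slope inversely proportional to the free PIP2 density.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(d_grid < 0) or r_local < 0 or E_cytosol < 0 or p_free <= 0:
        raise ValueError("inputs must be positive (p_free strictly)")
    lam = pa_dag_ratio(params)
    part = _pkc_partition(params, C_cytosol if C_cytosol is not None
                          else params.C_total)
    d_free = d_grid / part
    dp = lam * d_free
    x = params.K_PA * dp
    bracket = (1.0 + params.epsilon * x) / (1.0 + x)
    e_null = params.k_on_e * r_local * E_cytosol / (
        params.k_on_e * E_cytosol + params.k_off_e * bracket)
    if params.K_m_hyd > 0:
        hyd_coef = params.k_hyd * p_free / (1.0 + p_free / params.K_m_hyd)
    else:
        hyd_coef = params.k_hyd * p_free
    d_null = params.k_basal_dp * lam * d_free / max(hyd_coef, 1e-300)
    diff = e_null - d_null
    sign = np.sign(diff)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    fps = []
    for i in idx:
        # linear interpolation of the crossing
        f0, f1 = diff[i], diff[i + 1]
        w = f0 / (f0 - f1)
        fps.append(d_grid[i] + w * (d_grid[i + 1] - d_grid[i]))
    return PhasePlane(d_grid=d_grid, e_nullcline=e_null, d_nullcline=d_null,
                      fixed_points=np.asarray(fps), location=location,
                      r_local=float(r_local), p_free=float(p_free))


def phase_planes_from_result(res: ProtocolResult, geometry: CellGeometry,
                             params: RateParameters,
                             d_max: float | None = None,
                             n_grid: int = 400) -> dict[str, PhasePlane]:
    """Front and back phase planes built from a converged simulation.

    Local r comes from the stimulus, free PIP2 from the membrane field, and
    the (near-uniform) cytosolic PLC/PKC concentrations from the
    membrane-adjacent voxels.
    """
    from .geometry import receptor_field
    ph = res.phase1
    mem, cyt = ph.final_membrane, ph.final_cytosol
    r = receptor_field(geometry, res.stimulus)
    out = {}
    for loc, idx in (("front", ph.front_index), ("back", ph.back_index)):
        vox = geometry.boundary_voxel[idx]
        dmax = d_max
        if dmax is None:
            d_tot_probe = mem.d[idx] + mem.c_star[idx] + mem.c_inact[idx]
            dmax = max(4.0 * d_tot_probe, 50.0)
        grid = np.linspace(0.0, dmax, n_grid)
        out[loc] = nullclines(grid, float(r[idx]), float(cyt.E[vox]),
                              float(max(mem.p[idx], 1e-9)), params,
                              C_cytosol=float(cyt.C[vox]), location=loc)
    return out


# ---------------------------------------------------------------------------
# parameter perturbations
# ---------------------------------------------------------------------------

def perturbation_scan(parameter_name: str, factors, rsteep: float,
                      rfrac_list, config: SweepConfig) -> pd.DataFrame:
    """Repeat the dose-response sweep with one parameter scaled.

    Returns one row per factor with the maximum steady front/back ratio and
    the polarization span (the sensitivity-analysis summary quantities).
    """
    if not hasattr(config.params, parameter_name):
        raise KeyError(f"unknown parameter {parameter_name!r}")
    rows = []
    for factor in factors:
        if factor <= 0:
            raise ValueError("factors must be positive")
        pscaled = config.params.scaled(parameter_name, factor)
        cfg = dc_replace(config, params=pscaled)
        tab = dose_response_sweep(rsteep, rfrac_list, cfg)
        rows.append({"parameter": parameter_name, "factor": factor,
                     "max_ratio": tab.max_steady_ratio,
                     "span": polarization_span(tab),
                     "optimal_rfrac": tab.optimal_rfrac})
    return pd.DataFrame(rows)


def scale_lipid_parameters(params: RateParameters, s: float) -> RateParameters:
    """Joint lipid-scaling: divide k_DAGK, k_PAP, k_basal_dp, K_PA by s and
    multiply k_off_c by s.

    Raises steady DAG and PA levels ~s-fold while preserving the PA/DAG
    ratio and the strength of PFL 1 and PKC recruitment, so the
    polarization classification is expected to be unchanged.
    """
    if s <= 0:
        raise ValueError("scale factor must be positive")
    return params.replace(k_DAGK=params.k_DAGK / s, k_PAP=params.k_PAP / s,
                          k_basal_dp=params.k_basal_dp / s,
                          K_PA=params.K_PA / s, k_off_c=params.k_off_c * s)
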