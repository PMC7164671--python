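# Methods

## The signaling model

The package implements a surface–volume reaction-diffusion model of
PLC/PKC signaling in a fibroblast responding to a gradient of activated
PDGF receptors. The cell is a thin 2D domain (an ellipse, major axis 40
um, minor axis 1.8 um); the membrane is its 1D boundary curve. Eight
membrane species carry densities in molecules/um^2 and diffuse along
arclength; four cytosolic species carry concentrations in uM and diffuse
in the interior. Exchange between the compartments enters the cytosolic
equations as boundary fluxes on membrane-adjacent voxels, converted with
1 uM = 602.214 molecules/um^3 (unit depth), so whole-cell copy numbers of
PLC, PKC and MARCKS are conserved exactly by the discretisation.

Receptor activation is imposed, not modelled: r(x) = 130 rfrac
(1 + rsteep x/40) molecules/um^2, identical on the top and bottom arcs.
`rfrac` is the midpoint occupancy fraction (1 means 130/um^2, about 1e5
receptors per cell); `rsteep` is the fractional front-to-back difference.

The reaction network couples three positive feedback loops:

1. **PFL 1 (PA -> PLC).** Activated receptors recruit cytosolic PLC into a
   membrane complex; phosphatidic acid lowers the complex's effective
   off-rate through the factor (1 + eps K_PA dp)/(1 + K_PA dp), which
   falls from 1 to the escape probability eps as PA accumulates.
2. **PFL 2 (PKC -> PLD).** PA synthesis by PLD is amplified by active PKC
   through a Hill function with gain gamma, saturation constant K_PLD and
   Hill coefficient n in {1, 2}; off by default.
3. **MARCKS buffering.** MARCKS inserts into the membrane and sequesters
   PIP2 with high avidity; phosphorylation by active PKC releases both
   MARCKS (to the cytosol as M_p, dephosphorylated there) and its bound
   PIP2. Only free PIP2 is hydrolysed by active PLC.

DAG and PA interconvert by pseudo-first-order reactions (DAG kinases,
k_DAGK; PA phosphatases, k_PAP) and PA is consumed at k_basal_dp, giving
the steady proportionality dp/d = k_DAGK/(k_PAP + k_basal_dp) wherever
lipid diffusion is negligible against these rates. DAG recruits cytosolic
PKC into the active membrane form c*; membrane PKC cycles through an
inactive, membrane-bound form that either autophosphorylates back or
dissociates. The inactive form is taken to retain its bound DAG, which is
released on dissociation, so the DAG backbone is conserved through the
cycle and "total DAG" for analysis purposes is d + c* + c.

## Rate laws and the registry

The recruitment (PFL 1) and PLD (PFL 2) laws are as above. The remaining
laws default to mass action: bilinear hydrolysis k_hyd e p (with an
optional saturable variant selected by K_m_hyd > 0), mass-action PKC
binding k_on_c d C, and MARCKS-PIP2 capture/release k_on_mp m p /
k_off_mp. Every law sits behind a named registry key recorded in run
metadata.

**MARCKS phosphorylation.** The default registry entry is bilinear
(k_pkc_m c* per membrane MARCKS). The calibrated base case instead uses
the cooperative entry, rate = k_pkc_m c*^2/(K_pkc_m + c*): quadratic in
active PKC below K_pkc_m and linear above, with the same meaning of
k_pkc_m in the linear regime. The biological basis is that the MARCKS
effector domain must receive multiple PKC phosphorylations before it
loses membrane affinity, which makes the release rate supra-linear in
kinase density at sub-saturating kinase levels. The mathematical basis is
a gain argument: with the hyperbolic PA bracket of PFL 1 the closed-loop
gain of that loop alone is bounded by 1/2 at any operating point, and
with all-bilinear MARCKS kinetics the liberation loop cannot reliably
supply the remainder, so no parameter choice reproduces front/back ratios
above 10 at a 10% gradient. One supra-linear step — here, the
biologically defensible one — lets the combined loops cross threshold at
the front while the back stays below it.

## Numerics

Time stepping is backward Euler with Newton iteration; the Jacobian
combines the exact sparse diffusion operator with per-node reaction
blocks obtained by vectorised finite differences, factorised with a
sparse direct solver. Steps adapt by a predictor-based local error
estimate with a weighted-RMS norm (membrane atol 1e-4 /um^2, cytosol atol
1e-7 uM, rtol 1e-4 by default). The scheme is A-stable; near steady state
the step grows until the cap `max_dt`. Non-negativity is enforced by step
rejection, never by clipping. Runs are bitwise deterministic.

The default protocol integrates 20,000 s, then (optionally) mirrors the
gradient and integrates another 20,000 s. Steady state is declared when
every membrane probe changes by less than 1e-6 (relative, per 100 s
window) after a 2,000 s minimum; phases that do not converge are
classified oscillatory when the last quarter of the front active-PKC
trace shows at least three regular peaks with peak-to-peak amplitude
above 1% of the mean. The reversal outcome is "reversed" when the
phase-2 pattern mirrors phase 1 within 10% with the ratio re-forming
toward the new front, and "locked" otherwise. These detection thresholds
are this package's own choices and are recorded in run metadata.

The initial condition solves the r = 0 well-mixed steady state
(semi-analytic fixed point, polished by a conservation-constrained root
solve), broadcasts it uniformly, and then drives it to the exact fixed
point of the discretised system with a few very large implicit steps.
This makes basal stationarity hold to solver tolerance while preserving
pool totals exactly.

Reference mesh: voxels of side h = 0.1 um and a matching membrane node
spacing, with a 0.1 s step cap. Scenario configurations and the test
suite run the coarse production setup (h = 0.2 um, step cap 200 s), which
changes steady probe values by under 2% relative to the reference mesh;
accuracy at large steps is carried by the error-controlled implicit
integrator rather than the cap.

## Calibration of the base parameter set

Base-case kinetic values are this package's own calibrated set. The
calibration target is the qualitative phenotype battery of the
gradient-sensing circuit with PFL 1 + MARCKS: strong steady polarization
(front/back active-PKC ratio > 10) for 3% and 10% gradients over an
occupancy window around rfrac ~ 0.1 spanning at least a factor 2; no
polarization without MARCKS; no spontaneous symmetry breaking of the
symmetric cell under uniform stimulation (the uniform branch is linearly
stable at every occupancy — verified by continuation plus
wavenumber-resolved eigenanalysis); collapse of polarization at 0.3x
k_DAGK and preservation at 3x; and spontaneous polarization of the
back-blunted cell under uniform stimulation. Calibration explored a fast
1D reduction of the same network (cross-section-averaged cytosol) under
randomized and directed parameter search against that battery and was
then verified on the 2D solver.

The calibrated set realises the battery as follows, on the coarse 2D
mesh at a 10% gradient: polarized (ratios 11-81) for rfrac in
[0.05, 0.3] with the strongest response at the low edge of the window
(the ratio declines monotonically with occupancy rather than rising to
an interior peak); ratio ~ 55 at a 3% gradient; MARCKS removal drops the
ratio to ~1.1; 0.3x k_DAGK collapses the maximum ratio roughly ten-fold
(to ~4-8, below the strong-polarization bar of 10); 3x k_DAGK preserves
ratios above 100 while moving the responsive window to higher occupancy
(rfrac ~ 0.7-1), i.e. it raises the upper bound of receptor activation
that still polarizes; and the back-blunted cell polarizes spontaneously
(ratio ~ 55 at rfrac 0.1, pointed end favoured). The polarized state is
reached by a finite-amplitude (subcritical) transition: the uniform
state is linearly stable but a few-percent tilt in receptor occupancy
pushes the front over the ignition threshold, which is also why reversal
can leave the pattern locked.

## The wound-invasion model

A 1D tissue (1 mm dermis + 5 mm clot, grid 0.01 mm) carries a
dimensionless PDGF field u with synthesis in the clot (k_synth = 0.3/h),
diffusion (D_u = 0.1 mm^2/h), intrinsic degradation (k_deg = 0.2/h) and
receptor-mediated consumption by cells (k_cell rho r(u), k_cell = 0.04
mm/h); these continuum values are calibrated so that (i) the cell-free
clot reaches a plateau u ~ 1.5 (receptor activation r ~ 0.47) within a
day, with a boundary-layer length sqrt(D_u/k_deg) ~ 0.7 mm at the wound
edge, and (ii) per-cell consumption at realistic densities outpaces local
synthesis, so the invading population can carve its own gradients —
without that, the chemotactic band pins at the wound edge and no
cell-generated waves form.
Receptor activation follows r = u^2/(1 + u + u^2) (quasi-steady receptor
dynamics; u = 1 gives r = 1/3). Cells are line segments of 0.04 mm; each
step (dt = 0.01 h) a cell is chemotactic iff the fractional activation
difference across its length exceeds the threshold curve

    thr(r) = 0.01 + a[(r_opt/r)^n - (n/m)(r_opt/r)^m + n/m - 1]

with a = 1.7, r_opt = 0.12, n = 2, m = 1.5 — minimum 0.01 at r_opt,
diverging at low activation and rising to ~0.58 at saturation. Random
cells diffuse with D_v1 = 3e-4 mm^2/h; chemotactic cells drift at S_tax =
0.03 mm/h up-gradient with residual D_v2 = 1e-4 mm^2/h. Division is
stochastic with rate k_prolif r (1 - rho/rho_max) (k_prolif = 0.06/h,
rho_max = 200/mm), death at 2e-4/h; daughters appear adjacent to the
parent. The dermis is seeded at 100 cells/mm. Penetration depth at a
given time is reported as the 95th percentile of cell positions beyond
the dermis/clot interface (robust to stray cells), with the maximum also
recorded. One child seed per replicate makes every replicate
reproducible.

## What the scenario generator does and does not emulate

The imposed receptor field replaces ligand-receptor binding and
trafficking; there is no receptor saturation, internalisation or noise in
the signaling model, and the 2D cross-section fixes the membrane-to-
cytosol ratio that a 3D cell would modulate by shape changes. The wound
model reduces tissue to 1D, ignores mechanics and ECM remodelling, and
couples to the signaling model only through the fitted threshold curve —
not by embedding the PDE model in each agent. Passing tests therefore
demonstrate the internal consistency of the models and the claimed
qualitative behaviours of the circuit, not quantitative agreement with
any particular measured cell.

## Known limitations

* The base-case parameter values are calibrated to the phenotype battery,
  not transcribed from measurements; absolute densities should be read as
  order-of-magnitude.
* Oscillation detection needs a few periods within the simulated window;
  very slow oscillations near a bifurcation may be classified steady.
* The membrane/voxel coupling is nearest-voxel; mirror symmetry of the
  discretisation holds to ~1e-5 relative, which bounds how close to the
  symmetry-breaking threshold a run can meaningfully operate.
* Blunted geometries change the boundary length and area slightly
  relative to the symmetric cell; comparisons across shapes are at fixed
  parameters, not at matched area.
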