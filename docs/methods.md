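# Methods

`angiopet` simulates how a PET tracer (FDG by default) distributes in a
vascularized solid tumor, from the growth of the vascular network itself
down to the voxel-level tracer kinetics.  The pipeline has four stages
that share one uniform square lattice: sprouting angiogenesis, network
hemodynamics with structural adaptation, interstitial (Darcy) fluid flow,
and a spatiotemporal three-field tracer model.  This note records the
model, the defaults and why they were chosen, the numerical choices, and
the known limitations.

## Geometry and conventions

The domain is an L x L square (default L = 1 cm) discretized by an
N x N node lattice (default N = 201, spacing h = 50 um).  A parent vessel
runs along the left edge; its lower end is the inflow (3325 Pa ~ 25 mmHg)
and its upper end the outflow (1330 Pa ~ 10 mmHg).  The tumor is a disc of
diameter D = 0.2 L (scenario multipliers 1x/2x/3x) centered at fractional
coordinates (0.65, 0.5).  Indices are (row = y, col = x), node-centered
fields, SI units throughout except vessel diameters, which are carried in
micrometres because the empirical blood-viscosity law is written for
diameters in um.  One top-level RNG seed drives all stochastic stages;
every run is bit-reproducible for a fixed seed.

## Angiogenesis

Tip endothelial cells (tECs) leave the parent vessel at 3 or 5 equally
spaced sprout points and perform a biased lattice walk.  Movement
probabilities discretize the EC conservation law

    dn/dt = Dn lap(n) - div[ chi/(1+alpha c) n grad c + phi n grad f ]

with random motility Dn = 3.5e-4, saturating chemotaxis (chi = 0.38,
alpha = 0.6) up the tumor-angiogenesis-factor (TAF) gradient, and
haptotaxis (phi = 0.34) up the fibronectin gradient; the nondimensional
walk step is dt = 5e-3.  These coefficients are the standard values of the
hybrid tip-cell model family from which this model descends.  The
continuum fields evolve by df/dt = beta n - gamma n f (beta = 0.05,
gamma = 0.1) and dc/dt = -eta n c (eta = 0.1), with n the vessel occupancy
indicator.

Initial profiles: TAF equals 1 on the tumor and decays as a Gaussian of
the normalized distance to the tumor rim (width 0.45), so its maximum is
in the tumor and its minimum near the parent vessel.  Fibronectin is
k exp(-x^2/0.45) with k = 0.75, maximal at the parent vessel; inside the
tumor it is flattened to its lowest rim value because tumor proteases
degrade the adhesive matrix — without this, the inward haptotactic pull
of the decaying profile traps tips at the tumor rim and large tumors
never vascularize their core.

Branching probability per step follows a piecewise-constant table of the
local TAF (0 below 0.3, then 0.2 / 0.3 / 0.4 above 0.3 / 0.5 / 0.7), with
a minimum tip age of 5 steps.  A branch also requires room: an unoccupied
4-neighbor and fewer than two tips on the node.  Without the two-tip cap,
co-located tips at a saturated-TAF colonization front double every few
steps and the population diverges (observed: ~3.6 million tips on a
201-lattice).  A tip stepping onto any occupied node fuses there
(anastomosis) and deactivates; stepping back onto its immediately
preceding node is excluded (tips are elongating cells, not reversible
walkers — without the no-U-turn rule every tip self-fuses within ~10
steps).  Growth runs 30 simulated days at 100 steps/day.  New segments
start at d0 = 10 um; the parent vessel is 60 um — arteriole calibre, so
that the capillary draw does not sag the trunk pressure profile and tap
pressures stay on the linear inlet-outlet profile for every network size.

## Network hemodynamics

Mass balance at every lattice junction combines Hagen-Poiseuille
intravascular flow, Q = (pi/128) dP d^4/(l mu), with Starling
transvascular leakage Q_t = pi d l Lp [Pb - Pi - sigma(pi_b - pi_i)].
Blood viscosity follows the Pries in-vitro law mu_rel(d, H) (diameter in
um), and discharge hematocrit splits at bifurcations by the
phase-separation rule: all red cells enter the faster branch above a
critical velocity ratio (U_cr = 2.5), otherwise H1/H2 = lambda U1/U2
(lambda = 2) closed with H1 + H2 = H_parent as the model family writes it
(a flux-weighted variant is available behind a flag).  Hematocrit
propagates from the inlet (H = 0.45) through the flow-directed network in
descending-pressure order; converging junctions mix flow-weighted.

The nonlinear pressure/viscosity/hematocrit fixed point is solved by
repeated sparse linear solves with an annealed under-relaxation of the
hematocrit update (factor 0.5, decaying by 0.85 per iteration).  The
annealing is needed because the all-or-nothing phase-separation rule puts
the plain fixed point on a limit cycle; every linear solve still enforces
junction mass balance exactly for its conductances, and the converged
state reproduces an independent dense solve to 1e-8.

Blind ends and void-of-flow vessels are removed first: segments carrying
less than 1% of the network's maximum capillary flow are deleted, then
anything disconnected from the parent.  The reference "maximum" is the
99.9th percentile of capillary |Q| with the parent trunk excluded — the
trunk is the boundary condition at ~1e3x any capillary flow, and on some
realizations a single short loop adjacent to the parent carries several
times the 99.9th-percentile flow, which would otherwise double the pruned
fraction and the seed-to-seed variance.  Removal before adaptation leaves
the remaining flow distribution essentially unchanged (the removed
segments carried ~no flow); pruning after adaptation would instead delete
most of the tumor loops, because structural adaptation concentrates flow.

Diameters then adapt by d <- d + dt (S_wss + k_p S_p + k_m S_m - k_s)
with S_wss = log10(tau_w + tau_ref), S_p = -log10(tau_e(Pb)) and
S_m = log10(Q_ref/(Q H) + 1), clamped to [4, 35] um.  tau_e(P) =
100 - 86 exp(-5000 (log10 log10 P)^5.4) with P in mmHg; below 10 mmHg the
nested logarithm has no real non-integer power, so the curve is continued
by its boundary value tau_e = 14.  In this lattice's flow regime the
capillary wall shear is O(0.01-0.1 Pa), so log10(tau_w + tau_ref) is
uniformly negative; because the update is additive, the offset k_s sets
the growth/shrink threshold, and the defaults (tau_ref = 0.002 Pa,
k_p = 0.1, k_m = 0.07, k_s = -2.07, Q H floored at 1e-4 Q_ref) place that
threshold near the lower quartile of perfused shear: well-perfused loops
remodel up toward feeding-vessel calibre and unperfused remnants shrink.
The upper clamp of 35 um lets the adapted backbone act as feeding
arterioles/venules so distal tap pressures do not sag along long supply
paths.  Adaptation runs up to 80 structural steps (dt = 0.75), each with
one warm-started Picard sweep of the flow problem, followed by a strict
final solve; borderline segments may oscillate around the threshold
within a bounded band, which is logged rather than treated as failure.

## Interstitial fluid flow

Steady Darcy flow with Starling sources and lymphatic sinks:

    div(v) = phi_b - phi_L,   v = -K grad(Pi)

phi_b = Lp S/V (Pb - Pi - sigma(pi_b - pi_i)) on vessel-bearing cells and
phi_L = LpL SL/V (Pi - P_L) in normal tissue only (intratumoral
lymphatics are absent or non-functional).  Both terms are affine in Pi,
so the five-point finite-difference problem is one sparse linear solve.
The conservative form div(K grad Pi) with harmonic-mean face
conductivities is discretized so the ~5x conductivity jump at the tumor
rim is handled correctly; within a region this is identical to the
constant-K Poisson form.  The outer boundary is Dirichlet Pi = 0
(far-field normal tissue at gauge pressure).  v = -K grad(Pi) by central
differences.

2D volume convention: cells are cubes of side h, so a segment of diameter
d in a cell contributes S/V = pi d l / h^3 ~ 1.3e4 1/m for d = 10 um —
the physiological capillary surface density.  (A unit-depth slab would
give S/V ~ 1 1/m, five orders too low.)  Exchange surface uses
min(d, 10 um) per segment: remodeled 35-um feeding vessels have mature,
non-exchanging walls, which also keeps normal-tissue IFP independent of
how thick the backbone happens to remodel on a given seed.

Defaults: K_tumor = 3.10e-14, K_normal = 6.40e-15 m^2/(Pa s) (the classic
4.13e-8 and 8.53e-9 cm^2/(mmHg s) interstitial conductivities);
oncotic pressures pi_b = 2666 Pa, pi_i = 2000/1333 Pa and reflection
coefficients sigma = 0.1/0.82 (tumor/normal); a `neglect_osmotic` flag
zeroes the oncotic terms.  The leakage magnitude is stated per reference
vessel cell: LpS/V = 2.64e-7 1/(Pa s) for a d = 10 um tumor segment in a
50-um cell (equivalent wall conductivity Lp = 2.1e-11 m/(Pa s), the
classic leaky-tumor value), scaled linearly by each cell's mapped S/V;
normal walls are 5x tighter, and the lymphatic drainage coefficient is
LpL SL/V = 1.75e-7 1/(Pa s).  The last two values were fixed once, at
design time, so that the seed-averaged mean IFP of the default scenarios
sits at the physiological levels reported for tumors (~1.5-1.9 kPa) and
normal tissue (~50-100 Pa); they are stand-ins for tissue-specific
measurements and are ordinary config values.

## Tracer kinetics

Three concentration fields on the lattice: extracellular Ci (transported
by interstitial diffusion and convection), intracellular free Ce, and
phosphorylated Cm (trapped; no transport for the intracellular pools):

    dCi/dt = D lap(Ci) - v.grad(Ci) + L1 Cp - (L2 + L3) Ci + L4 Ce
    dCe/dt = L3 Ci - (L4 + L5) Ce
    dCm/dt = L5 Ce

L1 combines Starling filtration with Peclet-moderated transvascular
diffusion, L1 = phi_b(1 - sigma_f) + Pm S/V Pe/(e^Pe - 1) with
Pe = phi_b(1 - sigma_f)/(Pm S/V); L2 is the diffusive back-flux plus
lymphatic drainage.  The removable singularity of Pe/(e^Pe - 1) is
evaluated by its series below |Pe| < 1e-4.  Cells without vessel surface
have no transvascular exchange.  The plasma concentration Cp(t) is
spatially uniform across the vascular source (no intravascular transport
PDE); it comes from a tabulated CSV or the built-in parametric bolus
A1 t e^{-t/tau1} + A2(e^{-t/tau2} - e^{-t/tau1}) (A1 = 0.8 kBq/ml/s,
tau1 = 40 s, A2 = 3 kBq/ml, tau2 = 1200 s: zero at t = 0, a single early
peak ~12 kBq/ml near 45 s, then monotone washout).

Cellular rates default to FDG-like values: L3 = 1.8e-3, L4 = 2.2e-5,
L5 = 1.0e-3 1/s in tumor, scaled by 0.3 in normal tissue (higher tumor
metabolism); D = 2e-10 m^2/s; Pm = 3e-7 (tumor) / 3e-8 (normal) m/s;
sigma_f = 0.1.  Integration is operator splitting with dt = 1 s over 1 h:
explicit first-order upwind advection (CFL checked; interstitial
velocities ~0.1 um/s leave the limit far away), backward-Euler diffusion
with a once-factorized sparse operator and no-flux boundaries, and an
exact per-cell propagation of the local linear reaction system (the rate
fields are constant in time, so the 3x3-plus-forcing exponential is
precomputed once per distinct rate tuple; Cp is taken at mid-step).  The
scheme preserves non-negativity, keeps Cm pointwise non-decreasing, and
its global mass balance against the integrated plasma exchange holds to
~5e-5 relative on full runs.  In the well-mixed limit (D = 0, v = 0,
uniform rates) per-cell trajectories match the classic 4-compartment
5-rate-constant (5K) ODE model to better than 0.1% over an hour — the
module's primary correctness anchor.

The "uniform network" limit replaces the vascular stages entirely:
vessels exist nowhere physically but act as a uniform source with
S/V = 3.1e4 1/m (= pi d_max/h^2, a maximum-calibre vessel in every cell)
and Pb equal to the mean of the inlet and outlet pressures.  This is the
extreme-MVD reference that upper-bounds every vascularized run.

Synthetic PET frames are the total concentration convolved with an
isotropic Gaussian point-spread function (default FWHM 2 cells).

## Scenario matrix and outputs

Networks 1-3 are tumor sizes D, 2D, 3D with 3 sprouts; 4-6 the same sizes
with 5 sprouts.  Every run writes (when an output directory is given) the
network CSV/VTK, IFP/IFV grids and PNGs, regional time-activity CSVs, PET
frame PNGs at 1/3/6/10/30/60 min, and a summary JSON stamped with the
config hash and seed.  `scripts/acceptance.py` recomputes the
seed-averaged regional IFP statistics from scratch (five seeds per
scenario at the default resolution; the tracer stage is not needed for
those quantities and is skipped there).

## What the synthetic conditions do and do not show

All inputs are synthesized: the vascular networks are lattice-bound
caricatures of real microvasculature (4-neighbor segments of equal
length, vessels allowed arbitrarily close to tumor cells), the tumor is a
disc, the parent vessel is a straight line serving as both supply and
drain, and the plasma input is a parametric bolus.  Passing tests
therefore demonstrate internal consistency of the coupled physics —
conservation laws, analytic limits, orderings with vessel density and
tumor size, physiological pressure levels — not agreement with any
patient's vasculature or image.  Quantities that depend on absolute
vessel surface per voxel are resolution-linked: the per-cell S/V of a
lattice-bound network falls with coarser grids, so reduced-resolution
test fixtures scale the leakage coefficients accordingly (noted where
done).  No radioactive-decay correction, partial-volume modeling beyond
the PSF blur, pulsatile flow, vessel compliance, red-cell tracking,
poroelasticity, or 3D geometry.

## Numerical summary

- Flow fixed point: relative Pb tolerance 1e-4, annealed hematocrit
  relaxation, raises with residual history on non-convergence.
- Junction mass balance: exact per linear solve (~1e-13 of max |Q|).
- IFP: single sparse solve (the sources are affine in Pi); O(h^2)
  five-point scheme; mean tumor IFP changes < 2% under grid halving on a
  fixed source.
- Tracer stepping: splitting error dominated by the first-order advection
  term, which is negligible at interstitial velocities; reaction and
  diffusion substeps are exact/implicit and unconditionally stable.
- Determinism: one `numpy` Generator seeded from the config; module
  streams are consumed in a fixed documented order.
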