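# Methods

This note documents the model, the numerical choices, and the design
decisions behind `macpol`, in the order of the package's layers.

## Intracellular circuit (`macpol.network`)

The fate-deciding circuit couples three normalized pathway activities
x = (NFκB, STAT1, STAT6) ∈ [0,1]³ through the transformed Wilson–Cowan
(sigmoidal-rate) equations

    dx_i/dt = γ_i (A_i (1 − x_i) − B_i x_i) / (A_i + B_i)

with exponential activation/inhibition rates A_i = exp(σ_i u_i),
B_i = exp(σ_i v_i), where u_i and v_i are affine in the node states and the
external stimuli (LPS, IFNγ, IL4).  The default parameterization uses
σ_i = 8, γ_i = 1 per minute, unit weights on every interaction arc
(STAT1→NFκB and NFκB→STAT1 activation; STAT6⊣NFκB, STAT6⊣STAT1, STAT1⊣STAT6
inhibition; LPS, IFNγ, IL4 activating their respective nodes) and offsets
a₀ = (−1.5, −0.5, 0), b₀ = (−0.5 ≤ b₀ ≤ 0 range; values −0.1, −0.5, −0.05).

*Key identity.*  The rate law collapses to
dx_i/dt = γ_i (sigmoid(σ_i (u_i − v_i)) − x_i).  This makes three things
immediate: trajectories can never leave the unit cube (the derivative points
inward on every face); every equilibrium solves the fixed point
x = sigmoid(σ(u−v)); and the Jacobian is analytic,
J_ij = γ_i (p_i (1−p_i) σ_i (a_ij − b_ij) − δ_ij) with p_i the sigmoid.
The implementation evaluates the sigmoid in an overflow-safe form, so
arbitrarily large stimulus inputs are handled exactly.

**Equilibrium finding.**  `find_equilibria` runs a damped Newton iteration
(step clipped to 0.5 per component, iterates confined to [−0.25, 1.25]³)
from every node of a 5×5×5 seed lattice on the unit cube, keeps converged
roots (residual < 1e-12) inside the cube, deduplicates at 1e-6 (∞-norm) and
classifies stability by the eigenvalues of the analytic Jacobian
(stable ⇔ max real part < −1e-9).  Seeds whose Jacobian becomes numerically
singular near folds are skipped, never fatal.  At most five equilibria
coexist anywhere in the explored stimulus ranges; the 125-seed lattice
recovers all of them (cross-checked in the tests against an independent
scalar-reduction oracle that enumerates equilibria by a 1-D root scan).

**Relaxation.**  `integrate` (and the batched `relax_batch` used by the
tissue layer) integrates with LSODA until ‖dx/dt‖∞ < 1e-5, then polishes
with Newton to 1e-12.  The polished root is accepted only if it lies within
0.05 (∞-norm) of the integration endpoint, which keeps the result on the
branch actually reached from the initial state — the property that makes
fate decisions hysteretic.  Failure to settle within the horizon raises an
explicit `ConvergenceError`.  Default initial condition for "a naive cell"
is the origin; the resting state it converges to is
(≈0, ≈0.010, ≈0.58) — note the intermediate resting STAT6 level, a direct
consequence of the small STAT6 inhibition offset (−0.05).

## Bifurcation analysis and phenotypes (`macpol.bifurcation`)

One-parameter sweeps sample the stimulus range (default [0, 2], 201 points),
enumerate all equilibria per value, link them into branches by
nearest-state continuation (branches carry a single stability flag), and
refine every change of the equilibrium count by bisection to 1e-3 in the
parameter — matching the two-decimal precision at which critical values are
conventionally reported.  For LPS alone the counts run 1→3→5→3→1 with folds
at ≈0.378, 0.430, 0.480, 1.643: a bistable switching window [0.38, 1.64]
containing a narrow tri-stable sliver.  IFNγ alone gives a small bistable
window (≈0.005–0.137); IL4 alone produces no bifurcation.

**Level classification.**  Steady states are discretized per component with
thresholds 0.25/0.75 (config-exposed): Low < 0.25, High > 0.75, Medium
between.  On the abundance scale this corresponds to Low ≈ zero,
Medium ≈ normal abundance, High ≈ twice normal, since the normalized state
maps linearly onto [0, 2×normal].  Named profiles: (H,H,L) M1, (L,L,H) M2a,
(H,M,H) M2b; all others are reported as `unnamed-k` in lexicographic order.

**Multi-parameter analyses** are grids of the one-parameter logic (all
stable equilibria at every grid point), not true two-parameter continuation:
the object of interest is the region map of attainable profiles, not
codimension-2 curves.  `enumerate_phenotypes` defaults to a 21-per-axis grid
on [0,2]³ and returns 13 distinct profiles there.  A caveat documented
deliberately: the *count* of distinct profiles is discretization-dependent.
Because the sigmoids are steep but continuous, steady states pass through
the Medium band over thin parameter slivers near region boundaries, so finer
grids surface additional transitional triples, and coarse, figure-level
region counts will generally be smaller than mechanical grid counts.  Two
robust statements survive any resolution: the M1 and M2a patterns appear on
[0,2]³, and M2b requires LPS ≳ 2.4 (STAT6-mediated NFκB inhibition must be
overcome), i.e. a stimulus range wider than [0,2].

**Reachability.**  For each profile a representative (stimulus, state) is
taken at the occurrence closest to the profile's region centroid.  Each
single stimulus is then switched to the probe levels (0 and 2) and the cell
relaxed from the representative state; a changed profile becomes a directed
edge labeled with the switched cytokine.  If forcing another stimulus high
changes the outcome, the edge carries a condition annotation ("IFNγ low",
"LPS low") — reproducing the conditional switches of the fate map (e.g.
IL4 repolarizes only while IFNγ is low).

## Cytokine secretion (`macpol.secretion`)

IFNγ and IL4 production is mass action through the mediators IL12 and IL10
(rates a–j, per minute, from the literature; IL10's auto-negative feedback
enters as −2c·IL10).  The system is linear in the cytokines, so the steady
state is closed-form; the package evaluates the coefficients from the rate
table exactly:

    g/i = 2.0000,  f/(2i(e+f)) = 808.12,  fd/(i(e+f)) = 0.22304,
    ed/((e+f)j) = 0.0090162,  e/(2(e+f)j) = 32.667.

Reports that round intermediate values (809.09, 0.22, 0.009, 32.35) agree
within 1%; tests compare at 2% relative for this reason.  Clamping at zero
is applied to the closed-form outputs only; the raw ODE is integrated
without clamping (it may transiently go negative), and any concentration
used as a tissue source is floored at zero.  The rate *h* (STAT6→IL10) is
fixed by requiring a mixed M1/M2 cell (NFκB = 0, STAT1 and STAT6 at normal
abundance) to secrete both cytokines: 0.00107 < h < 0.00355 from the exact
coefficients (the rounded-coefficient algebra gives the familiar
0.001 < h < 0.0036; the interval width 2g(e+f)/f is abundance-independent,
and both bounds scale with the STAT1/STAT6 ratio).  Default h = 0.002.

A consequence worth flagging: the resting state (STAT6 ≈ 0.58, i.e. near
normal abundance) secretes IL4 at ≈ 57% of the maximal M2a rate.  Naive
populations therefore drift toward M2a through their own field on the field
accumulation time scale — an emergent autocrine property of the model, not
a bug; the no-spontaneous-switching invariant holds exactly when fields are
held at zero.

## Tissue fields (`macpol.tissue`)

Each diffusible cytokine obeys ∂φ/∂t = D(φ_xx + φ_yy) + f on a disc of
radius 4 length-units with zero-Dirichlet (absorbing) boundary.  One
length-unit is interpreted as 100 µm, so D = 1800 µm²/min = 0.18 units²/min
(config-exposed length scale).  The solver is an explicit 5-point scheme on
a default 81×81 grid (spacing 0.1), substepped to satisfy
dt_sub ≤ 0.9 h²/(4D), with the boundary re-imposed each substep — the guard
makes the macro step unconditionally stable, and source terms act
continuously during the substeps.  Sources are deposited either into the
nearest cell (point semantics, used in the kernel/symmetry tests) or over a
truncated-Gaussian cell footprint of width 0.25 units ≈ 25 µm (macrophage
scale, the tissue-layer default); the footprint keeps an agent's autocrine
signal commensurate with what its neighbors receive, whereas a point source
concentrates the agent's own deposit ~30-fold above the neighbor level and
locks every secreting cell into its own state.  Field sampling is bilinear.

## Agent population (`macpol.abm`)

Thirty agents are placed i.i.d. bivariate normal (variance σ² = 0.25 per
axis, resampled to stay inside the domain) with resting internal states
unless a pre-polarized composition is given.  Every sampling interval
Ts = 0.1 min each agent: senses stimulus = κ_c · (bilinear field sample) +
scheduled ambient, capped at 4; relaxes its circuit from its *current*
state (hysteresis preserved; an optional quantized lookup cache agrees with
direct relaxation and exists purely as an optimization); secretes IL4/IFNγ
at the closed-form steady-state rates of its new state; then moves a
uniform distance in [0, 2σ² = 0.5] in a uniform direction, resampling (up
to 10 tries) rather than clipping at the boundary.  The minute is the
canonical time unit throughout (the alternative second-based reading of Ts
is inconsistent with D in µm²/min; Ts is config-exposed).

**Sensing gain.**  The map from field concentration to the dimensionless
circuit stimulus is not physically determined, so κ is calibrated from the
model's own scales: fields relax toward a diffusive quasi-steady state over
τ ≈ (R/j₀₁)²/D ≈ 15 min, so the relevant concentration is the
population-scale quasi-steady level, ≈ n·Q·G(σ) for n cells secreting at
rate Q, with the 2-D Green's factor G(σ) = ln(R/σ)/(2πD).  κ_c maps that
level, for Q the cytokine's maximal closed-form rate, to the top of the
responsive stimulus range (sensing_reference = 2).  The gain is per
cytokine because the maximal IL4 and IFNγ rates differ ~30-fold; a single
gain would leave IFNγ signaling inert or saturate IL4.  A per-deposit
calibration (one cell, one interval) was tried first and rejected: it
ignores the ~τ/Ts ≈ 150-fold field accumulation and saturates every channel,
freezing the population.

**Repolarization scenarios (`scenario_case2`).**  An M1- or M2-dominant
population of 30 cells is exposed to the opposite stimulus: sustained
ambient IL4 = 2 against an M1-dominant start, sustained LPS = IFNγ = 2
against an M2-dominant start (LPS accompanies IFNγ because NFκB cannot
reach High without it).  Two initializations:

- `bolus` (default): a naive population is polarized by an initial Gaussian
  deposit of the inducing cytokine (amplitude 2 in post-sensing stimulus
  units, width 1) and runs 50 intervals (5 min) before the stimulus flips.
- `composition`: the population starts pre-polarized (optionally with m0
  naive cells mixed in) over the deterministic quasi-steady field of that
  composition, produced by a frozen-state spin-up of 380 intervals
  (≈ 2.5 τ).

In both directions the initially dominant profile loses its majority.  With
a fully accumulated field the switch is gradual: the ambient stimulus flips
the directly driven pathway within one decision, but the orthogonal pathway
is held by the population's own field, which must drain through the
absorbing boundary (time scale τ) before the target profile takes the
majority.  Mixed populations containing naive cells cross the 50% line
earlier than pure ones because naive cells secrete none of one and less of
the other dominant-identity cytokine, so the mixed population's self-field
starts lower and crosses the switching threshold sooner — the model's
mechanistic version of naive cells accelerating population repolarization.

**Problem sizes.**  The shipped scenarios and the verification suite use a
61×61 grid for population runs (81×81 default elsewhere), 200–400 phase-2
intervals, 5 seeds for the repolarization property and a 21³ stimulus grid
for enumeration; these sizes were chosen as the smallest at which the
reported quantities are grid- and seed-stable (the grid-refinement test
bounds the 41→81 trajectory change by 5%).

## What the simulations do and do not show

All populations here are synthetic study conditions: fixed cell number (no
influx, proliferation or death), no cell–cell contact mechanics, no LPS
diffusion field (LPS enters only as a scheduled ambient stimulus), no bulk
cytokine degradation (loss is purely boundary absorption), and IL10/IL12
kept intracellular.  Passing tests establish the internal consistency of
the two-layer mechanism — switch-like fate decisions, hysteresis,
field-mediated population coupling — not quantitative agreement with any
particular tissue; real inflammatory sites differ in geometry, cytokine
half-lives, receptor kinetics and cell traffic.

## Known limitations

- The distinct-profile count is resolution-dependent (see above); treat the
  profile *set* at a stated grid, not the bare count, as the reproducible
  object.
- The stimulus scale is dimensionless; κ absorbs the unknown
  concentration-to-stimulus conversion, and conclusions that depend on the
  absolute field level (e.g. crossover step counts) are calibration-relative.
- The M2b pattern requires LPS beyond the default [0, 2] sweep range.
- Near fold points the relaxation time diverges; `relax_batch` handles this
  by chunked integration with a guarded Newton polish, but decisions taken
  exactly at a fold may consume several chunks.
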