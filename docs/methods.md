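# Methods

## The model

`pyrcell` implements a two-compartment conductance-based hippocampal
pyramidal cell.  The axosomatic compartment carries a transient Na current
(instantaneous activation, `INa = gNa m_inf^2(Vs) h (Vs - VNa)`), a
delayed-rectifier K current and a leak; the dendritic compartment carries a
persistent Ca current (`ICa = gCa s^2 (Vd - VCa)`), a Ca-activated K current
(`IKCa = gKCa c chi(Ca) (Vd - VK)`), a slow afterhyperpolarisation K current
(`IKAHP = gKAHP q (Vd - VK)`) and a leak.  The compartments are coupled by
an ohmic conductance `gC`; applied currents and coupling currents are
divided by the respective area fractions `p` and `1 - p`.  Gates follow
first-order kinetics `dx/dt = (x_inf(U) - x)/tau_x(U)`; intracellular
calcium (dimensionless, as in the original formulation, because the shell
volume is unspecified) obeys `dCa/dt = -0.13 ICa - 0.075 Ca`.  Time is in
ms, voltages in mV, conductances/currents in the historical per-area unit
set.

Two kinetic variants coexist:

* **original** — the historical discontinuous kinetics for `c`, `q`, `chi`
  (Heaviside switch at `Vd = -10`, `min`-caps on `alpha_q` and `chi`); kept
  for validation.
* **smooth** — fully continuous fitted replacements (a sigmoid power for
  `c_inf`, single/double exponentials for `tau_c`, `q_inf`, `tau_q`, a
  three-term sine series for `chi`).  Only this variant is differentiable,
  so all continuation work uses it.  The fit error against the originals is
  of order 1e-2 to 1e-3 (largest at the originals' kinks); the
  `validate-smoothing` command and `approximation_error()` recompute the
  error table.

### Conventions the source description leaves open

* **Membrane capacitance.** `Cm` is not part of the printed parameter
  table; we adopt `Cm = 3`, the value of the original two-compartment
  formulation whose f/I behaviour the smooth model reproduces, and expose
  it as an ordinary parameter.
* **Coupling sign.** The coupling current is defined as
  `ISD = -IDS = gC (Vd - Vs)`.  Charge conservation requires the dendrite
  to receive `gC (Vs - Vd)/(1 - p)`; we use that (the original model's
  form).  With it, every published bifurcation value is reproduced to four
  significant figures, which we take as decisive.
* **`m` is instantaneous.** The Na current uses `m_inf^2(Vs)` directly;
  `m` is not integrated.  (The generic gating text also lists `m`, but the
  current formula governs.)
* **Removable singularities.** The `a*x/(exp(x/b) - 1)` rate forms are
  evaluated by a series limit for `|x/b| < 1e-7` and by their exact
  asymptotes beyond `|x/b| > 50`, which also makes the vector field
  overflow-safe at the extreme voltages reached when continuing to
  I = +-500.
* **Fitted-function domains.** `q_inf` grows without bound for very large
  Ca and the sine-series `chi` is periodic outside the fitted window; both
  are used as printed (no clamping) because trajectories and branches of
  interest stay inside Ca < 500.  Clamping, if wanted, is a one-line
  parameter wrapper.
* **Initial conditions.** The published traces do not state theirs.
  `default_initial_state()` (both compartments at -65 mV, gates at steady
  state, q = 0.1, Ca = 0.2) is our own choice, documented as such; regime
  classification is attractor-based and does not depend on it beyond basin
  membership.

## Jacobians

The smooth right-hand side is written against a pluggable math backend and
traced symbolically (SymPy), yielding generated code for the vector field,
the exact 8x8 state Jacobian and the derivatives with respect to ISapp,
IDapp and gCa.  A test cross-checks the generated Jacobian against central
finite differences of the generated vector field, and the hand-written
reference implementation against the generated one.

## Equilibrium continuation

Keller pseudo-arclength continuation with a bordered-corrector Newton and
adaptive steps (initial 1e-2, minimum 1e-6, maximum 1.0 in the scaled
metric; voltages and Ca carry weight 1/100, applied currents 1/50).  Two
test functions are monitored between accepted points and refined by
bisection on secant hyperplanes to a parameter tolerance of 1e-5:

* **fold** — sign of `det J` (with the fold confirmed by the local
  parameter extremum and a zero eigenvalue below 1e-6);
* **Hopf** — sign of the phase-normalised product of pairwise eigenvalue
  sums (the bialternate-product test).  A plain unstable-eigenvalue count
  is unreliable here because the crossing pair is real over much of the
  bracketing interval.  At the refined point the closest-to-singular pair
  must be complex conjugate; a neutral saddle is discarded.

A genuine subtlety: within ~1e-4 of the rheobase fold the model has an
additional complex-pair crossing with angular frequency of order 1e-3
rad/ms (a singular-Hopf structure typical of slow-fast systems).  It is
far below the resolution of the published diagrams; the report layer
labels it `HB_singular` and reserves `HB` for the principal
high-frequency Hopf.

## Periodic orbits

Multiple shooting (default 40 segments for a standalone solve; branch
continuation adapts between 16 and 64 segments with the period and the
orbit's accumulated expansion) with nodes equidistributed in a mixed
metric of weighted state arclength, a time floor and the local expansion
rate, so spike upstrokes are resolved, slow passages are not starved, and
per-segment transition matrices stay well scaled on strongly unstable
orbits.  Orbits are re-sampled for re-meshing segment-by-segment from
their converged nodes — a single forward pass would drift off a strongly
unstable orbit near the period end.  The
phase is anchored by orthogonality of the first node's displacement to the
reference flow direction.  Segment transition matrices come from the
variational equations integrated alongside the state (LSODA, rtol 1e-8 /
atol 1e-9; the solver's own Jacobian for the variational block neglects
second-derivative coupling, which only affects step-size control).  The
monodromy product is accumulated with per-factor normalisation; its
eigenvalues are discarded as unreliable once the accumulated magnitude
exceeds ~5e11, which only happens deep in the high-period tails where
multipliers are no longer needed.  The trivial multiplier stays within
1e-3 of unity along every reported branch (a discretisation health check
asserted in the tests).

Branch continuation uses secant predictors in (nodes, log period,
parameter) with pseudo-arclength correctors.  Detection along the branch:
period doubling (most negative real multiplier crossing -1), torus
(product of the two leading nontrivial multipliers crossing +1, which
stays continuous when the pair collides into or out of the real axis,
with a complex-pair check at the refined point), fold of cycles (parameter
direction reversal away from the Hopf endpoints, where the amplitude is
still finite).  PD/TR crossings are refined by regula falsi on the secant
hyperplane.  A branch stops at the parameter range, at a period cap, at
step collapse, or when the orbit amplitude collapses onto an equilibrium
(the Hopf endpoint).

**Hopf-started cycles** pin the amplitude (projection onto the critical
eigenvector, scaled metric) and solve for the parameter, so the Newton
iteration cannot fall onto the equilibrium; the emergent period matches
`2 pi / omega` of the Hopf pair.  This construction also decides
super/subcriticality numerically (stability of the emergent cycle), which
is how the subcritical Hopf of the Ca-frozen fast subsystem is certified.

## Homoclinic vs SNIC termination

A branch tail whose period diverges is classified from its final orbit:
the equilibrium nearest the orbit's slowest point is located by Newton; if
it coincides with the SN1 fold equilibrium in the scaled state metric
(voltages and Ca scaled by 1/100, tolerance 1e-2) the cycle dies on the
fold — a SNIC; otherwise the termination is homoclinic to a saddle
distinct from the fold.  The asymptotic parameter value is estimated by
fitting the matching divergence law to the branch tail — logarithmic
(`T = a - b ln(p - p*)`) for a homoclinic, inverse square root for a SNIC
— with the law-recovery accuracy itself unit-tested on synthetic tails.

For a homoclinic the tail fit converges only slowly (the unstable Floquet
exponent of this model's tail orbits is ~0.7/ms, so monodromy norms reach
e^145 already at 50-ms periods and pushing the period out is expensive),
so the estimate is sharpened by *unstable-manifold bisection*: the
saddle's one-dimensional unstable manifold either re-excurses (second
spike) or decays to the coexisting stable rest state after its first
return, and the flip between the two fates happens exactly at the
connection.  Each fate evaluation is one short initial-value solve, so
the bisection pins the homoclinic parameter to 1e-4 in seconds.
Production runs therefore cap the HC-side tail at ~160-ms periods (enough
to identify the limiting saddle and the termination label) and the
SNIC-side tail at ~1.5 s (the inverse-square-root fit needs no
refinement); the 1e5-ms period cap remains available through the API.
On the SNIC side the saddle/node pair does not yet exist at the tail's
parameters, so the label is confirmed by the slow passage running through
the fold-ghost state itself.

## Two-parameter continuation

Fold and Hopf loci in (I, gCa) are continued as augmented defining systems
— equilibrium plus null vector (17 equations) or equilibrium plus real and
imaginary eigenpair conditions with two normalisations (26 equations) —
by the same bordered pseudo-arclength scheme; second-derivative actions
are taken by central differences of the analytic Jacobian.  Slice tests
assert agreement with the one-parameter detections to 1e-3 in I at
gCa = 7 and 10.

The homoclinic locus is not continued as a fixed-large-period orbit in two
parameters; instead it is traced pointwise, classifying the
periodic-branch tail per gCa with the machinery above.  This is more
expensive per point but reuses a fully tested path and gives the
termination *label*, which is what the codimension-2 search needs: the
codim-2 SNIC point is bracketed by bisection in gCa on that label (HC
above, SNIC below), not located from a defining system — its coordinates
are only defined graphically in the source material.

## Simulation and classification

LSODA with the analytic Jacobian, rtol = atol = 1e-8 by default; spike
times are upward -10 mV crossings of Vs refined by interpolation between
the solver's (adaptive, spike-resolving) steps.  Events are formed by an
adaptive inter-spike-interval split (Otsu's criterion on log ISIs,
accepted only when the two clusters are separated by a factor >= 2 with
the short cluster under 50 ms); a fixed 25-ms threshold is available but
conflates fast tonic spiking (period < 25 ms exists in this model) with
intraburst intervals.  A single-crossing event still counts as a burst
when it rides a full dendritic Ca spike (Vd > 0 mV), which is how VLF
bursts with one suprathreshold somatic spike are recognised.  The
classifier rules (rest split at -45 mV; regular spiking = ISI CV < 0.05
with a flat peak envelope; period-2 ISI alternation = doublets;
fast spiking with > 10 mV envelope undulation = waxing-waning; bursts
with inter-event intervals > 500 ms = VLF bursting; anything else
aperiodic) approximate the descriptive published regime boundaries and are
all configurable.

The phase analysis of the singlet-to-doublet transition builds a reference
oscillation with period equal to the mean inter-peak interval of the early
singlets' Vd peaks, phase-anchored by circular mean; phases are reported
in degrees with 0 at the oscillation peak, amplitudes normalised to each
variable's observed range, and the peak Ca-activated K current is measured
per event.

## Problem sizes and defaults in the shipped analyses

Equilibrium diagrams run over I in [-500, 500] (a few hundred corrector
points, seconds).  Periodic branches are seeded from the stable spiking
attractor at I = 10 — inside the regular-spiking window for both gCa = 10
and 7 — rather than from the Hopf, skipping the physiologically
irrelevant segment above the torus window when only the lower branch is
needed; the full-diagram builder still traverses TR1/TR2 from below.
Branch tails are capped as described above.  Fast-subsystem
diagrams span q in [-0.6, 0.3] — negative frozen-q values are
mathematically meaningful continuations even though q is physically a
gate — and Ca in [0, 500].  Burst overlays integrate 15-20 s of model
time.  The codimension-2 bisection uses two midpoint evaluations between
gCa = 7 and 10, which brackets the switch to width 0.75.

## Known limitations

* The NMDA-driven dendritic-input regimes of the original repertoire are
  out of scope (no published equations for the synaptic conductance).
* Torus (quasi-periodic) solutions are detected but not themselves
  continued; aperiodic windows are not quantified by Lyapunov exponents.
* The burst-orbit branch of the q-frozen fast subsystem (with its PD1/PD2
  and fold-of-cycles at negative q) is reachable with `continue_cycles`
  on the reduced system but is not part of the default test runs; the
  shipped analyses assert the SNIC and the frozen-q burst persistence,
  which carry the scientific conclusion.
* Multipliers are unavailable (by design) on extremely unstable
  high-period tail orbits; termination classification does not need them.
* The classifier thresholds approximate, not define, the descriptive
  regime boundaries; near-boundary currents can legitimately flip label.
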