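# Methods

## Scope and design

`ecodyn` implements twelve canonical model families from theoretical ecology
behind a single engine. Every model is declared as a `ModelSpec`: ordered
state names, a parameter schema (bounds and defaults), a derivative rule
(continuous time) or update map (discrete time), and an optional registry of
closed forms (solutions, equilibria, nullclines, Jacobians). The engine and
the analysis layer operate only through this interface, so each family's
module is a thin declaration of its biology plus any closed-form theory.

## Numerical integration

Continuous-time models use `scipy.integrate.solve_ivp` with the adaptive
Runge–Kutta 4(5) pair, defaults rel_tol = 1e-8 and abs_tol = 1e-10, sampled
onto a regular grid t = 0, dt_out, …, t_end (dt_out default 0.1 time units).
Models with registered closed-form solutions (exponential, logistic, island
biogeography richness) are verified against them to 1e-6 relative in the
test suite.

Abundances are clamped to zero when within ε = 1e-12 of zero (integrator
round-off below extinction); a state falling below −1e-9 aborts the run with
an error carrying the last good time, because an excursion of that size
signals a mis-specified model rather than round-off. Discrete maps iterate
in exact floating-point arithmetic with no clamping, so reruns are
bit-identical and extinction is N = 0 exactly.

The essential-resource (Tilman) model uses Liebig's raw `min()` of Monod
terms without smoothing; its default solver tolerance is tightened to 1e-9
because the right-hand side is nondifferentiable where the limiting resource
switches.

## Model-form choices

Where the underlying theory admits several textbook parameterisations, the
package fixes one and keeps parameter meanings uniform across families:

- **Discrete logistic** uses the additive form N′ = N + rN(1 − N/K), the
  form that pairs naturally with cobweb pedagogy; it shares the fixed point
  K with the continuous model and destabilises at r = 2.
- **Beverton–Holt** is parameterised as N′ = RN / (1 + ((R−1)/K)N) so that K
  is its nontrivial fixed point, keeping K's meaning uniform.
- **Mutualism** uses the linear facultative Lotka–Volterra form with
  self-limitation, dNi/dt = riNi(Ki − Ni + bijNj)/Ki. When b12·b21 ≥ 1 there
  is no interior equilibrium and growth is unbounded; runs are permitted but
  flagged, and divergence is declared when any state exceeds 10⁶·max(K1, K2).
- **Type II predation** is the Holling disc equation aH/(1 + aT_hH).
- **Epidemics** use frequency-dependent transmission βSI/N, which keeps β's
  interpretation independent of population size; the variant set is
  {SIR, SIS, SEIR, SIR with demography}. R₀ = β/γ (β/(γ+μ) with
  demography); the final-size relation z = 1 − e^(−R₀z) is solved by Brent's
  method to 1e-10.
- **Island biogeography** modifies the linear MacArthur–Wilson rate curves
  by exponential distance/area factors, λ(S) = I_max·e^(−φD)(1 − S/P) and
  μ(S) = E_max·e^(−εA)·S/P. This keeps the model linear, so S\* =
  P·I′/(I′+E′) and the full solution stay in closed form while capturing
  "far and small islands hold fewer species".
- **Source–sink** uses Pulliam-style annual surplus accounting in discrete
  time with a hard breeding-site ceiling (not a continuous logistic): the
  source grows by λ1, is truncated at N\*, and the truncated surplus
  emigrates to the sink.
- **Resource supply** in the abiotic competition model is semi-chemostat,
  a(S − R), which keeps R\* = km/(r − m) exact; consumption is proportional
  to realized growth (c·μ·N).
- **Smith–Fretwell** offspring fitness is a shifted Michaelis–Menten curve,
  W(I) = W_max(I − I_min)/(I − I_min + c), zero below the viability
  threshold I_min; it yields the closed-form optimum I\* = I_min + √(I_min·c),
  independent of budget R and ceiling W_max.
- **Leslie matrices** follow the pre-breeding census, birth-pulse
  convention. The dominant eigenvalue is taken from a full
  eigendecomposition, ties in modulus broken by largest real part, with a
  1e-12 realness tolerance.

## Equilibrium analysis

`find_equilibria` unions the spec's registered closed-form equilibria with
damped-Newton roots (`scipy.optimize.root`, hybrid Powell) started from an
8-per-axis lattice over the search box; candidates must satisfy
|dy/dt| < 1e-9 and duplicates are merged at L∞ distance 1e-6.

`classify_equilibrium` builds the Jacobian by central finite differences
(step max(1e-6, 1e-6·|x|); analytic Jacobians registered on a spec take
precedence) and classifies from its eigenvalues with a margin τ = 1e-7 on
real parts. Real parts within τ of zero with nonzero imaginary parts are
reported as `center` with a *marginal* flag: a true center (the classic
Lotka–Volterra cycle, eigenvalues ±i√(rd)) is numerically indistinguishable
from a very weakly damped spiral, so the label is honest only up to that
tolerance.

Nullclines are located by bisection (tolerance 1e-8 in state units) on sign
changes of one state's derivative, scanning both grid directions so that
near-vertical branches (e.g. the Rosenzweig–MacArthur predator isocline
H = d/(a(e − dT_h))) are captured as reliably as near-horizontal ones.

The enrichment threshold follows from the geometry of the prey isocline
P = (r/a)(1 + aT_hH)(1 − H/K), whose hump sits at H = K/2 − 1/(2aT_h); the
coexistence equilibrium H\* crosses the hump at K_crit = 2H\* + 1/(aT_h),
the Hopf bifurcation of the paradox of enrichment. Tests verify that the
leading eigenvalue's real part changes sign within ±1e-3 of K_crit and that
prey-peak amplitudes decay below and grow above it.

Oscillation growth/decay is measured by `peak_amplitudes`: strict local
maxima of the prey series on the sampled grid, as deviations from the
equilibrium value. Growing oscillations must be measured from a start near
the equilibrium — a trajectory started far outside the limit cycle
approaches it with *decreasing* amplitude even in the unstable regime — so
the dichotomy checks perturb the equilibrium by 10% and compare early versus
late amplitudes.

## Worked-example conditions

The bundled fixtures pin the standard demonstration conditions: the classic
predator–prey run (r = 0.5, a = 0.1, e = 0.2, d = 0.3, H₀ = P₀ = 10,
100 time units, unit output grid) and the two enrichment regimes of the
Rosenzweig–MacArthur model (r = 0.5, a = 0.02, T_h = 0.3, e = 0.4, d = 0.5
with K = 200 versus K = 500, bracketing K_crit ≈ 366.7). The worked-example
fixture sets rel_tol = 1e-10 because it is also the conservation check: the
first integral V = eaH − d·ln H + aP − r·ln P must drift less than 1e-5
relative over the run, which is an integration-accuracy statement, not a
property of the model.

Where a family needs defaults that the underlying theory does not fix (the
abiotic-competition demonstration parameter set, the three-age-class default
Leslie matrix, epidemic β = 0.4/γ = 0.2 with N = 1000), they are chosen as
typical classroom values: the abiotic defaults put the resource supply point
inside the coexistence cone so the two-consumer demonstration actually
coexists, and the epidemic defaults give R₀ = 2, the standard teaching case.

## What the tests do and do not show

All dynamics here are deterministic ODEs and maps at desk scale; the test
suite checks internal mathematical consistency (closed forms versus
simulation, conservation laws, stability theory versus trajectories), not
agreement with any field data. Problem sizes are small by construction —
trajectories of 10²–10⁴ samples, 2–4 state variables — because the models'
behaviour is fully expressed at that scale. Equality with any other software
implementation of the same models is not claimed beyond the closed-form
accuracy stated above, since solver choices and output grids differ.

## Known limitations

- No stochastic (demographic-noise) simulation, event handling, or delay
  differential equations.
- Stage-structured (Lefkovitch) matrices and sensitivity/elasticity analysis
  are out of scope; only strict Leslie structure is accepted.
- The equilibrium search is box-local and lattice-started; equilibria with
  tiny basins between lattice points could in principle be missed (the
  bundled models' equilibria are all re-found in tests).
- `center` classification is a statement about eigenvalues at tolerance
  1e-7, not a proof of a conserved orbit.
- Vector-field and nullcline grids are uniform; no adaptive refinement.
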