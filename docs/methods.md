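# Methods

## Model and standing assumptions

The state is `(u, w, v, z)`: uninfected target cells, infected cells, free
virus, CTL effectors.  Cells are recruited at constant rate `s` and die at
`d1`; infection converts them at rate `f1(u,v)·v + f2(u,w)·w`; infected
cells die at `d2` and are killed by CTLs at `p·w·z`; virions are produced
at `k` per infected cell and cleared at `d3`; CTLs are produced at `c` per
infected cell with a fixed activation delay `τ` and die at `d4`.  All rates
are strictly positive, `τ ≥ 0`, and the initial history on `[−τ, 0]` is a
nonnegative continuous function (constant histories in practice).

Incidence functions `f(u, y)` must satisfy three structural hypotheses,
checked numerically for custom rate laws (`check_hypotheses`, default grid:
a log-spaced lattice over `[0, 10⁴]²` plus the axes):

1. `f(0, y) = 0` — no infection without target cells (absolute tolerance
   1e-9);
2. `∂f/∂u > 0` and `∂f/∂y ≤ 0` — monotone in targets, interference in the
   infectious agent;
3. `f + y·∂f/∂y ≥ 0` — the total incidence `f·y` is nondecreasing in `y`.
   (This is the condition that makes the equilibrium combinations
   `Q1 = f1_v·v* + f1*` and `Q2 = f2_w·w* + f2*` nonnegative, which the
   stability analysis needs.)

The four named families satisfy all three identically; their partial
derivatives are analytic.  Custom specs without analytic partials fall back
to second-order central differences with step `6e-6·(1+|x|)` (one-sided at
the boundary `u = 0` or `y = 0`), which keeps the truncation error near the
square root of machine precision.

Solutions are nonnegative and ultimately bounded: with `d = min(d1, d2)`,
`limsup (u+w) ≤ s/d`, `limsup v ≤ k·s/(d·d3)`, `limsup z ≤ c·s/(d·d4)`.
The integrator enforces these as runtime invariants (below).

## Equilibria

`E0 = (s/d1, 0, 0, 0)` always exists.  The basic reproduction number is

    R0 = k·f1(u0,0)/(d2·d3) + f2(u0,0)/d2,   u0 = s/d1,

reported together with its two route components (their sum is exact by
construction).  For `R0 > 1` the steady-state relations `v = (k/d3)w`,
`z = (c/d4)w`, `u = [s − w(d2 + (pc/d4)w)]/d1` reduce the equilibrium to a
root of the infected-cell balance

    G(w) = f1(u,v)·v + f2(u,w)·w − (d2 + (pc/d4)w)·w

on `(0, w_bar)`, where `w_bar = 2s/(d2 + sqrt(d2² + 4spc/d4))` is the
positive root of the admissibility quadratic, written in the
cancellation-free form (it also degenerates correctly to `s/d2` as
`p → 0`).  `G(0) = 0`, the one-sided slope at zero is `d2(R0 − 1)`, and
`G(w_bar) < 0`; under the hypotheses `G` is strictly decreasing at each
zero, so the root is unique.

Numerics: `G` is sampled on a 4096-point grid of `(0, w_bar)`; more than
one sign change raises a consistency error (it can only happen when a
custom incidence violates the hypotheses), one sign change brackets Brent's
method (`xtol = 1e-14·w_bar`), and the root is polished by up to two Newton
steps with the analytic `G′`.  The accepted root must satisfy
`|G(w*)| ≤ 1e-12·d2·w_bar`.  If the scan finds no sign change (root closer
to zero than the grid spacing) the bracket is grown geometrically from
`1e-15·w_bar`.  Parameter sets with `|R0 − 1| ≤ 1e-8` are refused as
threshold-degenerate rather than solved; the theory does not cover `R0 = 1`.
`u` is clamped at zero when round-off at `w = w_bar` drives it to `−1e-13`.

## Linear stability and the Hopf machinery

At `E0` the characteristic equation factors into `(λ+d1)(λ+d4)` and a
quadratic whose constant term is `d2·d3·(1 − R0)`: stable iff `R0 < 1`
(the delay never enters — the CTL equation decouples from the infection-free
state).

At `E*` the linearization has the transcendental characteristic equation

    λ⁴ + A3λ³ + A2λ² + A1λ + A0 + (B2λ² + B1λ + B0)·e^{−λτ} = 0.

The coefficients are assembled from `Q0 = f1_u v* + f2_u w*`,
`Q1 = f1_v v* + f1*`, `Q2 = f2_w w* + f2*`, the effective infected-cell
decay `D = d2 + p z* − Q2` (positive at `E*`, equal to
`f1* k/d3 − f2_w w*` by the equilibrium identities) and
`X = D·d3 − k·Q1 = −k v* f1_v − d3 w* f2_w`:

    A3 = (d1+Q0) + D + d3 + d4
    A2 = (d1+Q0)(D+d3+d4) + d3·d4 + d4·D + X + Q0·Q2
    A1 = (d1+Q0+d4)·X + Q0·Q2·(d3+d4) + k·Q0·Q1 + (d1+Q0)·d4·(D+d3)
    A0 = d4·[(d1+Q0)·X + d3·Q0·Q2 + k·Q0·Q1]
    B2 = p·w*·c,  B1 = B2·(d1+d3+Q0),  B0 = B2·d3·(d1+Q0)

These are the exact expansion of the characteristic determinant: the
delay-free part factors as `(λ+d4)` times the cubic of the `(u, w, v)`
block, the delay part as `p w* c (λ+d1+Q0)(λ+d3)`.  The expansion was
derived symbolically and is oracle-tested: at `τ = 0` the quartic's roots
must coincide with the eigenvalues of a finite-difference Jacobian of the
vector field (delay column folded in), to 1e-5 relative, on every shipped
fixture.  All seven coefficients are provably positive under the
hypotheses; a non-positive value raises a consistency error.  The
coefficients do not depend on `τ` (the equilibrium and the partials do
not), so they are computed once per parameter set.

`τ = 0`: Routh–Hurwitz for the quartic with positive coefficients —
stable iff `H1 = A3(A2+B2) − (A1+B1) > 0` and
`H2 = A3(A2+B2)(A1+B1) − A3²(A0+B0) − (A1+B1)² > 0`.  The verdict is
oracle-tested against direct root signs on 1000 random quartics (draws
with `|H2|` at float-noise level are excluded as undecidable).

Imaginary-axis crossings: `λ = iω` solves the characteristic equation iff
`z = ω²` is a positive root of

    F(z) = z⁴ + M3z³ + M2z² + M1z + M0,
    M3 = A3² − 2A2
    M2 = A2² + 2A0 − 2A1A3 − B2²
    M1 = A1² − 2A2A0 + 2B2B0 − B1²
    M0 = A0² − B0²,

which is the identity `F(ω²) = |P(iω)|² − |Q(iω)|²` (tested as such).
Roots are found by the companion-matrix quartic solver; a root counts as a
positive real when `|Im| ≤ 1e-9·(1+|Re|)` and `Re > 1e-12`.  The classical
resolvent-cubic case analysis of root existence is computed only as a
consistency cross-check (a disagreement warns; configurations within 1e-9
of a boundary case are not classified).  Direct solving was chosen over
the case analysis because it is uniformly robust and sidesteps the
ambiguity of which cubic root the analysis should use.

For each crossing frequency, `cos(ωτ)` and `sin(ωτ)` follow rationally
from the real/imaginary split; the delay ladder is
`τ_j = [arccos(Fc) + 2πj]/ω` on the branch selected by the sine's sign,
`j = 0..⌈τ_max·ω/2π⌉+1` (default `τ_max = 50`).  A computed `|Fc|` beyond
`1+1e-9` is an error; values inside the band are clamped.  Every rung must
pass a residual check: the characteristic function at `(iω, τ_j)`,
normalized by the sum of its term moduli, must be below 1e-8.

Transversality: the crossing direction is
`sign(dReλ/dτ) = sign F′(ω²)` — `+1` destabilizing (the conjugate pair
moves into the right half-plane), `−1` stabilizing.  `|F′|` below
`1e-10` times the local derivative scale marks a repeated root of `F`;
such crossings are reported with sign 0 and excluded from Hopf claims.
The sign convention is verified by an independent oracle that
Newton-tracks the characteristic root across each rung and differences its
real part.

`hopf_summary` composes the pipeline and reports `τ*` as the global
minimum over all rungs of all ladders.  Because transversality signs can
interleave, `τ*` is the *first* stability loss, not necessarily the only
switch: the bilinear fixture destabilizes at 3.72, restabilizes at 10.52
and destabilizes again at 16.81, so it is steady at `τ = 15` and periodic
at `τ = 20`.  The full ladders with signs are part of the summary so
stability windows are recoverable by counting unstable root pairs.  What is
*not* computed: the direction/stability of the bifurcating periodic orbit
(no normal-form or center-manifold reduction); crossings beyond the first
are reported but the resulting attractors are characterized only
numerically.

## DDE integration

Classical RK4 by the method of steps.  The step snaps to the delay:
`h = τ/m` with `m = round(τ/h_requested)` (default `h_requested = 0.01`
time units), so the lagged times `t − τ` and `t + h − τ` of the first and
fourth stages land exactly on stored nodes.  The two half-stages need
`w(t + h/2 − τ)`, served by cubic Hermite interpolation from the values and
stored derivatives of the two bracketing nodes; the node derivative of `w`
is the first RK stage, which is computed anyway.  Derivative
discontinuities of the solution propagate at multiples of `τ`, which are
grid nodes by construction, so no step straddles one and the stepper keeps
its fourth order — confirmed by a step-halving test whose terminal-error
ratio must fall in `[10, 30]` (nominal 16).  `τ = 0` runs as a plain ODE in
the same loop (the lag reads the current stage value) and is oracle-tested
against an adaptive Runge–Kutta reference at tight tolerance.

Runtime invariants: a component within `1e-9` times its ultimate bound
below zero is clipped to zero (integration round-off); anything more
negative raises an error rather than being hidden.  A component exceeding
1000x its ultimate bound (or 1000x its initial value, whichever is larger)
raises a divergence error.

Default initial history (used whenever none is given, and by all scan
protocols): the constant `0.95·E*` when the positive equilibrium exists,
else `(0.9·u0, 1, 1, 1)`.  A near-equilibrium start reaches the *local*
attractor quickly and makes the stability verdicts sharp; its known cost is
that beyond a destabilizing crossing the trajectory must grow out of a 5%
perturbation, so fixed-window diagrams can show the outgoing spiral rather
than the settled cycle (see limitations).

## Bifurcation scans and period detection

A scan integrates once per delay on a grid, always from the same fresh
history (no continuation — with coexisting attractors a continuation
protocol would trace different branches; none is attempted).  On the
post-transient window (defaults mirror the study protocol: horizon 5500,
transient 5000, i.e. a 500-unit window):

- *equilibrium*: peak-to-peak amplitude of `v` below
  `1e-8 + 1e-3·|window mean|`;
- otherwise the strict local extrema of `v` are extracted by three-point
  comparison (plateau runs collapse to their midpoint), and the maxima are
  clustered by single-linkage with gap threshold `0.02·(max − min)` of the
  maxima; the label is *period-n* when the time-ordered cluster sequence
  repeats with period equal to the cluster count `n`, *aperiodic* when it
  does not or when more than 12 clusters appear (an operational label — no
  Lyapunov exponents are computed), and *unresolved* with fewer than 6
  maxima in the window.

The 0.02 threshold separates visibly distinct branches of the study
scenarios while absorbing numerical jitter.  The known failure mode of
absolute-level clustering is a *drifting* transient: the stronger
saturation fixture at `τ = 35` repeats maxima in clean triples, but the
triple pattern rides a slow amplitude drift for thousands of time units
(the settled attractor's three levels then contract toward a simple
cycle), so in early fixed windows every third maximum lands in its own
cluster and the label is aperiodic although the local signature is
period-three.  Sequence-based detection (clustering successive-maxima
patterns instead of levels) would be robust to drift but is deliberately
out of scope; the diagram rows store the raw extrema so users can apply
their own detector.

## Problem sizes used by the tests and the acceptance script

The acceptance script solves the equilibrium on the 4096-point bracketing
grid and runs the full ladder analysis; both complete in well under a
second.  The test suite integrates the period-window check at step 0.01 to
horizon 5500, the stability-window checks to horizon 4000, and the
onset-bracketing scans (4 delays per fixture, 8 fixtures) at step 0.02 to
horizon 5500 — sizes chosen to keep the full suite around two minutes on
one core while leaving every verdict far from its tolerance.

## Known limitations

- No Hopf direction/stability coefficients (normal form / center manifold).
- Stability windows are derived from crossing signs, not re-verified by
  eigenvalue continuation between rungs.
- Chaos labels are diagnostic (cluster-count based), not rigorous.
- Scan classifications near a crossing inherit the critical slowing down of
  the dynamics: within roughly one grid step of `τ*` a finite window may
  misclassify a slowly decaying (or slowly growing) spiral; onset
  comparisons are therefore made to one-grid-step resolution.
- Fresh-history scans cannot exhibit hysteresis between coexisting
  attractors.
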