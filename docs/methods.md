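# Methods

## Model

Swelling of a mitochondrial population after Ca²⁺ addition is described by
the fraction `X(t)` of mitochondria that are swollen or actively swelling,

    X'(t) = (a·X^r + b)·(X_p − X),   X(0) = 0,

together with a delayed three-subpopulation decomposition of the mean
volume,

    V(t) = V0·(1 − X(t)) + k·V_p·(X(t) − X(t−τ)) + V_p·X(t−τ).

Assumptions baked into this structure:

* A fixed fraction `1 − X_p` of the population never swells.
* Swelling starts at a background rate `b` (direct stimulus) and is
  self-accelerating through `a` (Ca²⁺ re-released by swollen mitochondria).
  With `a = 0` the kinetics are first order and the volume equation with
  `τ = 0` reduces to the classical single-exponential (Massari-type)
  description `V(t) = V0 + (V_p − V0)·X_p·(1 − e^{−bt})`.
* Each mitochondrion spends on average `τ` minutes actively swelling, with
  mean volume `k·V_p` during that window. The history convention is
  `X(s) = 0` for `s < 0`, so nothing finishes swelling before `t = τ`.
* Suspension optical density is affine in the mean volume with negative
  slope (swelling lowers light scattering).

Closed form (`r = 1`): separation of variables and partial fractions give
`X(t) = X_p·b·(e^{st} − 1)/(a·X_p + b·e^{st})` with `s = a·X_p + b`,
implemented in the overflow-safe equivalent
`X_p·b·(1 − e^{−st})/(a·X_p·e^{−st} + b)`. `X` is monotone, converges to
`X_p` exponentially, and has exactly one inflection point at positive time
when `a·X_p > b` (the regime of every row of the packaged titration table);
for weaker feedback the curve is concave from the start. `b = 0` makes
`X ≡ 0` (no swelling ever starts), which the containers allow even though
measured curves always imply `b > 0`.

The delayed term makes `V'` jump by `b·X_p·V_p·(1 − k)` at `t = τ`
(`derivative_break`); the jump vanishes as `b → 0` or `k → 1`.

The diagnostic `log_volume_transform` returns
`L(t) = ln((V∞ − V(t))/(V∞ − V0))` with `V∞ = V0(1 − X_p) + V_p·X_p`, the
model's true volume limit. Using `V∞` rather than `V_p` keeps `L(0) = 0`
and the argument positive; under the reduced model `L(t) = −b·t` exactly,
while the full model straightens only once most swelling is done.

## Parameters and defaults

| symbol | meaning | unit | default / typical |
|---|---|---|---|
| `a` | positive-feedback rate | 1/min | fitted; 0.12-0.46 across 40-140 µM |
| `b` | background swelling rate | 1/min | fixed at 0.021 for titration fits |
| `k` | mean swelling-subpopulation volume as fraction of `V_p` | — | fitted; 0.73-0.97; `k·V_p < V0` ⇒ transient shrinking |
| `τ` | mean single-mitochondrion swelling time | min | fitted; 1.8-26 |
| `r` | kinetic order of the feedback | — | 1 (free-order fits land in 0.6-1.6) |
| `X_p` | final swollen fraction | — | 0.9 |
| `V0`, `V_p` | unswollen / fully swollen volume | ml/mg protein | 1.2 / 1.7 |

The constants `X_p, V0, V_p` barely influence fitted kinetics because the
volume curve is affinely rescaled to the data.

## Fitting

* Objective: sum of squared residuals between the rescaled volume curve and
  the data, divided by the sum of squared data values. The relative
  normalisation makes per-curve errors O(1e−3) and comparable across
  assays; absolute SSR is available (`relative=False`).
* Rescaling: the affine map sending (min V, max V) to (max A, min A). A
  regression-based alternative (`rescale_method="regress"`) is provided for
  sensitivity checks.
* Bounds by reparameterisation inside unconstrained Nelder-Mead: `a, b`
  log-transformed, `k` logit-transformed on (0.05, 1], `τ = τ_min + e^u`.
  `τ_min` defaults to 0; the packaged titration table shows τ pinned at
  2.0 min for 110-130 µM, so a 2-minute bound can be reproduced via
  `tau_min=2`.
* Multi-start: one data-driven start (lag read off the first 10% OD drop)
  plus 5 seeded Latin-hypercube starts over the bounds; best result is
  polished by a simplex restart; ties broken by smallest τ. Convergence:
  simplex and objective tolerances 1e−10, at most 5000 iterations per
  start; non-convergence is flagged, never raised.
* Modes: `full` (a, b, k, τ), `fixed_b` (b frozen; the titration-table
  convention), `free_order` (adds r; staged search that first solves the
  r = 1 problem in closed form, then refines with the ODE integrator from
  r ∈ {0.7, 1.0, 1.3, 1.6} — a plain multi-start stalls in a local basin
  near r ≈ 1), `massari` (a = 0, τ = 0: only b is identifiable; k is
  reported as 1).
* Joint optimisation of all free parameters (no sequential conditioning).

Identifiability: on noiseless synthetic curves the full fit recovers all
four generating parameters to better than 1e−6 relative. At 1% measurement
noise `a` and `b` trade off when both are free (median error on `a` ~13%);
with `b` fixed at its known value — the same convention under which the
packaged table was produced — median errors over 20 replicates are about
5% (a), 1% (k) and 1% (τ).

## Meta-regressions

`relative_squared_error(obs, pred) = Σ((pred−obs)/obs)²` is the criterion
throughout. The linear law for `a` is plain OLS (with the relative error of
the fitted line reported alongside). The exponential laws for `τ` and `k`
are fitted by Nelder-Mead on the relative criterion, started from the
log-linear OLS solution plus seeded log-normal perturbations; the returned
error therefore never exceeds that of any published coefficient set for the
same data. Log-linear OLS alone does not minimise the relative criterion,
which is why the directly fitted τ law (prefactor ≈ 95.4, rate ≈ 0.0332,
error 0.98) differs from the classical printed one (83.7, 0.0293, error
1.71); both are obtainable, the package reports its own optimum.
Offset-exponential fits with `|rate|·range([Ca]) < 1e−6` are flagged
ill-posed (offset and scale not separately identifiable). Rows with τ at
the 2-minute bound are included by default (`exclude_bound_rows=True` to
drop them).

## Synthetic data

The generator emulates a 60-minute plate-reader MPT assay: model volume
kinetics on a 0.25-min grid (sampling interval chosen as a typical kinetic-
read setting; the real instrument's interval is unreported), an affine
volume→OD map anchored at `V0 → A0 = 1.0` and `V∞ → Ap = 0.4` (span chosen
to look like a typical swelling assay; fitted kinetics are invariant to the
map), and additive i.i.d. Gaussian noise (σ in OD units, seeded).
Per-dose generating parameters follow the empirical calcium laws
(`a = 0.00297·[Ca] + 0.0333`, `τ = 83.7·e^{−0.0293·[Ca]}`,
`k = 0.692 + 0.0137·e^{0.0218·[Ca]}`, `b = 0.021`), so a generated panel
reproduces the dose-ordering of onset times.

What the generator does **not** emulate: heteroscedastic or drifting
instrument noise, well-to-well baseline variation, biological heterogeneity
beyond the three discrete subpopulations, incomplete-swelling plateaus that
differ between inducers, and dead time before the first read. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to every
artefact of real plate-reader data.

## Numerical choices

* Integrator: adaptive RK (DOP853), rtol 1e−10 / atol 1e−12 by default —
  cheap at this problem size and trustworthy as an oracle for the closed
  form (agreement ≤ 1e−8 over 60 min across the parameter space). The
  fitting path for free-order uses rtol 1e−8 for speed.
* Degenerate inputs: constant data or constant model curves make the
  extreme-based rescaling undefined; fits return `converged=False` with the
  best-so-far parameters instead of raising.
* Monte-Carlo sizes: recovery experiments use 20 replicates on 241-point
  curves; closed-form/oracle agreement is checked on 200 random parameter
  sets.

## Limitations

* No uncertainty quantification — point estimates only.
* The three-subpopulation split causes the (small) slope break at `t = τ`;
  a continuous-swelling formulation would remove it but is out of scope.
* No spatial dynamics, no mechanistic pore/ion-flux modelling, no explicit
  model of inhibitor (CsA) or pore-former (alamethicin) controls beyond
  setting `a = 0` / small `b`.
* The model averages over the population and cannot represent
  subpopulations with qualitatively different swelling behaviour.
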