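# mitoswell

Kinetic analysis of Ca²⁺-induced mitochondrial permeability-transition (MPT)
swelling. When isolated mitochondria take up calcium, the permeability
transition opens a nonspecific inner-membrane pore, water flows into the
matrix and the organelles swell; in a plate reader this appears as a
monotone drop of suspension optical density (light scattering), typically
after an initial lag. `mitoswell` simulates this process with a
two-equation delay model, fits the model to optical-density time series,
and regresses the fitted kinetics against calcium dose.

## The model

Let `X(t)` be the fraction of mitochondria that are swollen or have started
swelling at time `t` (minutes), with final value `X_p < 1`:

    X'(t) = (a·X(t)^r + b)·(X_p − X(t)),   X(0) = 0.

* `b` (1/min) — background swelling driven directly by the stimulus;
* `a` (1/min) — positive feedback: Ca²⁺ released by swollen mitochondria
  accelerates the swelling of others (second-order kinetics for `r = 1`);
* `r` — kinetic order of the feedback (default 1, where the ODE has the
  closed form `X(t) = X_p·b·(e^{st} − 1)/(a·X_p + b·e^{st})`, `s = a·X_p + b`).

The mean population volume (ml/mg protein) splits into unswollen, actively
swelling, and fully swollen subpopulations, with a delay `τ` (the mean
single-mitochondrion swelling time) and a swelling-volume factor `k`:

    V(t) = V0·(1 − X(t)) + k·V_p·(X(t) − X(t−τ)) + V_p·X(t−τ),

with `X(s) = 0` for `s < 0`. Defaults are `X_p = 0.9`, `V0 = 1.2`,
`V_p = 1.7`. `k·V_p < V0` reproduces the transient shrinking often seen
before the main swelling phase.

Fitting: simulated `V(t)` is mapped onto a measured OD curve by the
decreasing affine map that matches both curves' extremes, and `(a, b, k, τ)`
are estimated by multi-start Nelder-Mead minimisation of the relative sum of
squared residuals. Across a calcium titration the fitted parameters follow
`a = slope·[Ca] + intercept` (OLS), `τ = A·e^{−c·[Ca]}` and
`k = k₀ + s·e^{c·[Ca]}` (both fitted in relative squared error,
`Σ((pred−obs)/obs)²`).

## Worked example

```python
import mitoswell as ms

# synthetic 50 uM curve: model kinetics + linear OD map + 1% Gaussian noise
gen = ms.calcium_parameters(50.0)            # a=0.1818 b=0.021 k=0.733 tau=19.34
curve = ms.generate_curve(gen, noise=ms.NoiseModel(sigma=0.006, seed=11))

res = ms.fit_swelling(curve, mode="fixed_b", seed=0)
print(f"a={res.params.a:.4f} k={res.params.k:.4f} "
      f"tau={res.params.tau:.2f} err={res.err:.3e}")
# a=0.1709 k=0.7384 tau=19.34 err=1.009e-04

for name, fit in ms.run_meta_regressions().items():
    print(name, fit.form, fit.coefficients, fit.rel_sq_error)
# a    linear              slope=0.00297  intercept=0.03338   0.1778
# tau  exponential-decay   prefactor=95.4 rate=0.0332         0.9824
# k    offset-exponential  offset=0.697 scale=0.0113 rate=0.0230  0.0026
```

The fixed-b fit recovers the generating delay to the printed precision and
the feedback rate to ~6% at this noise level; `err` is the relative
least-squares objective. `run_meta_regressions` refits the three
parameter-vs-calcium laws on the packaged 40-140 µM titration table; the
exponential laws are optimised directly in relative error, so their errors
are at most those of the classical published coefficients.

The same workflow is scriptable from the shell:

```sh
mitoswell generate --outdir panel --sigma 0.006 --seed 11
mitoswell fit panel/curve_ca*.csv --mode fixed_b --out fits.csv
mitoswell regress --table fits.csv --out laws.json
mitoswell recover --seed 7 --out report.json   # end-to-end self-check
```

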