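# betaburrx

A Python library for the **beta Burr type X (BBX) distribution** — a
four-parameter lifetime law for strictly positive data (strengths,
failure times, survival durations) that is flexible enough to capture
left-skewed samples and bathtub-shaped hazards that its classical
sub-models cannot.

The construction applies the beta generator with shapes (α, β) to the
Burr type X (generalized Rayleigh) baseline with scale λ and shape θ:

    F(x) = (1 − e^{−(λx)²})^θ                      (Burr X baseline)
    G(x) = I_{F(x)}(α, β)                           (BBX CDF)
    g(x) = 2θλ²x e^{−(λx)²} u^{θα−1} (1 − u^θ)^{β−1} / B(α, β),
           u = 1 − e^{−(λx)²},

where I is the regularized incomplete beta function.  Setting
α = β = 1 recovers the Burr X; additionally θ = 1 gives the Rayleigh
law and λ = 1 the one-parameter Burr X.

The package is aimed at statisticians and reliability analysts who need
the full working surface of this family:

- **distribution core** — pdf/log-pdf, CDF (incomplete-beta and series
  forms), survival and hazard (upper tail evaluated without
  cancellation), quantile, seeded sampling;
- **moments** — the double-series form of E[Xʳ] with certified adaptive
  truncation, finite-sum specializations, a quadrature oracle, and
  quantile-based Bowley skewness / Moors kurtosis;
- **order statistics** — exact beta-weighted densities and moments plus
  the multi-index series representation as a cross-check;
- **inference** — analytic score, multi-start maximum likelihood,
  observed information, Wald intervals, likelihood-ratio tests, and
  AIC/CAIC/BIC model comparison against the sub-models and the
  generalized exponential;
- **simulation** — seeded Monte-Carlo bias/RMSE studies of the ML
  estimators;
- the classical **63 glass-fibre strengths** benchmark bundled as
  `load_glass_fiber()`.

## Worked example

```python
import betaburrx as bb

sample = bb.load_glass_fiber().sample            # 63 strengths, 0.55 .. 2.24
fits = {fam: bb.fit_mle(sample, fam, seed=1)
        for fam in ("bbx", "burrx", "burrx1", "rayleigh")}
for row in bb.information_criteria(list(fits.values()), sample):
    print(f"{row.model:<10} negLL={row.neg_loglik:8.4f}  AIC={row.aic:8.3f}")
lr = bb.lr_test(fits["burrx"], fits["bbx"])
print(f"omega={lr.omega:.3f} vs chi2 critical {lr.critical:.3f} -> reject={lr.reject}")
```

prints

```
bbx        negLL= 14.5841  AIC=  37.168
burrx1     negLL= 23.9584  AIC=  49.917
burrx      negLL= 23.9288  AIC=  51.858
rayleigh   negLL= 49.7909  AIC= 101.582
```

and `omega=18.689 vs chi2 critical 5.991 -> reject=True`: the
four-parameter BBX fits the glass-fibre strengths decisively better
than every sub-model (smallest AIC), and the likelihood-ratio test
rejects the two-parameter Burr X restriction α = β = 1 at the 5% level.
The Rayleigh scale 0.6490 and the Burr X pair (λ̂, θ̂) = (0.9869,
5.4860) come from closed-form/profiled estimators, not black-box
search.

The `examples/` directory has one short narrative script per
capability: `fit_glass_fiber.py`, `distribution_curves.py`,
`moments_and_shape.py`, `order_statistics_demo.py`,
`monte_carlo_study.py`.  A thin CLI mirrors the library:

```sh
betaburrx fit --model burrx --dataset glass_fiber
betaburrx dist cdf --params 1 1 1 1 --at 0.8325546
betaburrx simulate --alpha 0.5 --beta 0.2 --lam 0.5 --theta 8 \
          --n-list 100 1000 --reps 200 --seed 42 --out mc.csv
```

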