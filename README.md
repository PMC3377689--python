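# hdmrnet

Random-sampling High Dimensional Model Representation (RS-HDMR) for inferring
the structure of biological signaling networks from multivariate single-cell
measurements, and for using the fitted expansions as predictive surrogate
models.

## Who this is for

Given tables of simultaneous per-cell measurements of many network nodes
(e.g. phosphoprotein levels from flow cytometry), one per experimental
condition, `hdmrnet` answers three questions:

1. **Structure** — which nodes directly influence which, once connections
   that merely pass through other *measured* nodes are discounted?
2. **Forward prediction** — given a cell's state on all other nodes, what is
   the level of an unmeasured node?
3. **Inverse classification** — given a cell's state, which experimental
   (perturbation) condition was it observed under?

## The model

Each node y is expanded over the remaining nodes x₁…x_N as a hierarchy of
component functions

    y = f₀ + Σᵢ fᵢ(xᵢ) + Σᵢ<ⱼ fᵢⱼ(xᵢ, xⱼ) + Σᵢ<ⱼ<ₖ fᵢⱼₖ(xᵢ, xⱼ, xₖ) + ε

where f₀ is the sample mean, fᵢ captures the (generally nonlinear)
independent effect of xᵢ and the higher-order terms capture cooperative
effects. Component functions are represented as weighted products of
per-variable polynomials φᵣ constructed to be *orthonormal over the empirical
sample measure* — zero mean, unit mean square, zero cross-products — so the
weights are estimable from scattered random samples by least squares.

Over-fitting (and the spurious inclusion of indirect connections) is
controlled by **model reduction**: a candidate component enters the expansion
only if the F statistic on its reduction in residual sum of squares is
significant (default α = 0.01), tested forward, order by order.

The fitted expansion's variance decomposition yields **sensitivity indices**

    Sₖ = cov(fₖ, y) / σ²_y,     Σₖ Sₖ + S_resid = 1 (exactly)

which reduce to var(fₖ)/σ²_y under independent inputs. The **total
sensitivity** Tᵢ — the sum of Sₖ over every component containing input i —
is the edge weight for network structure: W[out, in] is the maximum Tᵢ over
all experimental conditions, and connections with W ≥ τ (default 0.1) are
called significant. The same fitted expansion serves as a *fully equivalent
operational model* (FEOM) for forward prediction, and — fitted on a
control/perturbed "pairwise-comparison" dataset with the perturbed node's
values replaced by 0/1 condition labels — as an inverse classifier with a 0.5
score threshold.

## Worked example

Fit one expansion on a synthetic benchmark with a known cooperative
interaction and compare the estimated indices to the generative truth:

```python
from hdmrnet import (FitConfig, analytic_sensitivities, compute_sensitivities,
                     fit_hdmr, make_benchmark_spec, normalize_unit_interval,
                     sample_synthetic)

spec = make_benchmark_spec("cooperative", seed=0)
table = normalize_unit_interval(sample_synthetic(spec, 5000, seed=1))
model = fit_hdmr(table, "y", FitConfig(alpha=0.01, max_order=2))
report = compute_sensitivities(model, table)

print(f"selected {len(model.components)} component functions for output 'y'")
for (order, variables), s in sorted(report.S.items()):
    print(f"  order {order}  f({', '.join(variables)})  S = {s:.3f}")
print(f"residual index S_resid = {report.S_resid:.3f}")
print("analytic truth:", {k[1]: round(v, 3) for k, v in analytic_sensitivities(spec)["S"].items()})
```

Output:

```
selected 3 component functions for output 'y'
  order 1  f(x1)  S = 0.541
  order 1  f(x2)  S = 0.264
  order 2  f(x1, x2)  S = 0.185
residual index S_resid = 0.009
analytic truth: {('x1',): 0.535, ('x2',): 0.262, ('x1', 'x2'): 0.193}
```

The F-test kept exactly the three true terms (the two decoy inputs x3, x4
were rejected), the estimated variance shares match the analytic values to
about 0.01, and 99% of the output variance is explained. `T(x1) = 0.726` and
`T(x2) = 0.450` would both clear the default edge threshold τ = 0.1, so both
inputs are called direct connections of y.

A command-line interface mirrors the library:

```
hdmrnet simulate --preset indirect-chain --n 5000 --seed 7 --out bench/
hdmrnet fit --input bench/control.csv --output-node y --alpha 0.01 --model m.json
hdmrnet network --tables bench/control.csv --tau 0.1 --out net.sif
hdmrnet pipeline --config run.yaml
```

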