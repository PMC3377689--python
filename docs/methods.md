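# Methods

## Model

`hdmrnet` fits, for each designated output node y, a truncated HDMR expansion

    y = f₀ + Σ fᵢ(xᵢ) + Σ fᵢⱼ(xᵢ,xⱼ) + Σ fᵢⱼₖ(xᵢ,xⱼ,xₖ) + ε

over the remaining measured nodes, truncated at third order. The zeroth-order
term f₀ is the sample mean of y. Component functions are linear combinations
of orthonormal polynomial basis functions:

    fᵢ(xᵢ)      = Σᵣ αᵣ φᵣ(xᵢ)
    fᵢⱼ(xᵢ,xⱼ)  = Σₚ Σ_q β_pq φₚ(xᵢ) φ_q(xⱼ)
    fᵢⱼₖ(...)   = triple products analogously

All inputs are first linearly rescaled to [0, 1] per node by the training
min/max. The transform is frozen with the model; out-of-range points at
prediction time are clamped to [0, 1] with a warning (measurements outside
the training range carry no basis support, so extrapolation is deliberately
flat at the boundary).

### Orthonormal bases

For each input, the monomials x, x², …, x^k are orthonormalized against the
constant under the empirical inner product ⟨f,g⟩ = (1/n) Σₜ f(xₜ)g(xₜ) —
i.e. Monte-Carlo integration over the sample measure, so the basis adapts to
whatever marginal distribution the data has. Construction uses modified
Gram–Schmidt with one re-orthogonalization pass; the sign convention makes
every leading coefficient positive; a monomial whose norm falls below 10⁻¹⁰
of its original norm signals rank deficiency (too few distinct values) and is
an error. On the training sample every φᵣ then has mean 0, mean square 1, and
zero cross-moments to machine precision; on an independent sample from the
same distribution the deviations shrink as n^(−1/2).

Second- and third-order terms are pure tensor products of the univariate
bases. Product columns are *not* re-orthogonalized against lower-order basis
functions (the product form above is used as-is), but each product column is
centered on its training mean before fitting, with the mean stored on the
component. This enforces the HDMR zero-mean condition on every fitted
component function exactly, which in turn makes f₀ equal the training mean of
y and the training residual mean vanish exactly rather than only
asymptotically.

### Default degrees

k = 3 for first-order terms, 2 per factor for second order, 1 per factor for
third order; all configurable via `FitConfig`. These defaults keep the term
count per candidate small (3, 4, and 1 columns respectively) so that the
F-test's numerator degrees of freedom stay interpretable at cytometry-scale
sample sizes (hundreds to thousands of cells). When a variable's basis cannot
support the configured degree (few distinct values), the degree is capped at
what the basis provides.

### Model reduction

Candidates are enumerated first order (all inputs), then second, then third,
lexicographically by variable name. Under the default *hierarchical* policy,
higher-order candidates are drawn only from variables already significant at
first order — cooperative effects are expected between nodes that matter
individually — while the *exhaustive* policy enumerates all tuples.

Selection is forward and nested: each candidate's columns are appended to the
current design and the standard F statistic on the drop in residual sum of
squares (numerator df = columns added, denominator df = n − total columns −
1) is compared to the significance level α (default 0.01, configurable). A
candidate that fails is excluded; every test is logged with its F and p
value. Two numerical guards: a denominator df ≤ 0 is an error (more samples
or fewer terms needed), and once the current model reproduces y to a relative
residual below 10⁻¹², further F statistics would compare roundoff noise and
candidates are recorded as untested (p = 1) rather than spuriously included.

Optional Benjamini–Hochberg correction across candidates is available but OFF
by default. Because sequential forward testing has no single well-defined
batch, the corrected mode instead tests every candidate of an order against
the lower-order model, BH-adjusts that batch, and adds all survivors jointly.

All selected components are refit jointly in a final (optionally weighted)
least-squares pass on the centered output; coefficients from the selection
stage are discarded. Sample weights default to uniform. A rank-deficient
final design raises an error listing the collinear terms. Boolean outputs
(pairwise-comparison datasets) are fit as continuous 0/1 responses.

## Sensitivity decomposition

With population (1/n) moment conventions throughout, the total variance σ²_y
is decomposed over the fitted components. The variance of a sum contains all
pairwise covariances; when inputs are correlated the component functions are
not orthogonal, and the decomposition must allocate those covariance terms to
individual indices. We use

    Sₖ = cov(fₖ, y) / σ²_y,   S_resid = cov(ε, y) / σ²_y

— each component absorbs its full row of covariances, including with the
residual. This is the unique linear allocation that (a) sums to exactly 1
together with S_resid, by construction, and (b) reduces to var(fₖ)/σ²_y under
independent inputs. Negative indices are possible under correlation and are
reported as-is; the attribution rule is recorded in every report. Per-input
totals Tᵢ sum Sₖ over all components containing input i (a cooperative index
counts fully toward each participant, so Σᵢ Tᵢ can exceed Σₖ Sₖ); order
totals partition Σₖ Sₖ by component order.

## Network assembly

Each node in turn is the output of one mapping (N nodes → N mappings per
condition). Edge weight W[out, in] is the maximum of T_in over all
conditions' reports for that output — a connection need only be active in
*some* condition. Pairwise-comparison mappings contribute only the row of
their own output (the perturbed node). Edges are W ≥ τ with τ = 0.1 by
default. Because the appropriate τ is an empirical analysis choice, τ is a
required, logged parameter and an edge-count-versus-τ profile export supports
choosing it; max-normalized weights (matrix scaled to max 1) and a
symmetrized view (max of both directions) are available for comparison with
other methods. Weights follow the convention rows = outputs, columns =
inputs; the diagonal is undefined.

## FEOM prediction and inverse classification

Forward metrics: Pearson correlation R between predictions and observations,
plus the fraction of test points within relative-error tolerances (default
1%, 5%, 10%, 20%). The relative-error denominator is the observed value *on
the original measurement scale* (predictions are denormalized through the
stored transform); observed-zero rows are excluded from the fractions and
counted separately; constant observations make R undefined, which is flagged
rather than silently NaN-propagated.

Inverse classification: the model fitted on a pairwise-comparison dataset
scores each sample continuously; scores above the fixed threshold 0.5 are
class 1 (activated/high). Accuracy is the fraction correctly grouped. An ROC
export over all thresholds is provided as a diagnostic extra.

## Synthetic benchmarks

The generator draws exogenous inputs i.i.d. uniform on [0, 1] (or through a
Gaussian copula with a given correlation matrix), builds chain intermediates
as linear functions of their sources plus Gaussian noise, and evaluates
outputs as weighted products of orthonormal shifted-Legendre polynomials
L_d(u) = √(2d+1)·P_d(2u−1) plus Gaussian measurement noise on the output
only. In this system every truth term has zero mean and unit variance under
uniform sampling and all distinct terms are orthogonal, so true sensitivity
indices are available in closed form: S = w²/(Σ w² + σ²_noise). The closed
form is refused (with an error directing to the empirical estimator) for
correlated inputs and for outputs driven by chain intermediates, whose
marginals are not uniform.

Preset scenarios, with coefficients chosen once at unit scale and output
noise at 10% of the signal standard deviation unless stated:

- **additive** — three active first-order inputs with weights 1.0, 0.8, 0.6
  (the third purely quadratic), two silent decoys. True variance shares 0.50
  / 0.32 / 0.18, all comfortably above the τ = 0.1 edge threshold.
- **cooperative** — first-order weights 1.0 and 0.7 plus a product term with
  weight 0.6 between the same two inputs.
- **indirect-chain** — mid = 0.25 + 0.5·src + N(0, 0.15²); y depends only on
  mid (weight 0.8, output noise 0.05). src and mid correlate at ≈ 0.69, so a
  marginal method would link src to y; conditional on mid, src carries no
  information and model reduction plus the covariance-based indices drive
  T(src→y) to ≈ 0.
- **indirect-chain-direct** — same, plus a true direct src term (weight
  0.35), whose total sensitivity ≈ 0.36 must re-emerge above τ.
- **perturbation-pair** — perturbing tgt shifts it by +1.5, moving the
  readout y by ≈ 5 within-condition standard deviations: cleanly separable
  classes for the inverse FEOM.
- **perturbation-pair-null** — the perturbed node is statistically
  disconnected from every measured node; classification must stay at chance.

What the generator does *not* emulate: heavy-tailed and zero-inflated
cytometry marginals, feedback loops, unmeasured confounders, time dependence,
and instrument compensation artifacts. Passing benchmarks therefore
demonstrates correctness of the estimator under its own assumptions
(scattered continuous samples, dependencies within the truncated model
class), not performance on any particular laboratory dataset.

## Problem sizes and numerical choices

The shipped checks use n between 200 and 5000 samples, 2–6 inputs, 200
replicates for type-I calibration, and 10–20 seeds for the stochastic
protocols — sizes at which every quantity is stable to well within its
asserted tolerance while the whole suite runs in seconds. Degenerate inputs
are rejected early with the offending node named: constant columns (no basis
support), duplicate node names, missing values, n < 2, zero-variance outputs
(no variance to decompose). Ties in candidate testing order are broken
lexicographically by variable name; the tensor-product term enumeration is
row-major over degree indices and is part of the serialized model contract.

## Known limitations

- Without time-series data the method cannot resolve feedback or strict
  causal direction; the two directed edges of a pair are fit independently.
- The F-test's nominal α is per candidate within a sequential procedure;
  family-wise error is not controlled unless the BH option is enabled.
- The covariance attribution rule, while exact in aggregate, can assign
  individually negative indices under strong input correlation; totals Tᵢ
  should then be read jointly rather than term by term.
- Relative-error metrics are undefined at observed zero and sensitive to
  near-zero observations; such rows are excluded and counted, not imputed.
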