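"""Ground-truth synthetic benchmarks with the statistical structure the method
assumes: continuous node levels sampled per cell, known polynomial component
functions, cooperative (product) effects, indirect chains through measured
intermediates, Gaussian output noise, and paired control/perturbed conditions.

Truth terms are expressed in the orthonormal shifted-Legendre system
L_d(u) = sqrt(2d+1) * P_d(2u - 1), which has zero mean and unit variance under
U(0, 1).  A term ((v1, ..), (d1, ..), w) contributes w * prod_j L_dj(u_vj) to
its output, so under independent uniform sampling every term is zero-mean,
unit-variance and orthogonal to every other term — making the true sensitivity
indices available in closed form as w^2 / (sum w^2 + noise_sd^2).

Indirect chains generate an intermediate node from its source plus noise, with
the source given zero direct weight on the output: the source then influences
the output only through the measured intermediate, the situation model
reduction is designed to suppress.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_io import DataTable

__all__ = [
    "TruthTerm",
    "ChainLink",
    "SyntheticSpec",
    "PRESETS",
    "make_benchmark_spec",
    "sample_synthetic",
    "analytic_sensitivities",
    "legendre_orthonormal",
]


def legendre_orthonormal(degree: int, u: np.ndarray) -> np.ndarray:
    """Orthonormal shifted Legendre polynomial L_d on [0, 1]."""
    return np.sqrt(2 * degree + 1) * special.eval_sh_legendre(degree, np.asarray(u, float))


@dataclass(frozen=True)
class TruthTerm:
    """One true component function: weight * prod_j L_{degree_j}(u_{var_j})."""

    variables: tuple[str, ...]
    degrees: tuple[int, ...]
    weight: float

    @property
    def order(self) -> int:
        return len(self.variables)

    def evaluate(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        out = None
        for v, d in zip(self.variables, self.degrees):
            f = legendre_orthonormal(d, cols[v])
            out = f if out is None else out * f
        return self.weight * out


@dataclass(frozen=True)
class ChainLink:
    """intermediate = intercept + slope * source + N(0, noise_sd^2)."""

    source: str
    intermediate: str
    output: str
    intercept: float = 0.25
    slope: float = 0.5
    noise_sd: float = 0.15


@dataclass
class SyntheticSpec:
    """Fully parameterized generative model for one benchmark scenario."""

    name: str
    node_names: list[str]
    truth: dict[str, list[TruthTerm]]  # output node -> terms
    f0: dict[str, float]
    input_distribution: str = "independent-uniform"
    correlation: np.ndarray | None = None  # Gaussian-copula correlation (inputs)
    noise_sd: float = 0.0
    chain_specs: list[ChainLink] = field(default_factory=list)
    perturbations: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_distribution not in ("independent-uniform", "gaussian-copula"):
            raise ValueError(f"unknown input distribution {self.input_distribution!r}")
        if self.input_distribution == "gaussian-copula":
            if self.correlation is None:
                raise ValueError("gaussian-copula distribution needs a correlation matrix")
            R = np.asarray(self.correlation, dtype=float)
            if R.shape[0] != R.shape[1] or not np.allclose(R, R.T):
                raise ValueError("correlation matrix must be square symmetric")
            if np.min(np.linalg.eigvalsh(R)) < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for link in self.chain_specs:
            for term in self.truth.get(link.output, []):
                if link.source in term.variables:
                    raise ValueError(
                        f"chain source {link.source!r} must have zero direct weight "
                        f"on output {link.output!r}"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def outputs(self) -> list[str]:
        return list(self.truth.keys())

    @property
    def exogenous_inputs(self) -> list[str]:
        derived = set(self.truth) | {c.intermediate for c in self.chain_specs}
        return [v for v in self.node_names if v not in derived]

    def to_json(self, path=None) -> str:
        doc = {
            "name": self.name,
            "node_names": self.node_names,
            "truth": {
                o: [
                    {"variables": list(t.variables), "degrees": list(t.degrees), "weight": t.weight}
                    for t in terms
                ]
                for o, terms in self.truth.items()
            },
            "f0": self.f0,
            "input_distribution": self.input_distribution,
            "correlation": None if self.correlation is None else np.asarray(self.correlation).tolist(),
            "noise_sd": self.noise_sd,
            "chain_specs": [asdict(c) for c in self.chain_specs],
            "perturbations": [list(p) for p in self.perturbations],
            "seed": self.seed,
        }
        s = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


# ---------------------------------------------------------------------------
# Presets
#
# Coefficients are unit-scale weights in the orthonormal Legendre system, with
# output noise at 10% of the signal standard deviation unless stated.  Each
# preset realizes one qualitative regime the method must handle.


def _signal_sd(terms: list[TruthTerm]) -> float:
    return float(np.sqrt(sum(t.weight**2 for t in terms)))


def _preset_additive(seed: int) -> SyntheticSpec:
    # three active inputs (one purely quadratic), two silent decoys
    terms = [
        TruthTerm(("x1",), (1,), 1.0),
        TruthTerm(("x2",), (1,), 0.8),
        TruthTerm(("x3",), (2,), 0.6),
    ]
    return SyntheticSpec(
        name="additive",
        node_names=["x1", "x2", "x3", "x4", "x5", "y"],
        truth={"y": terms},
        f0={"y": 0.5},
        noise_sd=0.1 * _signal_sd(terms),
        seed=seed,
    )


def _preset_cooperative(seed: int) -> SyntheticSpec:
    # a pairwise cooperative (product) effect on top of two first-order terms
    terms = [
        TruthTerm(("x1",), (1,), 1.0),
        TruthTerm(("x2",), (1,), 0.7),
        TruthTerm(("x1", "x2"), (1, 1), 0.6),
    ]
    return SyntheticSpec(
        name="cooperative",
        node_names=["x1", "x2", "x3", "x4", "y"],
        truth={"y": terms},
        f0={"y": 0.5},
        noise_sd=0.1 * _signal_sd(terms),
        seed=seed,
    )


def _preset_indirect_chain(seed: int, direct_link: bool = False) -> SyntheticSpec:
    # src -> mid -> y; src touches y only through the measured intermediate.
    # The direct-link variant adds a strong src -> y connection on top, in
    # which case the chain link no longer claims y as its constrained output.
    terms = [TruthTerm(("mid",), (1,), 0.8)]
    if direct_link:
        terms = terms + [TruthTerm(("src",), (1,), 0.35)]
    return SyntheticSpec(
        name="indirect-chain-direct" if direct_link else "indirect-chain",
        node_names=["src", "mid", "bgd", "y"],
        truth={"y": terms},
        f0={"y": 0.5},
        noise_sd=0.05,
        chain_specs=[
            ChainLink(
                "src",
                "mid",
                "" if direct_link else "y",
                intercept=0.25,
                slope=0.5,
                noise_sd=0.15,
            )
        ],
        seed=seed,
    )


def _preset_perturbation_pair(seed: int) -> SyntheticSpec:
    # perturbing tgt shifts it by 1.5, moving the downstream readout y by
    # about five within-condition standard deviations -> separable classes
    return SyntheticSpec(
        name="perturbation-pair",
        node_names=["tgt", "u1", "u2", "y"],
        truth={"y": [TruthTerm(("tgt",), (1,), 0.3)]},
        f0={"y": 0.5},
        noise_sd=0.05,
        perturbations=[("tgt", 1.5)],
        seed=seed,
    )


def _preset_perturbation_null(seed: int) -> SyntheticSpec:
    # the perturbed node iso is statistically disconnected from every measured
    # node, so its condition cannot be classified above chance
    return SyntheticSpec(
        name="perturbation-pair-null",
        node_names=["iso", "u1", "u2", "y"],
        truth={"y": [TruthTerm(("u1",), (1,), 0.3)]},
        f0={"y": 0.5},
        noise_sd=0.05,
        perturbations=[("iso", 1.5)],
        seed=seed,
    )


PRESETS = {
    "additive": _preset_additive,
    "cooperative": _preset_cooperative,
    "indirect-chain": _preset_indirect_chain,
    "indirect-chain-direct": lambda seed: _preset_indirect_chain(seed, direct_link=True),
    "perturbation-pair": _preset_perturbation_pair,
    "perturbation-pair-null": _preset_perturbation_null,
}


def make_benchmark_spec(preset: str, seed: int = 0) -> SyntheticSpec:
    """Fully parameterized spec for a named benchmark scenario."""
    try:
        factory = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}") from None
    return factory(seed)


# ---------------------------------------------------------------------------
# Sampling


def _sample_inputs(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    names = spec.exogenous_inputs
    if spec.input_distribution == "independent-uniform":
        return {v: rng.uniform(0.0, 1.0, size=n) for v in names}
    R = np.asarray(spec.correlation, dtype=float)
    if R.shape[0] != len(names):
        raise ValueError(
            f"correlation matrix is {R.shape[0]}x{R.shape[0]} but there are "
            f"{len(names)} exogenous inputs"
        )
    z = rng.multivariate_normal(np.zeros(len(names)), R, size=n, method="eigh")
    u = stats.norm.cdf(z)
    return {v: u[:, j] for j, v in enumerate(names)}


def _realize(
    spec: SyntheticSpec,
    n: int,
    rng: np.random.Generator,
    shift: tuple[str, float] | None,
    condition_id: str,
) -> DataTable:
    cols = _sample_inputs(spec, n, rng)
    if shift is not None:
        node, delta = shift
        if node not in cols:
            raise ValueError(f"perturbation target {node!r} is not an exogenous input")
        cols[node] = cols[node] + delta
    for link in spec.chain_specs:
        cols[link.intermediate] = (
            link.intercept
            + link.slope * cols[link.source]
            + rng.normal(0.0, link.noise_sd, size=n)
        )
    for out, terms in spec.truth.items():
        y = np.full(n, spec.f0.get(out, 0.0))
        for t in terms:
            y = y + t.evaluate(cols)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=n)
        cols[out] = y
    df = pd.DataFrame({v: cols[v] for v in spec.node_names})
    return DataTable(values=df, condition_id=condition_id)


def sample_synthetic(spec: SyntheticSpec, n: int, seed: int | None = None):
    """Draw n samples from the generative model; reproducible under seed.

    Returns a control :class:`DataTable`; when the spec defines perturbations,
    returns ``(control, {"<node>+<shift>": perturbed_table, ...})`` with each
    perturbed condition regenerated from its own shifted inputs.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    control = _realize(spec, n, rng, None, f"{spec.name}:control")
    if not spec.perturbations:
        return control
    perturbed = {}
    for node, delta in spec.perturbations:
        label = f"{node}{delta:+g}"
        perturbed[label] = _realize(spec, n, rng, (node, delta), f"{spec.name}:{label}")
    return control, perturbed


# ---------------------------------------------------------------------------
# Analytic oracle


def analytic_sensitivities(spec: SyntheticSpec, output: str | None = None):
    """Exact sensitivity indices under independent uniform sampling.

    Each Legendre truth term has unit variance and zero covariance with every
    other, so S_term = w^2 / (sum_k w_k^2 + noise_sd^2) and the residual index
    is the noise share.  Unsupported for correlated inputs and for outputs
    driven by chain intermediates (whose marginals are not uniform) — use the
    empirical estimator there.
    """
    if spec.input_distribution != "independent-uniform":
        raise ValueError(
            "analytic indices are closed-form only for independent-uniform inputs"
        )
    if output is None:
        if len(spec.truth) != 1:
            raise ValueError(f"spec has outputs {spec.outputs}; name one")
        output = spec.outputs[0]
    terms = spec.truth[output]
    intermediates = {c.intermediate for c in spec.chain_specs}
    for t in terms:
        if set(t.variables) & intermediates:
            raise ValueError(
                "output depends on chain intermediates; no closed form available"
            )
    total = sum(t.weight**2 for t in terms) + spec.noise_sd**2
    S = {
        (t.order, t.variables): t.weight**2 / total for t in terms
    }
    T: dict[str, float] = {}
    for (_o, variables), s in S.items():
        for v in variables:
            T[v] = T.get(v, 0.0) + s
    return {
        "output_id": output,
        "S": S,
        "T": T,
        "S_resid": spec.noise_sd**2 / total,
        "total_variance": total,
    }
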