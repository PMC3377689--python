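"""Data-adaptive orthonormal polynomial bases.

For each input variable a family of polynomials phi_1 .. phi_k is built by
Gram-Schmidt orthonormalization of the monomials {x, x^2, ...} against the
constant, under the empirical inner product <f, g> = (1/n) sum_t f(x_t) g(x_t)
(Monte-Carlo integration over the sample measure).  On the training sample
every phi_r then has mean zero, unit mean square, and zero cross-products —
which is what lets component-function coefficients be estimated from scattered
random samples with low effort.

Second- and third-order component functions use pure tensor products of the
univariate bases: products of zero-mean orthonormal factors, without
re-orthogonalization against lower orders.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BasisSet",
    "build_orthonormal_basis",
    "evaluate_basis",
    "term_labels",
    "evaluate_terms",
]

# Rank-deficiency tolerance: a monomial whose norm drops below this fraction of
# its original norm during orthogonalization is linearly dependent on lower
# degrees over the sample support.
_RANK_TOL = 1e-10


@dataclass(frozen=True)
class BasisSet:
    """Orthonormal polynomial basis for one input variable.

    ``coeffs`` is lower-triangular: row r (0-based r-1) holds the monomial
    coefficients a_r^(0..r) of phi_r(x) = sum_j a_r^(j) x^j, padded with zeros.
    """

    variable_id: str
    degree: int
    coeffs: np.ndarray  # shape (degree, degree + 1)
    training_n: int

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate phi_1 .. phi_k at ``x``; returns shape (len(x), degree)."""
        return evaluate_basis(self.coeffs, x)

    def to_dict(self) -> dict:
        return {
            "variable_id": self.variable_id,
            "degree": self.degree,
            "coeffs": self.coeffs.tolist(),
            "training_n": self.training_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSet":
        return cls(
            variable_id=d["variable_id"],
            degree=int(d["degree"]),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            training_n=int(d["training_n"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def evaluate_basis(coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate the polynomials given by monomial coefficient rows at ``x``."""
    x = np.asarray(x, dtype=float)
    degree = coeffs.shape[0]
    # Vandermonde with powers 0..degree
    V = np.vander(x, N=degree + 1, increasing=True)
    return V @ coeffs.T


def build_orthonormal_basis(
    samples: np.ndarray, degree: int, variable_id: str = ""
) -> BasisSet:
    """Orthonormalize monomials x, x^2, ..., x^degree over the sample measure.

    Modified Gram-Schmidt with one re-orthogonalization pass for numerical
    stability.  The leading coefficient of each phi_r is made positive (sign
    convention).  Raises on zero-variance samples and when ``degree`` exceeds
    the number of distinct sample values minus one (the Vandermonde columns
    become linearly dependent).
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise ValueError(
            f"variable {variable_id!r}: samples have zero variance; cannot build a basis"
        )
    if n_distinct < degree + 1:
        raise ValueError(
            f"variable {variable_id!r}: degree {degree} needs at least {degree + 1} "
            f"distinct sample values, found {n_distinct}"
        )

    # Columns: monomial values x^1..x^degree evaluated on the sample; the
    # constant is the (implicit) zeroth basis member with coefficient row e_0.
    V = np.vander(x, N=degree + 1, increasing=True)
    # coefficient rows in the monomial basis, updated alongside the vectors
    C = np.eye(degree + 1)
    Q = V.copy().astype(float)

    def _ip(a: np.ndarray, b: np.ndarray) -> float:
        return float(a @ b) / n

    orig_norms = np.sqrt(np.array([_ip(V[:, j], V[:, j]) for j in range(degree + 1)]))
    for j in range(degree + 1):
        for _ in range(2):  # MGS + re-orthogonalization pass
            for i in range(j):
                r = _ip(Q[:, i], Q[:, j])
                Q[:, j] -= r * Q[:, i]
                C[j] -= r * C[i]
        nrm = np.sqrt(_ip(Q[:, j], Q[:, j]))
        if nrm < _RANK_TOL * max(orig_norms[j], 1.0):
            raise ValueError(
                f"variable {variable_id!r}: monomial degree {j} is numerically "
                "dependent on lower degrees over the sample support"
            )
        Q[:, j] /= nrm
        C[j] /= nrm
        if C[j, j] < 0:  # positive leading coefficient
            Q[:, j] *= -1.0
            C[j] *= -1.0

    return BasisSet(
        variable_id=variable_id,
        degree=degree,
        coeffs=C[1:],  # drop the constant; rows are phi_1..phi_k
        training_n=n,
    )


# ---------------------------------------------------------------------------
# Tensor-product term evaluation
#
# A term spec is (order, variables, degrees):
#   order 1: variables = (i,),      degrees = (k,)   -> phi_1(x_i)..phi_k(x_i)
#   order 2: variables = (i, j),    degrees = (l, l')
#            -> phi_p(x_i) * phi_q(x_j) for p = 1..l, q = 1..l'
#   order 3: triple products analogously.
# Enumeration is row-major over the degree indices (p outermost), matching
# itertools.product — this ordering is part of the model contract.


def term_labels(
    variables: tuple[str, ...], degrees: tuple[int, ...]
) -> list[tuple[tuple[str, int], ...]]:
    """Deterministic enumeration of ((variable, degree index), ...) per term."""
    ranges = [range(1, d + 1) for d in degrees]
    return [
        tuple(zip(variables, combo)) for combo in itertools.product(*ranges)
    ]


def evaluate_terms(
    bases: dict[str, BasisSet],
    term_spec: tuple[int, tuple[str, ...], tuple[int, ...]],
    x: dict[str, np.ndarray] | "object",
) -> np.ndarray:
    """Evaluate all basis-product values of one term spec, vectorized over rows.

    ``x`` maps variable name -> value array (a DataFrame works too).  Returns
    shape (n_rows, n_terms) where n_terms = prod(degrees).
    """
    order, variables, degrees = term_spec
    if order not in (1, 2, 3):
        raise ValueError(f"order must be in {{1, 2, 3}}, got {order}")
    if len(variables) != order or len(degrees) != order:
        raise ValueError(
            f"term spec mismatch: order {order} with variables {variables} "
            f"and degrees {degrees}"
        )
    for v in variables:
        if v not in bases:
            raise KeyError(f"no basis for variable {v!r}")

    phis = []
    for v, d in zip(variables, degrees):
        b = bases[v]
        if d > b.degree:
            raise ValueError(
                f"variable {v!r}: requested degree {d} exceeds basis degree {b.degree}"
            )
        phis.append(b.evaluate(np.asarray(x[v], dtype=float))[:, :d])

    if order == 1:
        return phis[0]
    n = phis[0].shape[0]
    if order == 2:
        out = phis[0][:, :, None] * phis[1][:, None, :]
        return out.reshape(n, -1)
    out = (
        phis[0][:, :, None, None]
        * phis[1][:, None, :, None]
        * phis[2][:, None, None, :]
    )
    return out.reshape(n, -1)
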