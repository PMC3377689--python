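"""HDMR expansion fitting: candidate enumeration, F-test model reduction, and
joint least-squares estimation of component-function weights.

The fitted object represents one output node y as

    y  =  f0  +  sum_i f_i(x_i)  +  sum_{i<j} f_ij(x_i, x_j)  +  ...  +  eps

where f0 is the output mean over the sample space and each component function
is a weighted combination of orthonormal basis products.  Over-fitting on
noisy, correlated data is controlled by *model reduction*: a candidate
component enters the expansion only if the F statistic on its reduction in
residual sum of squares is significant, which is what suppresses connections
that proceed indirectly through measured intermediate nodes.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .basis import BasisSet, build_orthonormal_basis, evaluate_terms, term_labels
from .data_io import DataTable, apply_transform, denormalize_column

logger = logging.getLogger("hdmrnet")

__all__ = [
    "FitConfig",
    "ComponentFunction",
    "SelectionRecord",
    "HDMRModel",
    "enumerate_candidates",
    "f_test_select",
    "fit_least_squares",
    "fit_hdmr",
    "predict",
]

MODEL_FORMAT_VERSION = 1

# Relative residual floor below which the fit is numerically exact and further
# F statistics are meaningless (both RSS values are roundoff noise).
_EXACT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of one HDMR fit.

    degree_first/second/third are the per-factor polynomial degrees (k, l, m)
    of first-, second-, and third-order component functions; alpha is the
    F-test significance level for model reduction; ``policy`` restricts
    higher-order candidates to variables already significant at first order
    (``hierarchical``) or enumerates all tuples (``exhaustive``).
    """

    degree_first: int = 3
    degree_second: int = 2
    degree_third: int = 1
    alpha: float = 0.01
    max_order: int = 2
    policy: str = "hierarchical"
    bh_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_order not in (1, 2, 3):
            raise ValueError(f"max_order must be in {{1, 2, 3}}, got {self.max_order}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.policy not in ("hierarchical", "exhaustive"):
            raise ValueError(f"unknown candidate policy {self.policy!r}")

    def degrees_for(self, order: int) -> tuple[int, ...]:
        d = {1: self.degree_first, 2: self.degree_second, 3: self.degree_third}[order]
        return (d,) * order


@dataclass
class ComponentFunction:
    """One fitted term of the expansion: f_i, f_ij or f_ijk.

    ``weights`` follows the deterministic tensor-product enumeration of
    :func:`hdmrnet.basis.evaluate_terms`; ``term_means`` holds the training
    means subtracted from each basis-product column so the component function
    has exactly zero mean over the training sample.
    """

    order: int
    variable_ids: tuple[str, ...]
    degrees: tuple[int, ...]
    weights: np.ndarray
    term_means: np.ndarray

    def __post_init__(self) -> None:
        expected = int(np.prod(self.degrees))
        if len(self.weights) != expected or len(self.term_means) != expected:
            raise ValueError(
                f"component {self.variable_ids}: weight vector length "
                f"{len(self.weights)} does not match term enumeration ({expected})"
            )

    def evaluate(self, bases: dict[str, BasisSet], x) -> np.ndarray:
        T = evaluate_terms(bases, (self.order, self.variable_ids, self.degrees), x)
        return (T - self.term_means) @ self.weights

    def labels(self) -> list:
        return term_labels(self.variable_ids, self.degrees)


@dataclass(frozen=True)
class SelectionRecord:
    candidate: tuple[int, tuple[str, ...]]
    F_statistic: float
    p_value: float
    included: bool


@dataclass
class HDMRModel:
    """Fitted HDMR expansion for one output node (a FEOM).

    Stores the frozen normalization transforms of every node so that raw-scale
    points can be mapped into model space and predictions mapped back.
    """

    output_id: str
    f0: float
    components: list[ComponentFunction]
    bases: dict[str, BasisSet]
    selection_log: list[SelectionRecord]
    residual_variance: float
    transforms: dict[str, tuple[float, float]]
    fit_meta: dict = field(default_factory=dict)

    @property
    def input_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.components:
            for v in c.variable_ids:
                if v not in seen:
                    seen.append(v)
        return seen

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "output_id": self.output_id,
            "f0": self.f0,
            "residual_variance": self.residual_variance,
            "transforms": {k: list(v) for k, v in self.transforms.items()},
            "bases": {k: b.to_dict() for k, b in self.bases.items()},
            "components": [
                {
                    "order": c.order,
                    "variable_ids": list(c.variable_ids),
                    "degrees": list(c.degrees),
                    "weights": c.weights.tolist(),
                    "term_means": c.term_means.tolist(),
                }
                for c in self.components
            ],
            "selection_log": [
                {
                    "order": r.candidate[0],
                    "variables": list(r.candidate[1]),
                    "F": r.F_statistic,
                    "p": r.p_value,
                    "included": r.included,
                }
                for r in self.selection_log
            ],
            "fit_meta": self.fit_meta,
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "HDMRModel":
        return cls(
            output_id=d["output_id"],
            f0=float(d["f0"]),
            components=[
                ComponentFunction(
                    order=int(c["order"]),
                    variable_ids=tuple(c["variable_ids"]),
                    degrees=tuple(int(x) for x in c["degrees"]),
                    weights=np.asarray(c["weights"], dtype=float),
                    term_means=np.asarray(c["term_means"], dtype=float),
                )
                for c in d["components"]
            ],
            bases={k: BasisSet.from_dict(b) for k, b in d["bases"].items()},
            selection_log=[
                SelectionRecord(
                    candidate=(int(r["order"]), tuple(r["variables"])),
                    F_statistic=float(r["F"]),
                    p_value=float(r["p"]),
                    included=bool(r["included"]),
                )
                for r in d["selection_log"]
            ],
            residual_variance=float(d["residual_variance"]),
            transforms={k: tuple(v) for k, v in d["transforms"].items()},
            fit_meta=d.get("fit_meta", {}),
        )

    @classmethod
    def from_json(cls, source) -> "HDMRModel":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        try:
            return cls.from_dict(json.loads(source))
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_candidates(
    inputs: list[str],
    max_order: int,
    policy: str = "hierarchical",
    selected_first_order: list[str] | None = None,
) -> list[tuple[int, tuple[str, ...]]]:
    """All candidate component functions up to ``max_order``, lexicographic.

    Under the hierarchical policy, second/third-order candidates are drawn
    only from variables already selected at first order (cooperative effects
    are expected between nodes that matter individually); the exhaustive
    policy enumerates every tuple.
    """
    if max_order not in (1, 2, 3):
        raise ValueError(f"max_order must be in {{1, 2, 3}}, got {max_order}")
    inputs = sorted(inputs)
    out: list[tuple[int, tuple[str, ...]]] = [(1, (v,)) for v in inputs]
    pool = inputs if policy == "exhaustive" else sorted(selected_first_order or [])
    for order in (2, 3):
        if max_order >= order:
            out.extend((order, combo) for combo in itertools.combinations(pool, order))
    return out


# ---------------------------------------------------------------------------
# F-test forward selection


def _cand_degrees(
    candidate: tuple[int, tuple[str, ...]],
    bases: dict[str, BasisSet],
    config: FitConfig,
) -> tuple[int, ...]:
    """Per-factor degrees: the configured order degree, capped at what each
    variable's basis actually provides."""
    order, variables = candidate
    want = config.degrees_for(order)
    return tuple(min(d, bases[v].degree) for v, d in zip(variables, want))


def _candidate_columns(
    table_values: pd.DataFrame,
    candidate: tuple[int, tuple[str, ...]],
    bases: dict[str, BasisSet],
    config: FitConfig,
) -> np.ndarray:
    order, variables = candidate
    degrees = _cand_degrees(candidate, bases, config)
    return evaluate_terms(bases, (order, variables, degrees), table_values)


def _rss(X: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    if w is not None:
        sw = np.sqrt(w)
        X, y = X * sw[:, None], y * sw
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def f_test_select(
    table: DataTable,
    output_id: str,
    candidates: list[tuple[int, tuple[str, ...]]],
    alpha: float,
    bases: dict[str, BasisSet],
    config: FitConfig | None = None,
    sample_weights: np.ndarray | None = None,
) -> tuple[list[tuple[int, tuple[str, ...]]], list[SelectionRecord]]:
    """Forward, order-by-order nested-model F-test selection.

    Each candidate's basis columns are appended to the current model; the
    standard F statistic on the reduction in residual sum of squares
    (numerator df = number of added columns, denominator df = n - total
    columns - 1) decides inclusion at level ``alpha``.  Candidates are visited
    in lexicographic order within each order.  Every test is logged.
    """
    if config is None:
        config = FitConfig(alpha=alpha)
    if output_id not in table.node_names:
        raise KeyError(f"output {output_id!r} not in table")
    y = table.values[output_id].to_numpy(dtype=float)
    n = y.size
    X = np.ones((n, 1))
    y_scale = max(float(np.var(y)) * n, np.finfo(float).tiny)
    rss_current = _rss(X, y, sample_weights)

    selected: list[tuple[int, tuple[str, ...]]] = []
    log: list[SelectionRecord] = []

    by_order: dict[int, list] = {1: [], 2: [], 3: []}
    for cand in candidates:
        by_order[cand[0]].append(cand)

    def _test_against(
        cand, X_base: np.ndarray, rss_base: float
    ) -> tuple[float, float, np.ndarray]:
        T = _candidate_columns(table.values, cand, bases, config)
        q = T.shape[1]
        X_full = np.hstack([X_base, T])
        dfd = n - (X_full.shape[1] - 1) - 1
        if dfd <= 0:
            raise ValueError(
                f"denominator df = {dfd} testing {cand}: use fewer terms or more samples"
            )
        rss_full = _rss(X_full, y, sample_weights)
        if rss_base / y_scale < _EXACT_FIT_RTOL:
            # model already reproduces y to machine precision; the F statistic
            # would compare two roundoff-level residuals
            return float("nan"), 1.0, T
        F = ((rss_base - rss_full) / q) / (rss_full / dfd) if rss_full > 0 else np.inf
        F = max(F, 0.0)
        p = float(stats.f.sf(F, q, dfd)) if np.isfinite(F) else 0.0
        return float(F), p, T

    for order in (1, 2, 3):
        order_cands = sorted(by_order[order], key=lambda c: c[1])
        if not order_cands:
            continue
        if config.bh_correction:
            # batch mode: test every candidate of this order against the model
            # of lower orders, BH-adjust, then add all survivors jointly
            results = []
            for cand in order_cands:
                F, p, T = _test_against(cand, X, rss_current)
                results.append((cand, F, p, T))
            m = len(results)
            order_idx = np.argsort([r[2] for r in results])
            passed = np.zeros(m, dtype=bool)
            k_max = 0
            for rank, idx in enumerate(order_idx, start=1):
                if results[idx][2] <= rank * alpha / m:
                    k_max = rank
            for rank, idx in enumerate(order_idx, start=1):
                passed[idx] = rank <= k_max
            for (cand, F, p, T), ok in zip(results, passed):
                log.append(SelectionRecord(cand, F, p, bool(ok)))
                if ok:
                    selected.append(cand)
                    X = np.hstack([X, T])
            rss_current = _rss(X, y, sample_weights)
        else:
            for cand in order_cands:
                F, p, T = _test_against(cand, X, rss_current)
                include = p < alpha
                log.append(SelectionRecord(cand, F, p, include))
                if include:
                    selected.append(cand)
                    X = np.hstack([X, T])
                    rss_current = _rss(X, y, sample_weights)
    return selected, log


# ---------------------------------------------------------------------------
# Least squares


def fit_least_squares(
    table: DataTable,
    output_id: str,
    selected: list[tuple[int, tuple[str, ...]]],
    bases: dict[str, BasisSet],
    sample_weights: np.ndarray | None = None,
    config: FitConfig | None = None,
    selection_log: list[SelectionRecord] | None = None,
) -> HDMRModel:
    """Jointly refit all selected component functions by (weighted) least squares.

    f0 is the (weighted) output mean; every basis-product column is centered
    on its training mean so each fitted component function has exactly zero
    mean over the training sample, and the weights solve the least-squares
    problem on the centered output.
    """
    if config is None:
        config = FitConfig()
    y = table.values[output_id].to_numpy(dtype=float)
    n = y.size
    if sample_weights is not None:
        w = np.asarray(sample_weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("sample_weights must be non-negative, not all zero, length n")
        w = w / w.sum()
    else:
        w = np.full(n, 1.0 / n)

    f0 = float(w @ y)
    yc = y - f0

    blocks, spans = [], []
    for cand in selected:
        T = _candidate_columns(table.values, cand, bases, config)
        mu = w @ T
        blocks.append((cand, T - mu, mu))
        spans.append(T.shape[1])

    if not blocks:
        resid_var = float(w @ yc**2)
        return HDMRModel(
            output_id=output_id,
            f0=f0,
            components=[],
            bases=dict(bases),
            selection_log=list(selection_log or []),
            residual_variance=resid_var,
            transforms=dict(table.transforms),
            fit_meta=_meta(n, config, output_id),
        )

    X = np.hstack([b[1] for b in blocks])
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], yc * sw
    beta, _, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        _raise_collinear(Xw, blocks, spans)

    components: list[ComponentFunction] = []
    pos = 0
    for (cand, _Tc, mu), width in zip(blocks, spans):
        order, variables = cand
        components.append(
            ComponentFunction(
                order=order,
                variable_ids=variables,
                degrees=_cand_degrees(cand, bases, config),
                weights=beta[pos : pos + width].copy(),
                term_means=np.asarray(mu, dtype=float),
            )
        )
        pos += width

    resid = yc - X @ beta
    resid_var = float(w @ resid**2)
    return HDMRModel(
        output_id=output_id,
        f0=f0,
        components=components,
        bases=dict(bases),
        selection_log=list(selection_log or []),
        residual_variance=resid_var,
        transforms=dict(table.transforms),
        fit_meta=_meta(n, config, output_id),
    )


def _meta(n: int, config: FitConfig, output_id: str) -> dict:
    return {
        "n": n,
        "output_id": output_id,
        "alpha": config.alpha,
        "max_order": config.max_order,
        "policy": config.policy,
        "degrees": [config.degree_first, config.degree_second, config.degree_third],
        "seed": config.seed,
    }


def _raise_collinear(Xw, blocks, spans) -> None:
    _, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps
    bad_cols = sorted(piv[diag < tol].tolist()) if np.any(diag < tol) else []
    col_owner = []
    for (cand, _T, _mu), width in zip(blocks, spans):
        col_owner.extend([cand] * width)
    offenders = sorted({str(col_owner[c]) for c in bad_cols}) or ["<undetermined>"]
    raise ValueError(f"rank-deficient design; collinear terms involve: {offenders}")


# ---------------------------------------------------------------------------
# Orchestration


def fit_hdmr(
    table: DataTable,
    output_id: str,
    config: FitConfig | None = None,
    sample_weights: np.ndarray | None = None,
) -> HDMRModel:
    """Fit one full HDMR expansion: bases -> candidates -> F-test -> refit.

    The table must be normalized; all non-output nodes serve as inputs.  With
    the hierarchical policy, second/third-order candidates are enumerated from
    the variables selected at first order.  Deterministic given (table,
    config).
    """
    if config is None:
        config = FitConfig()
    if not table.normalized:
        raise ValueError("table must be normalized to [0, 1] before fitting")
    if output_id not in table.node_names:
        raise KeyError(f"output {output_id!r} not in table")
    inputs = [c for c in table.node_names if c != output_id]

    bases = {
        v: build_orthonormal_basis(
            table.values[v].to_numpy(dtype=float), config.degree_first, variable_id=v
        )
        for v in inputs
    }

    # order 1
    cands1 = enumerate_candidates(inputs, 1)
    sel1, log1 = f_test_select(
        table, output_id, cands1, config.alpha, bases, config, sample_weights
    )
    selected, log = list(sel1), list(log1)

    if config.max_order >= 2:
        first_vars = sorted({v for _o, vs in sel1 for v in vs})
        higher = [
            c
            for c in enumerate_candidates(
                inputs, config.max_order, config.policy, first_vars
            )
            if c[0] >= 2
        ]
        if higher:
            sel_h, log_h = _select_higher(
                table, output_id, higher, bases, config, sample_weights, sel1
            )
            selected += sel_h
            log += log_h

    model = fit_least_squares(
        table, output_id, selected, bases, sample_weights, config, log
    )
    logger.info(
        "fit %s: %d/%d candidates selected, residual variance %.4g",
        output_id,
        len(selected),
        len(log),
        model.residual_variance,
    )
    return model


def _select_higher(table, output_id, higher, bases, config, sample_weights, sel1):
    """Continue forward selection at orders 2-3 on top of the order-1 model."""
    y = table.values[output_id].to_numpy(dtype=float)
    n = y.size
    X = np.ones((n, 1))
    for cand in sel1:
        X = np.hstack([X, _candidate_columns(table.values, cand, bases, config)])
    base_rss = _rss(X, y, sample_weights)

    # reuse f_test_select's logic by faking the current state: simplest is to
    # re-run selection with the order-1 columns pre-loaded
    sel_h, log_h = [], []
    y_scale = max(float(np.var(y)) * n, np.finfo(float).tiny)
    by_order = {2: [], 3: []}
    for c in higher:
        by_order[c[0]].append(c)
    rss_current = base_rss
    for order in (2, 3):
        for cand in sorted(by_order[order], key=lambda c: c[1]):
            T = _candidate_columns(table.values, cand, bases, config)
            q = T.shape[1]
            X_full = np.hstack([X, T])
            dfd = n - (X_full.shape[1] - 1) - 1
            if dfd <= 0:
                raise ValueError(
                    f"denominator df = {dfd} testing {cand}: use fewer terms or more samples"
                )
            rss_full = _rss(X_full, y, sample_weights)
            if rss_current / y_scale < _EXACT_FIT_RTOL:
                log_h.append(SelectionRecord(cand, float("nan"), 1.0, False))
                continue
            F = (
                ((rss_current - rss_full) / q) / (rss_full / dfd)
                if rss_full > 0
                else np.inf
            )
            F = max(F, 0.0)
            p = float(stats.f.sf(F, q, dfd)) if np.isfinite(F) else 0.0
            include = p < config.alpha
            log_h.append(SelectionRecord(cand, float(F), p, include))
            if include:
                sel_h.append(cand)
                X = X_full
                rss_current = rss_full
    return sel_h, log_h


# ---------------------------------------------------------------------------
# Prediction


def predict(
    model: HDMRModel,
    inputs,
    denormalize: bool = False,
) -> np.ndarray:
    """Evaluate the FEOM: f0 + sum of component functions, vectorized over rows.

    ``inputs`` may be a DataTable, DataFrame, or mapping of node -> values.  A
    DataTable flagged normalized is used as-is; anything else is mapped
    through the model's stored normalization transforms (clamped to [0, 1]
    with a warning when outside the training range).  ``denormalize`` returns
    predictions on the original measurement scale of the output node.
    """
    if isinstance(inputs, DataTable):
        df = inputs.values
        already = inputs.normalized
    elif isinstance(inputs, pd.DataFrame):
        df = inputs
        already = False
    else:
        df = pd.DataFrame(dict(inputs))
        already = False

    needed = model.input_ids
    missing = [v for v in needed if v not in df.columns]
    if missing:
        raise KeyError(f"missing required input variable(s): {missing}")

    cols: dict[str, np.ndarray] = {}
    for v in needed:
        x = df[v].to_numpy(dtype=float)
        if not already:
            if v not in model.transforms:
                raise KeyError(f"model stores no normalization transform for {v!r}")
            x = apply_transform(x, model.transforms[v], node=v)
        cols[v] = x

    n = len(df)
    pred = np.full(n, model.f0, dtype=float)
    for comp in model.components:
        pred += comp.evaluate(model.bases, cols)
    if denormalize:
        if model.output_id not in model.transforms:
            raise KeyError(f"no stored transform for output {model.output_id!r}")
        pred = denormalize_column(pred, model.transforms[model.output_id])
    return pred
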