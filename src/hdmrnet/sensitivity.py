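"""Variance-based sensitivity decomposition of a fitted HDMR expansion.

The total output variance sigma_y^2 is decomposed over the fitted component
functions.  When inputs are sampled independently the component functions are
mutually orthogonal and each index reduces to var(f_k) / sigma_y^2; under
correlated inputs the decomposition also carries pairwise covariances between
component functions.  We attribute to each component its full row of
covariances, S_k = cov(f_k, y) / sigma_y^2 (population 1/n convention): this
is the unique linear allocation that sums exactly to one together with the
residual index S_resid = cov(eps, y) / sigma_y^2, and it reduces to
var(f_k)/sigma_y^2 under independence.  Negative indices are possible under
correlation and are reported as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataTable
from .model_fit import HDMRModel

__all__ = ["SensitivityReport", "compute_sensitivities", "summarize_totals"]

ATTRIBUTION_RULE = "S_k = cov(f_k, y) / var(y); population (1/n) moments"


@dataclass
class SensitivityReport:
    """Per-component sensitivity indices for one output node.

    ``S`` maps component key (order, variable tuple) -> index; ``T`` maps each
    input variable to the sum of indices over every component containing it
    (a second-order index therefore contributes fully to both participants);
    ``order_totals`` partitions sum(S) by component order.
    """

    output_id: str
    total_variance: float
    S: dict[tuple[int, tuple[str, ...]], float]
    S_resid: float
    T: dict[str, float] = field(default_factory=dict)
    order_totals: dict[int, float] = field(default_factory=dict)
    n: int = 0
    attribution: str = ATTRIBUTION_RULE

    @property
    def sum_S(self) -> float:
        return float(sum(self.S.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": "+".join(vs),
                "order": o,
                "variables": ",".join(vs),
                "S": s,
            }
            for (o, vs), s in self.S.items()
        ]
        return pd.DataFrame(rows, columns=["component", "order", "variables", "S"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary_dict(self) -> dict:
        return {
            "output_id": self.output_id,
            "total_variance": self.total_variance,
            "sum_S": self.sum_S,
            "S_resid": self.S_resid,
            "T": dict(self.T),
            "order_totals": {str(k): v for k, v in self.order_totals.items()},
            "n": self.n,
            "attribution": self.attribution,
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.summary_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


def compute_sensitivities(model: HDMRModel, table: DataTable) -> SensitivityReport:
    """Evaluate every component over the table and decompose the output variance.

    sigma_y^2 = mean((y - ybar)^2); S_k = cov(f_k, y) / sigma_y^2;
    S_resid = cov(eps, y) / sigma_y^2 with eps = y - prediction.  Because
    y - ybar = sum_k f_k + eps + const, the indices sum to one exactly.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to decompose variance")
    missing = [v for v in model.input_ids + [model.output_id] if v not in table.node_names]
    if missing:
        raise KeyError(f"table lacks model variable(s): {missing}")

    if table.normalized:
        y = table.values[model.output_id].to_numpy(dtype=float)
        cols = {v: table.values[v].to_numpy(dtype=float) for v in model.input_ids}
    else:  # raw-scale table: map output and inputs through the model transforms
        from .data_io import apply_transform

        y = apply_transform(
            table.values[model.output_id].to_numpy(dtype=float),
            model.transforms[model.output_id],
            node=model.output_id,
        )
        cols = {
            v: apply_transform(
                table.values[v].to_numpy(dtype=float), model.transforms[v], node=v
            )
            for v in model.input_ids
        }
    n = y.size
    ybar = y.mean()
    yc = y - ybar
    sigma2 = float(yc @ yc) / n
    if np.ptp(y) == 0.0 or sigma2 == 0.0:
        raise ValueError(
            f"output {model.output_id!r} is constant; no variance to decompose"
        )

    S: dict[tuple[int, tuple[str, ...]], float] = {}
    total_f = np.zeros(n)
    for comp in model.components:
        f_k = comp.evaluate(model.bases, cols)
        total_f += f_k
        S[(comp.order, comp.variable_ids)] = float((f_k - f_k.mean()) @ yc) / (n * sigma2)

    eps = yc - (model.f0 - ybar) - total_f
    S_resid = float((eps - eps.mean()) @ yc) / (n * sigma2)

    report = SensitivityReport(
        output_id=model.output_id,
        total_variance=sigma2,
        S=S,
        S_resid=S_resid,
        n=n,
    )
    report.T, report.order_totals = summarize_totals(report)
    return report


def summarize_totals(
    report: SensitivityReport,
) -> tuple[dict[str, float], dict[int, float]]:
    """Per-input totals T_i and order-wise totals from the component indices.

    T_i sums S over every component whose variable tuple contains input i, so
    a cooperative index counts fully toward each participant and sum(T) may
    exceed sum(S).  Order totals partition sum(S) by order.
    """
    T: dict[str, float] = {}
    order_totals: dict[int, float] = {}
    for (order, variables), s in report.S.items():
        order_totals[order] = order_totals.get(order, 0.0) + s
        for v in variables:
            T[v] = T.get(v, 0.0) + s
    return T, order_totals
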