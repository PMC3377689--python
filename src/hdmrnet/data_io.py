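"""Condition tables: loading, unit-interval normalization, pairwise-comparison
construction, and the noise / resampling protocols used in robustness analyses.

A :class:`DataTable` holds one experimental condition's samples-by-nodes matrix
(rows = cells/samples, columns = named network nodes).  All downstream fitting
assumes node values normalized to [0, 1]; the normalization transform is frozen
from the data it was computed on, so held-out points can be mapped consistently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("hdmrnet")

__all__ = [
    "DataTable",
    "PairwiseTable",
    "NoiseConfig",
    "ParseError",
    "load_table",
    "write_table",
    "normalize_unit_interval",
    "denormalize_column",
    "make_pairwise",
    "split_train_test",
    "add_noise",
    "resample",
]


class ParseError(ValueError):
    """Raised when a condition table cannot be parsed."""


@dataclass
class DataTable:
    """One condition's samples x nodes matrix.

    Parameters
    ----------
    values
        DataFrame with one column per network node, one row per sample/cell.
    condition_id
        Label for the experimental condition the samples were observed under.
    normalized
        True once every column has been rescaled to [0, 1].
    transforms
        Per-node ``(min, max)`` recorded when the table was normalized; used to
        map new points with the *same* transform.
    """

    values: pd.DataFrame
    condition_id: str = ""
    normalized: bool = False
    transforms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2:
            raise ValueError(
                f"condition {self.condition_id!r}: need at least 2 samples, got {df.shape[0]}"
            )
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate node names: {dupes}")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"missing values in nodes: {bad}")

    @property
    def node_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[1])

    def copy(self) -> "DataTable":
        return replace(self, values=self.values.copy(), transforms=dict(self.transforms))


@dataclass
class PairwiseTable(DataTable):
    """Control + perturbed condition concatenation with a Boolean output.

    The perturbed node's column is overwritten with the class label (0 = low /
    inhibited, 1 = high / activated); ``class_labels`` mirrors that column.
    """

    perturbed_node: str = ""
    class_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.perturbed_node:
            col = self.values[self.perturbed_node].to_numpy()
            if not np.array_equal(col, self.class_labels):
                raise ValueError(
                    f"perturbed node {self.perturbed_node!r} column must equal class_labels"
                )
            classes = set(np.unique(self.class_labels).tolist())
            if classes != {0, 1}:
                raise ValueError(f"both classes must be present, got {sorted(classes)}")


@dataclass(frozen=True)
class NoiseConfig:
    """Noise protocol: additive per-node-sd-scaled or multiplicative Gaussian.

    ``scale`` is the dimensionless fraction c: additive noise is
    N(0, (c * sd_j)^2) per column j; multiplicative noise multiplies each value
    by (1 + eta), eta ~ N(0, c^2).
    """

    mode: str = "additive"
    scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")


# ---------------------------------------------------------------------------
# I/O


def load_table(path, condition_id: str = "") -> DataTable:
    """Read a delimited text table (header row of node names, numeric body).

    Delimiter is auto-detected between comma and tab.  Raises
    :class:`ParseError` naming the offending row/column on malformed input.
    """
    with open(path) as fh:
        head = fh.readline()
    if not head.strip():
        raise ParseError(f"{path}: empty file or missing header")
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    header_names = [h.strip() for h in head.strip().split(sep)]
    if len(set(header_names)) != len(header_names):
        dupes = sorted({h for h in header_names if header_names.count(h) > 1})
        raise ParseError(f"{path}: duplicate node name(s) {dupes}")
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise ParseError(f"{path}: table has a header but no data rows")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate node name(s) {dupes}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) if len(bad) else 0
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ParseError(f"{path}: missing value(s) in column(s) {bad}")
    return DataTable(values=df.astype(float), condition_id=condition_id or str(path))


def write_table(table: DataTable, path, sep: str = ",") -> None:
    """Write a table in the same delimited dialect as read (default CSV)."""
    table.values.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Normalization


def normalize_unit_interval(table: DataTable) -> DataTable:
    """Linearly rescale every column to [0, 1] by its own (min, max).

    The per-column (min, max) is stored on the returned table so that new
    points can be mapped with the same frozen transform.  A constant column is
    an error: a zero-variance input cannot support an orthonormal basis.
    """
    if table.normalized:
        raise ValueError(f"condition {table.condition_id!r} is already normalized")
    df = table.values
    transforms: dict[str, tuple[float, float]] = {}
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise ValueError(
                f"node {col!r} is constant (value {lo}); zero-variance inputs "
                "cannot support a basis"
            )
        out[col] = (x - lo) / (hi - lo)
        transforms[col] = (lo, hi)
    return replace(
        table,
        values=pd.DataFrame(out, index=df.index),
        normalized=True,
        transforms=transforms,
    )


def apply_transform(
    x: np.ndarray, bounds: tuple[float, float], node: str = "", clamp: bool = True
) -> np.ndarray:
    """Map raw values through a frozen (min, max) transform, clamping to [0,1]."""
    lo, hi = bounds
    z = (np.asarray(x, dtype=float) - lo) / (hi - lo)
    if clamp:
        n_out = int(np.sum((z < 0) | (z > 1)))
        if n_out:
            warnings.warn(
                f"{n_out} value(s) for node {node!r} fall outside the training "
                "range and were clamped to [0, 1]",
                stacklevel=2,
            )
            z = np.clip(z, 0.0, 1.0)
    return z


def denormalize_column(z: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Invert the unit-interval transform back to the original scale."""
    lo, hi = bounds
    return np.asarray(z, dtype=float) * (hi - lo) + lo


# ---------------------------------------------------------------------------
# Pairwise-comparison construction


def make_pairwise(
    control: DataTable,
    perturbed: DataTable,
    node: str,
    direction: str = "activated",
) -> PairwiseTable:
    """Concatenate a control and a perturbed condition into a Boolean dataset.

    The perturbation (drug) is exogenous and not itself observed, so the
    perturbed node's measured values are replaced by the known condition label:
    for an *activating* perturbation control rows get 0 (low) and perturbed
    rows 1 (high); for an *inhibiting* perturbation the roles swap (the drug
    makes its target low, so perturbed rows get 0).
    """
    if direction not in ("activated", "inhibited"):
        raise ValueError(f"direction must be 'activated' or 'inhibited', got {direction!r}")
    if control.node_names != perturbed.node_names:
        raise ValueError(
            "control and perturbed tables must share identical node names: "
            f"{control.node_names} vs {perturbed.node_names}"
        )
    if node not in control.node_names:
        raise ValueError(f"node {node!r} not present in tables")
    n_ctrl, n_pert = control.n_samples, perturbed.n_samples
    df = pd.concat([control.values, perturbed.values], ignore_index=True)
    if direction == "activated":
        labels = np.concatenate([np.zeros(n_ctrl), np.ones(n_pert)])
    else:
        labels = np.concatenate([np.ones(n_ctrl), np.zeros(n_pert)])
    df[node] = labels
    return PairwiseTable(
        values=df,
        condition_id=f"{control.condition_id}|{perturbed.condition_id}:{node}:{direction}",
        perturbed_node=node,
        class_labels=labels,
    )


# ---------------------------------------------------------------------------
# Resampling and noise protocols


def split_train_test(
    table: DataTable, fraction: float, seed: int
) -> tuple[DataTable, DataTable]:
    """Random disjoint row partition: round(fraction * n) training rows."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n = table.n_samples
    n_train = int(round(fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError(
            f"fraction {fraction} leaves {n_train} train / {n - n_train} test rows; "
            "each side needs at least 2"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train = replace(table, values=table.values.iloc[tr].reset_index(drop=True))
    test = replace(table, values=table.values.iloc[te].reset_index(drop=True))
    return train, test


def add_noise(table: DataTable, cfg: NoiseConfig) -> DataTable:
    """Perturb every value with Gaussian noise per the configured protocol.

    additive:        m' = m + eta,      eta ~ N(0, (c * sd_j)^2), sd_j the
                     column's sample standard deviation
    multiplicative:  m' = m * (1 + eta), eta ~ N(0, c^2)
    """
    rng = np.random.default_rng(cfg.seed)
    df = table.values
    vals = df.to_numpy(dtype=float)
    if cfg.mode == "additive":
        sd = vals.std(axis=0, ddof=0)
        noisy = vals + rng.standard_normal(vals.shape) * (cfg.scale * sd)
    else:
        noisy = vals * (1.0 + cfg.scale * rng.standard_normal(vals.shape))
    return replace(table, values=pd.DataFrame(noisy, columns=df.columns))


def resample(
    table: DataTable,
    mode: str,
    factor: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> DataTable:
    """Subsample rows without replacement, or oversample with Gaussian jitter.

    ``subsample`` draws round(factor * n) rows (0 < factor <= 1).
    ``oversample`` replicates each row ``factor`` times (positive integer),
    adding N(0, jitter_sd^2) to every replicated value so that the original
    row is the centroid of its replicates.
    """
    rng = np.random.default_rng(seed)
    n = table.n_samples
    if mode == "subsample":
        if not 0.0 < factor <= 1.0:
            raise ValueError(f"subsample factor must lie in (0, 1], got {factor}")
        k = int(round(factor * n))
        idx = np.sort(rng.choice(n, size=k, replace=False))
        return replace(table, values=table.values.iloc[idx].reset_index(drop=True))
    if mode == "oversample":
        if factor != int(factor) or factor < 1:
            raise ValueError(f"oversample factor must be a positive integer, got {factor}")
        k = int(factor)
        vals = np.repeat(table.values.to_numpy(dtype=float), k, axis=0)
        if jitter_sd > 0:
            vals = vals + rng.standard_normal(vals.shape) * jitter_sd
        return replace(table, values=pd.DataFrame(vals, columns=table.values.columns))
    raise ValueError(f"unknown resample mode {mode!r}")
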