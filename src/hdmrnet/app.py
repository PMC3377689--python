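"""Command-line orchestration: fit, sensitivity, network, predict, classify,
simulate, and a full pipeline with a reproducible run manifest.

The pipeline executes load/normalize -> per-node HDMR fits -> sensitivity
decomposition -> max-aggregation -> thresholded network export, recording
every parameter, seed, and output checksum in a JSON manifest so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from .data_io import DataTable, load_table, make_pairwise, normalize_unit_interval, write_table
from .feom import classify_inverse, evaluate_prediction
from .model_fit import FitConfig, HDMRModel, fit_hdmr, predict
from .network import aggregate_network, edge_threshold_profile, export_network, fit_all_nodes
from .sensitivity import compute_sensitivities
from .synthetic import make_benchmark_spec, sample_synthetic

logger = logging.getLogger("hdmrnet")


def _setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(levelname)s %(name)s: %(message)s", stream=sys.stderr
    )


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    tables: list[str] = field(default_factory=list)
    pairwise: list[dict] = field(default_factory=list)  # control/perturbed/node/direction
    simulate: dict | None = None  # {preset, n, seed}
    degree_first: int = 3
    degree_second: int = 2
    degree_third: int = 1
    alpha: float = 0.01
    max_order: int = 2
    policy: str = "hierarchical"
    tau: float = 0.1
    seed: int = 0
    out_dir: str = "hdmr_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config key(s): {sorted(extra)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.tables and self.simulate is None:
            raise ValueError("config must list input tables or a simulate block")
        for p in self.tables:
            if not Path(p).exists():
                raise FileNotFoundError(f"input table not found: {p}")
        for pw in self.pairwise:
            for key in ("control", "perturbed", "node", "direction"):
                if key not in pw:
                    raise ValueError(f"pairwise entry missing {key!r}: {pw}")
        self.fit_config()  # raises on bad degrees/alpha/order/policy

    def fit_config(self) -> FitConfig:
        return FitConfig(
            degree_first=self.degree_first,
            degree_second=self.degree_second,
            degree_third=self.degree_third,
            alpha=self.alpha,
            max_order=self.max_order,
            policy=self.policy,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fit_cfg = config.fit_config()

    stage = "load"
    try:
        conditions: list[DataTable] = []
        if config.simulate is not None:
            spec = make_benchmark_spec(
                config.simulate["preset"], int(config.simulate.get("seed", config.seed))
            )
            sampled = sample_synthetic(spec, int(config.simulate.get("n", 2000)))
            if isinstance(sampled, tuple):
                control, pert = sampled
                conditions.append(control)
                conditions.extend(pert.values())
            else:
                conditions.append(sampled)
        for p in config.tables:
            conditions.append(load_table(p, condition_id=Path(p).stem))

        stage = "normalize"
        raw = {t.condition_id: t for t in conditions}
        normed = [normalize_unit_interval(t) for t in conditions]

        stage = "fit"
        reports = {}
        failed = []
        for table in normed:
            pairs = fit_all_nodes(table, fit_cfg)
            reports[table.condition_id] = [r for _m, r in pairs if r is not None]
            failed += [
                (table.condition_id, node)
                for (m, _r), node in zip(pairs, table.node_names)
                if m is None
            ]

        stage = "pairwise"
        pairwise_reports = {}
        for pw in config.pairwise:
            ctrl, pert = raw[pw["control"]], raw[pw["perturbed"]]
            pt = make_pairwise(ctrl, pert, pw["node"], pw["direction"])
            ptn = normalize_unit_interval(pt)
            model = fit_hdmr(ptn, pw["node"], fit_cfg)
            pairwise_reports[ptn.condition_id] = [compute_sensitivities(model, ptn)]

        stage = "network"
        graph = aggregate_network(
            reports, pairwise_reports or None, tau=config.tau
        )
        export_network(graph, out_dir / "network.sif", "edge-list-sif")
        export_network(graph, out_dir / "network_adjacency.tsv", "adjacency-tsv")
        export_network(graph, out_dir / "network.json", "json")
        edge_threshold_profile(graph).to_csv(out_dir / "edge_profile.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "conditions": sorted(reports.keys()),
            "pairwise_conditions": sorted(pairwise_reports.keys()),
            "failed_fits": failed,
            "n_edges": len(graph.edges),
            "outputs": {
                f.name: _sha256(f)
                for f in sorted(out_dir.iterdir())
                if f.is_file() and f.name != "manifest.json"
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--verbose", is_flag=True, help="Debug-level logging.")
@click.version_option(__version__)
def cli(verbose: bool) -> None:
    """RS-HDMR network inference, sensitivity analysis, and FEOM prediction."""
    _setup_logging(verbose)


@cli.command("fit")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--output-node", required=True)
@click.option("--alpha", default=0.01, show_default=True)
@click.option("--max-order", default=2, show_default=True)
@click.option("--model", "model_path", required=True, type=click.Path())
def cli_fit(input_path, output_node, alpha, max_order, model_path):
    """Fit one HDMR expansion and serialize it to JSON."""
    table = normalize_unit_interval(load_table(input_path))
    cfg = FitConfig(alpha=alpha, max_order=max_order)
    model = fit_hdmr(table, output_node, cfg)
    model.to_json(model_path)
    click.echo(f"fit {output_node}: {len(model.components)} components -> {model_path}")


@cli.command("sensitivity")
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_sensitivity(model_path, input_path, out):
    """Sensitivity decomposition of a fitted model over a table."""
    model = HDMRModel.from_json(model_path)
    table = normalize_unit_interval(load_table(input_path))
    report = compute_sensitivities(model, table)
    report.to_tsv(out)
    report.to_json(str(out) + ".summary.json")
    click.echo(f"sum S = {report.sum_S:.4f}, S_resid = {report.S_resid:.4f}")


@cli.command("network")
@click.option("--tables", required=True, multiple=True, type=click.Path(exists=True))
@click.option("--tau", default=0.1, show_default=True)
@click.option("--alpha", default=0.01, show_default=True)
@click.option("--max-order", default=2, show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_network(tables, tau, alpha, max_order, out):
    """Fit all nodes of each condition table and export the aggregated network."""
    cfg = FitConfig(alpha=alpha, max_order=max_order)
    reports = {}
    for p in tables:
        t = normalize_unit_interval(load_table(p, condition_id=Path(p).stem))
        reports[t.condition_id] = [r for _m, r in fit_all_nodes(t, cfg) if r is not None]
    graph = aggregate_network(reports, tau=tau)
    fmt = "edge-list-sif" if str(out).endswith(".sif") else "adjacency-tsv"
    export_network(graph, out, fmt)
    click.echo(f"{len(graph.edges)} edges at tau={tau} -> {out}")


@cli.command("predict")
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
@click.option("--report", "report_path", required=True, type=click.Path())
def cli_predict(model_path, table_path, report_path):
    """Forward FEOM prediction metrics on a held-out table."""
    model = HDMRModel.from_json(model_path)
    test = load_table(table_path)
    metrics = evaluate_prediction(model, test)
    metrics.to_json(report_path)
    click.echo(metrics.to_json())


@cli.command("classify")
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--table", "table_path", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def cli_classify(model_path, table_path, out):
    """Inverse-FEOM classification of perturbation condition."""
    model = HDMRModel.from_json(model_path)
    samples = load_table(table_path)
    result = classify_inverse(model, samples)
    result.to_frame().to_csv(out, sep="\t", index=False)
    click.echo(f"{len(result.labels)} samples classified -> {out}")


@cli.command("simulate")
@click.option("--preset", required=True)
@click.option("--n", default=2000, show_default=True)
@click.option("--seed", default=7, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def cli_simulate(preset, n, seed, out_dir):
    """Generate a synthetic benchmark condition (plus perturbed variants)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = make_benchmark_spec(preset, seed)
    spec.to_json(out / "spec.json")
    sampled = sample_synthetic(spec, n)
    if isinstance(sampled, tuple):
        control, pert = sampled
        write_table(control, out / "control.csv")
        for label, t in pert.items():
            write_table(t, out / f"perturbed_{label}.csv")
        click.echo(f"wrote control + {len(pert)} perturbed tables -> {out}")
    else:
        write_table(sampled, out / "control.csv")
        click.echo(f"wrote {sampled.n_samples}x{sampled.n_nodes} table -> {out}")


@cli.command("pipeline")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--tau", default=None, type=float, help="Override config tau.")
@click.option("--seed", default=None, type=int, help="Override config seed.")
def cli_pipeline(config_path, tau, seed):
    """Run the full load -> fit -> sensitivity -> network pipeline."""
    config = RunConfig.from_yaml(config_path)
    if tau is not None:
        config.tau = tau
    if seed is not None:
        config.seed = seed
    try:
        manifest = run_pipeline(config)
    except RuntimeError as exc:
        click.echo(str(exc), err=True)
        raise SystemExit(1)
    click.echo(f"{manifest['n_edges']} edges; manifest -> {config.out_dir}/manifest.json")


if __name__ == "__main__":  # pragma: no cover
    cli()
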