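"""Experiment orchestration: validated configs, dispatch, and
reproducible output bundles (CSV tables + summary JSON + manifest)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._exceptions import InvalidParameterError
from .explorability import (
    HeterogeneityConfig,
    explorability_heterogeneous,
    sample_explorability_distribution,
)
from .io import write_weight_matrix
from .optimize import (
    OptimizationConfig,
    hill_climb,
    multi_objective_climb,
)
from .robustness import sample_robustness_distribution, robustness_R
from .sparsity import (
    ScalingRecordSet,
    fit_inverse_scaling,
    generate_scaling_table,
    may_instability_probability,
)
from .topology import add_random_links, make_tree_like

logger = logging.getLogger("explora")

EXPERIMENTS = ("explorability", "robustness", "optimize", "fit", "synth-table", "may-demo")


@dataclass
class ExperimentConfig:
    experiment: str
    params: dict = field(default_factory=dict)
    out_dir: str | Path = "explora-out"
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise InvalidParameterError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        p = self.params
        if "delta_eps" in p and not (1e-3 <= p["delta_eps"] <= 1e-1):
            raise InvalidParameterError(
                f"delta_eps={p['delta_eps']} outside the supported range [1e-3, 1e-1]"
            )
        for key in ("size", "n_samples", "n_eps", "n_xi", "steps"):
            if key in p and p[key] < 1:
                raise InvalidParameterError(f"{key} must be >= 1, got {p[key]}")
        if "connectivity" in p and "size" in p:
            if not (2 / p["size"] <= p["connectivity"] <= 1):
                raise InvalidParameterError(
                    f"connectivity={p['connectivity']} outside [2/S, 1]"
                )

    @classmethod
    def from_json(cls, path, **overrides) -> "ExperimentConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Dispatch an experiment, write its output bundle, and return the
    summary dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        logger.info("experiment=%s seed=%s params=%s", cfg.experiment, cfg.seed, cfg.params)
        summary = _DISPATCH[cfg.experiment](cfg, out)
        _write_json(
            out / "manifest.json",
            {
                "experiment": cfg.experiment,
                "params": cfg.params,
                "seed": cfg.seed,
                "version": __version__,
            },
        )
        _write_json(out / "summary.json", summary)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_explorability(cfg: ExperimentConfig, out: Path) -> dict:
    p = cfg.params
    S = p.get("size", 20)
    C = p.get("connectivity", 2 / S)
    sigma_eps = p.get("sigma_eps", 0.1)
    n = p.get("n_samples", 100)
    topo = make_tree_like(S, p.get("loop_length", 3), seed=cfg.seed)
    dist = sample_explorability_distribution(
        topo, C, sigma_eps, n, seed=cfg.seed + 1
    )
    rows = [
        {
            "realization_id": i,
            "C": C,
            "sigma_eps": sigma_eps,
            "x_c": r.x_c,
            "V_E": r.V_E,
            "single_crossing": r.single_crossing,
        }
        for i, r in enumerate(dist.results)
    ]
    pd.DataFrame(rows).to_csv(out / "explorability_samples.csv", index=False)
    summary = {
        "mean_V_E": dist.mean_V_E,
        "fraction_single_crossing": dist.fraction_single_crossing,
        "n_realizations": dist.n_realizations,
    }
    logger.info(
        "skip rate (no single crossing): %.3f", 1 - dist.fraction_single_crossing
    )
    if p.get("heterogeneous"):
        het = HeterogeneityConfig(
            sigma_alpha=p.get("sigma_alpha", 0.1), sigma_x=p.get("sigma_x", 0.1)
        )
        extra = add_random_links(topo, C, sigma_eps, seed=cfg.seed + 2)
        samples = explorability_heterogeneous(topo, extra, het, seed=cfg.seed + 3)
        pd.DataFrame({"V_E": samples}).to_csv(
            out / "explorability_heterogeneous.csv", index=False
        )
        summary["heterogeneous_mean_V_E"] = (
            float(np.mean(samples)) if samples.size else None
        )
        summary["heterogeneous_n_samples"] = int(samples.size)
    return summary


def _run_robustness(cfg: ExperimentConfig, out: Path) -> dict:
    p = cfg.params
    S = p.get("size", 20)
    C = p.get("connectivity", 2 / S)
    topo = make_tree_like(S, p.get("loop_length", 3), seed=cfg.seed)
    sample = sample_robustness_distribution(
        topo,
        C,
        p.get("sigma_eps", 0.1),
        p.get("n_eps", 100),
        p.get("n_xi", 100),
        seed=cfg.seed + 1,
        percentile=p.get("percentile", 5),
    )
    pd.DataFrame({"abscissa": sample.abscissas}).to_csv(
        out / "robustness_abscissas.csv", index=False
    )
    logger.info("skip rate (no edge matrix): %.3f", sample.skip_rate)
    return {
        "R": sample.R,
        "percentile": sample.percentile,
        "R_by_percentile": {
            str(q): robustness_R(sample.abscissas, q) for q in (5, 10, 20, 50)
        },
        "n_abscissas": int(sample.abscissas.size),
        "skip_rate": sample.skip_rate,
    }


def _run_optimize(cfg: ExperimentConfig, out: Path) -> dict:
    p = cfg.params
    S = p.get("size", 10)
    C = p.get("connectivity", 0.5)
    topo = make_tree_like(S, p.get("loop_length", 3), seed=cfg.seed)
    extra0 = add_random_links(topo, C, p.get("sigma_eps", 0.1), seed=cfg.seed + 1)
    opt_cfg = OptimizationConfig(
        objective=p.get("objective", "explorability"),
        steps=p.get("steps", 200),
        step_std=p.get("delta_eps", 0.01),
        seed=cfg.seed + 2,
    )
    climb = (
        multi_objective_climb
        if opt_cfg.objective in ("both", "alternating")
        else hill_climb
    )
    trace = climb(topo, extra0, opt_cfg)
    pd.DataFrame(
        [
            {"step": s.step, "accepted": s.accepted, "V_E": s.V_E, "R": s.R}
            for s in trace.steps
        ]
    ).to_csv(out / "optimization_trace.csv", index=False)
    # final values are recomputed at full sampling, independent of the
    # noisy in-loop estimates
    from .optimize import evaluate_network
    from .robustness import edge_matrix

    final_V, final_R = evaluate_network(
        topo, trace.final_extra, n_xi=2000, seed=cfg.seed + 3
    )
    try:
        edge = edge_matrix(topo, trace.final_extra)
        write_weight_matrix(out / "final_network.tsv", edge.weights.weights)
    except Exception:
        logger.warning("final network has no edge matrix; TSV not written")
    return {
        "objective": opt_cfg.objective,
        "initial_V_E": trace.initial_V_E,
        "initial_R": trace.initial_R,
        "final_V_E": final_V,
        "final_R": final_R,
        "acceptance_fraction": trace.acceptance_fraction,
    }


def _run_fit(cfg: ExperimentConfig, out: Path) -> dict:
    p = cfg.params
    if "input" not in p:
        raise InvalidParameterError("fit experiment requires params['input']")
    data = ScalingRecordSet.from_csv(p["input"])
    fit = fit_inverse_scaling(data, method=p.get("method", "origin-ols"))
    return {
        "c1": fit.c1,
        "c1_stderr": fit.c1_stderr,
        "n_records": fit.n_records,
        "method": fit.method,
    }


def _run_synth_table(cfg: ExperimentConfig, out: Path) -> dict:
    p = cfg.params
    table = generate_scaling_table(
        c1_true=p.get("c1", 3.8),
        n_networks=p.get("n", 83),
        S_range=(p.get("s_min", 10), p.get("s_max", 1000)),
        noise_cv=p.get("noise_cv", 0.3),
        seed=cfg.seed,
    )
    table.to_csv(out / "scaling_table.csv")
    return {"n_records": len(table), "n_clipped": table.n_clipped}


def _run_may_demo(cfg: ExperimentConfig, out: Path) -> dict:
    p = cfg.params
    sizes = p.get("sizes", [50, 100, 200])
    c1 = p.get("c1", 3.8)
    d = p.get("d", 1.0)
    sigma = p.get("sigma", 1.5 * d / np.sqrt(c1))
    n_matrices = p.get("n_matrices", 50)
    fractions = {
        str(S): may_instability_probability(
            S, c1 / S, sigma, d, n_matrices, seed=cfg.seed + i
        )
        for i, S in enumerate(sizes)
    }
    return {
        "fraction_unstable_by_S": fractions,
        "sigma_sqrt_c1_over_d": sigma * np.sqrt(c1) / d,
    }


_DISPATCH = {
    "explorability": _run_explorability,
    "robustness": _run_robustness,
    "optimize": _run_optimize,
    "fit": _run_fit,
    "synth-table": _run_synth_table,
    "may-demo": _run_may_demo,
}
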