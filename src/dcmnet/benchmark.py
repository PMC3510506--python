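"""In-silico benchmark driver.

Reproduces the simulation study end to end: simulate the 6-gene / 4-stage
benchmark, run the cascaded method and the static and dynamic comparators,
and score network recovery.  Also provides parameter sweeps (inter-stage
influence coefficient rho, bootstrap group size, noise level).

Each modelling repetition yields one pooled AUC (edges scored by the
repetition's |coefficient|); results report mean +/- sd over repetitions,
optionally pooled over several independent topology draws (each draw
re-randomizes the benchmark's edge signs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BaselineConfig, dynamic_infer, static_infer
from .core import DCMConfig, FractionConfig, infer
from .evaluate import MetricsReport, evaluate_networks
from .simulate import (
    KineticNetwork,
    add_noise,
    build_benchmark_network,
    integrate,
    to_sample_based,
)

__all__ = ["BenchmarkResult", "run_benchmark", "sweep"]


@dataclass
class BenchmarkResult:
    """Per-method recovery metrics on the benchmark."""

    reports: dict[str, MetricsReport]
    auc_values: dict[str, list[float]]  # pooled-AUC per repetition (all draws)

    def mean_auc(self, method: str) -> float:
        return float(np.mean(self.auc_values[method]))

    def sd_auc(self, method: str) -> float:
        return float(np.std(self.auc_values[method]))

    def table(self, method: str) -> pd.DataFrame:
        """Metrics table (rows AUC/p/F2/MCC, columns stages + overall)."""
        rep = self.reports[method]
        keys = [*rep.stage_labels, "overall"]
        return pd.DataFrame(
            {
                k: [
                    f"{rep.auc[k]:.2f} ± {rep.auc_sd[k]:.3f}",
                    f"{rep.p_value[k]:.4f}",
                    f"{rep.f2[k]:.2f} ± {rep.f2_sd[k]:.3f}",
                    f"{rep.mcc[k]:.2f} ± {rep.mcc_sd[k]:.3f}",
                ]
                for k in keys
            },
            index=["AUC", "P-value", "F2-score", "MCC"],
        )


def _simulate_draw(
    seed: int, noise: float
) -> tuple[KineticNetwork, "np.ndarray", "np.ndarray"]:
    net = build_benchmark_network(seed)
    tc = integrate(net)
    data = to_sample_based(tc, seed=seed + 1)
    if noise > 0:
        data = add_noise(data, noise, seed=seed + 2)
    return net, tc, data


def run_benchmark(
    reps: int = 20,
    seed: int = 0,
    noise: float = 0.0,
    rho: float = 0.6,
    group_size: int = 16,
    n_bootstrap_groups: int = 200,
    network_draws: int = 1,
    methods: tuple[str, ...] = ("dcm", "static", "dynamic"),
    fc: FractionConfig | None = None,
) -> BenchmarkResult:
    """Simulate the benchmark and score the requested methods.

    ``reps`` repetitions are run per topology draw for the stochastic
    methods (cascaded and static); the dynamic comparator is deterministic
    per draw, so its repetitions are the draws themselves.
    """
    if reps < 2:
        raise ValueError("at least 2 repetitions are required")
    fc = fc or FractionConfig()
    draw_seeds = np.random.SeedSequence(seed).generate_state(network_draws) % (2**31)

    auc_values: dict[str, list[float]] = {m: [] for m in methods}
    reports: dict[str, MetricsReport] = {}
    for d, dseed in enumerate(map(int, draw_seeds)):
        net, tc, data = _simulate_draw(dseed, noise)
        for method in methods:
            if method == "dcm":
                cfg = DCMConfig(
                    rho=rho,
                    group_size=group_size,
                    n_bootstrap_groups=n_bootstrap_groups,
                    n_repetitions=reps,
                    seed=dseed + 3,
                )
                nets = infer(data, fc, cfg)
            elif method == "static":
                bcfg = BaselineConfig(
                    n_repetitions=reps, group_size=group_size, seed=dseed + 4
                )
                nets = static_infer(data, bcfg)
            elif method == "dynamic":
                nets = dynamic_infer(tc, BaselineConfig(seed=dseed + 5))
            else:
                raise ValueError(f"unknown method {method!r}")
            report = evaluate_networks(nets, net)
            auc_values[method].extend(report.auc_values["overall"])
            if d == 0:
                reports[method] = report
    return BenchmarkResult(reports=reports, auc_values=auc_values)


def sweep(
    parameter: str,
    values: list,
    reps: int = 10,
    seed: int = 0,
    network_draws: int = 1,
    **fixed,
) -> pd.DataFrame:
    """Sweep one benchmark parameter ('rho', 'group_size' or 'noise').

    Returns a frame with columns [parameter, mean_auc, sd_auc], the mean and
    sd of the cascaded method's per-repetition pooled AUC at each setting.
    """
    if parameter not in ("rho", "group_size", "noise"):
        raise ValueError("parameter must be 'rho', 'group_size' or 'noise'")
    rows = []
    for v in values:
        kwargs = dict(fixed)
        kwargs[parameter] = v
        res = run_benchmark(
            reps=reps,
            seed=seed,
            network_draws=network_draws,
            methods=("dcm",),
            **kwargs,
        )
        rows.append((v, res.mean_auc("dcm"), res.sd_auc("dcm")))
    return pd.DataFrame(rows, columns=[parameter, "mean_auc", "sd_auc"])
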