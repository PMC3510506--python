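"""Multi-stage kinetic network simulator.

Generates ground-truth gene regulatory networks whose topology switches at
stage boundaries, integrates the linear transcription-kinetics ODE

    dx_i/dt = -deg_i * x_i + sum_{j in R_i} beta_ij^s * x_j

with the state carried continuously across stage transitions, and converts
the resulting time course into stage-labelled "sample-based" data by
scrambling the within-stage temporal order.  Additive Gaussian noise can be
injected at a configurable noise-to-signal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StageSpec",
    "KineticNetwork",
    "TimeCourse",
    "StagedExpressionData",
    "IntegrationError",
    "BENCHMARK_MOTIFS",
    "motif_edges",
    "build_benchmark_network",
    "integrate",
    "to_sample_based",
    "add_noise",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE state becomes non-finite during integration."""


@dataclass(frozen=True)
class StageSpec:
    """One stage of a progression: a label and a time span.

    ``samples_per_unit_time`` controls the sampling cadence of the recorded
    time course (one sample per time unit by default).
    """

    label: str
    time_span: float
    samples_per_unit_time: int = 1

    def __post_init__(self) -> None:
        if self.time_span <= 0:
            raise ValueError(f"stage {self.label!r}: time_span must be > 0")
        if self.samples_per_unit_time < 1:
            raise ValueError(f"stage {self.label!r}: samples_per_unit_time must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.time_span * self.samples_per_unit_time))


@dataclass
class KineticNetwork:
    """Ground-truth kinetic model: per-stage strength matrices + turnover rates.

    ``strengths[s][i, j]`` is the signed regulatory strength of gene *j* on
    gene *i* during stage *s* (zero when *j* does not regulate *i*).  The
    diagonal is zero: self-degradation is carried by ``degradation`` alone.
    """

    gene_ids: list[str]
    stages: list[StageSpec]
    strengths: list[np.ndarray]
    degradation: np.ndarray
    initial_state: np.ndarray

    def __post_init__(self) -> None:
        p = self.n_genes
        if not self.stages:
            raise ValueError("stage list must be non-empty")
        if len(self.strengths) != len(self.stages):
            raise ValueError("one strength matrix required per stage")
        self.degradation = np.asarray(self.degradation, dtype=float)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if self.degradation.shape != (p,) or self.initial_state.shape != (p,):
            raise ValueError("degradation / initial_state must have one entry per gene")
        if np.any(self.degradation < 0):
            raise ValueError("degradation rates must be non-negative")
        self.strengths = [np.asarray(b, dtype=float) for b in self.strengths]
        for s, b in enumerate(self.strengths):
            if b.shape != (p, p):
                raise ValueError(f"stage {s}: strength matrix must be {p}x{p}")
            if np.any(np.diag(b) != 0):
                raise ValueError(f"stage {s}: diagonal of the strength matrix must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def true_edges(self, stage: int) -> set[tuple[int, int]]:
        """Directed edge set (regulator, target) of stage ``stage``."""
        b = self.strengths[stage]
        return {(j, i) for i, j in zip(*np.nonzero(b))}


@dataclass
class TimeCourse:
    """Time-ordered expression profiles with per-column stage indices."""

    gene_ids: list[str]
    stage_labels: list[str]
    times: np.ndarray
    values: np.ndarray  # genes x timepoints
    stage_of_timepoint: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stage_of_timepoint = np.asarray(self.stage_of_timepoint, dtype=int)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.stage_of_timepoint) < 0):
            raise ValueError("stage indices must be non-decreasing along time")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError("values must be genes x timepoints")

    def stage_columns(self, stage: int) -> np.ndarray:
        return np.flatnonzero(self.stage_of_timepoint == stage)


@dataclass
class StagedExpressionData:
    """Stage-partitioned expression matrices; within-stage order is meaningless."""

    gene_ids: list[str]
    stage_labels: list[str]
    matrices: list[np.ndarray]  # one genes x N_s matrix per stage

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.stage_labels):
            raise ValueError("one matrix required per stage")
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        p = len(self.gene_ids)
        for lab, m in zip(self.stage_labels, self.matrices):
            if m.ndim != 2 or m.shape[0] != p:
                raise ValueError(f"stage {lab!r}: matrix must be genes x samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def samples_per_stage(self) -> list[int]:
        return [m.shape[1] for m in self.matrices]

    def copy(self) -> "StagedExpressionData":
        return StagedExpressionData(
            list(self.gene_ids), list(self.stage_labels), [m.copy() for m in self.matrices]
        )


# ---------------------------------------------------------------------------
# Benchmark network
# ---------------------------------------------------------------------------

#: Regulatory motifs of the 6-gene, 4-stage benchmark (1-based gene labels).
#: "loop" g1..gn closes the cycle g1->g2->...->gn->g1; "feedforward" is the
#: chain g1->...->gn plus the skip g1->gn; "central" is the hub g1 regulating
#: every other listed gene.
BENCHMARK_MOTIFS: dict[str, list[tuple[str, tuple[int, ...]]]] = {
    "I": [
        ("loop", (3, 5, 4)),
        ("feedforward", (3, 5, 2)),
        ("feedforward", (3, 2, 1, 6)),
        ("central", (3, 2, 5, 6)),
    ],
    "II": [
        ("loop", (2, 6, 3)),
        ("loop", (1, 4, 5)),
    ],
    "III": [
        ("loop", (2, 6, 4, 3)),
        ("feedforward", (2, 6, 1)),
        ("feedforward", (5, 4, 3)),
    ],
    "IV": [
        ("loop", (2, 3, 4)),
        ("loop", (1, 2, 3, 5, 6)),
        ("feedforward", (3, 5, 4)),
    ],
}

BENCHMARK_SPANS = (20.0, 30.0, 20.0, 30.0)
BENCHMARK_DEGRADATION = 0.05
BENCHMARK_STRENGTH = 0.1


def motif_edges(kind: str, genes: tuple[int, ...]) -> list[tuple[int, int]]:
    """Directed edges (regulator, target) realizing a named motif (1-based)."""
    if kind == "loop":
        return [(genes[k], genes[(k + 1) % len(genes)]) for k in range(len(genes))]
    if kind == "feedforward":
        chain = [(genes[k], genes[k + 1]) for k in range(len(genes) - 1)]
        return chain + [(genes[0], genes[-1])]
    if kind == "central":
        return [(genes[0], g) for g in genes[1:]]
    raise ValueError(f"unknown motif kind {kind!r}")


def build_benchmark_network(seed: int) -> KineticNetwork:
    """The 6-gene / 4-stage benchmark network.

    Topology realizes the benchmark's per-stage motif lists; every edge strength
    is drawn as +0.1 or -0.1 with the given seed, degradation rates are all
    0.05, initial expression is 1.0 and the stage spans are (20, 30, 20, 30).
    """
    rng = np.random.default_rng(seed)
    p = 6
    gene_ids = [f"G{k}" for k in range(1, p + 1)]
    stages = [StageSpec(lab, span) for lab, span in zip(BENCHMARK_MOTIFS, BENCHMARK_SPANS)]
    strengths = []
    for lab in BENCHMARK_MOTIFS:
        b = np.zeros((p, p))
        edges: set[tuple[int, int]] = set()
        for kind, genes in BENCHMARK_MOTIFS[lab]:
            edges.update(motif_edges(kind, genes))
        for reg, tgt in sorted(edges):
            b[tgt - 1, reg - 1] = BENCHMARK_STRENGTH * rng.choice([1.0, -1.0])
        strengths.append(b)
    return KineticNetwork(
        gene_ids=gene_ids,
        stages=stages,
        strengths=strengths,
        degradation=np.full(p, BENCHMARK_DEGRADATION),
        initial_state=np.ones(p),
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _rk4_step(a: np.ndarray, x: np.ndarray, dt: float) -> np.ndarray:
    k1 = a @ x
    k2 = a @ (x + 0.5 * dt * k1)
    k3 = a @ (x + 0.5 * dt * k2)
    k4 = a @ (x + dt * k3)
    return x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate(net: KineticNetwork, dt: float = 0.01) -> TimeCourse:
    """Integrate the piecewise-linear kinetics with RK4 at fixed step ``dt``.

    The per-stage strength matrix switches at stage boundaries while the
    state is carried over unchanged, so profiles are continuous across the
    whole process.  Samples are recorded at each stage's configured cadence,
    at the start of every sampling interval.
    """
    times: list[float] = []
    cols: list[np.ndarray] = []
    stage_idx: list[int] = []

    x = net.initial_state.copy()
    t0 = 0.0
    for s, spec in enumerate(net.stages):
        n_steps = int(round(spec.time_span / dt))
        if abs(n_steps * dt - spec.time_span) > 1e-9:
            raise ValueError(f"dt={dt} does not divide the span of stage {spec.label!r}")
        a = -np.diag(net.degradation) + net.strengths[s]
        record_every = int(round(1.0 / (spec.samples_per_unit_time * dt)))
        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(n_steps):
                if k % record_every == 0:
                    times.append(t0 + k * dt)
                    cols.append(x.copy())
                    stage_idx.append(s)
                x = _rk4_step(a, x, dt)
                if not np.all(np.isfinite(x)):
                    bad_t = t0 + (k + 1) * dt
                    raise IntegrationError(
                        f"non-finite state at t={bad_t:.6g} (stage {spec.label!r})"
                    )
        t0 += spec.time_span

    return TimeCourse(
        gene_ids=list(net.gene_ids),
        stage_labels=[s.label for s in net.stages],
        times=np.array(times),
        values=np.column_stack(cols),
        stage_of_timepoint=np.array(stage_idx),
    )


def to_sample_based(tc: TimeCourse, seed: int) -> StagedExpressionData:
    """Scramble each stage's timepoints into unordered, stage-labelled samples."""
    rng = np.random.default_rng(seed)
    matrices = []
    for s, lab in enumerate(tc.stage_labels):
        cols = tc.stage_columns(s)
        if cols.size < 2:
            raise ValueError(f"stage {lab!r} has fewer than 2 timepoints")
        perm = rng.permutation(cols.size)
        matrices.append(tc.values[:, cols[perm]])
    return StagedExpressionData(list(tc.gene_ids), list(tc.stage_labels), matrices)


def add_noise(
    data: StagedExpressionData, noise_to_signal: float, seed: int
) -> StagedExpressionData:
    """Corrupt the data with additive Gaussian noise.

    The noise sd for gene *i* is ``noise_to_signal`` times gene *i*'s
    empirical sd across all stages pooled, so a gene with no signal
    variation receives no noise.
    """
    if noise_to_signal < 0:
        raise ValueError("noise_to_signal must be >= 0")
    out = data.copy()
    if noise_to_signal == 0:
        return out
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(data.matrices, axis=1)
    sd = pooled.std(axis=1, ddof=0)
    for m in out.matrices:
        m += rng.standard_normal(m.shape) * (noise_to_signal * sd)[:, None]
    return out
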