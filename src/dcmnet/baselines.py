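"""Static (steady-state) and dynamic (time-course) comparator methods.

The static method assumes every gene is at steady state within a stage, so
the kinetic balance 0 = -deg_i x_i + sum_j beta_ij x_j reduces (after
dividing by deg_i > 0, which preserves signs) to an L1 regression of each
gene on the others within each stage.  The dynamic method uses the time
course directly: per stage it estimates dx_i/dt by finite differences and
L1-regresses the derivative on all genes' expression levels, the
self-coefficient recovering minus the turnover rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DCMConfig, InferredStageNetworks, select_sparsity_cv
from .simulate import StagedExpressionData, TimeCourse

__all__ = ["BaselineConfig", "static_infer", "dynamic_infer"]


@dataclass
class BaselineConfig:
    """Fitting parameters shared by the two comparator methods."""

    cv_folds: int = 5
    n_penalties: int = 50
    penalty_eps: float = 1e-3
    penalty_grid: tuple[float, ...] | None = None
    n_repetitions: int = 100
    group_size: int = 16
    top_k_edges: int | str = "cv"
    seed: int = 0
    derivative_scheme: str = "central"

    def _as_dcm(self) -> DCMConfig:
        return DCMConfig(
            cv_folds=self.cv_folds,
            n_penalties=self.n_penalties,
            penalty_eps=self.penalty_eps,
            penalty_grid=self.penalty_grid,
            n_repetitions=self.n_repetitions,
            group_size=self.group_size,
            top_k_edges=self.top_k_edges,
            seed=self.seed,
        )


def _fit_stage_lasso(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: DCMConfig,
    rng: np.random.Generator,
    include_self: bool,
) -> np.ndarray:
    """Per-gene L1 fits of response rows Y on predictor rows X (genes x n).

    Returns the (P, P) coefficient matrix; with ``include_self`` the
    diagonal carries the self-coefficient, otherwise it is excluded from
    the design and fixed at zero.
    """
    p, n = X.shape
    coefs = np.zeros((p, p))
    if not np.any(X - X.mean(axis=1, keepdims=True)):
        warnings.warn("no predictor variance in stage: returning an empty network")
        return coefs
    rows = np.arange(n)
    for i in range(p):
        pred = np.arange(p) if include_self else np.array([j for j in range(p) if j != i])
        Z = X[pred].T
        y = Y[i]
        _, coef = select_sparsity_cv(Z, y, rows, cfg, rng)
        coefs[i, pred] = coef
    return coefs


def static_infer(
    data: StagedExpressionData, cfg: BaselineConfig | None = None
) -> InferredStageNetworks:
    """Steady-state inference on stage-labelled sample data.

    Per repetition, each stage's samples are subsampled (``group_size``
    drawn without replacement, mirroring the cascaded method's bootstrap)
    and each gene is L1-regressed on the others with CV-selected sparsity;
    repetitions are aggregated into mean coefficients and edge confidences.
    """
    cfg = cfg or BaselineConfig()
    if any(n < 3 for n in data.samples_per_stage):
        raise ValueError("static inference needs >= 3 samples per stage")
    # canonical within-stage sample order: results do not depend on the
    # (meaningless) column order of the input
    data = data.copy()
    for m in data.matrices:
        m[:] = m[:, np.lexsort(m)]
    dcm_cfg = cfg._as_dcm()
    p, n_stages = data.n_genes, data.n_stages
    reps = cfg.n_repetitions
    children = np.random.SeedSequence(cfg.seed).spawn(reps)

    rep_coefs = np.zeros((reps, n_stages, p, p))
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        for s in range(n_stages):
            n_s = data.matrices[s].shape[1]
            take = min(cfg.group_size, n_s)
            idx = rng.choice(n_s, size=take, replace=False)
            X = data.matrices[s][:, idx]
            rep_coefs[r, s] = _fit_stage_lasso(X, X, dcm_cfg, rng, include_self=False)

    rep_supports = rep_coefs != 0
    if cfg.top_k_edges != "cv":
        from .core import _binarize

        rep_supports = np.stack(
            [_binarize(rep_coefs[r], cfg.top_k_edges) for r in range(reps)]
        )
    return InferredStageNetworks(
        gene_ids=list(data.gene_ids),
        stage_labels=list(data.stage_labels),
        coefficients=rep_coefs.mean(axis=0),
        confidence=rep_supports.mean(axis=0),
        rep_coefficients=rep_coefs,
        rep_supports=rep_supports,
        metadata={"method": "static", "seed": cfg.seed, "n_repetitions": reps},
    )


def _stage_derivatives(times: np.ndarray, values: np.ndarray, scheme: str) -> np.ndarray:
    """dx/dt within one stage, never across a boundary.

    ``central``: second-order central differences, one-sided at the stage
    edges, divided differences on non-uniform grids.  ``spline``: derivative
    of a cubic interpolating spline, slightly more accurate on smooth
    noiseless profiles.
    """
    if times.size < 3:
        raise ValueError("a stage needs >= 3 timepoints for derivative estimation")
    if scheme == "central":
        return np.gradient(values, times, axis=1)
    if scheme == "spline":
        from scipy.interpolate import CubicSpline

        return np.stack([CubicSpline(times, row)(times, 1) for row in values])
    raise ValueError("derivative_scheme must be 'central' or 'spline'")


def dynamic_infer(tc: TimeCourse, cfg: BaselineConfig | None = None) -> InferredStageNetworks:
    """Time-course inference: L1 regression of dx/dt on expression levels.

    Derivatives are estimated per stage (never across a stage boundary) by
    central differences, one-sided at stage edges, handling non-uniform
    grids by divided differences.  The fitted self-coefficient estimates
    minus the degradation rate; off-diagonal coefficients form the per-stage
    network.  The fit is deterministic given the time course, so the
    returned confidence is the binary support of the single fit.
    """
    cfg = cfg or BaselineConfig()
    dcm_cfg = cfg._as_dcm()
    p = len(tc.gene_ids)
    n_stages = len(tc.stage_labels)
    rng = np.random.default_rng(cfg.seed)

    coefs = np.zeros((n_stages, p, p))
    for s in range(n_stages):
        cols = tc.stage_columns(s)
        X = tc.values[:, cols]
        D = _stage_derivatives(tc.times[cols], X, cfg.derivative_scheme)
        full = _fit_stage_lasso(X, D, dcm_cfg, rng, include_self=True)
        coefs[s] = full
    self_coef = np.stack([np.diag(coefs[s]).copy() for s in range(n_stages)])
    for s in range(n_stages):
        np.fill_diagonal(coefs[s], 0.0)

    rep_coefs = coefs[None]
    rep_supports = rep_coefs != 0
    return InferredStageNetworks(
        gene_ids=list(tc.gene_ids),
        stage_labels=list(tc.stage_labels),
        coefficients=coefs,
        confidence=rep_supports[0].astype(float),
        rep_coefficients=rep_coefs,
        rep_supports=rep_supports,
        metadata={
            "method": "dynamic",
            "seed": cfg.seed,
            "self_coefficients": self_coef.tolist(),
        },
    )
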