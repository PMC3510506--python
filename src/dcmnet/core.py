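"""Dynamic cascaded network inference.

The cascaded model links consecutive stages of a progression: under the
intra-stage steady-rate and continuity assumptions, the expression of gene
*i* at the same relative position ("fraction" f) of two consecutive stages
satisfies a linear relation

    q_i^{s+1}(f) = rho * q_i^{s}(f) + sum_{j != i} b_ij * q_j^{s}(f)

where rho in (-1, 1) is the inter-stage influence coefficient (a monotone
function of the turnover rate and the stage duration, treated here as a
shared hyperparameter) and the b_ij are sign-preserving monotone transforms
of the regulatory strengths.  Because sample-based data carry no within-
stage time order, q_i^s(f) is estimated by an empirical quantile of stage
s's samples — the f-quantile when the gene ascends in that stage, the
(1-f)-quantile when it descends.  Fractions outside [0, 1] extrapolate the
chord through the extreme order statistics and anchor the fit's linearity
beyond the stage ends.

Equations are generated over bootstrap subsamples and several fraction
settings, fitted per (gene, stage) family by L1-penalized regression with
cross-validated sparsity, and aggregated over independent repetitions into
per-stage coefficient and edge-confidence matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .simulate import StagedExpressionData
from .trends import ASCENDING, TrendAssignment, estimate_trends

__all__ = [
    "FractionConfig",
    "DCMConfig",
    "EquationFamily",
    "DCMEquationSet",
    "InferredStageNetworks",
    "stage_quantile",
    "build_equations",
    "fit_sparse_path",
    "select_sparsity_cv",
    "infer",
    "threshold_network",
]


@dataclass(frozen=True)
class FractionConfig:
    """Fraction settings of the cascaded equations.

    ``interpolation_fractions`` are the within-stage check-points (0 = stage
    start, 1 = stage end); ``head_extrapolation`` and ``tail_extrapolation``
    are the distances of the two out-of-stage linearity anchors, i.e. the
    equations are additionally evaluated at f = -head and f = 1 + tail.
    """

    interpolation_fractions: tuple[float, ...] = (0.0, 0.5, 1.0)
    head_extrapolation: float = 4.0
    tail_extrapolation: float = 4.0

    def __post_init__(self) -> None:
        fr = tuple(self.interpolation_fractions)
        if not fr:
            raise ValueError("at least one interpolation fraction is required")
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("interpolation fractions must lie in [0, 1]")
        if list(fr) != sorted(fr):
            raise ValueError("interpolation fractions must be sorted")
        if self.head_extrapolation <= 0 or self.tail_extrapolation <= 0:
            raise ValueError("extrapolation distances must be > 0")

    @property
    def settings(self) -> np.ndarray:
        """All fraction settings: head anchor, interpolations, tail anchor."""
        return np.array(
            [-self.head_extrapolation, *self.interpolation_fractions, 1.0 + self.tail_extrapolation]
        )


@dataclass
class DCMConfig:
    """Tunable parameters of the cascaded inference.

    rho: inter-stage influence coefficient, fixed across genes, in (-1, 1).
    n_bootstrap_groups: bootstrap groups per repetition.
    group_size: samples per bootstrap group (drawn without replacement).
    cv_folds: cross-validation folds (stratified by bootstrap group).
    n_penalties / penalty_eps: geometric L1 penalty grid, from the smallest
        penalty that zeroes all coefficients down by the factor ``penalty_eps``;
        an explicit descending ``penalty_grid`` overrides it.
    n_repetitions: independent bootstrap-and-fit repetitions pooled into the
        edge confidence.
    top_k_edges: per-repetition edge binarization — "cv" keeps the
        CV-selected support, an integer keeps the k strongest edges per stage.
    """

    rho: float = 0.6
    n_bootstrap_groups: int = 200
    group_size: int = 16
    cv_folds: int = 5
    penalty_grid: tuple[float, ...] | None = None
    n_penalties: int = 50
    penalty_eps: float = 1e-3
    n_repetitions: int = 100
    top_k_edges: int | str = "cv"
    seed: int = 0
    discretization: str = "forward"
    trend_method: str = "dp_continuity"
    trend_trim: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly between -1 and 1")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.n_bootstrap_groups < 1 or self.n_repetitions < 1 or self.cv_folds < 2:
            raise ValueError("counts must be positive (cv_folds >= 2)")
        if self.discretization not in ("forward", "trapezoid"):
            raise ValueError("discretization must be 'forward' or 'trapezoid'")
        if self.top_k_edges != "cv" and int(self.top_k_edges) < 1:
            raise ValueError("top_k_edges must be 'cv' or a positive integer")
        if self.penalty_grid is not None:
            grid = tuple(float(a) for a in self.penalty_grid)
            if any(a <= 0 for a in grid) or list(grid) != sorted(grid, reverse=True):
                raise ValueError("penalty_grid must be descending positive reals")
            self.penalty_grid = grid


# ---------------------------------------------------------------------------
# Quantile estimation
# ---------------------------------------------------------------------------

def stage_quantile(samples: np.ndarray, fraction: float, direction: int) -> float:
    """Expression at fraction ``fraction`` of a stage, from unordered samples.

    Uses the empirical quantile with linear interpolation between order
    statistics at plotting positions (k-1)/(n-1): the ``fraction``-quantile
    for an ascending gene, the ``1-fraction``-quantile for a descending one.
    Fractions outside [0, 1] extend the chord through the direction-adjusted
    extreme order statistics: value(f) = Q(0) + f * (Q(1) - Q(0)).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("stage_quantile needs at least 2 samples")
    srt = np.sort(samples)
    if direction != ASCENDING:
        srt = srt[::-1]
    if 0.0 <= fraction <= 1.0:
        pos = fraction * (srt.size - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        w = pos - lo
        return float((1 - w) * srt[lo] + w * srt[hi])
    a, b = srt[0], srt[-1]
    return float(a + fraction * (b - a))


def _group_quantiles(
    sorted_groups: np.ndarray, fractions: np.ndarray, ascending_mask: np.ndarray
) -> np.ndarray:
    """Vectorized ``stage_quantile`` over bootstrap groups.

    sorted_groups: (P, G, n) ascending-sorted subsample values.
    ascending_mask: (P,) True where the gene ascends in this stage.
    Returns (P, G, F).
    """
    adj = np.where(ascending_mask[:, None, None], sorted_groups, sorted_groups[:, :, ::-1])
    n = adj.shape[-1]
    out = np.empty(adj.shape[:2] + (fractions.size,))
    for k, f in enumerate(fractions):
        if 0.0 <= f <= 1.0:
            pos = f * (n - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            w = pos - lo
            out[..., k] = (1 - w) * adj[..., lo] + w * adj[..., hi]
        else:
            out[..., k] = adj[..., 0] + f * (adj[..., -1] - adj[..., 0])
    return out


# ---------------------------------------------------------------------------
# Equation building
# ---------------------------------------------------------------------------

@dataclass
class EquationFamily:
    """Regression rows owned by one (target gene, stage) pair."""

    gene: int
    stage: int
    predictor_genes: np.ndarray  # column j of Z corresponds to this gene index
    y: np.ndarray  # (n_rows,)
    Z: np.ndarray  # (n_rows, P-1)
    groups: np.ndarray  # bootstrap group id per row
    fractions: np.ndarray  # fraction setting per row


@dataclass
class DCMEquationSet:
    """All equation families of one bootstrap repetition."""

    gene_ids: list[str]
    stage_labels: list[str]
    families: dict[tuple[int, int], EquationFamily]

    def family(self, gene: int, stage: int) -> EquationFamily:
        return self.families[(gene, stage)]

    @property
    def n_rows(self) -> int:
        return sum(f.y.size for f in self.families.values())

    def rows_per_family(self) -> int:
        sizes = {f.y.size for f in self.families.values()}
        if len(sizes) != 1:
            raise ValueError("families have unequal row counts")
        return sizes.pop()


def build_equations(
    data: StagedExpressionData,
    trends: TrendAssignment,
    fc: FractionConfig,
    cfg: DCMConfig,
    seed: int | np.random.Generator,
) -> DCMEquationSet:
    """Generate the cascaded model equations for one bootstrap repetition.

    For every bootstrap group (an independent without-replacement subsample
    of ``group_size`` samples per gene per stage) and every fraction setting,
    each stage s with a successor contributes, per gene i, a row

        y = q_i^{s+1}(f) - rho * q_i^{s}(f),   z_j = q_j^{s}(f)  (j != i)

    attributed to stage s; the terminal stage owns the backward family
    y = q_i^{S-1}(f) - rho * q_i^{S-2}(f) with stage S-1 predictors, so every
    stage has an equation family.  With ``discretization="trapezoid"`` the
    predictors average the two stages' quantiles.
    """
    if data.n_stages < 2:
        raise ValueError("DCM requires >= 2 stages")
    if trends.directions.shape != (data.n_genes, data.n_stages):
        raise ValueError("trend assignment does not match the data")
    for lab, n in zip(data.stage_labels, data.samples_per_stage):
        if cfg.group_size > n:
            raise ValueError(f"group_size {cfg.group_size} exceeds stage {lab!r} size {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p, n_stages = data.n_genes, data.n_stages
    n_groups, gsize = cfg.n_bootstrap_groups, cfg.group_size
    fracs = fc.settings
    n_f = fracs.size

    # q[s]: (P, G, F) quantiles of each gene's own subsample per group
    q = []
    for s in range(n_stages):
        n_s = data.matrices[s].shape[1]
        # without-replacement subsample per (gene, group) via argpartition of
        # uniform keys — equivalent to a seeded random subset
        keys = rng.random((p, n_groups, n_s))
        idx = np.argpartition(keys, gsize - 1, axis=-1)[..., :gsize]
        vals = data.matrices[s][np.arange(p)[:, None, None], idx]
        vals.sort(axis=-1)
        q.append(_group_quantiles(vals, fracs, trends.directions[:, s] == ASCENDING))

    group_col = np.repeat(np.arange(n_groups), n_f)
    frac_col = np.tile(fracs, n_groups)

    families: dict[tuple[int, int], EquationFamily] = {}
    for s in range(n_stages):
        if s < n_stages - 1:
            pred_s, resp_hi, resp_lo = s, s + 1, s
        else:  # terminal stage: backward contrast, own-stage predictors
            pred_s, resp_hi, resp_lo = s, s, s - 1
        if cfg.discretization == "trapezoid":
            other = resp_hi if s < n_stages - 1 else resp_lo
            z_all = 0.5 * (q[pred_s] + q[other])
        else:
            z_all = q[pred_s]
        for i in range(p):
            predictors = np.array([j for j in range(p) if j != i])
            y = (q[resp_hi][i] - cfg.rho * q[resp_lo][i]).ravel()
            z = z_all[predictors].transpose(1, 2, 0).reshape(-1, p - 1)
            families[(i, s)] = EquationFamily(
                gene=i,
                stage=s,
                predictor_genes=predictors,
                y=y,
                Z=z,
                groups=group_col.copy(),
                fractions=frac_col.copy(),
            )
    return DCMEquationSet(list(data.gene_ids), list(data.stage_labels), families)


# ---------------------------------------------------------------------------
# Sparse fitting
# ---------------------------------------------------------------------------

def _penalty_grid(zc: np.ndarray, yc: np.ndarray, cfg: DCMConfig) -> np.ndarray:
    if cfg.penalty_grid is not None:
        return np.asarray(cfg.penalty_grid, dtype=float)
    n = yc.size
    alpha_max = np.max(np.abs(zc.T @ yc)) / n
    if alpha_max <= 0:
        return np.array([])
    return np.geomspace(alpha_max, alpha_max * cfg.penalty_eps, cfg.n_penalties)


def fit_sparse_path(
    Z: np.ndarray, y: np.ndarray, penalties: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """L1 coefficient path min_b ||y - Zb||^2 / (2n) + penalty * ||b||_1.

    ``Z`` and ``y`` are centered internally (family-level intercept).
    Returns (penalties, coefs) with ``coefs`` of shape (n_predictors,
    n_penalties).  A degenerate design (no predictor variance) yields an
    all-zero path with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("at least 2 rows are required")
    zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    penalties = np.asarray(penalties, dtype=float)
    if penalties.size == 0 or not np.any(zc):
        warnings.warn("degenerate design: returning an all-zero coefficient path")
        grid = penalties if penalties.size else np.array([1.0])
        return grid, np.zeros((Z.shape[1], grid.size))
    coefs = _lasso_path(zc, yc, penalties)
    return penalties, coefs


def _lasso_path(zc: np.ndarray, yc: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Coordinate-descent L1 path; residual convergence chatter is silenced
    (the smallest penalties on near-collinear designs converge slowly but the
    attained duality gaps are immaterial for edge ranking)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(zc, yc, alphas=grid, max_iter=5000, tol=1e-6)
    return coefs


def _cv_folds_by_group(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Row-index folds that never split a bootstrap group across folds."""
    uniq = np.unique(groups)
    if uniq.size < n_folds:
        warnings.warn(
            f"only {uniq.size} bootstrap groups for {n_folds} folds; reducing folds"
        )
        n_folds = max(2, uniq.size)
    order = rng.permutation(uniq)
    assign = {g: k % n_folds for k, g in enumerate(order)}
    fold_of_row = np.array([assign[g] for g in groups])
    return [np.flatnonzero(fold_of_row == k) for k in range(n_folds)]


def select_sparsity_cv(
    Z: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cfg: DCMConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the L1 penalty by group-stratified K-fold CV and refit on all rows.

    The penalty minimizing the mean held-out squared error wins; ties go to
    the larger penalty (sparser model).  Returns (penalty, coefficients).
    """
    rng = rng or np.random.default_rng(0)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    grid = _penalty_grid(zc, yc, cfg)
    if grid.size == 0:
        warnings.warn("degenerate design: selecting the empty model")
        return 1.0, np.zeros(Z.shape[1])

    folds = _cv_folds_by_group(np.asarray(groups), cfg.cv_folds, rng)
    err = np.zeros((len(folds), grid.size))
    for k, test_idx in enumerate(folds):
        mask = np.ones(y.size, dtype=bool)
        mask[test_idx] = False
        z_tr, y_tr = Z[mask], y[mask]
        zm, ym = z_tr.mean(axis=0), y_tr.mean()
        coefs = _lasso_path(z_tr - zm, y_tr - ym, grid)
        pred = (Z[test_idx] - zm) @ coefs + ym
        err[k] = np.mean((pred - y[test_idx, None]) ** 2, axis=0)
    best = int(np.argmin(err.mean(axis=0)))  # grid is descending: first min = sparser
    coefs = _lasso_path(zc, yc, grid)
    return float(grid[best]), coefs[:, best]


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

@dataclass
class InferredStageNetworks:
    """Per-stage inferred networks with bootstrap edge confidences.

    ``coefficients[s][i, j]`` is the mean inferred influence of gene j on
    gene i in stage s; ``confidence[s][i, j]`` is the fraction of
    repetitions whose binarized network contained the edge j -> i.  The
    per-repetition coefficient matrices and supports are retained for
    recounting and per-repetition scoring.
    """

    gene_ids: list[str]
    stage_labels: list[str]
    coefficients: np.ndarray  # (S, P, P)
    confidence: np.ndarray  # (S, P, P) in [0, 1]
    rep_coefficients: np.ndarray  # (R, S, P, P)
    rep_supports: np.ndarray  # (R, S, P, P) boolean
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValueError("confidences must lie in [0, 1]")
        for s in range(len(self.stage_labels)):
            if np.any(np.diagonal(self.coefficients[s]) != 0):
                raise ValueError("coefficient diagonals must be zero")

    @property
    def n_repetitions(self) -> int:
        return self.rep_coefficients.shape[0]


def _binarize(coefs: np.ndarray, top_k: int | str) -> np.ndarray:
    """Per-stage edge support from a (S, P, P) coefficient array."""
    if top_k == "cv":
        return coefs != 0
    k = int(top_k)
    s_count, p, _ = coefs.shape
    support = np.zeros_like(coefs, dtype=bool)
    for s in range(s_count):
        edges = _ranked_edges(np.abs(coefs[s]), np.abs(coefs[s]))
        for reg, tgt in edges[:k]:
            support[s, tgt, reg] = True
    return support


def _ranked_edges(primary: np.ndarray, secondary: np.ndarray) -> list[tuple[int, int]]:
    """Off-diagonal edges (reg, tgt) ranked by primary desc, secondary desc,
    then lexicographic (reg, tgt)."""
    p = primary.shape[0]
    edges = [(j, i) for i in range(p) for j in range(p) if i != j]
    return sorted(edges, key=lambda e: (-primary[e[1], e[0]], -secondary[e[1], e[0]], e))


def infer(
    data: StagedExpressionData,
    fc: FractionConfig | None = None,
    cfg: DCMConfig | None = None,
    trends: TrendAssignment | None = None,
) -> InferredStageNetworks:
    """Run the full cascaded inference on stage-labelled sample data.

    Performs ``cfg.n_repetitions`` independent repetitions of the bootstrap →
    equation → L1-with-CV pipeline, binarizes each repetition's networks, and
    aggregates coefficients (mean) and edge confidences (occurrence
    frequency).  Deterministic under a fixed ``cfg.seed``.
    """
    fc = fc or FractionConfig()
    cfg = cfg or DCMConfig()
    if trends is None:
        trends = estimate_trends(data, method=cfg.trend_method, trim=cfg.trend_trim)

    p, n_stages = data.n_genes, data.n_stages
    reps = cfg.n_repetitions
    children = np.random.SeedSequence(cfg.seed).spawn(reps)

    rep_coefs = np.zeros((reps, n_stages, p, p))
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        eqs = build_equations(data, trends, fc, cfg, rng)
        for (i, s), fam in eqs.families.items():
            _, coef = select_sparsity_cv(fam.Z, fam.y, fam.groups, cfg, rng)
            rep_coefs[r, s, i, fam.predictor_genes] = coef

    rep_supports = np.stack([_binarize(rep_coefs[r], cfg.top_k_edges) for r in range(reps)])
    return InferredStageNetworks(
        gene_ids=list(data.gene_ids),
        stage_labels=list(data.stage_labels),
        coefficients=rep_coefs.mean(axis=0),
        confidence=rep_supports.mean(axis=0),
        rep_coefficients=rep_coefs,
        rep_supports=rep_supports,
        metadata={
            "method": "dcm",
            "seed": cfg.seed,
            "rho": cfg.rho,
            "n_repetitions": reps,
            "group_size": cfg.group_size,
            "n_bootstrap_groups": cfg.n_bootstrap_groups,
        },
    )


def threshold_network(
    nets: InferredStageNetworks, mode: str, value: float | int
) -> dict[str, list[tuple[str, str, float, float]]]:
    """Restore per-stage edge lists from the aggregated networks.

    ``mode="confidence"`` keeps edges with confidence >= ``value``;
    ``mode="top_k"`` keeps the ``value`` highest-confidence edges per stage
    (ties broken by |coefficient|, then lexicographic gene pair).  Returns
    ``{stage_label: [(regulator, target, coefficient, confidence), ...]}``.
    """
    p = len(nets.gene_ids)
    out: dict[str, list[tuple[str, str, float, float]]] = {}
    for s, lab in enumerate(nets.stage_labels):
        conf, coef = nets.confidence[s], nets.coefficients[s]
        if mode == "confidence":
            kept = [(j, i) for i in range(p) for j in range(p) if i != j and conf[i, j] >= value]
            kept.sort(key=lambda e: (-conf[e[1], e[0]], -abs(coef[e[1], e[0]]), e))
        elif mode == "top_k":
            k = int(value)
            if k > p * (p - 1):
                warnings.warn(f"top_k {k} exceeds the {p * (p - 1)} possible edges; keeping all")
                k = p * (p - 1)
            kept = _ranked_edges(conf, np.abs(coef))[:k]
        else:
            raise ValueError("mode must be 'confidence' or 'top_k'")
        out[lab] = [
            (nets.gene_ids[j], nets.gene_ids[i], float(coef[i, j]), float(conf[i, j]))
            for j, i in kept
        ]
    return out
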