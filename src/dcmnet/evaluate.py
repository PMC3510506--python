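"""Scoring of inferred networks and known-interaction enrichment.

Network recovery is scored as a ranking problem over the universe of
ordered non-self gene pairs: ROC/AUC via the Mann-Whitney statistic with
midrank tie handling, a Z-score against the chance level using the
Hanley-McNeil null standard error, and binary F2 / Matthews correlation
once a hard edge set is chosen.  Enrichment of a predicted edge set in a
catalogue of known interactions is the ratio of the hit proportion to the
baseline proportion, with a hypergeometric upper-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import InferredStageNetworks
from .simulate import KineticNetwork

__all__ = [
    "MetricsReport",
    "EnrichmentResult",
    "roc_auc",
    "rank_auc",
    "pooled_auc",
    "auc_significance",
    "binary_metrics",
    "enrichment",
    "evaluate_networks",
]

Edge = tuple[str, str]


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of ``scores`` ranking positive ``labels``, midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined without both positive and negative instances")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(threshold, fpr, tpr) rows at every distinct score, descending."""
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    n_pos = lab.sum()
    n_neg = lab.size - n_pos
    tp = np.cumsum(lab)
    fp = np.cumsum(~lab)
    last = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    rows = [(np.inf, 0.0, 0.0)]
    rows += [(s[k], fp[k] / n_neg, tp[k] / n_pos) for k in last]
    return np.array(rows)


def roc_auc(
    edge_scores: dict[Edge, float], truth: set[Edge], universe: set[Edge]
) -> tuple[float, np.ndarray]:
    """AUC and ROC points for scored edges against a truth edge set.

    Edges of the universe missing from ``edge_scores`` score 0.  Truth is
    membership of the (directed) truth set; the sign of an interaction is
    not part of the task.  Raises if truth is empty or covers the universe.
    """
    if not truth or truth == universe:
        raise ValueError("AUC is undefined for an empty or complete truth set")
    if not truth <= universe:
        raise ValueError("truth must be a subset of the universe")
    edges = sorted(universe)
    scores = np.array([edge_scores.get(e, 0.0) for e in edges])
    labels = np.array([e in truth for e in edges])
    return rank_auc(scores, labels), _roc_points(scores, labels)


def _stage_scores_labels(
    score: np.ndarray, truth_edges: set[tuple[int, int]], p: int
) -> tuple[np.ndarray, np.ndarray]:
    off = ~np.eye(p, dtype=bool)
    truth = np.zeros((p, p), dtype=bool)
    for reg, tgt in truth_edges:
        truth[tgt, reg] = True
    return score[off], truth[off]


def pooled_auc(
    score_matrices: np.ndarray, net: KineticNetwork
) -> float:
    """AUC pooled over all stages' edge instances.

    ``score_matrices`` is (S, P, P) with entry [s, i, j] the score of the
    candidate edge j -> i in stage s; truth is the simulator's per-stage
    edge set (direction respected, sign ignored).
    """
    p = net.n_genes
    scores, labels = [], []
    for s in range(net.n_stages):
        sc, lb = _stage_scores_labels(score_matrices[s], net.true_edges(s), p)
        scores.append(sc)
        labels.append(lb)
    return rank_auc(np.concatenate(scores), np.concatenate(labels))


def auc_significance(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Z-score and two-sided p-value of an AUC against the chance level 0.5.

    Uses the Hanley-McNeil standard error under the null AUC = 0.5, which
    reduces to the Wilcoxon null sd sqrt((n_pos + n_neg + 1) / (12 n+ n-)).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    se = np.sqrt((n_pos + n_neg + 1) / (12.0 * n_pos * n_neg))
    z = (auc - 0.5) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def binary_metrics(
    predicted: set, truth: set, universe: set
) -> tuple[float, float]:
    """(F2, MCC) of a hard edge prediction over a fixed universe.

    F_beta with beta = 2 weights recall over precision; MCC uses the
    determinant formula and is defined as 0 when any confusion marginal is
    zero.
    """
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth must be subsets of the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    beta2 = 4.0
    denom_f = (1 + beta2) * tp + beta2 * fn + fp
    f2 = (1 + beta2) * tp / denom_f if denom_f > 0 else 0.0
    denom_m = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom_m) if denom_m > 0 else 0.0
    return float(f2), float(mcc)


@dataclass
class EnrichmentResult:
    """Enrichment of a predicted edge set in a known-interaction catalogue."""

    n_predicted: int
    n_known_hits: int
    universe_size: int
    n_known: int
    baseline: float
    ratio: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def enrichment(
    predicted: set[Edge],
    known: set[Edge],
    n_genes: int,
    directed: bool = False,
) -> EnrichmentResult:
    """Known-interaction enrichment of a predicted edge set.

    The universe is the n_genes * (n_genes - 1) ordered non-self pairs.  The
    baseline is the proportion of known interactions a random guess would
    hit, ``|known| / |universe|``; the enrichment ratio divides the observed
    hit proportion by that baseline.  By default a predicted edge matches a
    known interaction in either orientation (interaction catalogues are
    undirected); ``directed=True`` requires the exact orientation.  The
    p-value is the hypergeometric upper tail P(X >= hits).
    """
    if not predicted:
        raise ValueError("predicted edge set is empty")
    universe_size = n_genes * (n_genes - 1)
    if directed:
        hits = len(predicted & known)
    else:
        undirected_known = {frozenset(e) for e in known}
        hits = sum(frozenset(e) in undirected_known for e in predicted)
    baseline = len(known) / universe_size
    ratio = (hits / len(predicted)) / baseline if baseline > 0 else 0.0
    p = float(stats.hypergeom.sf(hits - 1, universe_size, len(known), len(predicted)))
    return EnrichmentResult(
        n_predicted=len(predicted),
        n_known_hits=hits,
        universe_size=universe_size,
        n_known=len(known),
        baseline=baseline,
        ratio=ratio,
        p_value=p,
    )


@dataclass
class MetricsReport:
    """Per-stage and pooled recovery metrics, mean +/- sd across repetitions."""

    stage_labels: list[str]
    auc: dict[str, float]
    auc_sd: dict[str, float]
    z: dict[str, float]
    p_value: dict[str, float]
    f2: dict[str, float]
    f2_sd: dict[str, float]
    mcc: dict[str, float]
    mcc_sd: dict[str, float]
    auc_values: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        keys = [*self.stage_labels, "overall"]
        return {
            k: {
                "auc": self.auc[k],
                "auc_sd": self.auc_sd[k],
                "z": self.z[k],
                "p_value": self.p_value[k],
                "f2": self.f2[k],
                "f2_sd": self.f2_sd[k],
                "mcc": self.mcc[k],
                "mcc_sd": self.mcc_sd[k],
            }
            for k in keys
        }


def evaluate_networks(
    nets: InferredStageNetworks, net: KineticNetwork, score: str = "coefficient"
) -> MetricsReport:
    """Score inferred stage networks against the simulator ground truth.

    AUC is computed per repetition from that repetition's edge scores
    (``score="coefficient"``: |fitted coefficient|; ``score="confidence"``:
    the aggregated confidence matrix, one deterministic value) and averaged;
    F2 and MCC use each repetition's binarized support.  The "overall" entry
    pools all stages' edge instances.
    """
    p = net.n_genes
    labels = nets.stage_labels
    keys = [*labels, "overall"]
    aucs: dict[str, list[float]] = {k: [] for k in keys}
    f2s: dict[str, list[float]] = {k: [] for k in keys}
    mccs: dict[str, list[float]] = {k: [] for k in keys}

    off = ~np.eye(p, dtype=bool)
    truth_mats = []
    for s in range(net.n_stages):
        t = np.zeros((p, p), dtype=bool)
        for reg, tgt in net.true_edges(s):
            t[tgt, reg] = True
        truth_mats.append(t)

    if score == "confidence":
        score_sets = [nets.confidence]
        support_sets = [nets.confidence >= 0.5]
    elif score == "coefficient":
        score_sets = list(np.abs(nets.rep_coefficients))
        support_sets = list(nets.rep_supports)
    else:
        raise ValueError("score must be 'coefficient' or 'confidence'")

    for sc, sup in zip(score_sets, support_sets):
        pooled_scores, pooled_labels = [], []
        for s, lab in enumerate(labels):
            svec, lvec = sc[s][off], truth_mats[s][off]
            aucs[lab].append(rank_auc(svec, lvec))
            pvec = sup[s][off]
            f2, mcc = _confusion_f2_mcc(pvec, lvec)
            f2s[lab].append(f2)
            mccs[lab].append(mcc)
            pooled_scores.append(svec)
            pooled_labels.append(lvec)
        all_s = np.concatenate(pooled_scores)
        all_l = np.concatenate(pooled_labels)
        aucs["overall"].append(rank_auc(all_s, all_l))
        all_p = np.concatenate([sup[s][off] for s in range(len(labels))])
        f2, mcc = _confusion_f2_mcc(all_p, all_l)
        f2s["overall"].append(f2)
        mccs["overall"].append(mcc)

    n_edges_stage = p * (p - 1)
    mean = {k: float(np.mean(aucs[k])) for k in keys}
    z, pv = {}, {}
    for s, lab in enumerate(labels):
        n_pos = int(truth_mats[s].sum())
        z[lab], pv[lab] = auc_significance(mean[lab], n_pos, n_edges_stage - n_pos)
    n_pos_all = int(sum(t.sum() for t in truth_mats))
    n_all = n_edges_stage * len(labels)
    z["overall"], pv["overall"] = auc_significance(
        mean["overall"], n_pos_all, n_all - n_pos_all
    )
    return MetricsReport(
        stage_labels=list(labels),
        auc=mean,
        auc_sd={k: float(np.std(aucs[k])) for k in keys},
        z=z,
        p_value=pv,
        f2={k: float(np.mean(f2s[k])) for k in keys},
        f2_sd={k: float(np.std(f2s[k])) for k in keys},
        mcc={k: float(np.mean(mccs[k])) for k in keys},
        mcc_sd={k: float(np.std(mccs[k])) for k in keys},
        auc_values={k: list(map(float, aucs[k])) for k in keys},
    )


def _confusion_f2_mcc(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    beta2 = 4.0
    denom_f = (1 + beta2) * tp + beta2 * fn + fp
    f2 = (1 + beta2) * tp / denom_f if denom_f > 0 else 0.0
    denom_m = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom_m) if denom_m > 0 else 0.0
    return float(f2), float(mcc)
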