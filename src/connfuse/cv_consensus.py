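"""Nested cross-validated classification and consensus extraction.

Outer loop: stratified K-fold (K = 10) repeated over many rounds with
round-specific shuffles.  All data-driven steps -- structural networks,
overlap filtering, jackknife structural features, and the k-support fusion
fit -- are recomputed inside each training fold; the held-out fold only
ever meets the frozen artifacts.  The regularization pair (lambda1,
lambda2) is chosen per training fold by inner stratified CV accuracy over
a mesh grid; features with non-zero fusion coefficients feed an RBF-kernel
SVM (C = 10).  Absolute fusion coefficients are accumulated over every
fold of every round; the top 1% of edges (40 of 4005) are the consensus
connections and the top 10% of regions (9 of 90) incident to them, ranked
by summed incident weight, are the consensus nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectome import EdgeIndex, structural_network
from .fusion_select import (
    EmptySelectionError,
    FusionDesign,
    build_design,
    default_k,
    filter_features,
    fit_fusion,
    subject_structural_features,
)

DEFAULT_GRID = (1.0, 21.0, 41.0, 61.0, 81.0)  # the mesh grid G = 1:20:100


@dataclass
class CvConfig:
    n_folds: int = 10
    n_rounds: int = 100
    svm_c: float = 10.0
    grid: tuple = DEFAULT_GRID
    inner_folds: int = 5
    seed: int = 0
    k: int | None = None  # k-support parameter; None -> 10% of |L|
    fit_tol: float = 1e-6
    fit_max_iter: int = 2000
    penalty: str = "ksupport"
    intermodality: str = "weighted"
    standardize: bool = True
    store_fold_weights: bool = False

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not self.grid:
            raise ValueError("grid must be nonempty")


@dataclass
class CvResult:
    round_metrics: pd.DataFrame  # one row per round
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    summed_abs_w: np.ndarray  # length n_edges, zeros for never-selected edges
    fold_records: pd.DataFrame  # round, fold, lambda1, lambda2, |L|, nonzeros
    fold_weights: list = field(default_factory=list)


def compute_metrics(predictions, labels, scores=None) -> dict:
    """Accuracy / sensitivity / specificity / AUC with patients (+1) as the
    positive class.  AUC is the rank statistic of the decision scores
    (ties averaged); predictions stand in for scores when none are given."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    pos, neg = labels > 0, labels <= 0
    if not (pos.any() and neg.any()):
        raise ValueError("both classes must be present")
    tp = int(np.sum((predictions > 0) & pos))
    tn = int(np.sum((predictions <= 0) & neg))
    fn = int(pos.sum()) - tp
    fp = int(neg.sum()) - tn
    if scores is None:
        scores = predictions.astype(float)
    return {
        "accuracy": (tp + tn) / labels.size,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auc": float(roc_auc_score(pos.astype(int), np.asarray(scores, dtype=float))),
    }


# ---------------------------------------------------------------------------
# consensus extraction


@dataclass
class ConsensusSet:
    connections: np.ndarray  # edge positions, descending score
    connection_scores: np.ndarray
    connection_ability: np.ndarray  # scores normalized to max 1
    nodes: np.ndarray  # region indices (0-based), descending score
    node_scores: np.ndarray
    node_ability: np.ndarray
    edge_index: EdgeIndex


def _top_by_score(scores: np.ndarray, n_top: int) -> np.ndarray:
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:n_top]


def consensus_connections(
    summed_abs_w: np.ndarray,
    top_fraction: float = 0.01,
    edge_index: EdgeIndex | None = None,
) -> ConsensusSet:
    """Top-1% edges by accumulated |w| (exactly 40 of 4005 for 90 regions).

    Boundary ties are broken by edge position, ascending; if fewer than the
    quota of edges have nonzero score the set is padded by that same rule,
    with a warning.
    """
    w = np.asarray(summed_abs_w, dtype=float)
    idx = edge_index or _edge_index_for(w.size)
    n_top = int(round(top_fraction * w.size))
    if int(np.sum(w > 0)) < n_top:
        warnings.warn(
            "fewer nonzero edge scores than the consensus quota; padding by rank",
            stacklevel=2,
        )
    conns = _top_by_score(w, n_top)
    scores = w[conns]
    ability = scores / scores.max() if scores.max() > 0 else scores
    return ConsensusSet(
        connections=conns,
        connection_scores=scores,
        connection_ability=ability,
        nodes=np.array([], dtype=int),
        node_scores=np.array([]),
        node_ability=np.array([]),
        edge_index=idx,
    )


def consensus_nodes(
    cset: ConsensusSet, summed_abs_w: np.ndarray, top_fraction: float = 0.10
) -> ConsensusSet:
    """Top-10% regions (9 of 90) by summed |w| over their incident
    consensus connections; ties broken by region index."""
    w = np.asarray(summed_abs_w, dtype=float)
    idx = cset.edge_index
    node_scores = np.zeros(idx.n_regions)
    pairs = idx.pairs
    for e in cset.connections:
        i, j = pairs[e]
        node_scores[i] += w[e]
        node_scores[j] += w[e]
    n_top = int(round(top_fraction * idx.n_regions))
    nodes = _top_by_score(node_scores, n_top)
    scores = node_scores[nodes]
    ability = scores / scores.max() if scores.max() > 0 else scores
    return ConsensusSet(
        connections=cset.connections,
        connection_scores=cset.connection_scores,
        connection_ability=cset.connection_ability,
        nodes=nodes,
        node_scores=scores,
        node_ability=ability,
        edge_index=idx,
    )


def extract_consensus(
    summed_abs_w: np.ndarray,
    edge_index: EdgeIndex | None = None,
    connection_fraction: float = 0.01,
    node_fraction: float = 0.10,
) -> ConsensusSet:
    cset = consensus_connections(summed_abs_w, connection_fraction, edge_index)
    return consensus_nodes(cset, summed_abs_w, node_fraction)


def _edge_index_for(n_edges: int) -> EdgeIndex:
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n * (n - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a lower-triangle edge count")
    return EdgeIndex(n)


# ---------------------------------------------------------------------------
# nested cross-validation


def _train_fold_artifacts(func, vols, labels, train_idx, config: CvConfig):
    """Everything fitted on one training fold: filter result and design."""
    f_tr, v_tr, y_tr = func[train_idx], vols[train_idx], labels[train_idx]
    ms_a = structural_network(v_tr[y_tr > 0], group_label=+1).edge_vector
    ms_b = structural_network(v_tr[y_tr <= 0], group_label=-1).edge_vector
    filt = filter_features(ms_a, ms_b, f_tr, y_tr)
    m = subject_structural_features(v_tr, y_tr)
    design = build_design(f_tr, m, y_tr, filt.selected)
    return filt, design


def _svm_predict(x_tr, y_tr, x_te, cols, config: CvConfig):
    """Train the RBF SVM on the given feature columns; return predictions
    and decision scores for the test rows.

    An all-zero fusion fit selects no features: the fold falls back to the
    training majority class (controls on a tie) with zero decision scores.
    """
    cols = np.asarray(cols, dtype=int)
    if cols.size == 0:
        majority = 1 if np.sum(y_tr > 0) > np.sum(y_tr <= 0) else -1
        n = x_te.shape[0]
        return np.full(n, majority), np.zeros(n)
    a, b = x_tr[:, cols], x_te[:, cols]
    if config.standardize:
        scaler = StandardScaler().fit(a)
        a, b = scaler.transform(a), scaler.transform(b)
    clf = SVC(C=config.svm_c, kernel="rbf", gamma="scale")
    clf.fit(a, y_tr)
    return clf.predict(b), clf.decision_function(b)


def _selected_columns(fit_w: np.ndarray) -> np.ndarray:
    return np.flatnonzero(fit_w != 0)


def _grid_pairs(grid) -> list[tuple[float, float]]:
    return [(float(l1), float(l2)) for l1 in grid for l2 in grid]


def _fit_grid(design: FusionDesign, config: CvConfig) -> dict:
    """Fusion fits over the whole grid, warm-started along the path."""
    fits = {}
    w_start = None
    k = config.k or default_k(design.x.shape[1])
    k = min(k, design.x.shape[1])
    for pair in _grid_pairs(config.grid):
        fit = fit_fusion(
            design,
            lambda1=pair[0],
            lambda2=pair[1],
            k=k,
            tol=config.fit_tol,
            max_iter=config.fit_max_iter,
            penalty=config.penalty,
            intermodality=config.intermodality,
            w0=w_start,
        )
        w_start = fit.w
        fits[pair] = fit
    return fits


def _choose_lambdas(func, vols, labels, train_idx, config: CvConfig, round_seed: int):
    """Inner stratified CV over the grid; ties go to the smaller lambda1,
    then the smaller lambda2."""
    y_tr = labels[train_idx]
    inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=round_seed % (2**31)
    )
    pairs = _grid_pairs(config.grid)
    correct = {pair: 0 for pair in pairs}
    total = 0
    for in_tr, in_va in inner.split(np.zeros(train_idx.size), y_tr > 0):
        tr_idx, va_idx = train_idx[in_tr], train_idx[in_va]
        try:
            _, design = _train_fold_artifacts(func, vols, labels, tr_idx, config)
        except EmptySelectionError:
            continue
        fits = _fit_grid(design, config)
        total += va_idx.size
        for pair, fit in fits.items():
            pred, _ = _svm_predict(
                func[tr_idx][:, design.selected],
                labels[tr_idx],
                func[va_idx][:, design.selected],
                _selected_columns(fit.w),
                config,
            )
            correct[pair] += int(np.sum(pred == labels[va_idx]))
    best_pair, best_acc = None, -1.0
    for pair in sorted(pairs):
        acc = correct[pair] / total if total else 0.0
        if acc > best_acc:
            best_pair, best_acc = pair, acc
    return best_pair


def nested_cv(
    functional_features: np.ndarray,
    volumes: np.ndarray,
    labels: np.ndarray,
    config: CvConfig,
    edge_index: EdgeIndex | None = None,
) -> CvResult:
    """Repeated stratified nested cross-validation of the fusion classifier.

    ``functional_features`` are the covariate-corrected Fisher-z edge
    vectors (subjects x 4005), ``volumes`` the covariate-corrected regional
    volumes (subjects x 90).  Per-round fold assignment is deterministic
    given ``config.seed`` (per-round seeds are seed + round).
    """
    func = np.asarray(functional_features, dtype=float)
    vols = np.asarray(volumes, dtype=float)
    labels = np.asarray(labels)
    n, n_edges = func.shape
    idx = edge_index or _edge_index_for(n_edges)

    summed_abs_w = np.zeros(n_edges)
    round_rows, fold_rows, fold_weights = [], [], []
    for rnd in range(config.n_rounds):
        round_seed = config.seed + rnd
        outer = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=round_seed % (2**31)
        )
        preds = np.zeros(n)
        scores = np.zeros(n)
        for fold_i, (tr, te) in enumerate(outer.split(np.zeros(n), labels > 0)):
            pair = _choose_lambdas(func, vols, labels, tr, config, round_seed)
            filt, design = _train_fold_artifacts(func, vols, labels, tr, config)
            k = min(config.k or default_k(design.x.shape[1]), design.x.shape[1])
            fit = fit_fusion(
                design,
                lambda1=pair[0],
                lambda2=pair[1],
                k=k,
                tol=config.fit_tol,
                max_iter=config.fit_max_iter,
                penalty=config.penalty,
                intermodality=config.intermodality,
            )
            cols = _selected_columns(fit.w)
            pred, score = _svm_predict(
                func[tr][:, design.selected],
                labels[tr],
                func[te][:, design.selected],
                cols,
                config,
            )
            preds[te], scores[te] = pred, score
            summed_abs_w[design.selected] += np.abs(fit.w)
            fold_rows.append(
                {
                    "round": rnd,
                    "fold": fold_i,
                    "lambda1": pair[0],
                    "lambda2": pair[1],
                    "n_selected": int(design.selected.size),
                    "n_nonzero": int(np.sum(fit.w != 0)),
                    "converged": fit.converged,
                }
            )
            if config.store_fold_weights:
                w_full = np.zeros(n_edges)
                w_full[design.selected] = fit.w
                fold_weights.append(w_full)
        m = compute_metrics(preds, labels, scores)
        round_rows.append({"round": rnd, **m})

    rm = pd.DataFrame(round_rows)
    return CvResult(
        round_metrics=rm,
        accuracy=float(rm["accuracy"].mean()),
        sensitivity=float(rm["sensitivity"].mean()),
        specificity=float(rm["specificity"].mean()),
        auc=float(rm["auc"].mean()),
        summed_abs_w=summed_abs_w,
        fold_records=pd.DataFrame(fold_rows),
        fold_weights=fold_weights,
    )
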