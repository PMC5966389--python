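"""Cross-validation of association predictions: LOOCV, k-fold, rank-based ROC.

Each trial hides one (or one fold of) known association(s), recomputes the
interaction-profile kernels on the reduced network — the kernels depend on the
associations, so reusing full-data similarity would leak the test edge — and
ranks the hidden microbe among the disease's candidate set (all microbes with
no remaining known association to that disease).  Symptom-based similarity
does not depend on the association network and is computed once.

Candidate sets differ in size across diseases, so the ROC pools trials on the
percentile-rank scale: a threshold theta in [0, 1] calls a candidate positive
when its (rank - 1) / (n_candidates - 1) percentile is at most theta.
Sensitivity is the fraction of test samples called positive; the false
positive rate averages, over trials, the fraction of non-test candidates
called positive.  AUC is the trapezoidal area under that curve: 1 is perfect
retrieval, 0.5 is random ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .network_data import AssociationNetwork
from .projection import DEFAULT_DELTA, _symptom_to_ss, predict
from .errors import DegenerateNetworkError

logger = logging.getLogger(__name__)

__all__ = ["Trial", "CVResult", "rank_roc", "loocv", "kfold_cv"]


@dataclass
class Trial:
    """One held-out association and the rank it received."""

    disease: str
    microbe: str
    rank: float           # average rank of the held-out microbe among candidates
    n_candidates: int
    fold: int | None = None

    @property
    def percentile(self) -> float:
        """Rank on a [0, 1] scale; 0 is top-ranked, 1 is bottom-ranked."""
        if self.n_candidates <= 1:
            return 0.0
        return (self.rank - 1.0) / (self.n_candidates - 1.0)


@dataclass
class CVResult:
    """Ranks, ROC points and AUC of one cross-validation run."""

    trials: list[Trial]
    roc_points: np.ndarray        # (K, 2) array of (FPR, TPR)
    auc: float
    protocol: str                 # 'loocv' or 'kfold'
    mode: str = "full"
    seed: int | None = None
    folds: int | None = None
    fold_aucs: list[float] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "mode": self.mode,
            "seed": self.seed,
            "folds": self.folds,
            "auc": self.auc,
            "fold_aucs": self.fold_aucs,
            "n_trials": len(self.trials),
            "n_skipped": len(self.skipped),
            "skipped": self.skipped,
            "trials": [
                {"disease": t.disease, "microbe": t.microbe, "rank": t.rank,
                 "n_candidates": t.n_candidates, "fold": t.fold}
                for t in self.trials
            ],
            "roc_points": [[float(f), float(t)] for f, t in self.roc_points],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def rank_roc(trials: list) -> tuple[np.ndarray, float]:
    """ROC points and AUC from pooled (rank, n_candidates) trials.

    ``trials`` may be :class:`Trial` objects or plain (rank, n_candidates)
    pairs.  The threshold sweeps every attainable percentile cut; ties in the
    underlying scores should already be resolved to average ranks.
    """
    if not trials:
        raise ValueError("no trials to build a ROC from")
    pairs = [(t.rank, t.n_candidates) if isinstance(t, Trial) else (t[0], t[1])
             for t in trials]
    ranks = np.array([r for r, _ in pairs], dtype=float)
    ns = np.array([n for _, n in pairs], dtype=float)
    if (ranks < 1).any() or (ranks > ns).any():
        raise ValueError("ranks must lie in [1, n_candidates]")
    denom = np.maximum(ns - 1.0, 1.0)
    perc = np.where(ns > 1, (ranks - 1.0) / denom, 0.0)

    # Every percentile at which any trial's candidate list has a position.
    eps = 1e-9
    grids = [np.arange(int(n)) / max(int(n) - 1, 1) for n in np.unique(ns)]
    thetas = np.unique(np.concatenate([[0.0, 1.0], *grids]))

    # positions called positive in trial t at threshold theta
    c = np.floor(thetas[:, None] * (ns - 1.0)[None, :] + eps) + 1.0
    c = np.minimum(c, ns[None, :])
    hit = perc[None, :] <= thetas[:, None] + eps
    tpr = hit.mean(axis=1)
    nontest = np.clip(c - hit, 0.0, ns[None, :] - 1.0)
    with np.errstate(invalid="ignore"):
        fpr_t = np.where(ns[None, :] > 1, nontest / denom[None, :], 0.0)
    fpr = fpr_t.mean(axis=1)

    order = np.argsort(fpr, kind="stable")
    pts = np.column_stack([fpr[order], tpr[order]])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    # numerical guard: enforce monotonicity before integrating
    pts[:, 0] = np.maximum.accumulate(pts[:, 0])
    pts[:, 1] = np.maximum.accumulate(pts[:, 1])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def _rank_held_out(scores_row: np.ndarray, candidates: np.ndarray, j: int) -> float:
    """Average rank (descending score) of microbe j within the candidate set."""
    ranks = rankdata(-scores_row[candidates], method="average")
    return float(ranks[int(np.nonzero(candidates == j)[0][0])])


def loocv(net: AssociationNetwork, symptom_input=None, mode: str = "full",
          delta: float = DEFAULT_DELTA, gamma_prime: float = 1.0,
          log_base: float = 10.0) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    For each known edge (i, j): the edge is removed, all interaction-profile
    kernels are recomputed on the reduced network, the predictor is run, and
    microbe j is ranked among disease i's candidates (which now include j).
    Trials whose removal empties the network entirely are skipped with a
    warning.
    """
    edges = net.edges()
    if len(edges) < 2:
        raise ValueError("need at least 2 known associations for LOOCV")
    SS = _symptom_to_ss(symptom_input, log_base)
    trials: list[Trial] = []
    skipped: list[dict] = []
    for i, j in edges:
        A = net.A.copy()
        A[i, j] = 0.0
        reduced = AssociationNetwork(net.diseases, net.microbes, A,
                                     net.label_order)
        try:
            sc = predict(reduced, SS, mode=mode, delta=delta,
                         gamma_prime=gamma_prime, log_base=log_base)
        except DegenerateNetworkError as exc:
            logger.warning("trial (%s, %s) skipped: %s",
                           net.diseases[i], net.microbes[j], exc)
            skipped.append({"disease": net.diseases[i],
                            "microbe": net.microbes[j], "reason": str(exc)})
            continue
        candidates = np.nonzero(A[i] == 0)[0]
        r = _rank_held_out(sc.ncp[i], candidates, j)
        trials.append(Trial(net.diseases[i], net.microbes[j], r,
                            len(candidates)))
    roc, auc = rank_roc(trials)
    return CVResult(trials=trials, roc_points=roc, auc=auc,
                    protocol="loocv", mode=mode, skipped=skipped)


def kfold_cv(net: AssociationNetwork, symptom_input=None, mode: str = "full",
             k: int = 5, seed: int | None = 0, delta: float = DEFAULT_DELTA,
             gamma_prime: float = 1.0, log_base: float = 10.0) -> CVResult:
    """k-fold cross-validation: associations split randomly into equal folds.

    All of a fold's edges are hidden simultaneously, similarities recomputed,
    and each hidden edge ranked among its disease's candidates.  Ranks are
    pooled across folds into one ROC; per-fold AUCs are reported as well.
    Identical seeds give identical results.
    """
    edges = net.edges()
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(edges):
        raise ValueError(f"k={k} exceeds the {len(edges)} known associations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    folds = np.array_split(perm, k)
    SS = _symptom_to_ss(symptom_input, log_base)
    trials: list[Trial] = []
    skipped: list[dict] = []
    fold_aucs: list[float] = []
    for f, fold in enumerate(folds):
        A = net.A.copy()
        for e in fold:
            i, j = edges[e]
            A[i, j] = 0.0
        reduced = AssociationNetwork(net.diseases, net.microbes, A,
                                     net.label_order)
        try:
            sc = predict(reduced, SS, mode=mode, delta=delta,
                         gamma_prime=gamma_prime, log_base=log_base)
        except DegenerateNetworkError as exc:
            logger.warning("fold %d skipped: %s", f, exc)
            for e in fold:
                i, j = edges[e]
                skipped.append({"disease": net.diseases[i],
                                "microbe": net.microbes[j], "fold": f,
                                "reason": str(exc)})
            continue
        fold_trials = []
        for e in fold:
            i, j = edges[e]
            candidates = np.nonzero(A[i] == 0)[0]
            r = _rank_held_out(sc.ncp[i], candidates, j)
            fold_trials.append(Trial(net.diseases[i], net.microbes[j], r,
                                     len(candidates), fold=f))
        trials.extend(fold_trials)
        if fold_trials:
            fold_aucs.append(rank_roc(fold_trials)[1])
    roc, auc = rank_roc(trials)
    return CVResult(trials=trials, roc_points=roc, auc=auc, protocol="kfold",
                    mode=mode, seed=seed, folds=k, fold_aucs=fold_aucs,
                    skipped=skipped)
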