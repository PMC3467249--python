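"""Confusion-matrix metrics, ROC/AUC, SMACOF multidimensional scaling and
cohort-comparison statistics.

The positive class is the non-responder throughout; all confusion rates are
percentages, with undefined rates (zero denominator) reported as NaN rather
than 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateLabelError, DimensionError, DomainError

log = logging.getLogger(__name__)

POSITIVE = "NR"
NEGATIVE = "CCR"


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    """Counts and percentage rates with the non-responder as positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def _pct(self, num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def fpr(self) -> float:
        return self._pct(self.fp, self.tn + self.fp)

    @property
    def fnr(self) -> float:
        return self._pct(self.fn, self.tp + self.fn)

    @property
    def accuracy(self) -> float:
        return self._pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def fdr(self) -> float:
        return self._pct(self.fp, self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "fpr": self.fpr,
            "fnr": self.fnr, "accuracy": self.accuracy, "fdr": self.fdr,
        }


def confusion_from_counts(pos_correct: int, pos_total: int,
                          neg_correct: int, neg_total: int) -> ConfusionSummary:
    """Build the summary from 'x of n positives / y of m negatives correct'."""
    return ConfusionSummary(tp=pos_correct, fn=pos_total - pos_correct,
                            tn=neg_correct, fp=neg_total - neg_correct)


def confusion_metrics(true, predicted) -> ConfusionSummary:
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise DomainError("empty class vectors")
    if true.shape != predicted.shape:
        raise DomainError("true/predicted length mismatch")
    for v in np.concatenate([true, predicted]):
        if v not in (POSITIVE, NEGATIVE):
            raise DomainError(f"class label {v!r} outside {{NR, CCR}}")
    tp = int(np.sum((true == POSITIVE) & (predicted == POSITIVE)))
    fn = int(np.sum((true == POSITIVE) & (predicted == NEGATIVE)))
    tn = int(np.sum((true == NEGATIVE) & (predicted == NEGATIVE)))
    fp = int(np.sum((true == NEGATIVE) & (predicted == POSITIVE)))
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, true) -> tuple[pd.DataFrame, float]:
    """ROC points over all thresholds and the midrank (Mann-Whitney) AUC.

    Constant score vectors yield AUC 0.5 with a degeneracy warning.
    """
    scores = np.asarray(scores, float)
    true = np.asarray(true)
    pos = true == POSITIVE
    neg = true == NEGATIVE
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelError("ROC needs both classes")
    if np.all(scores == scores[0]):
        log.warning("roc_auc: constant scores; AUC degenerate at 0.5")
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    thresholds = np.concatenate([[np.inf], scores[order]])
    pts = []
    for thr in thresholds:
        pred_pos = scores >= thr
        tpr = np.sum(pred_pos & pos) / n_pos
        fpr = np.sum(pred_pos & neg) / n_neg
        pts.append((thr, fpr, tpr))
    roc = pd.DataFrame(pts, columns=["threshold", "fpr", "tpr"]) \
            .drop_duplicates(subset=["fpr", "tpr"]).reset_index(drop=True)
    return roc, float(auc)


# ---------------------------------------------------------------------------
# SMACOF multidimensional scaling
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    coordinates: np.ndarray      # n_samples x dims
    stress: float                # Kruskal stress-1
    variance_fraction: float     # classical-scaling variance in `dims` axes
    n_iter: int
    stress_path: np.ndarray      # per-iteration stress-1 (diagnostic)


def kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    """Stress-1 = sqrt(sum (d - dhat)^2 / sum dhat^2) over the upper triangle."""
    iu = np.triu_indices_from(d, k=1)
    num = np.sum((d[iu] - dhat[iu]) ** 2)
    den = np.sum(dhat[iu] ** 2)
    return math.sqrt(num / den) if den > 0 else 0.0


def classical_scaling(d: np.ndarray, dims: int) -> tuple[np.ndarray, float]:
    """Torgerson double-centering start; returns coords and the fraction of
    positive-eigenvalue variance captured by the leading ``dims`` axes."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    pos = np.clip(vals, 0, None)
    coords = vecs[:, :dims] * np.sqrt(pos[:dims])
    total = pos.sum()
    frac = float(pos[:dims].sum() / total) if total > 0 else 1.0
    return coords, frac


def mds_smacof(X, dims: int = 3, seed: int = 0, max_iter: int = 300,
               tol: float = 1e-6) -> EmbeddingResult:
    """Metric MDS by SMACOF majorization from a classical-scaling start.

    ``X`` is a samples x features matrix (Euclidean target distances) or a
    precomputed square distance matrix.  Majorization guarantees the stress
    sequence is non-increasing; iteration stops when the stress change drops
    below ``tol``.  ``seed`` only matters for the (unused by default) random
    restart and is kept for interface stability.
    """
    X = np.asarray(X, float)
    if X.ndim == 2 and X.shape[0] == X.shape[1] and np.allclose(X, X.T) \
            and np.allclose(np.diag(X), 0):
        d = X.copy()
    else:
        d = squareform(pdist(X))
    n = d.shape[0]
    if dims >= n:
        raise DimensionError(f"dims={dims} must be < number of samples ({n})")

    coords, frac = classical_scaling(d, dims)
    dhat = squareform(pdist(coords))
    stress = kruskal_stress(d, dhat)
    path = [stress]
    for it in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dhat > 0, d / dhat, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        coords = b @ coords / n  # Guttman transform
        dhat = squareform(pdist(coords))
        new_stress = kruskal_stress(d, dhat)
        path.append(new_stress)
        if abs(stress - new_stress) < tol:
            stress = new_stress
            break
        stress = new_stress
    return EmbeddingResult(coordinates=coords, stress=float(stress),
                           variance_fraction=frac, n_iter=len(path) - 1,
                           stress_path=np.asarray(path))


# ---------------------------------------------------------------------------
# exact and rank tests
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, probability-mass method."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise DomainError("table must be a 2x2 array of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        log.warning("fisher_exact: zero margin -> p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def freeman_halton(table, max_n: int = 50, n_mc: int = 100_000,
                   seed: int = 0) -> float:
    """Exact (Freeman-Halton) two-sided p for an r x 2 table.

    All tables with the observed margins are enumerated when the total count
    is <= ``max_n``; larger tables fall back to seeded Monte-Carlo sampling
    of the fixed-margin null.
    """
    t = np.asarray(table, int)
    if t.ndim != 2 or t.shape[1] != 2 or np.any(t < 0):
        raise DomainError("table must be r x 2 with non-negative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or np.any(cols == 0):
        return 1.0

    def log_prob(cells_col0: np.ndarray) -> float:
        # hypergeometric probability of the table given fixed margins
        lp = (sum(math.lgamma(r + 1) for r in rows)
              + sum(math.lgamma(c + 1) for c in cols)
              - math.lgamma(n + 1))
        for r, a in zip(rows, cells_col0):
            lp -= math.lgamma(a + 1) + math.lgamma(r - a + 1)
        return lp

    obs_lp = log_prob(t[:, 0])
    if n <= max_n:
        total = 0.0
        stack = [(0, cols[0], ())]
        while stack:
            i, remaining, acc = stack.pop()
            if i == len(rows) - 1:
                if 0 <= remaining <= rows[i]:
                    cells = np.array(acc + (remaining,))
                    lp = log_prob(cells)
                    if lp <= obs_lp + 1e-10:
                        total += math.exp(lp)
                continue
            lo = max(0, remaining - int(rows[i + 1:].sum()))
            hi = min(rows[i], remaining)
            for a in range(lo, hi + 1):
                stack.append((i + 1, remaining - a, acc + (a,)))
        return float(min(total, 1.0))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        draw = rng.multivariate_hypergeometric(rows, cols[0])
        if log_prob(draw) <= obs_lp + 1e-10:
            count += 1
    return float((count + 1) / (n_mc + 1))


def group_compare(x, y, method: str = "welch_t") -> float:
    """Two-sided p comparing two samples.

    methods: ``welch_t`` (unequal-variance t with Welch-Satterthwaite df),
    ``pooled_t`` (equal-variance t), ``mann_whitney`` (midrank U with
    tie-corrected normal approximation, no continuity correction).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("need >= 2 values per group")
    if method in ("welch_t", "pooled_t"):
        if np.var(x) == 0 and np.var(y) == 0:
            if x.mean() == y.mean():
                return 1.0
            log.warning("group_compare: zero variance with unequal means -> p=0")
            return 0.0
        res = stats.ttest_ind(x, y, equal_var=(method == "pooled_t"))
        return float(res.pvalue)
    if method == "mann_whitney":
        _, p = mann_whitney_u(x, y)
        return p
    raise DomainError(f"unknown method {method!r}")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Midrank U statistic of the first sample and its two-sided normal p.

    The normal approximation uses the tie-corrected variance and no
    continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12 * (n + 1 - tie_term)
    if var_u == 0:
        return float(u1), 1.0
    z = (u1 - n1 * n2 / 2) / math.sqrt(var_u)
    return float(u1), float(2 * stats.norm.sf(abs(z)))


def auc_brute_force(scores, true) -> float:
    """Concordant-pair AUC: ties count one half (independent oracle)."""
    scores = np.asarray(scores, float)
    true = np.asarray(true)
    pos = scores[true == POSITIVE]
    neg = scores[true == NEGATIVE]
    total = conc = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                conc += 1
            elif sp == sn:
                conc += 0.5
    return conc / total
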