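"""Linear-SVM signature training and leave-one-out cross-validation.

The key contract is leakage freedom: inside every LOOCV fold the whole gene
selection (differential test + composite filter) is recomputed on the
training samples only, so the held-out sample never informs feature choice
or model fitting.  The final signature ranks genes by how often the folds
selected them, breaking ties by mean absolute standardized SVM weight and
then lexicographic gene ID.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .diffexp import moderated_t_test, summarize_groups
from .errors import (
    DegenerateLabelError,
    EncodingError,
    SizeError,
)
from .io_formats import SampleSheet
from .preprocess import ExpressionMatrix
from .signature_filter import FilterThresholds, apply_selection_criteria

log = logging.getLogger(__name__)

POSITIVE_CLASS = "NR"
DEFAULT_COST = 1.0
DEFAULT_K = 10


@dataclass
class SignatureModel:
    """A trained linear decision rule over a fixed gene panel.

    Decision score ``s(x) = sum_i w_i * (x_i - center_i) / scale_i + b``;
    a positive score predicts the non-responder class.
    """

    genes: list[str]
    weights: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    positive_class: str = POSITIVE_CLASS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.center = np.asarray(self.center, float)
        self.scale = np.asarray(self.scale, float)
        if not (len(self.genes) == len(self.weights) == len(self.center)
                == len(self.scale)):
            raise ValueError("genes / weights / standardization length mismatch")
        if np.any(self.scale <= 0):
            raise ValueError("standardization scales must be positive")

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.genes if g not in X.columns]
        if missing:
            raise KeyError(f"features absent from input: {missing}")
        Z = (X[self.genes].to_numpy(float) - self.center) / self.scale
        return Z @ self.weights + self.intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        s = self.decision_scores(X)
        return np.where(s > 0, self.positive_class, "CCR")

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "positive_class": self.positive_class,
            "provenance": self.provenance,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class CVReport:
    """Outcome of leave-one-out cross-validation with per-fold re-selection."""

    predictions: pd.DataFrame  # index sample; columns true, predicted, score
    selection_frequency: pd.Series
    fold_genes: dict  # held-out sample -> selected gene list
    fold_weights: dict  # held-out sample -> {gene: standardized weight}

    @property
    def accuracy(self) -> float:
        df = self.predictions
        return float((df["true"] == df["predicted"]).mean())

    def mean_abs_weight(self) -> pd.Series:
        rows = [pd.Series(w) for w in self.fold_weights.values()]
        if not rows:
            return pd.Series(dtype=float)
        return pd.DataFrame(rows).abs().mean(axis=0)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = scale == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s); scale set "
                      "to 1", stacklevel=3)
        scale = np.where(zero, 1.0, scale)
    return (X - center) / scale, center, scale


def train_linear_svm(X: pd.DataFrame, y, cost: float = DEFAULT_COST,
                     provenance: dict | None = None) -> SignatureModel:
    """Fit a soft-margin linear SVM on z-scored features.

    ``X`` is samples x genes; ``y`` holds NR/CCR labels.  The returned model
    keeps the training standardization so that raw feature vectors can be
    scored directly.
    """
    y = np.asarray(y)
    classes = set(y)
    if classes != {"NR", "CCR"}:
        if len(classes) < 2:
            raise DegenerateLabelError(f"need both classes, got {sorted(classes)}")
        raise DegenerateLabelError(f"unexpected labels {sorted(classes)}")
    Xv = X.to_numpy(float)
    Z, center, scale = _standardize(Xv)
    # numeric target with NR = +1 fixes the sign of decision_function
    target = (y == POSITIVE_CLASS).astype(int)
    svc = SVC(kernel="linear", C=cost, tol=1e-7)
    svc.fit(Z, target)
    weights = svc.coef_.ravel().copy()
    intercept = float(svc.intercept_[0])
    return SignatureModel(
        genes=list(X.columns), weights=weights, intercept=intercept,
        center=center, scale=scale,
        provenance=provenance or {"cost": cost, "n_train": len(y)})


def select_genes_for_fold(expr: ExpressionMatrix, sheet: SampleSheet,
                          thr: FilterThresholds, fallback_k: int = 10
                          ) -> list[str]:
    """Run the full test + filter on (training) samples; fall back to the
    top-``fallback_k`` genes by |moderated t| when nothing passes."""
    de = moderated_t_test(summarize_groups(expr, sheet))
    selected, _ = apply_selection_criteria(de, thr)
    if not selected:
        log.warning("fold selected zero genes; falling back to top %d by |t|",
                    fallback_k)
        ranked = de.table["t_mod"].abs().sort_values(ascending=False)
        selected = list(ranked.index[:fallback_k])
    return selected


def loocv_with_reselection(expr: ExpressionMatrix, sheet: SampleSheet,
                           thr: FilterThresholds = FilterThresholds(),
                           cost: float = DEFAULT_COST) -> CVReport:
    """Leave-one-out CV re-running gene selection inside every fold."""
    resp = sheet.responses.reindex(expr.samples)
    counts = resp.value_counts()
    if counts.get("NR", 0) < 3 or counts.get("CCR", 0) < 3:
        raise DegenerateLabelError("need >= 3 samples per class for LOOCV")
    complete = expr.complete_genes()
    m = expr.m.loc[complete]
    a = expr.a.loc[complete]

    records, fold_genes, fold_weights = [], {}, {}
    tally: dict[str, int] = {}
    for held in expr.samples:
        train_samples = [s for s in expr.samples if s != held]
        sub = ExpressionMatrix(m=m[train_samples].copy(),
                               a=a[train_samples].copy())
        genes = select_genes_for_fold(sub, sheet, thr)
        fold_genes[held] = genes
        for g in genes:
            tally[g] = tally.get(g, 0) + 1
        X_train = m.loc[genes, train_samples].T
        model = train_linear_svm(X_train, resp.loc[train_samples].to_numpy(),
                                 cost=cost)
        fold_weights[held] = dict(zip(genes, model.weights))
        x_held = m.loc[genes, [held]].T
        score = float(model.decision_scores(x_held)[0])
        records.append({"sample": held, "true": resp.loc[held],
                        "predicted": POSITIVE_CLASS if score > 0 else "CCR",
                        "score": score})
    preds = pd.DataFrame(records).set_index("sample")
    freq = pd.Series(tally, dtype=float) / len(expr.samples)
    report = CVReport(predictions=preds, selection_frequency=freq.sort_index(),
                      fold_genes=fold_genes, fold_weights=fold_weights)
    log.info("LOOCV: %d folds, accuracy %.1f%%", len(preds),
             100 * report.accuracy)
    return report


def rank_signature_genes(report: CVReport) -> pd.DataFrame:
    """Rank genes by (selection frequency desc, mean |weight| desc, gene ID)."""
    freq = report.selection_frequency
    weight = report.mean_abs_weight().reindex(freq.index).fillna(0.0)
    ranking = pd.DataFrame({"frequency": freq, "mean_abs_weight": weight})
    ranking["_gene"] = ranking.index
    ranking = ranking.sort_values(
        by=["frequency", "mean_abs_weight", "_gene"],
        ascending=[False, False, True], kind="mergesort")
    return ranking.drop(columns="_gene")


def derive_final_signature(report: CVReport, expr: ExpressionMatrix,
                           sheet: SampleSheet, k: int = DEFAULT_K,
                           cost: float = DEFAULT_COST,
                           override_genes: list[str] | None = None,
                           provenance: dict | None = None) -> SignatureModel:
    """Take the top-k cross-fold genes (or an explicit override) and train
    the final model on all samples."""
    if override_genes is not None:
        genes = list(override_genes)
    else:
        if k < 1:
            raise SizeError("k must be >= 1")
        ranking = rank_signature_genes(report)
        if k > len(ranking):
            raise SizeError(
                f"k={k} exceeds the {len(ranking)} genes ever selected")
        kth = ranking.iloc[k - 1]
        tied = ranking[(ranking["frequency"] == kth["frequency"]) &
                       (ranking["mean_abs_weight"] == kth["mean_abs_weight"])]
        if len(tied) > 1:
            log.info("tie at rank %d broken lexicographically among %s",
                     k, list(tied.index))
        genes = list(ranking.index[:k])
    resp = sheet.responses.reindex(expr.samples)
    X = expr.m.loc[genes].T
    if X.isna().any().any():
        raise ValueError("signature genes contain missing values")
    model = train_linear_svm(X, resp.to_numpy(), cost=cost,
                             provenance=provenance or {})
    model.provenance.setdefault("k", len(genes))
    model.provenance.setdefault("cost", cost)
    return model


def augment_with_covariates(X: pd.DataFrame, sheet: SampleSheet,
                            covariates: list[str]) -> pd.DataFrame:
    """Append 0/1-encoded binary covariates (e.g. HPV status) as features.

    Samples whose covariate is unknown are dropped (and counted in the log),
    mirroring a cohort member whose status could not be ascertained.
    """
    if not covariates:
        return X
    out = X.copy()
    meta = sheet.data.set_index("patient_id").reindex(out.index)
    for name in covariates:
        if name not in meta.columns:
            raise EncodingError(f"covariate {name!r} not in sample sheet")
        col = meta[name]
        if name == "hpv":
            known = col.isin(["positive", "negative"])
            if (~known).any():
                log.info("augment: dropping %d sample(s) with unknown %s",
                         int((~known).sum()), name)
            out = out.loc[known.to_numpy()]
            out[name] = (col[known.to_numpy()] == "positive").astype(float)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            uniq = set(vals.dropna().unique())
            if not uniq <= {0, 1}:
                raise EncodingError(
                    f"covariate {name!r} is not binary; provide an encoding")
            keep = vals.notna()
            out = out.loc[keep.to_numpy()]
            out[name] = vals[keep.to_numpy()].astype(float)
    return out


def covariate_baseline(sheet: SampleSheet,
                       covariates: tuple[str, ...] = (
                           "age", "cigarettes_per_day", "alcohol_l_per_day",
                           "hemoglobin")) -> dict:
    """LOOCV accuracy of a Fisher linear discriminant on clinical covariates.

    A singular pooled covariance gets a 1e-6 ridge jitter (logged).  Returns
    {'accuracy': float in [0, 1], 'predictions': DataFrame}.
    """
    df = sheet.data.set_index("patient_id")
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise EncodingError(f"covariates absent from sheet: {missing}")
    X = df[list(covariates)].apply(pd.to_numeric, errors="coerce")
    keep = X.notna().all(axis=1)
    X = X.loc[keep].to_numpy(float)
    y = (df.loc[keep.to_numpy(), "response"] == POSITIVE_CLASS
         ).to_numpy(int)
    ids = list(df.index[keep.to_numpy()])
    if len(set(y)) < 2:
        raise DegenerateLabelError("both classes required")

    def lda_predict(Xtr, ytr, xte):
        mu1 = Xtr[ytr == 1].mean(axis=0)
        mu0 = Xtr[ytr == 0].mean(axis=0)
        diffs = np.vstack([Xtr[ytr == 1] - mu1, Xtr[ytr == 0] - mu0])
        cov = diffs.T @ diffs / max(len(Xtr) - 2, 1)
        try:
            w = np.linalg.solve(cov, mu1 - mu0)
        except np.linalg.LinAlgError:
            log.info("singular pooled covariance; adding 1e-6 ridge jitter")
            w = np.linalg.solve(cov + 1e-6 * np.eye(len(cov)), mu1 - mu0)
        score = w @ (xte - 0.5 * (mu1 + mu0))
        return 1 if score > 0 else 0

    preds = []
    for i in range(len(X)):
        mask = np.ones(len(X), bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            preds.append(1 - y[i])  # held-out class vanished; forced error
            continue
        preds.append(lda_predict(X[mask], y[mask], X[i]))
    preds = np.asarray(preds)
    out = pd.DataFrame({
        "true": np.where(y == 1, "NR", "CCR"),
        "predicted": np.where(preds == 1, "NR", "CCR")}, index=ids)
    return {"accuracy": float((preds == y).mean()), "predictions": out}


def config_hash(obj) -> str:
    """Short deterministic hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
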