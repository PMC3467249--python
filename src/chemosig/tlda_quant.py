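"""ddCt relative quantification and cross-platform signature transfer.

Ct replicates are averaged arithmetically, normalized within each sample to
the reference gene (dCt), then to the calibrator sample (ddCt), giving the
relative quantity RQ = 2^-ddCt.  Undetermined wells are treated as missing,
never imputed at the cycle ceiling: a single failed replicate leaves its
partner in charge (flagged), two failed replicates leave the cell missing.

Transfer of a microarray-derived signature keeps the gene panel fixed but
refits the linear weights on log2(RQ) features, because the two platforms'
scales differ; a frozen, previously qPCR-fitted model can instead be applied
unchanged to new samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    CVReport,
    POSITIVE_CLASS,
    SignatureModel,
    train_linear_svm,
)
from .diffexp import signed_fold_change
from .errors import DegenerateLabelError, StateError
from .io_formats import CtTable, SampleSheet, write_matrix

log = logging.getLogger(__name__)


@dataclass
class RQMatrix:
    """Genes x samples relative quantities with per-cell replicate metadata."""

    rq: pd.DataFrame
    replicate_count: pd.DataFrame
    ct_sd: pd.DataFrame
    reference_gene: str
    calibrator_id: str

    def __post_init__(self) -> None:
        vals = self.rq.to_numpy(float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("RQ must be positive where defined")

    def log2(self) -> pd.DataFrame:
        return np.log2(self.rq)

    def sample_columns(self) -> list[str]:
        return [c for c in self.rq.columns if c != self.calibrator_id]

    def to_tsv(self, path, config_hash: str = "-") -> None:
        write_matrix(self.rq, path, config_hash=config_hash)


def compute_rq(ct: CtTable) -> RQMatrix:
    """ddCt quantification: dCt -> ddCt against the calibrator -> RQ=2^-ddCt."""
    df = ct.data
    grouped = df.groupby(["gene", "sample_id"])["ct"]
    mean_ct = grouped.mean().unstack("sample_id")       # NaN-aware replicate mean
    n_rep = grouped.count().unstack("sample_id")
    sd_ct = grouped.std(ddof=1).unstack("sample_id")
    partial = (n_rep > 0) & (n_rep < df.groupby(["gene", "sample_id"])["replicate"]
                             .size().unstack("sample_id"))
    if partial.to_numpy().any():
        log.warning("compute_rq: %d cell(s) with a failed replicate; using the "
                    "remaining replicate", int(partial.to_numpy().sum()))
    if (n_rep == 0).to_numpy().any():
        log.warning("compute_rq: %d cell(s) fully undetermined -> RQ missing",
                    int((n_rep == 0).to_numpy().sum()))

    if ct.calibrator_id not in mean_ct.columns:
        raise StateError(f"calibrator sample {ct.calibrator_id!r} absent")
    ref = mean_ct.loc[ct.reference_gene]
    if ref.isna().any():
        bad = list(ref.index[ref.isna()])
        raise StateError(f"reference gene undetermined for sample(s) {bad}")
    dct = mean_ct.sub(ref, axis=1)
    ddct = dct.sub(dct[ct.calibrator_id], axis=0)
    rq = np.power(2.0, -ddct)
    return RQMatrix(rq=rq, replicate_count=n_rep, ct_sd=sd_ct,
                    reference_gene=ct.reference_gene,
                    calibrator_id=ct.calibrator_id)


def tlda_fold_change(rq: RQMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene signed NR-over-CCR fold change on log2(RQ), with a test p.

    Group means are taken on log2(RQ); the sign convention matches the
    microarray differential-expression table.  p is a two-sided Welch t on
    the log2 values (NaN where a class has < 2 values).
    """
    l2 = rq.log2()[rq.sample_columns()]
    resp = sheet.responses.reindex(l2.columns)
    if resp.isna().any():
        raise KeyError(f"samples missing from sheet: "
                       f"{list(l2.columns[resp.isna()])}")
    nr = l2.loc[:, (resp == "NR").to_numpy()]
    ccr = l2.loc[:, (resp == "CCR").to_numpy()]
    if nr.shape[1] == 0 or ccr.shape[1] == 0:
        raise DegenerateLabelError("both classes required for fold change")
    m_nr, m_ccr = nr.mean(axis=1), ccr.mean(axis=1)
    diff = m_nr - m_ccr
    fc = pd.Series(signed_fold_change(diff.to_numpy()), index=l2.index)
    fc[diff.isna()] = np.nan
    pvals = []
    for g in l2.index:
        x = nr.loc[g].dropna().to_numpy()
        y = ccr.loc[g].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            pvals.append(np.nan)
        else:
            pvals.append(stats.ttest_ind(x, y, equal_var=False).pvalue)
    out = pd.DataFrame({"m_nr": m_nr, "m_ccr": m_ccr, "fc_signed": fc,
                        "p": pvals}, index=l2.index)
    out.loc[rq.reference_gene, "fc_signed"] = np.nan
    return out


def transfer_signature(model: SignatureModel, rq: RQMatrix,
                       sheet: SampleSheet | None = None,
                       retrain: bool = True, cost: float = 1.0
                       ) -> dict:
    """Apply a signature to qPCR relative quantities.

    retrain=True (labeled cohort): keep the gene panel fixed, run LOOCV on
    log2(RQ) features and refit a qPCR-scale model on all samples.  Returns
    {'report': CVReport, 'model': SignatureModel, 'predictions': DataFrame}.

    retrain=False (new samples): ``model`` must itself have been fitted on
    qPCR features (``provenance['platform'] == 'tlda'``); it is applied
    frozen.  Returns {'predictions': DataFrame}.
    """
    missing = [g for g in model.genes if g not in rq.rq.index]
    if missing:
        raise KeyError(f"signature gene(s) absent from RQ matrix: {missing}")
    feats = rq.log2().loc[model.genes, rq.sample_columns()].T  # samples x genes

    if not retrain:
        if model.provenance.get("platform") != "tlda":
            raise StateError("retrain=False requires a model previously "
                             "fitted on qPCR features")
        scores = model.decision_scores(feats)
        preds = pd.DataFrame({
            "predicted": np.where(scores > 0, POSITIVE_CLASS, "CCR"),
            "score": scores}, index=feats.index)
        return {"predictions": preds}

    if sheet is None:
        raise StateError("retrain=True requires labeled samples")
    resp = sheet.responses.reindex(feats.index)
    if resp.isna().any():
        raise KeyError(f"samples missing from sheet: "
                       f"{list(feats.index[resp.isna()])}")
    records, fold_weights = [], {}
    for held in feats.index:
        train_idx = [s for s in feats.index if s != held]
        m = train_linear_svm(feats.loc[train_idx],
                             resp.loc[train_idx].to_numpy(), cost=cost)
        fold_weights[held] = dict(zip(model.genes, m.weights))
        score = float(m.decision_scores(feats.loc[[held]])[0])
        records.append({"sample": held, "true": resp.loc[held],
                        "predicted": POSITIVE_CLASS if score > 0 else "CCR",
                        "score": score})
    preds = pd.DataFrame(records).set_index("sample")
    report = CVReport(
        predictions=preds,
        selection_frequency=pd.Series(1.0, index=model.genes),
        fold_genes={s: list(model.genes) for s in feats.index},
        fold_weights=fold_weights)
    final = train_linear_svm(feats, resp.to_numpy(), cost=cost,
                             provenance={"platform": "tlda", "cost": cost})
    log.info("TLDA transfer LOOCV accuracy: %.1f%%", 100 * report.accuracy)
    return {"report": report, "model": final,
            "predictions": preds}
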