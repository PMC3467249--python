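"""Spot filtering and intra-array loess normalization.

The normalization removes the intensity-dependent dye bias by subtracting a
locally weighted linear regression (tricube weights) of the log-ratio M on
the mean log-intensity A.  No background subtraction is performed anywhere;
flagged (not found / bad / saturated) spots and control probes are discarded
before any statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import EmptyArrayError, JoinError, ParameterError
from .io_formats import SampleSheet, SpotTable, read_matrix, write_matrix

log = logging.getLogger(__name__)

DEFAULT_SPAN = 0.5


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2(sample/reference) values.

    ``m`` holds the normalized log-ratios (NaN marks a gene discarded on a
    given array); ``a`` the matching mean log-intensities.  Control probes
    never enter this matrix.
    """

    m: pd.DataFrame
    a: pd.DataFrame

    def __post_init__(self) -> None:
        if self.m.shape != self.a.shape:
            raise ValueError("M and A dimensions differ")
        self.m.index = self.m.index.astype(str)
        self.a.index = self.a.index.astype(str)

    @property
    def genes(self) -> pd.Index:
        return self.m.index

    @property
    def samples(self) -> pd.Index:
        return self.m.columns

    def complete_genes(self) -> pd.Index:
        """Genes observed in every sample (usable for classifier training)."""
        return self.m.index[self.m.notna().all(axis=1)]

    def mean_a(self) -> pd.Series:
        """Cross-sample mean intensity per gene."""
        return self.a.mean(axis=1)

    def to_tsv(self, m_path, a_path=None, config_hash: str = "-") -> None:
        write_matrix(self.m, m_path, config_hash=config_hash)
        if a_path is not None:
            write_matrix(self.a, a_path, config_hash=config_hash)

    @classmethod
    def from_tsv(cls, m_path, a_path=None) -> "ExpressionMatrix":
        m = read_matrix(m_path)
        a = read_matrix(a_path) if a_path is not None else m * np.nan
        return cls(m=m, a=a)


def compute_ma(spots: SpotTable) -> SpotTable:
    """Attach raw M = log2(Cy5/Cy3) and A = log2(Cy5*Cy3)/2 columns."""
    out = spots.copy()
    cy5 = out.data["cy5_fg"].to_numpy(float)
    cy3 = out.data["cy3_fg"].to_numpy(float)
    out.data["m"] = np.log2(cy5 / cy3)
    out.data["a"] = 0.5 * np.log2(cy5 * cy3)
    return out


def filter_spots(spots: SpotTable) -> SpotTable:
    """Discard flagged spots and control probes; backgrounds are never touched.

    Raises :class:`EmptyArrayError` when nothing analysable remains.
    """
    df = spots.data
    flagged = df["flag"] != 0
    control = df["is_control"]
    keep = ~(flagged | control)
    log.info("array %s: %d spots, %d flagged removed, %d controls removed, "
             "%d retained", spots.array_id, len(df), int(flagged.sum()),
             int((control & ~flagged).sum()), int(keep.sum()))
    if not keep.any():
        raise EmptyArrayError(f"array {spots.array_id}: all spots flagged or control")
    return SpotTable(spots.array_id, df.loc[keep].reset_index(drop=True))


def _lowess_fit(m: np.ndarray, a: np.ndarray, span: float,
                xvals: np.ndarray) -> np.ndarray:
    fitted = lowess(m, a, frac=span, it=0, return_sorted=True)
    return np.interp(xvals, fitted[:, 0], fitted[:, 1])


def loess_normalize(spots: SpotTable, span: float = DEFAULT_SPAN) -> SpotTable:
    """Subtract the loess trend of M on A; returns spots with ``m_norm``.

    The trend is fitted on non-control spots and evaluated on every retained
    spot.  A table that already carries ``m_norm`` is returned unchanged
    (normalization is idempotent by contract; re-fitting a non-projection
    smoother on its own residuals would drift instead of converging).
    """
    if not (0 < span <= 1):
        raise ParameterError(f"span must be in (0, 1], got {span}")
    if "m_norm" in spots.data.columns:
        log.info("array %s: already normalized, returning unchanged",
                 spots.array_id)
        return spots.copy()
    out = spots if "m" in spots.data.columns else compute_ma(spots)
    out = out.copy()
    df = out.data
    fit_mask = (~df["is_control"] & (df["flag"] == 0)).to_numpy()
    if int(fit_mask.sum()) < 50:
        raise EmptyArrayError(
            f"array {spots.array_id}: need >= 50 unflagged non-control spots "
            f"to fit loess, have {int(fit_mask.sum())}")
    a = df["a"].to_numpy(float)
    m = df["m"].to_numpy(float)
    trend = _lowess_fit(m[fit_mask], a[fit_mask], span, a)
    df["m_norm"] = m - trend
    return out


def build_expression_matrix(arrays: list[SpotTable],
                            sheet: SampleSheet) -> ExpressionMatrix:
    """Assemble the gene x sample matrix from normalized arrays.

    Replicate probes of a gene are collapsed by median; a gene discarded on
    some array gets an explicit NaN there and is retained in the matrix.
    Every array must map (by ``array_id``) to a sample-sheet row.
    """
    known = set(sheet.data["patient_id"])
    m_cols, a_cols = {}, {}
    for arr in arrays:
        if arr.array_id not in known:
            raise JoinError(f"array {arr.array_id!r} has no sample-sheet entry")
        df = arr.data
        if "m_norm" not in df.columns:
            raise ValueError(f"array {arr.array_id}: not normalized "
                             "(run loess_normalize first)")
        grouped = df.groupby("gene_symbol")
        m_cols[arr.array_id] = grouped["m_norm"].median()
        a_cols[arr.array_id] = grouped["a"].median()
    order = [a.array_id for a in arrays]
    m = pd.DataFrame(m_cols)[order]
    a = pd.DataFrame(a_cols)[order]
    n_missing = int(m.isna().sum().sum())
    if n_missing:
        log.info("expression matrix: %d missing gene/sample cells", n_missing)
    return ExpressionMatrix(m=m, a=a)


def preprocess_arrays(arrays: list[SpotTable], sheet: SampleSheet,
                      span: float = DEFAULT_SPAN) -> ExpressionMatrix:
    """filter -> loess-normalize -> assemble, for a list of raw arrays."""
    normalized = [loess_normalize(filter_spots(compute_ma(a)), span=span)
                  for a in arrays]
    return build_expression_matrix(normalized, sheet)
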