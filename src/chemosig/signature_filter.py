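"""Six-criterion composite gene-selection filter.

A gene is selected when ALL of the following strict inequalities hold on its
differential-expression summaries (adjusted p by default):

1. q < p_max
2. |fc_signed| > fc_min
3. a_mean > a_min
4. max(|m_nr|, |m_ccr|) > mean_min      ("at least one group mean is large")
5. min(s_nr, s_ccr) < sd_max            ("at least one group SD is small")
6. |m_nr - m_ccr| - (s_nr + s_ccr) > sep_min   (group-separation score)

Each criterion is recorded separately in an audit table so a rejection can
be traced to the inequality that caused it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .diffexp import DEResult
from .errors import DomainError

log = logging.getLogger(__name__)

CRITERIA = ["p_ok", "fc_ok", "a_ok", "mean_ok", "sd_ok", "sep_ok"]


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the composite filter (defaults are the published ones)."""

    p_max: float = 0.025
    fc_min: float = 1.3
    a_min: float = 7.0
    mean_min: float = 0.4
    sd_max: float = 0.5
    sep_min: float = -0.55
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        for name in ("p_max", "fc_min", "a_min", "mean_min", "sd_max", "sep_min"):
            if not np.isfinite(getattr(self, name)):
                raise DomainError(f"threshold {name} must be finite")

    def with_(self, **kw) -> "FilterThresholds":
        return replace(self, **kw)


def separation_score(m_nr, m_ccr, s_nr, s_ccr):
    """|m_nr - m_ccr| - (s_nr + s_ccr): positive when groups barely overlap."""
    m_nr, m_ccr = np.asarray(m_nr, float), np.asarray(m_ccr, float)
    s_nr, s_ccr = np.asarray(s_nr, float), np.asarray(s_ccr, float)
    if np.any(s_nr < 0) or np.any(s_ccr < 0):
        raise DomainError("standard deviations must be non-negative")
    return np.abs(m_nr - m_ccr) - (s_nr + s_ccr)


def apply_selection_criteria(de: DEResult,
                             thr: FilterThresholds = FilterThresholds()
                             ) -> tuple[list[str], pd.DataFrame]:
    """Evaluate the six strict inequalities gene by gene.

    Returns (selected gene IDs in input order, boolean audit table with one
    column per criterion plus ``selected``).  Genes with missing summaries
    are skipped (all criteria False) and counted in the log, never passed.
    """
    tab = de.table
    p_col = "q" if thr.use_adjusted_p else "p"
    needed = tab[["m_nr", "m_ccr", "s_nr", "s_ccr", "a_mean", "fc_signed", p_col]]
    complete = needed.notna().all(axis=1).to_numpy()
    n_skipped = int((~complete).sum())
    if n_skipped:
        log.info("selection filter: %d gene(s) skipped for missing summaries",
                 n_skipped)

    with np.errstate(invalid="ignore"):
        sep = separation_score(tab["m_nr"], tab["m_ccr"], tab["s_nr"].fillna(0),
                               tab["s_ccr"].fillna(0))
        audit = pd.DataFrame({
            "p_ok": tab[p_col].to_numpy() < thr.p_max,
            "fc_ok": np.abs(tab["fc_signed"].to_numpy()) > thr.fc_min,
            "a_ok": tab["a_mean"].to_numpy() > thr.a_min,
            "mean_ok": np.maximum(np.abs(tab["m_nr"]), np.abs(tab["m_ccr"]))
                       .to_numpy() > thr.mean_min,
            "sd_ok": np.minimum(tab["s_nr"], tab["s_ccr"]).to_numpy() < thr.sd_max,
            "sep_ok": sep > thr.sep_min,
        }, index=tab.index)
    audit &= complete[:, None]
    audit["selected"] = audit[CRITERIA].all(axis=1)
    selected = list(audit.index[audit["selected"]])
    log.info("selection filter: %d / %d genes pass all six criteria",
             len(selected), len(tab))
    return selected, audit
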