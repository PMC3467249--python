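"""Group summaries, empirical-Bayes moderated t-test, and FDR adjustment.

Per-gene pooled variances are shrunk toward a prior estimated across genes
by moment-matching the log sample variances to a scaled inverse-chi-square
distribution; the resulting moderated t gains ``d0`` prior degrees of
freedom.  Fold changes follow the signed convention: a log2 group difference
d maps to +2^d when d >= 0 and to -2^-d otherwise, oriented non-responder
over responder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DomainError
from .io_formats import SampleSheet
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["m_nr", "m_ccr", "s_nr", "s_ccr", "n_nr", "n_ccr",
                   "a_mean", "fc_signed"]


@dataclass
class DEResult:
    """Per-gene differential-expression table plus shared hyperparameters."""

    table: pd.DataFrame  # columns: SUMMARY_COLUMNS + t_mod, df_total, p, q
    d0: float
    s0_sq: float

    def to_tsv(self, path, config_hash: str = "-") -> None:
        from .io_formats import write_matrix
        write_matrix(self.table, path, config_hash=config_hash)


def signed_fold_change(log2_diff):
    """Map a log2 difference of group means to the signed-ratio convention.

    Ratios >= 1 are reported as +ratio, ratios < 1 as -1/ratio, so
    ``|fc| >= 1`` always and the sign tracks the direction.
    """
    log2_diff = np.asarray(log2_diff, float)
    r = np.power(2.0, log2_diff)
    return np.where(r >= 1, r, -1.0 / r)


def summarize_groups(expr: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene group means/SDs on available values, plus signed fold change.

    Genes with fewer than 2 non-missing values in either class get NaN
    summaries (and are skipped by the downstream filter with a log entry).
    """
    resp = sheet.responses.reindex(expr.samples)
    if resp.isna().any():
        missing = list(expr.samples[resp.isna()])
        raise KeyError(f"samples absent from sheet: {missing}")
    nr = expr.m.loc[:, (resp == "NR").to_numpy()]
    ccr = expr.m.loc[:, (resp == "CCR").to_numpy()]
    n_nr = nr.notna().sum(axis=1)
    n_ccr = ccr.notna().sum(axis=1)
    out = pd.DataFrame(index=expr.genes)
    out["m_nr"] = nr.mean(axis=1).where(n_nr >= 2)
    out["m_ccr"] = ccr.mean(axis=1).where(n_ccr >= 2)
    out["s_nr"] = nr.std(axis=1, ddof=1).where(n_nr >= 2)
    out["s_ccr"] = ccr.std(axis=1, ddof=1).where(n_ccr >= 2)
    out["n_nr"] = n_nr
    out["n_ccr"] = n_ccr
    out["a_mean"] = expr.mean_a()
    diff = out["m_nr"] - out["m_ccr"]
    out["fc_signed"] = signed_fold_change(diff.to_numpy())
    out.loc[diff.isna(), "fc_signed"] = np.nan
    n_bad = int(diff.isna().sum())
    if n_bad:
        log.info("summarize_groups: %d gene(s) lack 2 values in a class", n_bad)
    return out


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    x = np.asarray(x, float)
    y = 0.5 + 1.0 / x  # good starting value for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * np.abs(y)):
            break
    return y


def estimate_prior(s_sq: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled inverse-chi-square prior.

    Returns (d0, s0_sq); d0 = inf when the observed spread of log variances
    is no larger than expected from chi-square sampling alone.
    """
    s_sq = np.asarray(s_sq, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (df > 0)
    z = np.log(s_sq[ok])
    d = df[ok]
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1)
    excess = e_var - np.mean(special.polygamma(1, d / 2))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = float(2 * _trigamma_inverse(np.array([excess]))[0])
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderated_t_test(summaries: pd.DataFrame, d0: float | None = None,
                     s0_sq: float | None = None) -> DEResult:
    """Moderated two-sample t-test from per-gene group summaries.

    Pooled per-gene variances are shrunk to
    ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and the t statistic is referred to
    a t distribution with ``d0 + d_g`` degrees of freedom.  Forcing ``d0=0``
    recovers the ordinary pooled t; ``d0=inf`` replaces every variance by
    ``s0^2``.  With fewer than 10 finite genes the prior cannot be estimated
    and the test falls back to the ordinary t with a warning.
    """
    tab = summaries.copy()
    n1 = tab["n_nr"].to_numpy(float)
    n2 = tab["n_ccr"].to_numpy(float)
    s1 = tab["s_nr"].to_numpy(float)
    s2 = tab["s_ccr"].to_numpy(float)
    d_g = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        s_sq = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / d_g
    ok = np.isfinite(s_sq) & (d_g >= 1)

    if d0 is None or s0_sq is None:
        if int(ok.sum()) < 10:
            log.warning("moderated_t_test: < 10 usable genes; falling back to "
                        "ordinary t (d0 = 0)")
            d0, s0_sq = 0.0, 0.0
        else:
            d0, s0_sq = estimate_prior(s_sq[ok], d_g[ok])
            log.info("moderated_t_test: prior d0=%.3g s0^2=%.4g", d0, s0_sq)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.full_like(s_sq, np.inf)
    else:
        s_tilde_sq = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
        t_mod = (tab["m_nr"].to_numpy(float) - tab["m_ccr"].to_numpy(float)) / se
        # zero spread with zero difference is a no-signal gene, not evidence
        t_mod = np.where((se == 0) &
                         (tab["m_nr"].to_numpy(float) ==
                          tab["m_ccr"].to_numpy(float)), 0.0, t_mod)
    if np.isinf(d0):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    tab["t_mod"] = t_mod
    tab["df_total"] = df_total
    tab["p"] = np.where(ok, p, np.nan)
    tab.loc[~pd.Series(ok, index=tab.index), "t_mod"] = np.nan
    tab["q"] = bh_adjust_with_nan(tab["p"].to_numpy())
    return DEResult(table=tab, d0=float(d0), s0_sq=float(s0_sq))


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise DomainError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    # guard against float round-off in p*m/m: q >= p holds exactly
    return np.maximum(q, p)


def bh_adjust_with_nan(p: np.ndarray) -> np.ndarray:
    """BH over the finite entries only; NaN stays NaN."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = bh_adjust(p[ok])
    return out


def permutation_p(expr: ExpressionMatrix, sheet: SampleSheet,
                  n_perm: int = 1000, seed: int = 0) -> pd.Series:
    """Gene-wise label-permutation p-values for the moderated t statistic.

    Offered as an alternative null to the parametric t; the observed
    statistic is included in the permutation distribution (so p >= 1/(B+1)).
    """
    rng = np.random.default_rng(seed)
    resp = sheet.responses.reindex(expr.samples).to_numpy()
    obs = moderated_t_test(summarize_groups(expr, sheet)).table["t_mod"]
    obs_abs = np.abs(obs.to_numpy())
    exceed = np.zeros(len(obs), dtype=int)
    labels = resp.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        perm_sheet = SampleSheet(pd.DataFrame({
            "patient_id": list(expr.samples), "response": labels,
            "regimen": "PF"}))
        t_perm = moderated_t_test(summarize_groups(expr, perm_sheet)).table["t_mod"]
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(t_perm.to_numpy()) >= obs_abs).astype(int)
    p = (exceed + 1) / (n_perm + 1)
    return pd.Series(p, index=obs.index, name="p_perm")
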