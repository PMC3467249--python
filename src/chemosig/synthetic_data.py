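"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each simulated patient gets a two-channel array measuring log2(sample /
universal reference) per gene: zero baseline for null genes, a signed group
effect planted in the non-responder class for the differential genes,
per-gene biological noise, an intensity-dependent dye bias of the form
``bias_amplitude * sin(A * pi / 8)`` and spot-level noise.  Matching Ct
tables are derived from the same true expression so that cross-platform
transfer can be exercised, and a ground-truth record allows recovery
oracles.  A single seed drives per-array spawned substreams, so adding
arrays never perturbs earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .io_formats import CtTable, SampleSheet, SpotTable
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    n_nr: int = 10
    n_ccr: int = 13
    n_genes: int = 2000          # total probes, controls included
    n_controls: int = 100
    n_de: int = 10               # planted differential genes
    delta: float = 1.0           # planted log2 group difference (magnitude)
    sigma_gene: float = 0.3      # per-gene biological SD, log2 units
    bias_amplitude: float = 0.5  # dye-bias amplitude, log2 units
    spot_noise_sd: float = 0.05  # technical spot noise, log2 units
    flag_fraction: float = 0.01  # fraction of spots randomly flagged bad
    ct_slope: float = 1.0        # cycles per log2-expression unit
    ct_noise_sd: float = 0.1     # cycles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes - self.n_controls:
            raise ValidationError("n_de exceeds non-control probe count")
        if self.sigma_gene <= 0:
            raise ValidationError("sigma_gene must be > 0")
        for name in ("n_nr", "n_ccr", "n_genes", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted differential genes (signed fold change) and true labels."""

    de_genes: pd.Series          # gene ID -> signed planted fold change
    true_class: pd.Series        # patient ID -> NR/CCR

    def __post_init__(self) -> None:
        if (self.de_genes.abs() < 1).any():
            raise ValidationError("|planted fold change| must be >= 1")


def _gene_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    n_real = cfg.n_genes - cfg.n_controls
    genes = [f"GENE{i:05d}" for i in range(n_real)]
    controls = [f"CTRL{i:05d}" for i in range(cfg.n_controls)]
    return genes, controls


def generate_cohort(cfg: SimulationConfig
                    ) -> tuple[list[SpotTable], SampleSheet, GroundTruth,
                               ExpressionMatrix]:
    """Simulate spot tables, a sample sheet, ground truth and the noise-free
    true expression matrix (the latter for concordant Ct generation).

    Planted genes alternate up/down in the non-responder group and are drawn
    from the bright half of the intensity range so the A > 7 selection
    criterion does not erase them; null genes have zero baseline.
    """
    root = np.random.SeedSequence(cfg.seed)
    # fixed-size spawn layout: design stream + one stream per possible array
    design_ss, ct_ss, *array_ss = root.spawn(2 + cfg.n_nr + cfg.n_ccr)
    rng = np.random.default_rng(design_ss)

    genes, controls = _gene_ids(cfg)
    n_real = len(genes)
    # per-gene baseline intensity A; planted genes forced above the filter cut
    a_gene = rng.uniform(6.0, 14.0, size=n_real)
    bright = np.flatnonzero(a_gene > 8.0)
    if len(bright) < cfg.n_de:
        raise DomainError("too few bright genes to plant; increase n_genes")
    de_idx = rng.choice(bright, size=cfg.n_de, replace=False)
    signs = np.where(np.arange(cfg.n_de) % 2 == 0, 1.0, -1.0)
    effect = np.zeros(n_real)
    effect[de_idx] = signs * cfg.delta
    a_control = rng.uniform(6.0, 14.0, size=cfg.n_controls)

    patients = ([f"NR{i+1:03d}" for i in range(cfg.n_nr)]
                + [f"CCR{i+1:03d}" for i in range(cfg.n_ccr)])
    classes = ["NR"] * cfg.n_nr + ["CCR"] * cfg.n_ccr

    arrays: list[SpotTable] = []
    true_m = {}
    for pid, cls, ss in zip(patients, classes, array_ss):
        arng = np.random.default_rng(ss)
        mu = effect if cls == "NR" else np.zeros(n_real)
        m_true = mu + arng.normal(0.0, cfg.sigma_gene, size=n_real)
        true_m[pid] = pd.Series(m_true, index=genes)

        a_spot = np.concatenate([a_gene, a_control]) \
            + arng.normal(0.0, 0.25, size=cfg.n_genes)
        m_clean = np.concatenate([m_true, np.zeros(cfg.n_controls)])
        bias = cfg.bias_amplitude * np.sin(a_spot * np.pi / 8)
        m_spot = m_clean + bias + arng.normal(0.0, cfg.spot_noise_sd,
                                              size=cfg.n_genes)
        cy5 = np.power(2.0, a_spot + m_spot / 2)
        cy3 = np.power(2.0, a_spot - m_spot / 2)
        flags = np.zeros(cfg.n_genes, dtype=int)
        bad = arng.random(cfg.n_genes) < cfg.flag_fraction
        bad[de_idx] = False  # keep the planted signal observable on every array
        flags[bad] = arng.choice([-50, -75, -100], size=int(bad.sum()))
        df = pd.DataFrame({
            "probe_id": [f"P{i:06d}" for i in range(cfg.n_genes)],
            "gene_symbol": genes + controls,
            "cy5_fg": cy5,
            "cy3_fg": cy3,
            "flag": flags,
            "is_control": [False] * n_real + [True] * cfg.n_controls,
        })
        arrays.append(SpotTable(array_id=pid, data=df))

    sheet_rng = np.random.default_rng(design_ss.spawn(1)[0])
    n = len(patients)
    sheet = SampleSheet(pd.DataFrame({
        "patient_id": patients,
        "response": classes,
        "regimen": "PF",
        "hpv": sheet_rng.choice(["positive", "negative"], size=n),
        "cigarettes_per_day": sheet_rng.integers(0, 60, size=n),
        "alcohol_l_per_day": np.round(sheet_rng.uniform(0, 3, size=n), 1),
        "hemoglobin": np.round(sheet_rng.normal(12.5, 1.0, size=n), 1),
        "age": sheet_rng.integers(44, 72, size=n),
    }))

    fc = np.power(2.0, np.abs(effect[de_idx])) * signs
    truth = GroundTruth(
        de_genes=pd.Series(fc, index=[genes[i] for i in de_idx]).sort_index(),
        true_class=pd.Series(classes, index=patients))
    expr_true = pd.DataFrame(true_m)[patients]
    a_mat = pd.DataFrame(
        np.tile(a_gene[:, None], (1, n)), index=genes, columns=patients)
    log.info("simulated cohort: %d arrays, %d genes (%d controls), %d planted",
             n, cfg.n_genes, cfg.n_controls, cfg.n_de)
    return arrays, sheet, truth, ExpressionMatrix(m=expr_true, a=a_mat)


CT_BASELINE = 25.0
CALIBRATOR_ID = "calibrator"
REFERENCE_GENE = "GAPDH"


def generate_ct_table(expr: ExpressionMatrix, genes: list[str],
                      cfg: SimulationConfig,
                      samples: list[str] | None = None) -> CtTable:
    """Ct tables concordant with an expression matrix.

    ``Ct = 25 - ct_slope * M + N(0, ct_noise_sd)`` with two replicates per
    (sample, gene); the reference gene and the calibrator sample are
    generated at M = 0.
    """
    missing = [g for g in genes if g not in expr.m.index]
    if missing:
        raise KeyError(f"gene(s) absent from expression matrix: {missing}")
    if cfg.ct_slope <= 0:
        raise ValidationError("ct_slope must be > 0")
    samples = list(expr.samples) if samples is None else list(samples)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    rows = []
    all_genes = list(genes) + [REFERENCE_GENE]
    for sid in samples + [CALIBRATOR_ID]:
        for gene in all_genes:
            if sid == CALIBRATOR_ID or gene == REFERENCE_GENE:
                m = 0.0
            else:
                m = float(expr.m.loc[gene, sid])
            for rep in (1, 2):
                ct = CT_BASELINE - cfg.ct_slope * m \
                    + rng.normal(0.0, cfg.ct_noise_sd)
                rows.append((sid, gene, rep, ct))
    df = pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
    df["undetermined"] = False
    return CtTable(df, reference_gene=REFERENCE_GENE,
                   calibrator_id=CALIBRATOR_ID)


def classify_response(percent_decrease: float | None,
                      progressed: bool) -> str:
    """Map a tumor-size decrease to a response class.

    >90% decrease -> CCR; <50% decrease or progression -> NR; anything in
    the closed interval [50, 90] -> 'excluded' (the study design keeps only
    the two extreme groups; both published inequalities are strict).
    """
    if progressed:
        return "NR"
    if percent_decrease is None or not (0 <= percent_decrease <= 100):
        raise DomainError(
            f"percent_decrease must be in [0, 100] (got {percent_decrease!r}) "
            "unless progression is flagged")
    if percent_decrease > 90:
        return "CCR"
    if percent_decrease < 50:
        return "NR"
    return "excluded"
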