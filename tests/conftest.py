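import logging

import numpy as np
import pandas as pd
import pytest

from chemosig.io_formats import SampleSheet, SpotTable
from chemosig.preprocess import ExpressionMatrix, preprocess_arrays
from chemosig.synthetic_data import SimulationConfig, generate_cohort

logging.getLogger("chemosig").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_nr=10, n_ccr=13, n_genes=400, n_controls=40,
                            n_de=10, delta=2.0, sigma_gene=0.2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """A separable synthetic cohort shared by classifier-level tests."""
    arrays, sheet, truth, expr_true = generate_cohort(small_cfg)
    return {"arrays": arrays, "sheet": sheet, "truth": truth,
            "expr_true": expr_true}


@pytest.fixture(scope="session")
def small_expr(small_cohort) -> ExpressionMatrix:
    return preprocess_arrays(small_cohort["arrays"], small_cohort["sheet"])


def make_spot_table(n: int = 100, n_flagged: int = 0, n_control: int = 0,
                    seed: int = 0, array_id: str = "A1") -> SpotTable:
    """Handmade spot table: flat intensities, configurable flags/controls."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(7, 12, size=n)
    m = rng.normal(0, 0.2, size=n)
    flags = np.zeros(n, dtype=int)
    if n_flagged:
        flags[:n_flagged] = -100
    is_control = np.zeros(n, dtype=bool)
    if n_control:
        is_control[n_flagged:n_flagged + n_control] = True
    df = pd.DataFrame({
        "probe_id": [f"P{i}" for i in range(n)],
        "gene_symbol": [f"G{i}" for i in range(n)],
        "cy5_fg": 2 ** (a + m / 2),
        "cy3_fg": 2 ** (a - m / 2),
        "flag": flags,
        "is_control": is_control,
    })
    return SpotTable(array_id=array_id, data=df)


def make_sheet(n_nr: int, n_ccr: int) -> SampleSheet:
    ids = [f"NR{i}" for i in range(n_nr)] + [f"CCR{i}" for i in range(n_ccr)]
    return SampleSheet(pd.DataFrame({
        "patient_id": ids,
        "response": ["NR"] * n_nr + ["CCR"] * n_ccr,
        "regimen": "PF",
    }))
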