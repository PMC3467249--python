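"""Reference tables bundled with the package.

These are transcriptions of the published study tables that the pipeline is
benchmarked against: the per-patient clinical covariates of the three
induction-regimen cohorts, the reported per-cohort classification counts,
the HPV contingency counts of the microarray cohort, and the ten-gene panel
with its reported fold changes.  They serve as fixed inputs for the
desk-scale reproduction of the published summary statistics; no expression
data is bundled (the raw cohort measurements are not reproducible offline).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import SampleSheet

#: reported per-cohort prediction counts:
#: cohort -> (NR correct, NR total, CCR correct, CCR total)
CLASSIFICATION_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "MA": (7, 10, 12, 13),
    "TLDA_22": (8, 10, 12, 12),
    "TLDA_27": (13, 15, 12, 12),
    "T1PF": (2, 4, 0, 4),
    "T2PF": (0, 2, 2, 6),
}

#: HPV positivity in the microarray cohort: [[NR+, NR-], [CCR+, CCR-]]
#: (one responder with unknown status is excluded)
HPV_TABLE = [[3, 7], [10, 2]]

#: the ten signature genes with their reported signed fold changes and
#: p-values on each platform: gene -> (ma_fc, ma_p, tlda_fc, tlda_p)
SIGNATURE_PANEL: dict[str, tuple[float, float, float, float]] = {
    "ODZ2": (3.45, 2e-5, 6.04, 0.0042),
    "DLL1": (1.82, 6e-4, 2.65, 0.0025),
    "PLSCR4": (-1.35, 0.004, -3.23, 0.0014),
    "ZNF462": (1.41, 0.016, 1.39, 0.1996),
    "TXNDC9": (1.44, 0.019, 1.06, 0.720),
    "TCP1": (1.33, 0.028, 1.06, 0.674),
    "SSB": (1.37, 0.246, 1.06, 0.675),
    "RPL10": (-1.39, 0.022, -1.52, 0.156),
    "MORF4L1": (1.27, 0.151, -1.32, 0.340),
    "DNAJA1": (1.11, 0.075, -1.04, 0.839),
}

_ALCOHOL_NUMERIC = {"0": 0.0, "1": 1.0, "2": 2.0, "3": 3.0}


def load_cohort_table() -> pd.DataFrame:
    """The full 44-patient covariate table as transcribed (printed tokens kept)."""
    with resources.files("chemosig.data").joinpath("cohort_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"patient_id": str})
    return df


def load_sample_sheet(study: str | None = None,
                      regimen: str | None = None) -> SampleSheet:
    """Cohort covariates as a pipeline sample sheet.

    ``study`` filters on membership ("MA" keeps the 23 microarray patients,
    "TLDA" the 43 card-assayed patients); ``regimen`` filters on therapy.
    Qualitative alcohol entries (e.g. ">2") are stored as missing in the
    numeric column; HPV status is per-cohort aggregate only and therefore
    marked unknown per patient.
    """
    df = load_cohort_table()
    if study is not None:
        df = df[df["study"].str.contains(study)]
    if regimen is not None:
        df = df[df["regimen"] == regimen]
    sheet = pd.DataFrame({
        "patient_id": df["patient_id"],
        "response": df["response"],
        "regimen": df["regimen"],
        "hpv": "unknown",
        "cigarettes_per_day": df["cigarettes_per_day"],
        "alcohol_l_per_day": df["alcohol_printed"].map(_ALCOHOL_NUMERIC),
        "hemoglobin": df["hemoglobin"],
        "age": df["age"],
    }).reset_index(drop=True)
    return SampleSheet(sheet)


def ma_cohort_values(column: str) -> tuple[list[float], list[float]]:
    """(NR values, CCR values) of a numeric covariate in the 23-patient
    microarray cohort."""
    sheet = load_sample_sheet(study="MA").data
    nr = sheet.loc[sheet["response"] == "NR", column].dropna().tolist()
    ccr = sheet.loc[sheet["response"] == "CCR", column].dropna().tolist()
    return nr, ccr
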