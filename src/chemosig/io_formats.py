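"""Readers and writers for the on-disk tables the pipeline touches.

Three formats are handled here: GenePix-style per-spot two-channel tables
(tab-separated, one file per array), clinical sample sheets (CSV or TSV) and
long-format Ct tables from low-density qRT-PCR cards.  Every writer prepends
a comment line carrying the package version and a configuration hash so that
outputs are traceable; every reader validates against the format invariants
and raises instead of silently dropping rows.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .errors import (
    FormatError,
    IntegrityError,
    ParseError,
    ValidationError,
    VocabularyError,
)

log = logging.getLogger(__name__)

RESPONSE_VOCAB = frozenset({"NR", "CCR"})
REGIMEN_VOCAB = frozenset({"PF", "T1PF", "T2PF"})
HPV_VOCAB = frozenset({"positive", "negative", "unknown"})

#: token(s) a qPCR export uses for a reaction that never crossed threshold
UNDETERMINED_TOKENS = frozenset({"Undetermined", "undetermined", "UNDETERMINED"})


def header_comment(config_hash: str = "-") -> str:
    return f"# chemosig={__version__} config={config_hash}"


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotDialect:
    """Column naming and flag vocabulary of a per-spot export.

    The default mirrors GenePix-era tab-separated exports: named columns for
    the two foreground channels, an integer quality flag and a control-type
    marker.  Flag codes: 0 good, -50 not found, -75 bad, -100 saturated.
    """

    probe_id: str = "ProbeID"
    gene_symbol: str = "GeneSymbol"
    cy5: str = "F635"
    cy3: str = "F532"
    flag: str = "Flags"
    control: str = "ControlType"
    flag_codes: frozenset = frozenset({0, -50, -75, -100})

    @property
    def columns(self) -> list[str]:
        return [self.probe_id, self.gene_symbol, self.cy5, self.cy3,
                self.flag, self.control]


DEFAULT_DIALECT = SpotDialect()

SPOT_COLUMNS = ["probe_id", "gene_symbol", "cy5_fg", "cy3_fg", "flag", "is_control"]


@dataclass
class SpotTable:
    """Spot-level two-channel intensities for one array."""

    array_id: str
    data: pd.DataFrame  # columns: SPOT_COLUMNS (+ m/a/m_norm once normalized)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"SpotTable missing columns: {missing}")
        if (self.data["probe_id"].astype(str).str.len() == 0).any():
            raise ValidationError("empty probe_id in SpotTable")
        good = self.data["flag"] == 0
        inten = self.data.loc[good, ["cy5_fg", "cy3_fg"]].to_numpy(float)
        if inten.size and not (np.isfinite(inten).all() and (inten > 0).all()):
            raise ValidationError(
                f"array {self.array_id}: non-positive or non-finite intensity "
                "on an unflagged spot")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "SpotTable":
        return replace(self, data=self.data.copy())


def read_spot_table(path, dialect: SpotDialect = DEFAULT_DIALECT,
                    array_id: str | None = None) -> SpotTable:
    """Read one per-spot table; flags are preserved verbatim.

    Leading block-header lines (ATF/GPR preambles, ``#`` comments) are
    skipped; the first line containing every dialect column is taken as the
    header.  Non-numeric intensities raise :class:`ParseError` with the
    physical line number.
    """
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            continue
        fields = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]
        if all(col in fields for col in dialect.columns):
            header_idx = i
            break
    if header_idx is None:
        present: set[str] = set()
        for line in lines:
            present.update(f.strip().strip('"') for f in line.split("\t"))
        missing = [c for c in dialect.columns if c not in present]
        raise FormatError(f"{path}: missing column(s) {missing}")

    df = pd.read_csv(io.StringIO("".join(lines[header_idx:])), sep="\t",
                     dtype=str, comment="#")
    df.columns = [c.strip().strip('"') for c in df.columns]
    if df.empty:
        log.warning("%s: header only, no spots", path)

    out = pd.DataFrame({
        "probe_id": df[dialect.probe_id].astype(str),
        "gene_symbol": df[dialect.gene_symbol].astype(str),
    })
    for src, dst in ((dialect.cy5, "cy5_fg"), (dialect.cy3, "cy3_fg")):
        vals = pd.to_numeric(df[src], errors="coerce")
        bad = vals.isna() & df[src].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric intensity {df[src].iloc[row]!r} "
                f"in column {src}", line=header_idx + 2 + row)
        out[dst] = vals.astype(float)
    flags = pd.to_numeric(df[dialect.flag], errors="coerce")
    if flags.isna().any():
        row = int(np.flatnonzero(flags.isna().to_numpy())[0])
        raise ParseError(f"{path}: non-numeric flag", line=header_idx + 2 + row)
    out["flag"] = flags.astype(int)
    unknown = set(out["flag"]) - set(dialect.flag_codes)
    if unknown:
        raise ValidationError(f"{path}: flag codes outside dialect: {sorted(unknown)}")
    out["is_control"] = (
        pd.to_numeric(df[dialect.control], errors="coerce").fillna(0).astype(int) != 0
    )
    if array_id is None:
        import os
        array_id = os.path.splitext(os.path.basename(path))[0]
    table = SpotTable(array_id=array_id, data=out.reset_index(drop=True))
    log.info("%s: read %d spots", path, len(table))
    return table


def write_spot_table(table: SpotTable, path,
                     dialect: SpotDialect = DEFAULT_DIALECT,
                     config_hash: str = "-") -> None:
    df = pd.DataFrame({
        dialect.probe_id: table.data["probe_id"],
        dialect.gene_symbol: table.data["gene_symbol"],
        dialect.cy5: table.data["cy5_fg"],
        dialect.cy3: table.data["cy3_fg"],
        dialect.flag: table.data["flag"],
        dialect.control: table.data["is_control"].astype(int),
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_comment(config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["patient_id", "response", "regimen", "hpv",
                 "cigarettes_per_day", "alcohol_l_per_day", "hemoglobin", "age"]
_OPTIONAL_SHEET = {"hpv", "cigarettes_per_day", "alcohol_l_per_day",
                   "hemoglobin", "age"}


@dataclass
class SampleSheet:
    """Per-patient clinical covariates plus response class and regimen."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("patient_id", "response", "regimen")
                   if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df["patient_id"].duplicated().any():
            dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise IntegrityError(f"duplicate patient_id(s): {dupes}")
        bad = set(df["response"]) - RESPONSE_VOCAB
        if bad:
            raise VocabularyError(f"response value(s) outside {{NR, CCR}}: {sorted(bad)}")
        bad = set(df["regimen"]) - REGIMEN_VOCAB
        if bad:
            raise VocabularyError(
                f"regimen value(s) outside {{PF, T1PF, T2PF}}: {sorted(bad)}")
        if "hpv" in df.columns:
            bad = set(df["hpv"].dropna()) - HPV_VOCAB
            if bad:
                raise VocabularyError(f"hpv value(s) outside vocabulary: {sorted(bad)}")
        if "hemoglobin" in df.columns:
            hb = pd.to_numeric(df["hemoglobin"], errors="coerce").dropna()
            if ((hb <= 5) | (hb >= 25)).any():
                raise ValidationError("hemoglobin outside (5, 25) g/dL")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def responses(self) -> pd.Series:
        return self.data.set_index("patient_id")["response"]

    def class_counts(self) -> dict:
        return self.data["response"].value_counts().to_dict()

    def subset(self, patient_ids) -> "SampleSheet":
        keep = self.data["patient_id"].isin(list(patient_ids))
        return SampleSheet(self.data.loc[keep].reset_index(drop=True))


def read_sample_sheet(path) -> SampleSheet:
    """Read a CSV or TSV sample sheet (separator sniffed from the header)."""
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("cigarettes_per_day", "alcohol_l_per_day", "hemoglobin", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "hpv" in df.columns:
        df["hpv"] = df["hpv"].where(df["hpv"].notna(), None)
    return SampleSheet(df.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path, config_hash: str = "-") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_comment(config_hash) + "\n")
        sheet.data.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Long-format Ct replicates with a reference gene and calibrator sample.

    Undetermined wells carry ``NaN`` in ``ct`` and ``True`` in the
    ``undetermined`` column; the policy for handling them is decided by the
    relative-quantification stage, not here.
    """

    data: pd.DataFrame  # columns: sample_id, gene, replicate, ct, undetermined
    reference_gene: str
    calibrator_id: str

    def __post_init__(self) -> None:
        df = self.data
        required = ["sample_id", "gene", "replicate", "ct"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise IntegrityError(f"Ct table missing column(s): {missing}")
        if "undetermined" not in df.columns:
            df["undetermined"] = df["ct"].isna()
        dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            trip = df.loc[dup, ["sample_id", "gene", "replicate"]].iloc[0].tolist()
            raise IntegrityError(f"duplicate (sample, gene, replicate) triple: {trip}")
        ct = df["ct"].dropna()
        if ((ct <= 0) | (ct > 40)).any():
            raise ValidationError("determined Ct outside (0, 40]")
        for sid in df["sample_id"].unique():
            genes = set(df.loc[df["sample_id"] == sid, "gene"])
            if self.reference_gene not in genes:
                raise IntegrityError(
                    f"reference gene {self.reference_gene!r} absent for "
                    f"sample {sid!r}")

    def __len__(self) -> int:
        return len(self.data)

    def replicate_counts(self) -> pd.Series:
        return self.data.groupby(["sample_id", "gene"])["replicate"].count()


def read_ct_table(path, reference_gene: str | None = None,
                  calibrator_id: str | None = None) -> CtTable:
    """Read a long-format Ct TSV.

    ``reference_gene`` / ``calibrator_id`` default to the values stored in
    the file's ``# reference_gene=...`` / ``# calibrator_id=...`` comment
    lines written by :func:`write_ct_table`.
    """
    path = str(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in ("sample_id", "gene", "replicate", "ct"):
        if col not in df.columns:
            raise IntegrityError(f"{path}: missing column {col!r}")
    undet = df["ct"].isin(UNDETERMINED_TOKENS)
    ct = pd.to_numeric(df["ct"].where(~undet), errors="coerce")
    bad = ct.isna() & ~undet & df["ct"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: unparseable ct {df['ct'].iloc[row]!r}",
                         line=row + 2)
    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "gene": df["gene"].astype(str),
        "replicate": pd.to_numeric(df["replicate"]).astype(int),
        "ct": ct.astype(float),
        "undetermined": undet.to_numpy(),
    })
    if undet.any():
        log.warning("%s: %d undetermined Ct well(s) flagged", path, int(undet.sum()))
    reference_gene = reference_gene or meta.get("reference_gene")
    calibrator_id = calibrator_id or meta.get("calibrator_id")
    if reference_gene is None or calibrator_id is None:
        raise FormatError(
            f"{path}: reference_gene/calibrator_id neither given nor stored "
            "in header comments")
    return CtTable(out.reset_index(drop=True), reference_gene=reference_gene,
                   calibrator_id=calibrator_id)


def write_ct_table(table: CtTable, path, config_hash: str = "-") -> None:
    df = table.data.copy()
    df["ct"] = df["ct"].astype(object)
    df.loc[df["undetermined"], "ct"] = "Undetermined"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_comment(config_hash) + "\n")
        fh.write(f"# reference_gene={table.reference_gene}\n")
        fh.write(f"# calibrator_id={table.calibrator_id}\n")
        df[["sample_id", "gene", "replicate", "ct"]].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices (genes x samples TSV)
# ---------------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path, id_label: str = "gene",
                 config_hash: str = "-") -> None:
    """Write a genes-as-rows matrix with the gene ID as first column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_comment(config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=True, index_label=id_label)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return df
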