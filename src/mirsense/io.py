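"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
Expression matrices and GI50 panels are TSV/CSV with the first column
holding feature (or drug) identifiers and the header row holding sample
(or cell-line) identifiers; ``NA`` marks a missing value.  Signatures
are TSV with ``# treatment=`` / ``# threshold=`` header lines.  Clinical
tables are CSV with one row per patient.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DrugResponsePanel,
    ExpressionMatrix,
    PatientRecord,
    ResponseSignature,
    SubtypeProfile,
    ValidationError,
)

CLINICAL_COLUMNS = [
    "patient_id",
    "ipi",
    "treatment",
    "response",
    "os_days",
    "os_event",
    "pfs_days",
    "pfs_event",
    "relapse",
    "relapse_regimens",
]

_SEP = {"tsv": "\t", "csv": ","}


def _infer_dialect(path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _SEP:
            raise ValueError(f"dialect must be one of {sorted(_SEP)}, got {dialect!r}")
        return dialect
    return "csv" if str(path).endswith(".csv") else "tsv"


def _read_numeric_matrix(path, dialect: str | None) -> pd.DataFrame:
    """Read an id-indexed numeric matrix, locating any non-numeric cell."""
    sep = _SEP[_infer_dialect(path, dialect)]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if pd.Index(raw.index).has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate row ids in {path}: {dup}")
    if pd.Index(raw.columns).has_duplicates:
        dup = pd.Index(raw.columns)
        dup = dup[dup.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate column ids in {path}: {dup}")
    out = {}
    for col in raw.columns:
        cell = raw[col].str.strip()
        missing = cell.isin(["NA", "", "NaN", "nan"])
        converted = pd.to_numeric(cell.mask(missing), errors="coerce")
        bad = converted.isna() & ~missing
        if bad.any():
            row_id = raw.index[bad][0]
            raise ValidationError(
                f"non-numeric value {cell[bad].iloc[0]!r} in {path} at "
                f"row {row_id!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=raw.index)


def read_expression_matrix(path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a features-x-samples log2 expression matrix.

    First column = feature ids, header row = sample ids; ``NA`` cells
    are stored as missing (never coerced to zero).
    """
    return ExpressionMatrix(_read_numeric_matrix(path, dialect))


def write_expression_matrix(matrix: ExpressionMatrix, path, dialect: str | None = None) -> None:
    sep = _SEP[_infer_dialect(path, dialect)]
    matrix.values.to_csv(path, sep=sep, na_rep="NA", index_label="feature_id")


def read_gi50_table(path, scale: str = "neg_log10", dialect: str | None = None) -> DrugResponsePanel:
    """Read a drugs-x-cell-lines GI50 table.

    ``scale`` declares the input encoding: ``"gi50_molar"`` values are
    molar concentrations and are transformed to −log10(GI50);
    ``"neg_log10"`` values are already −log10(GI50) and pass through.
    """
    df = _read_numeric_matrix(path, dialect)
    if scale == "gi50_molar":
        vals = df.to_numpy()
        nonpos = np.where(np.nan_to_num(vals, nan=1.0) <= 0)
        if nonpos[0].size:
            i, j = nonpos[0][0], nonpos[1][0]
            raise ValidationError(
                f"non-positive molar GI50 ({vals[i, j]}) at drug "
                f"{df.index[i]!r}, cell line {df.columns[j]!r}: log undefined"
            )
        df = -np.log10(df)
    elif scale != "neg_log10":
        raise ValueError(
            f"scale must be 'gi50_molar' or 'neg_log10', got {scale!r}"
        )
    return DrugResponsePanel(df)


def write_gi50_table(panel: DrugResponsePanel, path, dialect: str | None = None) -> None:
    """Write a panel as a −log10(GI50) table (scale='neg_log10' on re-read)."""
    sep = _SEP[_infer_dialect(path, dialect)]
    panel.values.to_csv(path, sep=sep, na_rep="NA", index_label="drug")


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def read_clinical_table(path) -> list[PatientRecord]:
    """Read a clinical CSV into validated patient records.

    Response labels are matched case-insensitively against the seven
    allowed categories; ``relapse_regimens`` is a semicolon-separated
    list (possibly empty).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        regimens = tuple(
            r.strip() for r in str(row["relapse_regimens"]).split(";") if r.strip()
        )
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                ipi=int(float(row["ipi"])),
                treatment=row["treatment"],
                response=row["response"],
                os_days=float(row["os_days"]),
                os_event=_parse_bool(row["os_event"]),
                pfs_days=float(row["pfs_days"]),
                pfs_event=_parse_bool(row["pfs_event"]),
                relapse=_parse_bool(row["relapse"]),
                relapse_regimens=regimens,
            )
        )
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate patient ids in clinical table: {dup}")
    return records


def write_clinical_table(records: Sequence[PatientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "ipi": r.ipi,
                "treatment": r.treatment,
                "response": r.response,
                "os_days": repr(r.os_days),
                "os_event": int(r.os_event),
                "pfs_days": repr(r.pfs_days),
                "pfs_event": int(r.pfs_event),
                "relapse": int(r.relapse),
                "relapse_regimens": ";".join(r.relapse_regimens),
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def read_signature(path) -> ResponseSignature:
    """Read a signature TSV (``# treatment=``/``# threshold=`` header
    lines, then ``feature_id`` and ``selection_correlation`` columns;
    extra columns are preserved but unused)."""
    text = Path(path).read_text()
    treatment, threshold = None, None
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("treatment="):
                treatment = stripped.split("=", 1)[1].strip()
            elif stripped.startswith("threshold="):
                threshold = float(stripped.split("=", 1)[1])
        elif line.strip():
            body.append(line)
    if treatment is None or threshold is None:
        raise ValidationError(
            f"signature file {path} lacks '# treatment=' / '# threshold=' headers"
        )
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
    for col in ("feature_id", "selection_correlation"):
        if col not in df.columns:
            raise ValidationError(f"signature file {path} missing column {col!r}")
    entries = tuple(
        zip(df["feature_id"].astype(str), df["selection_correlation"].astype(float))
    )
    extra_cols = [c for c in df.columns if c not in ("feature_id", "selection_correlation")]
    extra = df.set_index("feature_id")[extra_cols] if extra_cols else None
    return ResponseSignature(
        treatment_name=treatment, entries=entries, threshold=threshold, extra=extra
    )


def write_signature(signature: ResponseSignature, path) -> None:
    """Write a signature TSV; write-then-read is the identity on the
    treatment name, threshold and entries (full float precision)."""
    with open(path, "w") as fh:
        fh.write(f"# treatment={signature.treatment_name}\n")
        fh.write(f"# threshold={signature.threshold!r}\n")
        fh.write("feature_id\tselection_correlation\n")
        for feat, r in signature.entries:
            fh.write(f"{feat}\t{r!r}\n")


def chop_signature() -> ResponseSignature:
    """The packaged 20-probe CHOP response signature.

    The distributed signature lists, for each probe, its Pearson
    correlation with in-vitro sensitivity to each CHOP component drug
    (vincristine, doxorubicin, cyclophosphamide) and with in-vivo
    remission.  The correlation against the summed combination vector
    was not published, so ``selection_correlation`` stores the strongest
    single-component correlation as a documented stand-in; all scoring
    uses only the feature list (equal weighting), never these values.
    """
    ref = resources.files("mirsense.data").joinpath("chop_signature.tsv")
    with resources.as_file(ref) as p:
        return read_signature(p)


def read_subtype_profile(path) -> SubtypeProfile:
    """Read a subtype profile TSV with columns ``feature_id`` and
    ``group`` (GCB or ABC)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("feature_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"subtype profile missing column {col!r}")
    group = df["group"].str.strip().str.upper()
    bad = sorted(set(group) - {"GCB", "ABC"})
    if bad:
        raise ValidationError(f"unknown subtype group labels: {bad}")
    return SubtypeProfile(
        gcb_features=tuple(df.loc[group == "GCB", "feature_id"]),
        abc_features=tuple(df.loc[group == "ABC", "feature_id"]),
    )


@dataclass
class AlignedCohort:
    """An expression matrix restricted to, and ordered like, the clinical
    cohort it was joined against; dropped ids on either side are kept
    for reporting."""

    expression: ExpressionMatrix
    records: list[PatientRecord]
    dropped_samples: tuple[str, ...]
    dropped_patients: tuple[str, ...]


def align(expr: ExpressionMatrix, cohort: Sequence[PatientRecord]) -> AlignedCohort:
    """Join expression columns with clinical rows on patient id.

    Returns the intersection in cohort order and reports ids dropped on
    both sides; an empty intersection is an error.
    """
    sample_ids = set(expr.sample_ids)
    kept = [r for r in cohort if r.patient_id in sample_ids]
    if not kept:
        raise ValidationError(
            "no overlap between expression sample ids and cohort patient ids"
        )
    kept_ids = [r.patient_id for r in kept]
    dropped_patients = tuple(
        r.patient_id for r in cohort if r.patient_id not in sample_ids
    )
    dropped_samples = tuple(s for s in expr.sample_ids if s not in set(kept_ids))
    return AlignedCohort(
        expression=expr.subset_samples(kept_ids),
        records=list(kept),
        dropped_samples=dropped_samples,
        dropped_patients=dropped_patients,
    )
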