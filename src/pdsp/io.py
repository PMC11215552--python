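"""Readers and writers for the package's tabular formats and checkpoints.

All tables are delimited text with a header row (tab by default, comma via
``sep=","``).  Validation is total: malformed input raises a
:class:`~pdsp.records.ValidationError` that names the offending row, column
or identifier, and nothing is silently coerced.

Formats
-------
drug features     first column ``drug_id``, remaining columns numeric
expression        genes x samples (or transposed with ``orientation``)
synergy           columns ``drug_i``, ``drug_j``, ``context``, ``bliss``
sensitivity       columns ``drug``, ``context`` and exactly one of
                  ``ln_ic50`` / ``label``
predictions       ``drug_i``, ``drug_j``, ``context``, ``y_hat``,
                  ``s_hat_i``, ``s_hat_j``
checkpoint        versioned ``.npz`` archive: parameter arrays plus the full
                  architecture config used at train time
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    Domain,
    DrugProfile,
    ExpressionMatrix,
    SensitivityRecord,
    SynergyRecord,
    ValidationError,
)

CHECKPOINT_SCHEMA = "pdsp-checkpoint-1"


def _read_table(path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed table ({exc})") from exc
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected at least 2 columns with sep={sep!r}")
    return df


def _numeric_block(df: pd.DataFrame, path, id_col: str) -> np.ndarray:
    """Convert all non-id columns to float, locating any bad cell."""
    body = df.drop(columns=[id_col])
    converted = body.apply(pd.to_numeric, errors="coerce")
    bad = converted.isna() | (body == "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {body.iat[r, c]!r} at row "
            f"{df[id_col].iat[r]!r}, column {body.columns[c]!r}"
        )
    return converted.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# drug features

def read_drug_features(path, sep: str = "\t") -> list[DrugProfile]:
    """Read a drug chemical-descriptor table, one fixed-length row per drug."""
    df = _read_table(path, sep)
    id_col = df.columns[0]
    ids = df[id_col].tolist()
    dupes = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dupes.empty:
        raise ValidationError(f"{path}: duplicate drug_id {dupes.iloc[0]!r}")
    feats = _numeric_block(df, path, id_col)
    return [DrugProfile(i, feats[k]) for k, i in enumerate(ids)]


def write_drug_features(profiles: Sequence[DrugProfile], path, sep: str = "\t") -> None:
    d = len(profiles[0].features)
    cols = [f"x{k}" for k in range(d)]
    df = pd.DataFrame([p.features for p in profiles], columns=cols)
    df.insert(0, "drug_id", [p.drug_id for p in profiles])
    df.to_csv(path, sep=sep, index=False)


def drug_feature_dict(profiles: Sequence[DrugProfile]) -> dict[str, np.ndarray]:
    widths = {len(p.features) for p in profiles}
    if len(widths) > 1:
        raise ValidationError(f"inconsistent drug feature widths: {sorted(widths)}")
    return {p.drug_id: p.features for p in profiles}


# ---------------------------------------------------------------------------
# expression

def read_expression_matrix(
    path,
    domain: Domain | str,
    orientation: str = "genes_by_samples",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read an expression table and tag every sample with ``domain``.

    ``orientation="samples_by_genes"`` transposes on read, so a transposed
    export round-trips to the identical matrix.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sep)
    id_col = df.columns[0]
    row_ids = df[id_col].tolist()
    col_ids = list(df.columns[1:])
    if len(set(row_ids)) != len(row_ids) or len(set(col_ids)) != len(col_ids):
        kind = "gene" if orientation == "genes_by_samples" else "sample"
        raise ValidationError(f"{path}: duplicate {kind} or column id")
    values = _numeric_block(df, path, id_col)
    if orientation == "samples_by_genes":
        return ExpressionMatrix(col_ids, row_ids, values.T, Domain(domain))
    return ExpressionMatrix(row_ids, col_ids, values, Domain(domain))


def write_expression_matrix(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# synergy / sensitivity

_SYNERGY_SCORE_ALIASES = ("bliss", "score", "synergy")


def read_synergy_table(path, sep: str = "\t") -> list[SynergyRecord]:
    """Read (drug_i, drug_j, context, bliss) rows, canonicalizing pair order.

    Replicate rows are preserved as-is; averaging is a separate preprocessing
    step.
    """
    df = _read_table(path, sep)
    required = {"drug_i", "drug_j", "context"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    score_col = next((c for c in _SYNERGY_SCORE_ALIASES if c in df.columns), None)
    if score_col is None:
        raise ValidationError(
            f"{path}: no synergy score column (expected one of "
            f"{_SYNERGY_SCORE_ALIASES})"
        )
    unknown = set(df.columns) - required - {score_col}
    if unknown:
        raise ValidationError(f"{path}: unknown columns {sorted(unknown)}")

    out = []
    for idx, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        try:
            bliss = float(d[score_col])
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-numeric score {d[score_col]!r} at row {idx}"
            ) from exc
        out.append(
            SynergyRecord(d["drug_i"], d["drug_j"], d["context"], bliss).canonical()
        )
    return out


def write_synergy_table(records: Sequence[SynergyRecord], path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [(r.drug_i, r.drug_j, r.context_id, r.bliss) for r in records],
        columns=["drug_i", "drug_j", "context", "bliss"],
    )
    df.to_csv(path, sep=sep, index=False)


def read_sensitivity_table(path, sep: str = "\t") -> list[SensitivityRecord]:
    """Read (drug, context, ln_ic50 | label) rows.

    A file carrying both a ``ln_ic50`` and a ``label`` column is rejected:
    the label source would be ambiguous.
    """
    df = _read_table(path, sep)
    required = {"drug", "context"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    has_ic50 = "ln_ic50" in df.columns
    has_label = "label" in df.columns
    if has_ic50 and has_label:
        raise ValidationError(f"{path}: ambiguous label source (both ln_ic50 and label)")
    if not (has_ic50 or has_label):
        raise ValidationError(f"{path}: need a ln_ic50 or label column")
    unknown = set(df.columns) - required - {"ln_ic50", "label"}
    if unknown:
        raise ValidationError(f"{path}: unknown columns {sorted(unknown)}")

    out = []
    for idx, row in df.iterrows():
        if has_ic50:
            try:
                val = float(row["ln_ic50"])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric ln_ic50 {row['ln_ic50']!r} at row {idx}"
                ) from exc
            out.append(SensitivityRecord(row["drug"], row["context"], ln_ic50=val))
        else:
            if row["label"] not in ("0", "1"):
                raise ValidationError(
                    f"{path}: label must be 0 or 1, got {row['label']!r} at row {idx}"
                )
            out.append(
                SensitivityRecord(row["drug"], row["context"], label=int(row["label"]))
            )
    return out


def write_sensitivity_table(
    records: Sequence[SensitivityRecord], path, sep: str = "\t"
) -> None:
    kinds = {r.label is None for r in records}
    if len(kinds) > 1:
        raise ValidationError("cannot mix ln_ic50 and label records in one table")
    if records and records[0].label is None:
        df = pd.DataFrame(
            [(r.drug_id, r.context_id, r.ln_ic50) for r in records],
            columns=["drug", "context", "ln_ic50"],
        )
    else:
        df = pd.DataFrame(
            [(r.drug_id, r.context_id, r.label) for r in records],
            columns=["drug", "context", "label"],
        )
    df.to_csv(path, sep=sep, index=False)


def write_predictions(rows: Sequence[dict], path, sep: str = "\t") -> None:
    cols = ["drug_i", "drug_j", "context", "y_hat", "s_hat_i", "s_hat_j"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def read_predictions(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    required = {"drug_i", "drug_j", "context", "y_hat"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(params, path) -> None:
    """Persist model parameters plus their architecture config.

    The archive is self-describing and versioned; a reload restores every
    parameter tensor bitwise, which the fine-tuning stage relies on.
    """
    arrays, meta = params.to_arrays()
    payload = dict(arrays)
    payload["__meta__"] = np.frombuffer(
        json.dumps({"schema": CHECKPOINT_SCHEMA, **meta}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path):
    """Load a checkpoint written by :func:`save_checkpoint`."""
    from .model import ModelParameters

    try:
        with np.load(path) as archive:
            data = {k: archive[k] for k in archive.files}
    except Exception as exc:
        raise ValidationError(f"{path}: unreadable checkpoint ({exc})") from exc
    if "__meta__" not in data:
        raise ValidationError(f"{path}: not a pdsp checkpoint (no metadata)")
    meta = json.loads(bytes(data.pop("__meta__")).decode())
    found = meta.get("schema")
    if found != CHECKPOINT_SCHEMA:
        raise ValidationError(
            f"{path}: checkpoint schema mismatch, expected "
            f"{CHECKPOINT_SCHEMA!r}, found {found!r}"
        )
    return ModelParameters.from_arrays(data, meta)


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
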