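"""Data preprocessing: replicate averaging, binarization, gene alignment and
quantile normalization.

The sensitivity call follows the ln IC50 < -2 convention (strictly below the
threshold is sensitive); Bliss classes are strict as well (a score of exactly
zero counts as antagonistic, since synergy requires a positive score).
Quantile normalization is asymmetric: one matrix (in practice the cell-line
training matrix) defines the reference quantile distribution and target
columns are mapped onto it by rank, which avoids fitting quantiles on a
handful of patient samples and keeps held-out data out of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .records import (
    ExpressionMatrix,
    SensitivityRecord,
    SynergyRecord,
    ValidationError,
)

__all__ = [
    "PreprocessConfig",
    "average_replicates",
    "binarize_sensitivity",
    "binarize_bliss",
    "binarize_sensitivity_records",
    "intersect_and_align_genes",
    "quantile_normalize_to_reference",
]


@dataclass(frozen=True)
class PreprocessConfig:
    ln_ic50_threshold: float = -2.0
    bliss_synergy_threshold: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ln_ic50_threshold", "bliss_synergy_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


def average_replicates(records: Sequence[SynergyRecord]) -> list[SynergyRecord]:
    """Collapse replicate measurements to one record per (pair, context).

    The Bliss score of each canonical (drug_i, drug_j, context) triple becomes
    the arithmetic mean of its replicates.  Output is sorted by the triple, so
    the operation is deterministic and idempotent.
    """
    sums: dict[tuple[str, str, str], list[float]] = {}
    for r in records:
        r = r.canonical()
        key = (r.drug_i, r.drug_j, r.context_id)
        sums.setdefault(key, []).append(r.bliss)
    return [
        SynergyRecord(i, j, k, float(np.mean(v)))
        for (i, j, k), v in sorted(sums.items())
    ]


def binarize_sensitivity(ln_ic50: float, cfg: PreprocessConfig = PreprocessConfig()) -> int:
    """1 (sensitive) iff ln IC50 is strictly below the threshold, else 0."""
    if not np.isfinite(ln_ic50):
        raise ValidationError(f"ln_ic50 must be finite, got {ln_ic50!r}")
    return int(ln_ic50 < cfg.ln_ic50_threshold)


def binarize_bliss(score: float, cfg: PreprocessConfig = PreprocessConfig()) -> int:
    """1 (synergistic) iff the Bliss score is strictly above the threshold."""
    if not np.isfinite(score):
        raise ValidationError(f"Bliss score must be finite, got {score!r}")
    return int(score > cfg.bliss_synergy_threshold)


def binarize_sensitivity_records(
    records: Sequence[SensitivityRecord],
    cfg: PreprocessConfig = PreprocessConfig(),
) -> list[SensitivityRecord]:
    """Turn ln IC50 records into labelled records; labelled records pass through."""
    out = []
    for r in records:
        if r.label is not None:
            out.append(r)
        else:
            out.append(
                SensitivityRecord(
                    r.drug_id,
                    r.context_id,
                    ln_ic50=r.ln_ic50,
                    label=binarize_sensitivity(r.ln_ic50, cfg),
                )
            )
    return out


def intersect_and_align_genes(
    matrix_a: ExpressionMatrix, matrix_b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Restrict two expression matrices to their shared genes, sorted.

    Missing genes are never imputed; intersection is the only reconciliation
    between domains measured on different platforms.
    """
    common = sorted(set(matrix_a.genes) & set(matrix_b.genes))
    if not common:
        raise ValidationError("no shared genes between expression matrices")

    def restrict(m: ExpressionMatrix) -> ExpressionMatrix:
        idx = [m.genes.index(g) for g in common]
        return ExpressionMatrix(common, list(m.sample_ids), m.values[idx, :], m.domain)

    return restrict(matrix_a), restrict(matrix_b), common


def _reference_quantiles(reference: np.ndarray) -> np.ndarray:
    """Per-rank means of the reference's sorted columns (length n_genes)."""
    return np.sort(reference, axis=0).mean(axis=1)


def quantile_normalize_to_reference(
    target: ExpressionMatrix, reference: ExpressionMatrix
) -> ExpressionMatrix:
    """Map each target column onto the reference quantile distribution.

    The reference quantile vector is the per-rank mean of the reference's
    sorted columns.  Each value in a target column is replaced by the
    reference quantile at its within-column rank; a run of tied values
    receives the mean of the quantiles at the ranks the run occupies, so
    for tie-free columns the output's sorted values equal the reference
    quantile vector exactly.
    """
    if target.genes != reference.genes:
        raise ValidationError("gene-list mismatch between target and reference")
    quantiles = _reference_quantiles(reference.values)
    csum = np.concatenate([[0.0], np.cumsum(quantiles)])

    out = np.empty_like(target.values)
    for c in range(target.values.shape[1]):
        col = target.values[:, c]
        lo = rankdata(col, method="min").astype(int)   # first rank of tie run
        hi = rankdata(col, method="max").astype(int)   # last rank of tie run
        # untied values take their quantile exactly; tie runs take the mean
        # of the quantiles at the ranks the run occupies
        vals = quantiles[lo - 1]
        tied = hi > lo
        if tied.any():
            vals = vals.copy()
            vals[tied] = (csum[hi[tied]] - csum[lo[tied] - 1]) / (
                hi[tied] - lo[tied] + 1
            )
        out[:, c] = vals
    return ExpressionMatrix(
        list(target.genes), list(target.sample_ids), out, target.domain
    )
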