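"""Core record types shared across the package.

A drug is a fixed-length vector of chemical descriptors; a context (cancer
cell line or patient sample) is a gene-expression vector over an ordered gene
list.  Synergy labels are Bliss scores for unordered drug pairs in a context;
sensitivity labels are per-drug binary calls (1 sensitive, 0 resistant),
optionally derived from ln IC50 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input table or record violates a documented invariant."""


class Domain(str, Enum):
    cell_line = "cell_line"
    patient = "patient"


@dataclass(frozen=True)
class DrugProfile:
    """A drug identifier plus its chemical-descriptor vector."""

    drug_id: str
    features: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if self.features.ndim != 1:
            raise ValidationError(f"drug {self.drug_id}: features must be 1-D")


@dataclass(frozen=True)
class ExpressionProfile:
    """One context's expression vector over an ordered gene list."""

    context_id: str
    domain: Domain
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValidationError(f"context {self.context_id}: values must be 1-D")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with a single domain tag.

    ``values`` is genes x samples; ``genes`` and ``sample_ids`` carry the
    (ordered) row and column labels.  Iterating yields one
    :class:`ExpressionProfile` per sample.
    """

    genes: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    domain: Domain

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in expression matrix")
        if self.values.size == 0:
            raise ValidationError("empty expression matrix")

    def __iter__(self) -> Iterator[ExpressionProfile]:
        for idx, sid in enumerate(self.sample_ids):
            yield ExpressionProfile(sid, self.domain, self.values[:, idx])

    def __len__(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {sid: self.values[:, i] for i, sid in enumerate(self.sample_ids)}


def canonicalize_pair(i: str, j: str) -> tuple[str, str]:
    """Return the unordered pair (i, j) in canonical (lexicographic) order.

    Drug pairs are unordered; a single canonical form prevents the same
    combination from leaking across data splits under two spellings.
    """
    if i == j:
        raise ValidationError(f"self-combination: drug {i!r} paired with itself")
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class SynergyRecord:
    """A Bliss synergy measurement for an unordered drug pair in a context."""

    drug_i: str
    drug_j: str
    context_id: str
    bliss: float

    def __post_init__(self) -> None:
        if self.drug_i == self.drug_j:
            raise ValidationError(
                f"self-combination: {self.drug_i} paired with itself"
            )
        object.__setattr__(self, "bliss", float(self.bliss))

    def canonical(self) -> "SynergyRecord":
        a, b = canonicalize_pair(self.drug_i, self.drug_j)
        if (a, b) == (self.drug_i, self.drug_j):
            return self
        return SynergyRecord(a, b, self.context_id, self.bliss)

    @property
    def pair(self) -> tuple[str, str]:
        return canonicalize_pair(self.drug_i, self.drug_j)


@dataclass(frozen=True)
class SensitivityRecord:
    """A single-drug response in a context: ln IC50 and/or a binary call.

    Exactly one of ``ln_ic50`` / ``label`` is present on raw input; after
    preprocessing every record carries a binary ``label``.
    """

    drug_id: str
    context_id: str
    ln_ic50: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"sensitivity label must be 0 or 1, got {self.label!r} "
                f"for ({self.drug_id}, {self.context_id})"
            )
        if self.ln_ic50 is None and self.label is None:
            raise ValidationError(
                f"sensitivity record ({self.drug_id}, {self.context_id}) "
                "has neither ln_ic50 nor label"
            )


def sensitivity_index(
    records: Sequence[SensitivityRecord],
) -> dict[tuple[str, str], int]:
    """Map (drug_id, context_id) -> binary label for labelled records."""
    out: dict[tuple[str, str], int] = {}
    for r in records:
        if r.label is None:
            raise ValidationError(
                f"unlabelled sensitivity record ({r.drug_id}, {r.context_id}); "
                "binarize ln_ic50 first"
            )
        out[(r.drug_id, r.context_id)] = int(r.label)
    return out
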