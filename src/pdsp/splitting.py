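"""Leave-drug-combination-out data splitting.

Every unordered drug pair is assigned wholly to one of train / validation /
test, regardless of how many contexts it was measured in, so a model is never
evaluated on a combination it has seen during training under any context.
Allocation is at the pair level with largest-remainder rounding and is fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import SynergyRecord, ValidationError, canonicalize_pair

__all__ = ["DatasetSplit", "canonicalize_pair", "leave_pair_out_split"]


@dataclass
class DatasetSplit:
    train: list[SynergyRecord]
    validation: list[SynergyRecord]
    test: list[SynergyRecord]
    split_seed: int
    ratios: tuple[float, float, float]

    def __iter__(self):
        return iter((self.train, self.validation, self.test))

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def _largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    """Allocate n items to bins in the given proportions.

    Floors the exact shares, then hands remaining items to the bins with the
    largest fractional remainders; remainder ties break on bin order
    (train, validation, test) for reproducibility.
    """
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    leftover = n - sum(counts)
    remainders = sorted(
        range(len(ratios)), key=lambda k: (-(exact[k] - counts[k]), k)
    )
    for k in remainders[:leftover]:
        counts[k] += 1
    return counts


def leave_pair_out_split(
    records: Sequence[SynergyRecord],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Partition synergy records so each canonical drug pair is in one split.

    Unique canonical pairs are shuffled with ``seed`` and allocated to
    train/validation/test in the given proportions (largest-remainder
    rounding at the pair level); every record then follows its pair.

    Raises
    ------
    ValidationError
        If the ratios are invalid or there are fewer than 3 unique pairs.
    """
    if len(ratios) != 3:
        raise ValidationError("ratios must have exactly three entries")
    if any(r <= 0 for r in ratios):
        raise ValidationError(f"ratios must be positive, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError(f"ratios must sum to 1, got sum {sum(ratios)!r}")

    pairs = sorted({r.pair for r in records})
    if len(pairs) < 3:
        raise ValidationError(
            f"need at least 3 unique drug pairs to split, got {len(pairs)}"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = [pairs[k] for k in order]

    counts = _largest_remainder_counts(len(pairs), ratios)
    assignment: dict[tuple[str, str], int] = {}
    start = 0
    for split_idx, c in enumerate(counts):
        for p in shuffled[start : start + c]:
            assignment[p] = split_idx
        start += c

    buckets: tuple[list[SynergyRecord], ...] = ([], [], [])
    for r in records:
        buckets[assignment[r.pair]].append(r)

    return DatasetSplit(
        train=buckets[0],
        validation=buckets[1],
        test=buckets[2],
        split_seed=seed,
        ratios=tuple(ratios),
    )
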