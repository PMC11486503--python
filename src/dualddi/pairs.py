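"""Labeled drug-pair handling: tables, negative sampling, stratified splits.

Pairs are unordered at the data layer: (a, b) and (b, a) denote the same
record, and every :class:`LabeledPair` stores its ids in lexicographic order
so that deduplication and set membership are straightforward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .chem import DrugRecord, _read_table

__all__ = [
    "LabeledPair",
    "SplitAssignment",
    "make_pair",
    "load_pair_table",
    "write_pair_table",
    "sample_negatives",
    "stratified_split",
]

log = logging.getLogger(__name__)

PARTITIONS = ("train", "valid", "test")


class LabeledPair(NamedTuple):
    drug_a: str
    drug_b: str
    label: int


def make_pair(a: str, b: str, label: int) -> LabeledPair:
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    if b < a:
        a, b = b, a
    return LabeledPair(a, b, int(label))


def load_pair_table(path, library: Iterable[DrugRecord]) -> list[LabeledPair]:
    """Read a (drug_a, drug_b[, label]) table; a 2-column file means positives.

    Ids must resolve against the library; order-swapped duplicates collapse to
    one record (logged), contradictory duplicate labels are an error.
    """
    known = {r.drug_id for r in library}
    df = _read_table(path, {"drug_a", "drug_b"})
    has_label = "label" in df.columns
    seen: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    n_dupes = 0
    for row in df.itertuples(index=False):
        unresolved = [d for d in (row.drug_a, row.drug_b) if d not in known]
        if unresolved:
            raise ValueError(f"{path}: unknown drug id(s) {unresolved} in pair "
                             f"({row.drug_a}, {row.drug_b})")
        label = int(row.label) if has_label else 1
        pair = make_pair(row.drug_a, row.drug_b, label)
        key = (pair.drug_a, pair.drug_b)
        if key in seen:
            if seen[key] != pair.label:
                raise ValueError(f"{path}: contradictory labels for pair {key}")
            n_dupes += 1
        else:
            seen[key] = pair.label
            order.append(key)
    if n_dupes:
        log.warning("%s: collapsed %d duplicate pair record(s)", path, n_dupes)
    return [LabeledPair(a, b, seen[(a, b)]) for a, b in order]


def write_pair_table(pairs: list[LabeledPair], path) -> None:
    pd.DataFrame(pairs, columns=["drug_a", "drug_b", "label"]).to_csv(path, index=False)


def sample_negatives(
    positives: list[LabeledPair],
    library: Iterable[DrugRecord],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[LabeledPair]:
    """Draw label-0 pairs uniformly from unordered non-edges of the library.

    Returns floor(ratio * |positives|) pairs, without replacement, disjoint
    from the positives; deterministic given the seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    ids = sorted({r.drug_id for r in library})
    positive_keys = {(p.drug_a, p.drug_b) for p in positives}
    candidates = [
        (a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
        if (a, b) not in positive_keys
    ]
    n_wanted = int(ratio * len(positives))
    if n_wanted > len(candidates):
        raise ValueError(
            f"requested {n_wanted} negatives but only {len(candidates)} "
            f"non-positive pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_wanted, replace=False)
    return [LabeledPair(*candidates[i], 0) for i in sorted(chosen)]


@dataclass
class SplitAssignment:
    fold_ratios: tuple[float, ...]
    seed: int
    assignment: dict[LabeledPair, str]

    def partition(self, name: str) -> list[LabeledPair]:
        if name not in PARTITIONS:
            raise KeyError(f"unknown partition {name!r}")
        return [p for p, part in self.assignment.items() if part == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.drug_a, p.drug_b, p.label, part) for p, part in self.assignment.items()],
            columns=["drug_a", "drug_b", "label", "partition"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def stratified_split(
    pairs: list[LabeledPair],
    ratios: tuple[float, ...] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Random train/valid/test partition preserving class proportions.

    Each class is shuffled independently and cut at the cumulative ratios, so
    per-partition sizes match the ratios up to rounding and class balance is
    preserved.  Deterministic given the seed.
    """
    if len(ratios) != len(PARTITIONS):
        raise ValueError(f"expected {len(PARTITIONS)} ratios, got {len(ratios)}")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    rng = np.random.default_rng(seed)
    assignment: dict[LabeledPair, str] = {}
    for label in (0, 1):
        members = [p for p in pairs if p.label == label]
        if not members:
            continue
        if len(members) < len(PARTITIONS):
            raise ValueError(
                f"class {label} has {len(members)} pairs, fewer than "
                f"{len(PARTITIONS)} partitions"
            )
        perm = rng.permutation(len(members))
        cuts = np.floor(np.cumsum(ratios) * len(members) + 1e-9).astype(int)
        start = 0
        for name, stop in zip(PARTITIONS, cuts):
            for i in perm[start:stop]:
                assignment[members[i]] = name
            start = stop
        for i in perm[start:]:  # rounding remainder goes to train
            assignment[members[i]] = PARTITIONS[0]
    return SplitAssignment(fold_ratios=tuple(ratios), seed=seed, assignment=assignment)
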