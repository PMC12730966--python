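"""Per-locus methylation-pattern transitions between control and treated samples.

Each locus contributes one (control, treated) pair of band patterns.
The 14 labeled classes are A1-A3 (no change), B1-B5 (demethylation) and
C1-C6 (methylation); the two patterns missing from that table,
III->II and IV->IV, fall into an UNCLASSIFIED bucket that is reported
but excluded from the rate denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    BandPair,
    BandType,
    ValidationError,
    classify_band,
    iter_band_pairs,
    matrix_samples,
    round_half_up,
)

__all__ = [
    "Category",
    "TransitionClass",
    "TransitionSummary",
    "TRANSITION_TABLE",
    "CLASS_LABELS",
    "classify_transition",
    "transition_summary",
    "pair_matrices",
    "consensus_pair",
]


import enum


class Category(enum.Enum):
    NO_CHANGE = "NO_CHANGE"
    DEMETHYLATION = "DEMETHYLATION"
    METHYLATION = "METHYLATION"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class TransitionClass:
    label: str
    category: Category
    from_type: BandType
    to_type: BandType


# (control (H,M), treated (H,M)) -> labeled class
_RAW_TABLE: list[tuple[str, Category, tuple[int, int], tuple[int, int]]] = [
    ("A1", Category.NO_CHANGE, (1, 1), (1, 1)),
    ("A2", Category.NO_CHANGE, (1, 0), (1, 0)),
    ("A3", Category.NO_CHANGE, (0, 1), (0, 1)),
    ("B1", Category.DEMETHYLATION, (1, 0), (1, 1)),
    ("B2", Category.DEMETHYLATION, (0, 1), (1, 1)),
    ("B3", Category.DEMETHYLATION, (0, 0), (1, 1)),
    ("B4", Category.DEMETHYLATION, (0, 0), (1, 0)),
    ("B5", Category.DEMETHYLATION, (0, 0), (0, 1)),
    ("C1", Category.METHYLATION, (1, 1), (1, 0)),
    ("C2", Category.METHYLATION, (1, 1), (0, 1)),
    ("C3", Category.METHYLATION, (1, 1), (0, 0)),
    ("C4", Category.METHYLATION, (1, 0), (0, 1)),
    ("C5", Category.METHYLATION, (1, 0), (0, 0)),
    ("C6", Category.METHYLATION, (0, 1), (0, 0)),
]

TRANSITION_TABLE: dict[tuple[tuple[int, int], tuple[int, int]], TransitionClass] = {
    (ctrl, trt): TransitionClass(
        label,
        category,
        classify_band(BandPair(*ctrl)),
        classify_band(BandPair(*trt)),
    )
    for label, category, ctrl, trt in _RAW_TABLE
}

CLASS_LABELS: list[str] = [label for label, *_ in _RAW_TABLE]


def classify_transition(control: BandPair, treated: BandPair) -> TransitionClass:
    """Classify one locus's (control, treated) band-pair change.

    Total over all 16 pair combinations; the two patterns absent from
    the 14-class table return an UNCLASSIFIED instance carrying the
    observed from/to band types.
    """
    key = ((control.h, control.m), (treated.h, treated.m))
    cls = TRANSITION_TABLE.get(key)
    if cls is None:
        cls = TransitionClass(
            "UNCLASSIFIED",
            Category.UNCLASSIFIED,
            classify_band(control),
            classify_band(treated),
        )
    return cls


@dataclass(frozen=True)
class TransitionSummary:
    """Per-class counts plus the three rates over classified loci."""

    class_counts: Mapping[str, int]
    n_unclassified: int
    unclassified_loci: tuple = ()

    @property
    def n_classified(self) -> int:
        return sum(self.class_counts.values())

    def _category_total(self, prefix: str) -> int:
        return sum(v for k, v in self.class_counts.items() if k.startswith(prefix))

    @property
    def no_change_pct(self) -> float:
        return 100.0 * self._category_total("A") / self.n_classified

    @property
    def demethylation_pct(self) -> float:
        return 100.0 * self._category_total("B") / self.n_classified

    @property
    def methylation_pct(self) -> float:
        return 100.0 * self._category_total("C") / self.n_classified

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            "no_change_pct": round_half_up(self.no_change_pct, ndigits),
            "demethylation_pct": round_half_up(self.demethylation_pct, ndigits),
            "methylation_pct": round_half_up(self.methylation_pct, ndigits),
        }

    def as_dict(self) -> dict:
        return {
            "class_counts": dict(self.class_counts),
            "n_classified": self.n_classified,
            "n_unclassified": self.n_unclassified,
            **self.rounded(),
        }


def transition_summary(
    paired: Iterable[tuple[BandPair, BandPair]] | Sequence,
    locus_ids: Sequence | None = None,
) -> TransitionSummary:
    """Summarize per-locus transitions into class counts and rates.

    ``paired`` yields (control, treated) BandPair tuples, one per locus.
    Percentages are over classified loci only; UNCLASSIFIED loci are
    counted (and their ids kept) but excluded from the denominator.
    """
    counts = {label: 0 for label in CLASS_LABELS}
    unclassified: list = []
    n_unclassified = 0
    for i, (control, treated) in enumerate(paired):
        cls = classify_transition(control, treated)
        if cls.category is Category.UNCLASSIFIED:
            n_unclassified += 1
            unclassified.append(locus_ids[i] if locus_ids is not None else i)
        else:
            counts[cls.label] += 1
    if sum(counts.values()) == 0:
        raise ValidationError(
            "no locus falls in a labeled transition class; rates are undefined"
        )
    return TransitionSummary(counts, n_unclassified, tuple(unclassified))


def consensus_pair(pairs: Sequence[BandPair | None]) -> BandPair | None:
    """Majority-vote consensus per lane across replicate samples.

    Ties (or an empty/all-missing input) yield ``None`` (missing).
    """
    present = [p for p in pairs if p is not None]
    if not present:
        return None
    lanes = []
    for lane in ("h", "m"):
        ones = sum(getattr(p, lane) for p in present)
        zeros = len(present) - ones
        if ones == zeros:
            return None
        lanes.append(int(ones > zeros))
    return BandPair(*lanes)


def pair_matrices(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    control_samples: Sequence[str] | None = None,
    treated_samples: Sequence[str] | None = None,
) -> tuple[list[tuple[BandPair, BandPair]], list]:
    """Align two band matrices on shared loci, one consensus pair per group.

    Returns (paired band pairs, locus ids); loci missing from either
    matrix, or with a missing/tied consensus in either group, are
    dropped.
    """
    shared = [loc for loc in control.index if loc in set(treated.index)]
    if not shared:
        raise ValidationError("control and treated matrices share no loci")

    def _consensus_by_locus(matrix, samples):
        per_locus: dict = {loc: [] for loc in shared}
        sub = matrix.loc[shared]
        for locus, _, pair in iter_band_pairs(sub, samples):
            per_locus[locus].append(pair)
        return {loc: consensus_pair(ps) for loc, ps in per_locus.items()}

    ctrl_cons = _consensus_by_locus(control, control_samples)
    trt_cons = _consensus_by_locus(treated, treated_samples)
    paired, ids = [], []
    for loc in shared:
        c, t = ctrl_cons[loc], trt_cons[loc]
        if c is not None and t is not None:
            paired.append((c, t))
            ids.append(loc)
    return paired, ids
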