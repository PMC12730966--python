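"""Band-pair scoring for HpaII/MspI isoschizomer methylation assays.

The observable unit of an MSAP experiment is a *band pair*: the presence
(1) or absence (0) of a locus in the HpaII-EcoRI lane and in the
MspI-EcoRI lane.  The four possible pairs map bijectively onto four band
types:

    =====  =========  ==========================================
    H/M    Band type  Interpretation
    =====  =========  ==========================================
    (1,1)  I          unmethylated CCGG site
    (1,0)  II         hemi-methylated (external C, one strand)
    (0,1)  III        fully methylated internal C
    (0,0)  IV         hypermethylated *or* fragment absent
    =====  =========  ==========================================

The enzyme model is carried by four per-cytosine 5mC flags on the
palindromic CCGG duplex (external/internal cytosine on each strand).
HpaII cleaves iff no internal cytosine is methylated and at most one
external cytosine is methylated; MspI cleaves iff no external cytosine
is methylated.  This makes the band-type table above self-consistent and
matches canonical MSAP usage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import FrozenSet, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CCGGMethylState",
    "MethylFlags",
    "BandPair",
    "BandType",
    "BandTypeCounts",
    "MethylationRatios",
    "ValidationError",
    "classify_band",
    "predict_bands",
    "classify_state",
    "count_band_types",
    "methylation_ratios",
    "proportion_pct",
    "round_half_up",
    "read_band_matrix",
    "write_band_matrix",
    "matrix_samples",
]


class ValidationError(ValueError):
    """Raised for malformed band matrices, pairs, or tracks."""


class CCGGMethylState(enum.Enum):
    """Canonical methylation configuration of one CCGG duplex.

    ``ABSENT`` marks a locus whose restriction fragment does not exist
    at all (site presence polymorphism), indistinguishable on a gel from
    full external methylation.
    """

    UNMETHYLATED = "UNMETHYLATED"
    HEMI_EXTERNAL = "HEMI_EXTERNAL"
    FULL_INTERNAL = "FULL_INTERNAL"
    FULL_EXTERNAL = "FULL_EXTERNAL"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class MethylFlags:
    """Per-cytosine 5mC flags on the palindromic CCGG duplex.

    ``ext``/``int`` refer to the 5' and 3' cytosine of CCGG; ``top`` and
    ``bottom`` are the two strands.  All 16 combinations are legal input
    to :func:`predict_bands`; only four patterns are canonical.
    """

    ext_top: bool = False
    int_top: bool = False
    ext_bottom: bool = False
    int_bottom: bool = False

    @property
    def n_external(self) -> int:
        return int(self.ext_top) + int(self.ext_bottom)

    @property
    def n_internal(self) -> int:
        return int(self.int_top) + int(self.int_bottom)

    def canonical_state(self) -> CCGGMethylState | None:
        """Map flags to the canonical four-state model, or ``None``.

        all-false -> UNMETHYLATED; exactly one external, no internal ->
        HEMI_EXTERNAL; both internal, no external -> FULL_INTERNAL; both
        external -> FULL_EXTERNAL.  Anything else is non-canonical.
        """
        if self.n_external == 2:
            return CCGGMethylState.FULL_EXTERNAL
        if self.n_external == 0 and self.n_internal == 0:
            return CCGGMethylState.UNMETHYLATED
        if self.n_external == 1 and self.n_internal == 0:
            return CCGGMethylState.HEMI_EXTERNAL
        if self.n_external == 0 and self.n_internal == 2:
            return CCGGMethylState.FULL_INTERNAL
        return None


#: Representative flag pattern for each canonical (non-ABSENT) state.
CANONICAL_FLAGS: dict[CCGGMethylState, MethylFlags] = {
    CCGGMethylState.UNMETHYLATED: MethylFlags(),
    CCGGMethylState.HEMI_EXTERNAL: MethylFlags(ext_top=True),
    CCGGMethylState.FULL_INTERNAL: MethylFlags(int_top=True, int_bottom=True),
    CCGGMethylState.FULL_EXTERNAL: MethylFlags(ext_top=True, ext_bottom=True),
}


def hpaii_cuts(flags: MethylFlags) -> bool:
    """HpaII cleaves iff no internal 5mC and at most one external 5mC."""
    return flags.n_internal == 0 and flags.n_external <= 1


def mspi_cuts(flags: MethylFlags) -> bool:
    """MspI cleaves iff no external 5mC (internal 5mC tolerated)."""
    return flags.n_external == 0


@dataclass(frozen=True)
class BandPair:
    """Presence (1) / absence (0) of a locus in the HpaII and MspI lanes."""

    h: int
    m: int

    def __post_init__(self) -> None:
        for lane, v in (("HpaII", self.h), ("MspI", self.m)):
            if v not in (0, 1):
                raise ValidationError(
                    f"band presence must be 0 or 1, got {v!r} in {lane} lane"
                )


class BandType(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


_BAND_TYPE_OF_PAIR: dict[tuple[int, int], BandType] = {
    (1, 1): BandType.I,
    (1, 0): BandType.II,
    (0, 1): BandType.III,
    (0, 0): BandType.IV,
}

_PAIR_OF_BAND_TYPE: dict[BandType, tuple[int, int]] = {
    v: k for k, v in _BAND_TYPE_OF_PAIR.items()
}


def classify_band(pair: BandPair) -> BandType:
    """Classify one (H, M) presence pair into band type I/II/III/IV."""
    return _BAND_TYPE_OF_PAIR[(pair.h, pair.m)]


def band_pair_of_type(band_type: BandType) -> BandPair:
    """Inverse of :func:`classify_band` (the mapping is a bijection)."""
    h, m = _PAIR_OF_BAND_TYPE[band_type]
    return BandPair(h, m)


def predict_bands(state: CCGGMethylState | MethylFlags) -> BandPair:
    """Predict the (H, M) band pair for a methylation configuration.

    Total over all 16 flag combinations plus the five canonical states.
    ``ABSENT`` yields (0, 0): a missing fragment shows in neither lane.
    """
    if isinstance(state, CCGGMethylState):
        if state is CCGGMethylState.ABSENT:
            return BandPair(0, 0)
        flags = CANONICAL_FLAGS[state]
    else:
        flags = state
    return BandPair(int(hpaii_cuts(flags)), int(mspi_cuts(flags)))


def classify_state(pair: BandPair) -> FrozenSet[CCGGMethylState]:
    """Every canonical state consistent with an observed band pair.

    (0,0) is ambiguous by construction (hypermethylated or absent);
    all other pairs have a unique preimage.
    """
    out = {
        s
        for s in CCGGMethylState
        if predict_bands(s) == pair
    }
    return frozenset(out)


# ---------------------------------------------------------------------------
# Counting and ratio statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandTypeCounts:
    """Per-band-type locus counts for one sample group."""

    n_I: int
    n_II: int
    n_III: int
    n_IV: int

    def __post_init__(self) -> None:
        for name in ("n_I", "n_II", "n_III", "n_IV"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_I + self.n_II + self.n_III + self.n_IV

    @property
    def n_methylated(self) -> int:
        """Loci of types II + III + IV."""
        return self.n_II + self.n_III + self.n_IV

    def as_dict(self) -> dict[str, int]:
        return {
            "I": self.n_I,
            "II": self.n_II,
            "III": self.n_III,
            "IV": self.n_IV,
            "total": self.total,
        }


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (5 rounds up for positive values)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MethylationRatios:
    """Methylation ratio statistics (percent, 0-100 scale, unrounded).

    total = (II+III+IV)/total, full = (III+IV)/total, hemi = II/total,
    non = I/total; the same total formula doubles as the MSAP
    polymorphism percentage.
    """

    total_pct: float
    full_pct: float
    hemi_pct: float
    non_pct: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Reporting view: percentages rounded half-away-from-zero."""
        return {
            "total_pct": round_half_up(self.total_pct, ndigits),
            "full_pct": round_half_up(self.full_pct, ndigits),
            "hemi_pct": round_half_up(self.hemi_pct, ndigits),
            "non_pct": round_half_up(self.non_pct, ndigits),
        }


def methylation_ratios(counts: BandTypeCounts) -> MethylationRatios:
    """Compute methylation ratio percentages from band-type counts."""
    total = counts.total
    if total == 0:
        raise ValidationError("no scorable loci: total band-type count is zero")
    return MethylationRatios(
        total_pct=100.0 * (counts.n_II + counts.n_III + counts.n_IV) / total,
        full_pct=100.0 * (counts.n_III + counts.n_IV) / total,
        hemi_pct=100.0 * counts.n_II / total,
        non_pct=100.0 * counts.n_I / total,
    )


def msap_polymorphism_pct(counts: BandTypeCounts) -> float:
    """Percentage of methylation-sensitive polymorphic bands.

    Identical formula to the total methylated ratio; both names are
    exposed because both appear in reports.
    """
    return methylation_ratios(counts).total_pct


def proportion_pct(k: int, n: int, ndigits: int = 2) -> float:
    """100*k/n with the reporting rounding rule (e.g. 12/28 -> 42.86)."""
    if n <= 0:
        raise ValidationError("denominator must be positive")
    if k < 0 or k > n:
        raise ValidationError(f"count {k} outside [0, {n}]")
    return round_half_up(100.0 * k / n, ndigits)


# ---------------------------------------------------------------------------
# Band matrices (loci x samples, one _H and one _M column per sample)
# ---------------------------------------------------------------------------

_MISSING = {"NA", "", "NAN", None}


def matrix_samples(matrix: pd.DataFrame) -> list[str]:
    """Sample names from paired ``<sample>_H`` / ``<sample>_M`` columns."""
    h_samples = [c[:-2] for c in matrix.columns if c.endswith("_H")]
    m_samples = {c[:-2] for c in matrix.columns if c.endswith("_M")}
    unpaired = set(h_samples).symmetric_difference(m_samples)
    if unpaired:
        raise ValidationError(
            f"unpaired lane columns for sample(s): {sorted(unpaired)}"
        )
    if not h_samples:
        raise ValidationError("no <sample>_H/<sample>_M column pairs found")
    return h_samples


def _cell_value(matrix: pd.DataFrame, locus, column: str) -> float:
    v = matrix.at[locus, column]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return math.nan
    if isinstance(v, str):
        if v.strip().upper() in _MISSING:
            return math.nan
        try:
            v = float(v)
        except ValueError:
            raise ValidationError(
                f"non-binary cell {v!r} at locus {locus!r}, column {column!r}"
            ) from None
    if v not in (0, 1):
        raise ValidationError(
            f"non-binary cell {v!r} at locus {locus!r}, column {column!r}"
        )
    return float(v)


def iter_band_pairs(
    matrix: pd.DataFrame, samples: Sequence[str] | None = None
) -> Iterable[tuple[object, str, BandPair | None]]:
    """Yield (locus, sample, pair) per cell; ``None`` when either lane is NA.

    Missing data are excluded pairwise: a locus with NA in one lane of a
    sample contributes nothing for that sample but still counts for the
    others.
    """
    if samples is None:
        samples = matrix_samples(matrix)
    else:
        known = set(matrix_samples(matrix))
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ValidationError(f"unknown sample name(s): {unknown}")
        if not samples:
            raise ValidationError("empty sample selection")
    for locus in matrix.index:
        for sample in samples:
            h = _cell_value(matrix, locus, f"{sample}_H")
            m = _cell_value(matrix, locus, f"{sample}_M")
            if math.isnan(h) or math.isnan(m):
                yield locus, sample, None
            else:
                yield locus, sample, BandPair(int(h), int(m))


def count_band_types(
    matrix: pd.DataFrame, samples: Sequence[str] | None = None
) -> BandTypeCounts:
    """Count band types over all (locus, selected sample) cells.

    Raises on empty matrices, unknown samples, and non-binary cells;
    cells with a missing lane are skipped (pairwise exclusion).
    """
    if matrix.empty:
        raise ValidationError("band matrix is empty")
    tallies = {t: 0 for t in BandType}
    for _, _, pair in iter_band_pairs(matrix, samples):
        if pair is not None:
            tallies[classify_band(pair)] += 1
    return BandTypeCounts(
        tallies[BandType.I], tallies[BandType.II], tallies[BandType.III], tallies[BandType.IV]
    )


def read_band_matrix(path) -> pd.DataFrame:
    """Read a TSV band matrix (``locus`` column + ``<sample>_H/_M`` pairs)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "locus" not in df.columns:
        raise ValidationError("band matrix must have a 'locus' column")
    df = df.set_index("locus")
    matrix_samples(df)  # validates column pairing
    # validate every cell eagerly so errors name the offender
    for locus in df.index:
        for col in df.columns:
            _cell_value(df, locus, col)
    return df


def write_band_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "locus"
    out.to_csv(path, sep="\t", na_rep="NA")
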