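"""In silico EcoRI + HpaII/MspI double digestion and virtual band calling.

Coordinates are 0-based half-open throughout.  EcoRI cuts GAATTC between
G|AATTC (offset +1 from the site start); both isoschizomers cut CCGG
between C|CGG (offset +1).  Only fragment lengths matter downstream, so
overhang bookkeeping is by convention.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CANONICAL_FLAGS,
    BandPair,
    CCGGMethylState,
    MethylFlags,
    ValidationError,
    hpaii_cuts,
    mspi_cuts,
)

__all__ = [
    "ECORI_SITE",
    "CCGG_SITE",
    "EndType",
    "Lane",
    "Fragment",
    "MethylomeTrack",
    "find_sites",
    "digest",
    "select_bands",
    "bands_to_matrix",
    "read_fasta",
    "write_fasta",
]

ECORI_SITE = "GAATTC"
CCGG_SITE = "CCGG"
ECORI_CUT_OFFSET = 1  # G | AATTC
CCGG_CUT_OFFSET = 1  # C | CGG

_ECORI_RE = re.compile(ECORI_SITE)
_CCGG_RE = re.compile(CCGG_SITE)


class Lane(enum.Enum):
    """Which methylation-sensitive enzyme shares the digest with EcoRI."""

    HPAII = "HpaII"
    MSPI = "MspI"


class EndType(enum.Enum):
    ECORI = "EcoRI"
    CCGG_ENZ = "HpaII/MspI"
    TERMINUS = "terminus"


@dataclass(frozen=True)
class Fragment:
    """One double-digest fragment with end provenance."""

    sequence_id: str
    start: int
    end: int
    left_end: EndType
    right_end: EndType

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid fragment interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_mixed(self) -> bool:
        """True iff one EcoRI end and one HpaII/MspI end."""
        return {self.left_end, self.right_end} == {EndType.ECORI, EndType.CCGG_ENZ}

    @property
    def ccgg_cut(self) -> tuple[int, str] | None:
        """(cut position, side) of the CCGG end, if any.

        ``side`` is "R" when the CCGG cut closes the fragment on the
        right, "L" when it opens it on the left.  A CCGG-CCGG fragment
        reports its left end.
        """
        if self.left_end is EndType.CCGG_ENZ:
            return self.start, "L"
        if self.right_end is EndType.CCGG_ENZ:
            return self.end, "R"
        return None


@dataclass
class MethylomeTrack:
    """Methylation states of CCGG sites, keyed by forward-strand start.

    CCGG is self-reverse-complementary, so one record covers both
    strands.  States may be canonical :class:`CCGGMethylState` values or
    raw :class:`MethylFlags`.
    """

    states: dict[tuple[str, int], CCGGMethylState | MethylFlags] = field(
        default_factory=dict
    )

    def set(self, seq_id: str, start: int, state) -> None:
        self.states[(seq_id, start)] = state

    def get(self, seq_id: str, start: int):
        """State at a site; unannotated sites default to UNMETHYLATED."""
        return self.states.get((seq_id, start), CCGGMethylState.UNMETHYLATED)

    def validate_against(self, sequences: Mapping[str, str]) -> None:
        for (seq_id, start) in self.states:
            seq = sequences.get(seq_id)
            if seq is None:
                raise ValidationError(f"track references unknown sequence {seq_id!r}")
            if seq[start : start + 4].upper() != CCGG_SITE:
                raise ValidationError(
                    f"track position {seq_id}:{start} does not address a CCGG site"
                )

    # BED-like 4-column TSV: seq_id, start, start+4, state
    @classmethod
    def read_tsv(cls, path) -> "MethylomeTrack":
        track = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValidationError(f"{path}:{lineno}: expected 4 columns")
                seq_id, start, end, state = fields[:4]
                start, end = int(start), int(end)
                if end != start + 4:
                    raise ValidationError(
                        f"{path}:{lineno}: CCGG interval must span 4 bp"
                    )
                key = (seq_id, start)
                if key in track.states:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate site {seq_id}:{start}"
                    )
                track.set(seq_id, start, CCGGMethylState(state))
        return track

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for (seq_id, start), state in sorted(self.states.items()):
                name = state.value if isinstance(state, CCGGMethylState) else repr(state)
                fh.write(f"{seq_id}\t{start}\t{start + 4}\t{name}\n")


def find_sites(sequence: str) -> tuple[list[int], list[int]]:
    """0-based starts of every GAATTC and CCGG on the forward strand.

    Both motifs are palindromic, so forward-strand scanning is complete.
    Motifs never contain N, so N-containing windows are skipped for free.
    """
    seq = sequence.upper()
    return (
        [m.start() for m in _ECORI_RE.finditer(seq)],
        [m.start() for m in _CCGG_RE.finditer(seq)],
    )


def _state_cuts(state, lane: Lane) -> bool:
    if isinstance(state, CCGGMethylState):
        if state is CCGGMethylState.ABSENT:
            return False
        flags = CANONICAL_FLAGS[state]
    else:
        flags = state
    return hpaii_cuts(flags) if lane is Lane.HPAII else mspi_cuts(flags)


def digest(
    sequence: str,
    track: MethylomeTrack,
    lane: Lane,
    seq_id: str = "seq",
) -> list[Fragment]:
    """Double-digest one sequence with EcoRI plus the lane's isoschizomer.

    EcoRI cuts every GAATTC regardless of methylation; the CCGG enzyme
    cuts a site only when its methylation state permits.  Returns the
    maximal uncut intervals covering the whole sequence.
    """
    track.validate_against({seq_id: sequence})
    ecori_pos, ccgg_pos = find_sites(sequence)
    cuts: list[tuple[int, EndType]] = [(p + ECORI_CUT_OFFSET, EndType.ECORI) for p in ecori_pos]
    for p in ccgg_pos:
        if _state_cuts(track.get(seq_id, p), lane):
            cuts.append((p + CCGG_CUT_OFFSET, EndType.CCGG_ENZ))
    cuts.sort()
    bounds = [(0, EndType.TERMINUS)] + cuts + [(len(sequence), EndType.TERMINUS)]
    fragments = []
    for (start, left_end), (end, right_end) in zip(bounds, bounds[1:]):
        if end > start:  # a cut at position 0 or len collapses an interval
            fragments.append(Fragment(seq_id, start, end, left_end, right_end))
    return fragments


def select_bands(
    fragments: Iterable[Fragment],
    min_len: int = 50,
    max_len: int = 700,
    require_mixed_ends: bool = True,
) -> list[Fragment]:
    """Keep gel-scorable fragments.

    The adapter scheme amplifies only EcoRI-(HpaII/MspI) fragments, so
    mixed ends are required by default; the length window models PAGE
    resolvability.
    """
    if min_len >= max_len:
        raise ValidationError("min_len must be < max_len")
    return [
        f
        for f in fragments
        if (f.is_mixed or not require_mixed_ends) and min_len <= f.length <= max_len
    ]


def locus_id(fragment: Fragment) -> str:
    """Stable locus identity: the CCGG cut that defines the fragment."""
    cc = fragment.ccgg_cut
    if cc is None:
        return f"{fragment.sequence_id}:{fragment.start}-{fragment.end}"
    pos, side = cc
    return f"{fragment.sequence_id}:{pos}:{side}"


def bands_to_matrix(
    hpaii_bands: Sequence[Fragment],
    mspi_bands: Sequence[Fragment],
    sample: str = "sim",
    gel_mode: bool = False,
) -> pd.DataFrame:
    """Score two lanes of virtual bands into a locus x 1-sample matrix.

    Exact mode identifies loci by their defining CCGG cut position;
    gel mode collapses equal-length fragments within a lane into one
    band and identifies loci by length alone (comigration noise).
    """
    if gel_mode:
        h_keys = {f"len:{f.length}" for f in hpaii_bands}
        m_keys = {f"len:{f.length}" for f in mspi_bands}
    else:
        h_keys = {locus_id(f) for f in hpaii_bands}
        m_keys = {locus_id(f) for f in mspi_bands}
    loci = sorted(h_keys | m_keys)
    data = {
        f"{sample}_H": [int(loc in h_keys) for loc in loci],
        f"{sample}_M": [int(loc in m_keys) for loc in loci],
    }
    df = pd.DataFrame(data, index=pd.Index(loci, name="locus"))
    return df


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
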