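"""Synthetic genomes, methylomes, and treatment kernels.

Generates paired control/treated datasets with the statistical structure
the scoring pipeline assumes: an i.i.d. categorical prior over CCGG
methylation states and a per-site treatment transition kernel whose
demethylation mass ``d`` and methylation mass ``m`` can be recovered
from the scored output.

All stochastic operations take an explicit seed (or Generator); child
streams are derived with ``numpy.random.SeedSequence.spawn``, so every
result is bit-for-bit reproducible.

Limitations (by design): sites are independent — no spatial correlation
— and a locus whose fragment is ABSENT stays absent under treatment
(the kernel makes ABSENT absorbing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    BandPair,
    BandType,
    BandTypeCounts,
    CCGGMethylState,
    ValidationError,
    band_pair_of_type,
    predict_bands,
)
from .digest import (
    CCGG_SITE,
    ECORI_SITE,
    Fragment,
    Lane,
    MethylomeTrack,
    bands_to_matrix,
    digest,
    find_sites,
    select_bands,
)
from .transitions import TRANSITION_TABLE, TransitionSummary, transition_summary

__all__ = [
    "StatePrior",
    "TreatmentKernel",
    "RateEstimate",
    "ck_prior",
    "transition_table_prior",
    "generate_genome",
    "generate_amplicon_genome",
    "AmpliconGenome",
    "generate_methylome",
    "apply_treatment",
    "recover_rates",
    "simulate_experiment",
    "SimulationResult",
    "matrix_from_type_counts",
    "paired_matrices_from_class_counts",
]

U = CCGGMethylState.UNMETHYLATED
H = CCGGMethylState.HEMI_EXTERNAL
FI = CCGGMethylState.FULL_INTERNAL
FE = CCGGMethylState.FULL_EXTERNAL
AB = CCGGMethylState.ABSENT

STATE_ORDER: tuple[CCGGMethylState, ...] = (U, H, FI, FE, AB)

# Demethylation (class-B) and methylation (class-C) transitions in state
# space, in table order, with their default relative weights.
B_TRANSITIONS: tuple[tuple[CCGGMethylState, CCGGMethylState], ...] = (
    (H, U),   # B1: II -> I
    (FI, U),  # B2: III -> I
    (FE, U),  # B3: IV -> I
    (FE, H),  # B4: IV -> II
    (FE, FI), # B5: IV -> III
)
C_TRANSITIONS: tuple[tuple[CCGGMethylState, CCGGMethylState], ...] = (
    (U, H),   # C1: I -> II
    (U, FI),  # C2: I -> III
    (U, FE),  # C3: I -> IV
    (H, FI),  # C4: II -> III
    (H, FE),  # C5: II -> IV
    (FI, FE), # C6: III -> IV
)
DEFAULT_B_WEIGHTS = (15.0, 4.0, 5.0, 9.0, 4.0)
DEFAULT_C_WEIGHTS = (4.0, 6.0, 0.0, 0.0, 4.0, 1.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class StatePrior:
    """Categorical prior over the five site states."""

    probs: Mapping[CCGGMethylState, float]

    def __post_init__(self) -> None:
        p = {s: float(self.probs.get(s, 0.0)) for s in STATE_ORDER}
        if any(v < 0 for v in p.values()):
            raise ValidationError("prior probabilities must be non-negative")
        if not math.isclose(sum(p.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("prior probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    def vector(self) -> np.ndarray:
        return np.array([self.probs[s] for s in STATE_ORDER])

    @classmethod
    def from_counts(cls, counts: Mapping[CCGGMethylState, float]) -> "StatePrior":
        total = sum(counts.values())
        return cls({s: c / total for s, c in counts.items()})


def ck_prior() -> StatePrior:
    """Default prior: control-column band-type frequencies 704:40:33:26.

    The uninformative type-IV mass is folded entirely into FULL_EXTERNAL
    (ABSENT gets 0), so every simulated locus is scoreable.
    """
    return StatePrior.from_counts({U: 704, H: 40, FI: 33, FE: 26})


def transition_table_prior() -> StatePrior:
    """Control-state marginal implied by the 14-class transition counts.

    Type I: 312+4+6+0 = 322; II: 24+15+0+4 = 43; III: 21+4+1 = 26;
    IV: 5+9+4 = 18; over 409 classified loci.  This is the prior under
    which the default kernel's class-B/C fractions equal d and m exactly.
    """
    return StatePrior.from_counts({U: 322, H: 43, FI: 26, FE: 18})


@dataclass(frozen=True)
class TreatmentKernel:
    """Per-state transition probabilities (control -> treated).

    ``d`` and ``m`` are the marginal demethylation / methylation
    probability masses the kernel realizes under its calibration prior.
    ABSENT is absorbing: a missing fragment cannot reappear.
    """

    rows: Mapping[CCGGMethylState, Mapping[CCGGMethylState, float]]
    d: float
    m: float

    def __post_init__(self) -> None:
        for s in STATE_ORDER:
            row = self.rows.get(s)
            if row is None:
                raise ValidationError(f"kernel missing row for {s}")
            total = sum(row.get(t, 0.0) for t in STATE_ORDER)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError(f"kernel row for {s} sums to {total}, not 1")
            if any(row.get(t, 0.0) < 0 for t in STATE_ORDER):
                raise ValidationError(f"kernel row for {s} has negative mass")
        ab_row = self.rows[AB]
        if not math.isclose(ab_row.get(AB, 0.0), 1.0, abs_tol=1e-9):
            raise ValidationError("ABSENT must be absorbing")

    def row_vector(self, state: CCGGMethylState) -> np.ndarray:
        row = self.rows[state]
        v = np.array([row.get(t, 0.0) for t in STATE_ORDER])
        return v / v.sum()

    @classmethod
    def identity(cls) -> "TreatmentKernel":
        rows = {s: {s: 1.0} for s in STATE_ORDER}
        return cls(rows, 0.0, 0.0)

    @classmethod
    def from_rates(
        cls,
        d: float,
        m: float,
        prior: StatePrior | None = None,
        b_weights: Sequence[float] = DEFAULT_B_WEIGHTS,
        c_weights: Sequence[float] = DEFAULT_C_WEIGHTS,
        overflow_tol: float = 1e-2,
    ) -> "TreatmentKernel":
        """Kernel whose marginal class-B mass is ``d`` and class-C mass ``m``.

        The joint (from, to) mass d*w_k / m*v_j is spread over the
        specific demethylation / methylation transitions proportionally
        to ``b_weights`` / ``c_weights`` (defaults: the empirical
         15:4:5:9:4 and 4:6:0:0:4:1), then conditioned on the calibration
        ``prior`` (default: :func:`transition_table_prior`).  A row whose
        off-diagonal mass exceeds its prior mass by more than
        ``overflow_tol`` (relative) is an infeasibility error; smaller
        overshoots (rounding of published rates) are renormalized.
        """
        if prior is None:
            prior = transition_table_prior()
        if not (0 <= d <= 1 and 0 <= m <= 1 and d + m <= 1):
            raise ValidationError("d and m must be probabilities with d + m <= 1")
        bw = np.asarray(b_weights, dtype=float)
        cw = np.asarray(c_weights, dtype=float)
        if len(bw) != len(B_TRANSITIONS) or len(cw) != len(C_TRANSITIONS):
            raise ValidationError("weight vectors must match the transition lists")
        joint: dict[CCGGMethylState, dict[CCGGMethylState, float]] = {
            s: {} for s in STATE_ORDER
        }
        if d > 0:
            if bw.sum() <= 0:
                raise ValidationError("b_weights must have positive mass when d > 0")
            for (s, t), w in zip(B_TRANSITIONS, bw / bw.sum()):
                joint[s][t] = joint[s].get(t, 0.0) + d * w
        if m > 0:
            if cw.sum() <= 0:
                raise ValidationError("c_weights must have positive mass when m > 0")
            for (s, t), w in zip(C_TRANSITIONS, cw / cw.sum()):
                joint[s][t] = joint[s].get(t, 0.0) + m * w
        rows: dict[CCGGMethylState, dict[CCGGMethylState, float]] = {}
        for s in STATE_ORDER:
            off_joint = joint[s]
            mass = sum(off_joint.values())
            p_s = prior.probs[s]
            if mass > 0 and p_s == 0:
                raise ValidationError(
                    f"kernel assigns transitions out of {s} but prior({s}) = 0"
                )
            if p_s == 0:
                rows[s] = {s: 1.0}
                continue
            off = {t: v / p_s for t, v in off_joint.items()}
            off_sum = sum(off.values())
            if off_sum > 1 + overflow_tol:
                raise ValidationError(
                    f"transitions out of {s} need probability {off_sum:.4f} > 1 "
                    "under the calibration prior; lower d/m or change the prior"
                )
            if off_sum > 1:
                off = {t: v / off_sum for t, v in off.items()}
                off_sum = 1.0
            row = dict(off)
            row[s] = row.get(s, 0.0) + (1.0 - off_sum)
            rows[s] = row
        rows[AB] = {AB: 1.0}
        return cls(rows, float(d), float(m))

    @classmethod
    def empirical_default(cls) -> "TreatmentKernel":
        """Kernel reproducing the published 9.05% / 3.67% rates exactly
        (d = 37/409, m = 15/409) under :func:`transition_table_prior`."""
        return cls.from_rates(37 / 409, 15 / 409)


# ---------------------------------------------------------------------------
# Genome generators
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_bases(rng: np.random.Generator, n: int, gc_content: float) -> np.ndarray:
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return rng.choice(_BASES, size=n, p=[at, gc, gc, at])


def _scrub_motifs(seq: str, rng: np.random.Generator) -> str:
    """Destroy every GAATTC/CCGG occurrence by mutating an internal base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for _ in range(100):
        text = arr.tobytes().decode()
        eco, ccgg = find_sites(text)
        if not eco and not ccgg:
            return text
        for p in eco:
            arr[p + 2] = b"C" if arr[p + 2] != b"C" else b"G"
        for p in ccgg:
            arr[p + 2] = b"A" if arr[p + 2] != b"A" else b"T"
    raise ValidationError("failed to scrub restriction motifs from filler")


def generate_genome(
    n_bp: int,
    gc_content: float = 0.5,
    n_ecori_min: int = 0,
    n_ccgg_min: int = 0,
    seed=0,
) -> str:
    """Random genome with at least the requested motif counts.

    Motifs are planted at random positions when the random draw falls
    short; deterministic given the seed.
    """
    if n_bp < 1000:
        raise ValidationError("n_bp must be >= 1000")
    if not 0 < gc_content < 1:
        raise ValidationError("gc_content must be in (0, 1)")
    need_bp = n_ecori_min * len(ECORI_SITE) + n_ccgg_min * len(CCGG_SITE)
    if need_bp > n_bp // 2:
        raise ValidationError("requested motif density is infeasible for n_bp")
    rng = _rng(seed)
    arr = _random_bases(rng, n_bp, gc_content)
    for _ in range(20):
        seq = arr.tobytes().decode()
        eco, ccgg = find_sites(seq)
        missing_eco = n_ecori_min - len(eco)
        missing_ccgg = n_ccgg_min - len(ccgg)
        if missing_eco <= 0 and missing_ccgg <= 0:
            return seq
        for motif, missing in ((ECORI_SITE, missing_eco), (CCGG_SITE, missing_ccgg)):
            for _ in range(max(0, missing)):
                p = int(rng.integers(0, n_bp - len(motif)))
                arr[p : p + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
    raise ValidationError("motif planting did not converge")


@dataclass(frozen=True)
class AmpliconGenome:
    """Structured genome where each CCGG is cleanly flanked by EcoRI sites.

    Each unit is ``GAATTC + filler + CCGG + long filler``; the
    EcoRI-CCGG fragment falls inside the scoring window while the
    CCGG-EcoRI fragment on the other side is too long to score, so each
    CCGG site yields exactly one scoreable locus with no interference
    from neighboring sites.
    """

    sequence: str
    ccgg_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    @property
    def n_loci(self) -> int:
        return len(self.ccgg_positions)


def generate_amplicon_genome(
    n_loci: int,
    seed=0,
    frag_len_range: tuple[int, int] = (80, 400),
    right_spacer_range: tuple[int, int] = (710, 760),
    gc_content: float = 0.5,
    unique_lengths: bool = False,
) -> AmpliconGenome:
    """Genome of ``n_loci`` independent EcoRI-CCGG amplicon units.

    ``frag_len_range`` bounds the EcoRI-cut-to-CCGG-cut fragment length
    (inclusive); with ``unique_lengths`` the lengths are sampled without
    replacement so every locus is unique on a virtual gel.
    """
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    lo, hi = frag_len_range
    if lo < 8:
        raise ValidationError("minimum fragment length must be >= 8")
    span = hi - lo + 1
    rng = _rng(seed)
    if unique_lengths:
        if n_loci > span:
            raise ValidationError(
                f"cannot draw {n_loci} unique lengths from range {frag_len_range}"
            )
        lengths = lo + rng.permutation(span)[:n_loci]
    else:
        lengths = rng.integers(lo, hi + 1, size=n_loci)
    spacers = rng.integers(
        right_spacer_range[0], right_spacer_range[1] + 1, size=n_loci
    )
    parts: list[str] = []
    ccgg_positions: list[int] = []
    pos = 0
    for L, lb in zip(lengths.tolist(), spacers.tolist()):
        la = L - 6  # EcoRI cut at +1, CCGG cut at +1: fragment length = la + 6
        filler_a = _scrub_motifs(_random_bases(rng, la, gc_content).tobytes().decode(), rng)
        filler_b = _scrub_motifs(_random_bases(rng, lb, gc_content).tobytes().decode(), rng)
        # junction-spanning motifs: GAATTC+CGG.. or ..CCG+GAATTC would
        # plant an extra CCGG; CCGG+AATTC.. or ..GAATT+CCGG an extra EcoRI
        if filler_a.startswith("CGG"):
            filler_a = "T" + filler_a[1:]
        if filler_a.endswith("GAATT"):
            filler_a = filler_a[:-1] + "A"
        if filler_b.startswith("AATTC"):
            filler_b = "T" + filler_b[1:]
        if filler_b.endswith("CCG"):
            filler_b = filler_b[:-1] + "A"
        unit = ECORI_SITE + filler_a + CCGG_SITE + filler_b
        ccgg_positions.append(pos + len(ECORI_SITE) + la)
        parts.append(unit)
        pos += len(unit)
    return AmpliconGenome(
        "".join(parts), tuple(ccgg_positions), tuple(int(x) for x in lengths)
    )


# ---------------------------------------------------------------------------
# Methylome generation and treatment
# ---------------------------------------------------------------------------


def generate_methylome(
    ccgg_positions: Sequence[int],
    prior: StatePrior,
    seed=0,
    seq_id: str = "chr1",
) -> MethylomeTrack:
    """i.i.d. state per CCGG site, drawn from the prior."""
    rng = _rng(seed)
    idx = rng.choice(len(STATE_ORDER), size=len(ccgg_positions), p=prior.vector())
    track = MethylomeTrack()
    for p, i in zip(ccgg_positions, idx.tolist()):
        track.set(seq_id, int(p), STATE_ORDER[i])
    return track


def apply_treatment(
    track: MethylomeTrack, kernel: TreatmentKernel, seed=0
) -> MethylomeTrack:
    """Per-site independent draw from the kernel row of the current state."""
    rng = _rng(seed)
    out = MethylomeTrack()
    sites = sorted(track.states.items())
    state_idx = {s: i for i, s in enumerate(STATE_ORDER)}
    keys = [k for k, _ in sites]
    idx = np.array([state_idx[s] for _, s in sites], dtype=int)
    new_idx = idx.copy()
    for i, s in enumerate(STATE_ORDER):
        where = np.nonzero(idx == i)[0]
        if len(where) == 0:
            continue
        draws = rng.choice(len(STATE_ORDER), size=len(where), p=kernel.row_vector(s))
        new_idx[where] = draws
    for (seq_id, pos), j in zip(keys, new_idx.tolist()):
        out.set(seq_id, pos, STATE_ORDER[j])
    return out


@dataclass(frozen=True)
class RateEstimate:
    """Method-of-moments estimates of the kernel's d and m."""

    d_hat: float
    m_hat: float
    n: int
    d_interval: tuple[float, float]
    m_interval: tuple[float, float]
    confidence: float


def recover_rates(summary: TransitionSummary, confidence: float = 0.95) -> RateEstimate:
    """Estimate (d, m) from a transition summary with binomial-SE intervals."""
    n = summary.n_classified
    if n == 0:
        raise ValidationError("cannot recover rates from zero classified loci")
    z = float(norm.ppf(0.5 + confidence / 2.0))
    d_hat = summary.demethylation_pct / 100.0
    m_hat = summary.methylation_pct / 100.0

    def interval(p: float) -> tuple[float, float]:
        se = math.sqrt(p * (1.0 - p) / n)
        return (max(0.0, p - z * se), min(1.0, p + z * se))

    return RateEstimate(d_hat, m_hat, n, interval(d_hat), interval(m_hat), confidence)


# ---------------------------------------------------------------------------
# End-to-end simulated experiment
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    genome: AmpliconGenome
    control_track: MethylomeTrack
    treated_track: MethylomeTrack
    control_matrix: pd.DataFrame
    treated_matrix: pd.DataFrame
    summary: TransitionSummary
    estimate: RateEstimate
    truth: dict


def _score_timepoint(
    genome: AmpliconGenome,
    track: MethylomeTrack,
    sample: str,
    min_len: int,
    max_len: int,
    seq_id: str = "chr1",
) -> pd.DataFrame:
    lanes = {}
    for lane in (Lane.HPAII, Lane.MSPI):
        frags = digest(genome.sequence, track, lane, seq_id=seq_id)
        lanes[lane] = select_bands(frags, min_len=min_len, max_len=max_len)
    return bands_to_matrix(lanes[Lane.HPAII], lanes[Lane.MSPI], sample=sample)


def simulate_experiment(
    n_loci: int,
    seed: int,
    prior: StatePrior | None = None,
    kernel: TreatmentKernel | None = None,
    min_len: int = 50,
    max_len: int = 700,
    frag_len_range: tuple[int, int] = (80, 400),
) -> SimulationResult:
    """generate -> treat -> digest (both lanes, both timepoints) -> score.

    Loci absent from one timepoint's matrix (no band in either lane,
    i.e. the (0,0) pattern) are re-added as explicit (0,0) rows on the
    union of loci before pairing, mirroring how a scorer reads two gels
    side by side.
    """
    prior = prior or transition_table_prior()
    kernel = kernel or TreatmentKernel.empirical_default()
    ss = np.random.SeedSequence(seed)
    g_seed, m_seed, t_seed = ss.spawn(3)
    genome = generate_amplicon_genome(
        n_loci, seed=np.random.default_rng(g_seed), frag_len_range=frag_len_range
    )
    control_track = generate_methylome(
        genome.ccgg_positions, prior, seed=np.random.default_rng(m_seed)
    )
    treated_track = apply_treatment(
        control_track, kernel, seed=np.random.default_rng(t_seed)
    )
    ctrl = _score_timepoint(genome, control_track, "CK", min_len, max_len)
    trt = _score_timepoint(genome, treated_track, "TRT", min_len, max_len)
    all_loci = sorted(set(ctrl.index) | set(trt.index))
    ctrl = ctrl.reindex(all_loci, fill_value=0)
    trt = trt.reindex(all_loci, fill_value=0)
    paired = [
        (
            BandPair(int(ctrl.at[loc, "CK_H"]), int(ctrl.at[loc, "CK_M"])),
            BandPair(int(trt.at[loc, "TRT_H"]), int(trt.at[loc, "TRT_M"])),
        )
        for loc in all_loci
    ]
    summary = transition_summary(paired, locus_ids=all_loci)
    estimate = recover_rates(summary)
    truth = {
        "d": kernel.d,
        "m": kernel.m,
        "n_loci": n_loci,
        "seed": seed,
        "prior": {s.value: p for s, p in prior.probs.items()},
    }
    return SimulationResult(
        genome, control_track, treated_track, ctrl, trt, summary, estimate, truth
    )


# ---------------------------------------------------------------------------
# Deterministic fixture matrices (known marginal counts)
# ---------------------------------------------------------------------------


def matrix_from_type_counts(
    counts: BandTypeCounts, seed: int = 0, sample: str = "S"
) -> pd.DataFrame:
    """Band matrix with exactly the requested per-type cell counts.

    Rows are shuffled deterministically so counting order cannot be
    load-bearing.
    """
    pairs: list[tuple[int, int]] = []
    for bt, n in zip(
        ("I", "II", "III", "IV"),
        (counts.n_I, counts.n_II, counts.n_III, counts.n_IV),
    ):
        bp = band_pair_of_type(BandType(bt))
        pairs.extend([(bp.h, bp.m)] * n)
    rng = _rng(seed)
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    index = pd.Index([f"L{i:05d}" for i in range(len(pairs))], name="locus")
    return pd.DataFrame(
        {f"{sample}_H": [p[0] for p in pairs], f"{sample}_M": [p[1] for p in pairs]},
        index=index,
    )


def paired_matrices_from_class_counts(
    class_counts: Mapping[str, int], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Control/treated matrices realizing given transition-class counts."""
    pattern_of_label = {
        cls.label: key for key, cls in TRANSITION_TABLE.items()
    }
    rows: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for label, n in class_counts.items():
        if label not in pattern_of_label:
            raise ValidationError(f"unknown transition class {label!r}")
        rows.extend([pattern_of_label[label]] * n)
    rng = _rng(seed)
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    index = pd.Index([f"L{i:05d}" for i in range(len(rows))], name="locus")
    control = pd.DataFrame(
        {"CK_H": [r[0][0] for r in rows], "CK_M": [r[0][1] for r in rows]}, index=index
    )
    treated = pd.DataFrame(
        {"TRT_H": [r[1][0] for r in rows], "TRT_M": [r[1][1] for r in rows]},
        index=index,
    )
    return control, treated
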