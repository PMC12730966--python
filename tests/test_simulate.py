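import math

import numpy as np
import pytest

from msapkit.core import (
    BandPair,
    BandTypeCounts,
    CCGGMethylState,
    ValidationError,
    count_band_types,
    predict_bands,
)
from msapkit.digest import Lane, MethylomeTrack, bands_to_matrix, digest, find_sites, select_bands
from msapkit.simulate import (
    B_TRANSITIONS,
    C_TRANSITIONS,
    STATE_ORDER,
    AmpliconGenome,
    StatePrior,
    TreatmentKernel,
    apply_treatment,
    ck_prior,
    generate_amplicon_genome,
    generate_genome,
    generate_methylome,
    matrix_from_type_counts,
    paired_matrices_from_class_counts,
    recover_rates,
    simulate_experiment,
    transition_table_prior,
)
from msapkit.transitions import pair_matrices, transition_summary

U = CCGGMethylState.UNMETHYLATED
H = CCGGMethylState.HEMI_EXTERNAL
FI = CCGGMethylState.FULL_INTERNAL
FE = CCGGMethylState.FULL_EXTERNAL
AB = CCGGMethylState.ABSENT


class TestStatePrior:
    def test_default_prior_frequencies(self):
        p = ck_prior()
        assert math.isclose(p.probs[U], 704 / 803)
        assert math.isclose(p.probs[FE], 26 / 803)
        assert p.probs[AB] == 0.0

    def test_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            StatePrior({U: 0.5})

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            StatePrior({U: 1.5, H: -0.5})


class TestTreatmentKernel:
    def test_rows_sum_to_one(self):
        k = TreatmentKernel.empirical_default()
        for s in STATE_ORDER:
            assert math.isclose(sum(k.rows[s].values()), 1.0, abs_tol=1e-9)

    def test_absent_is_absorbing(self):
        k = TreatmentKernel.empirical_default()
        assert k.rows[AB] == {AB: 1.0}
        with pytest.raises(ValidationError, match="absorbing"):
            TreatmentKernel({**TreatmentKernel.identity().rows, AB: {U: 1.0}}, 0, 0)

    def test_identity(self):
        k = TreatmentKernel.identity()
        assert k.d == 0.0 and k.m == 0.0
        for s in STATE_ORDER:
            assert k.rows[s] == {s: 1.0}

    def test_marginal_class_masses_match_d_and_m(self):
        prior = transition_table_prior()
        k = TreatmentKernel.from_rates(0.05, 0.02, prior=prior)
        d_marg = sum(
            prior.probs[s] * k.rows[s].get(t, 0.0) for s, t in B_TRANSITIONS
        )
        m_marg = sum(
            prior.probs[s] * k.rows[s].get(t, 0.0) for s, t in C_TRANSITIONS
        )
        assert math.isclose(d_marg, 0.05, abs_tol=1e-12)
        assert math.isclose(m_marg, 0.02, abs_tol=1e-12)

    def test_infeasible_rates_rejected(self):
        # all demethylation mass on FULL_EXTERNAL rows but almost no
        # FULL_EXTERNAL prior mass
        prior = StatePrior({U: 0.98, FE: 0.02})
        with pytest.raises(ValidationError, match="lower d/m"):
            TreatmentKernel.from_rates(0.5, 0.0, prior=prior, b_weights=(0, 0, 1, 1, 1))

    def test_published_rate_rounding_tolerated(self):
        # 0.0905 overshoots the exact 37/409 slightly; the FE row is
        # renormalized instead of erroring
        k = TreatmentKernel.from_rates(0.0905, 0.0367)
        assert math.isclose(sum(k.rows[FE].values()), 1.0, abs_tol=1e-9)


class TestGenerateGenome:
    def test_postconditions(self):
        seq = generate_genome(10_000, 0.5, n_ecori_min=5, n_ccgg_min=50, seed=1)
        eco, ccgg = find_sites(seq)
        assert len(seq) == 10_000
        assert len(eco) >= 5
        assert len(ccgg) >= 50

    def test_determinism(self):
        a = generate_genome(2_000, 0.4, 3, 10, seed=99)
        b = generate_genome(2_000, 0.4, 3, 10, seed=99)
        assert a == b

    def test_different_seed_differs(self):
        assert generate_genome(1_000, 0.5, seed=1) != generate_genome(1_000, 0.5, seed=2)

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValidationError, match="infeasible"):
            generate_genome(1_000, 0.5, n_ccgg_min=200)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            generate_genome(500)


class TestAmpliconGenome:
    def test_planted_sites_are_the_only_sites(self):
        g = generate_amplicon_genome(100, seed=4)
        eco, ccgg = find_sites(g.sequence)
        assert list(g.ccgg_positions) == ccgg
        assert len(eco) == 100

    def test_unique_lengths(self):
        g = generate_amplicon_genome(50, seed=4, unique_lengths=True)
        assert len(set(g.fragment_lengths)) == 50

    def test_determinism(self):
        a = generate_amplicon_genome(20, seed=8)
        b = generate_amplicon_genome(20, seed=8)
        assert a.sequence == b.sequence

    def test_fragment_lengths_realized_by_digest(self):
        g = generate_amplicon_genome(30, seed=2)
        track = generate_methylome(g.ccgg_positions, StatePrior({U: 1.0}), seed=0)
        frags = select_bands(digest(g.sequence, track, Lane.HPAII, seq_id="chr1"))
        assert sorted(f.length for f in frags) == sorted(g.fragment_lengths)


class TestGenerateMethylome:
    def test_point_mass_prior(self):
        track = generate_methylome([0, 10, 20], StatePrior({U: 1.0}), seed=0)
        assert all(s is U for s in track.states.values())

    def test_determinism(self):
        prior = ck_prior()
        a = generate_methylome(range(0, 1000, 10), prior, seed=3)
        b = generate_methylome(range(0, 1000, 10), prior, seed=3)
        assert a.states == b.states

    def test_state_counts_within_4_sd_of_expectation(self):
        prior = ck_prior()
        n = 8030
        track = generate_methylome(range(0, 4 * n, 4), prior, seed=12)
        from collections import Counter

        counts = Counter(track.states.values())
        for s in (U, H, FI, FE):
            p = prior.probs[s]
            sd = math.sqrt(n * p * (1 - p))
            assert abs(counts[s] - n * p) <= 4 * sd, s


class TestApplyTreatment:
    def test_identity_kernel_is_noop(self):
        track = generate_methylome(range(0, 400, 4), ck_prior(), seed=5)
        out = apply_treatment(track, TreatmentKernel.identity(), seed=6)
        assert out.states == track.states

    def test_forced_demethylation_of_hemi_sites(self):
        track = generate_methylome(range(0, 400, 4), StatePrior({H: 1.0}), seed=5)
        kernel = TreatmentKernel.from_rates(
            1.0, 0.0, prior=StatePrior({H: 1.0}), b_weights=(1, 0, 0, 0, 0)
        )
        out = apply_treatment(track, kernel, seed=7)
        assert all(s is U for s in out.states.values())

    def test_realized_demethylation_within_3_se(self):
        n = 10_000
        prior = transition_table_prior()
        kernel = TreatmentKernel.empirical_default()
        track = generate_methylome(range(0, 4 * n, 4), prior, seed=21)
        out = apply_treatment(track, kernel, seed=22)
        demeth = sum(
            1
            for key, before in track.states.items()
            if (before, out.states[key]) in set(B_TRANSITIONS)
        )
        d = kernel.d
        se = math.sqrt(d * (1 - d) / n)
        assert abs(demeth / n - d) <= 3 * se

    def test_determinism(self):
        track = generate_methylome(range(0, 4000, 4), ck_prior(), seed=1)
        kernel = TreatmentKernel.empirical_default()
        a = apply_treatment(track, kernel, seed=2)
        b = apply_treatment(track, kernel, seed=2)
        assert a.states == b.states


class TestRecoverRates:
    def test_published_summary(self, class_counts_14):
        c, t = paired_matrices_from_class_counts(class_counts_14, seed=0)
        paired, _ = pair_matrices(c, t)
        est = recover_rates(transition_summary(paired))
        assert round(est.d_hat, 4) == 0.0905
        assert round(est.m_hat, 4) == 0.0367

    def test_identity_simulation_recovers_zero(self):
        res = simulate_experiment(500, seed=11, kernel=TreatmentKernel.identity())
        assert res.estimate.d_hat == 0.0
        assert res.estimate.m_hat == 0.0

    def test_interval_contains_point(self):
        res = simulate_experiment(800, seed=13)
        lo, hi = res.estimate.d_interval
        assert lo <= res.estimate.d_hat <= hi


class TestEndToEnd:
    def test_round_trip_band_types_on_clean_genome(self):
        """simulate -> digest -> score -> classify recovers planted states."""
        prior = StatePrior({U: 0.4, H: 0.2, FI: 0.2, FE: 0.15, AB: 0.05})
        g = generate_amplicon_genome(
            60, seed=31, frag_len_range=(30, 90), right_spacer_range=(105, 140),
            unique_lengths=True,
        )
        track = generate_methylome(g.ccgg_positions, prior, seed=32)
        lanes = {}
        for lane in Lane:
            frags = digest(g.sequence, track, lane, seq_id="chr1")
            lanes[lane] = select_bands(frags, min_len=20, max_len=100)
        matrix = bands_to_matrix(lanes[Lane.HPAII], lanes[Lane.MSPI], sample="sim")
        observed = {
            int(loc.split(":")[1]) - 1: BandPair(int(row["sim_H"]), int(row["sim_M"]))
            for loc, row in matrix.iterrows()
        }
        for pos in g.ccgg_positions:
            state = track.get("chr1", pos)
            expected = predict_bands(state)
            got = observed.get(pos, BandPair(0, 0))
            assert got == expected, (pos, state)

    def test_scored_type_frequencies_approximate_prior(self):
        prior = ck_prior()
        res = simulate_experiment(4000, seed=41, prior=prior, kernel=TreatmentKernel.identity())
        counts = count_band_types(res.control_matrix)
        # bands visible in at least one lane: types I-III track the prior
        for bt, s in zip(("n_I", "n_II", "n_III"), (U, H, FI)):
            p = prior.probs[s]
            sd = math.sqrt(4000 * p * (1 - p))
            assert abs(getattr(counts, bt) - 4000 * p) <= 4 * sd, bt
        # fully blocked sites show no band at either timepoint, so they
        # never enter a single-group matrix at all
        assert counts.n_IV == 0
        p_fe = prior.probs[FE]
        sd = math.sqrt(4000 * p_fe * (1 - p_fe))
        assert abs(counts.total - 4000 * (1 - p_fe)) <= 4 * sd

    def test_determinism_bit_for_bit(self):
        a = simulate_experiment(300, seed=5)
        b = simulate_experiment(300, seed=5)
        assert a.genome.sequence == b.genome.sequence
        assert a.control_matrix.equals(b.control_matrix)
        assert a.treated_matrix.equals(b.treated_matrix)
        assert a.summary.class_counts == b.summary.class_counts

    @pytest.mark.parametrize("d", [0.02, 0.09, 0.2])
    @pytest.mark.parametrize("m", [0.01, 0.037, 0.1])
    def test_class_fractions_track_kernel_grid(self, d, m):
        # rate recovery is unbiased only when the kernel generates no
        # UNCLASSIFIED transitions: an FE -> FE locus shows no band at
        # either timepoint and silently leaves the denominator.  Setting
        # prior(FE) to exactly the demethylation mass leaving FE makes
        # that row fully off-diagonal.
        p_fe = d * 18 / 37
        prior = StatePrior({U: 1.0 - p_fe - 0.25 - 0.15, H: 0.25, FI: 0.15, FE: p_fe})
        kernel = TreatmentKernel.from_rates(d, m, prior=prior)
        res = simulate_experiment(5000, seed=51, prior=prior, kernel=kernel)
        n = res.summary.n_classified
        se_d = math.sqrt(d * (1 - d) / n)
        se_m = math.sqrt(m * (1 - m) / n)
        assert abs(res.estimate.d_hat - d) <= 3 * se_d
        assert abs(res.estimate.m_hat - m) <= 3 * se_m


class TestFixtureMatrices:
    def test_type_counts_realized(self, ck_counts):
        m = matrix_from_type_counts(ck_counts, seed=3)
        assert count_band_types(m) == ck_counts

    def test_class_counts_realized(self, class_counts_14):
        c, t = paired_matrices_from_class_counts(class_counts_14, seed=3)
        paired, _ = pair_matrices(c, t)
        summary = transition_summary(paired)
        assert summary.class_counts == class_counts_14

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            paired_matrices_from_class_counts({"Z9": 1})
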