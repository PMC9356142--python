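"""Bundled outcome predictor: scoring model, normalisation, symmetries."""

import math
import random

import pytest

from recedit import (
    IndelOutcome,
    OutcomeDistribution,
    PredictorParams,
    WindowError,
    apply_to_seq,
    canonicalize_deletion,
    concentration,
    get_predictor,
    microhomology_length,
    predict_outcomes,
    rank_outcomes,
    register_predictor,
    revcomp,
    validate_distribution,
)


def brute_force_scores(seq, cut, params=None):
    """Independent enumeration of the bundled model's raw scores.

    Re-derives every canonical deletion class touching the cut and both
    duplication insertions, without using the predictor's internals.
    """
    params = params or PredictorParams()
    scores = {}
    for d in range(1, min(params.d_max, len(seq)) + 1):
        for s in range(max(0, cut - d), min(cut, len(seq) - d) + 1):
            canon = canonicalize_deletion(seq, IndelOutcome(kind="deletion", start=s, length=d))
            key = ("deletion", canon.start, d)
            m = min(microhomology_length(seq, canon), params.mh_max)
            scores[key] = (1 + m) ** 2 * math.exp(-d / params.lambda_del)
    scores[("insertion", cut, 1)] = params.beta_ins1
    scores[("insertion", cut, 2)] = params.beta_ins2
    return scores


def make_mh_window(rng, mh_len=3, del_len=6, size=60, cut=30):
    """Engineer a window whose only strong microhomology is a planted
    ``mh_len``-repeat spanning a ``del_len`` deletion abutting the cut;
    rejection-sample until the exhaustive oracle confirms the planted class
    outscores everything else."""
    while True:
        seq = list(rng.choice("ACGT") for _ in range(size))
        rep = [rng.choice("ACGT") for _ in range(mh_len)]
        seq[cut : cut + mh_len] = rep
        seq[cut + del_len : cut + del_len + mh_len] = rep
        s = "".join(seq)
        planted_key = (
            "deletion",
            canonicalize_deletion(s, IndelOutcome(kind="deletion", start=cut, length=del_len)).start,
            del_len,
        )
        scores = brute_force_scores(s, cut)
        planted = scores[planted_key]
        if abs(planted - 16 * math.exp(-0.6)) > 1e-9:  # flank extensions changed m
            continue
        if all(v < planted - 1e-9 for k, v in scores.items() if k != planted_key):
            return s, planted_key


class TestWorkedExample:
    def test_engineered_mh_deletion_outranks_plus1(self, rng):
        """(1+3)^2 * exp(-0.6) = 8.78 beats beta_ins1 = 3.0 and every
        microhomology-free deletion, so the planted deletion ranks first."""
        seq, planted_key = make_mh_window(rng)
        assert 16 * math.exp(-0.6) == pytest.approx(8.781, abs=1e-3)
        dist = predict_outcomes(seq, 30)
        top = dist.outcomes[0]
        assert (top.kind, top.start, top.length) == planted_key
        # frequency agrees with the independent enumeration
        scores = brute_force_scores(seq, 30)
        assert top.freq == pytest.approx(scores[planted_key] / sum(scores.values()), abs=1e-12)

    def test_repeat_free_window_top_outcome_is_plus1_duplication(self, rng):
        """With no microhomology >= 1 near the cut, every deletion scores
        below beta_ins1 and the +1 duplication ranks first."""
        while True:
            seq = "".join(rng.choice("ACGT") for _ in range(60))
            scores = brute_force_scores(seq, 30)
            dels = {k: v for k, v in scores.items() if k[0] == "deletion"}
            if max(dels.values()) < 3.0:
                break
        dist = predict_outcomes(seq, 30)
        top = dist.outcomes[0]
        assert top.kind == "insertion" and top.length == 1
        assert top.inserted_seq == seq[29]


class TestDistributionContract:
    @pytest.mark.parametrize("n_windows", [50])
    def test_normalisation(self, rng, n_windows):
        for _ in range(n_windows):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(40, 120)))
            dist = predict_outcomes(seq, len(seq) // 2)
            total = sum(o.freq for o in dist.outcomes) + dist.truncated_mass
            assert total == pytest.approx(1.0, abs=1e-9)
            validate_distribution(dist, seq)

    def test_outcomes_sorted_and_deletions_canonical(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(80))
        dist = predict_outcomes(seq, 40)
        freqs = [o.freq for o in dist.outcomes]
        assert freqs == sorted(freqs, reverse=True)
        for o in dist.outcomes:
            if o.kind == "deletion":
                assert canonicalize_deletion(seq, o).start == o.start

    def test_cut_too_close_to_edge_raises(self):
        seq = "ACGT" * 10
        with pytest.raises(WindowError):
            predict_outcomes(seq, 3)
        with pytest.raises(WindowError):
            predict_outcomes(seq, len(seq) - 2)

    def test_truncation_moves_mass_not_renormalises(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(80))
        full = predict_outcomes(seq, 40, PredictorParams(min_report_freq=0.0))
        cut = predict_outcomes(seq, 40, PredictorParams(min_report_freq=0.02))
        kept = {(o.kind, o.start, o.length): o.freq for o in cut.outcomes}
        for o in full.outcomes:
            key = (o.kind, o.start, o.length)
            if key in kept:
                assert kept[key] == pytest.approx(o.freq, abs=1e-12)
            else:
                assert o.freq < 0.02
        assert cut.truncated_mass == pytest.approx(
            sum(o.freq for o in full.outcomes if (o.kind, o.start, o.length) not in kept),
            abs=1e-9,
        )


class TestSymmetries:
    def test_deletion_enumeration_reverse_complement_symmetric(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice("ACGT") for _ in range(80))
            cut = 40
            fwd = predict_outcomes(seq, cut)
            rev = predict_outcomes(revcomp(seq), len(seq) - cut)
            # class identity is the child sequence: the canonical (leftmost)
            # start maps to the rightmost member under reverse complement
            fdel = sorted(
                (revcomp(apply_to_seq(seq, o)), round(o.freq, 12))
                for o in fwd.outcomes if o.kind == "deletion"
            )
            rdel = sorted(
                (apply_to_seq(revcomp(seq), o), round(o.freq, 12))
                for o in rev.outcomes if o.kind == "deletion"
            )
            assert fdel == rdel

    def test_shift_equivariance_with_flanking_sequence(self, rng):
        """Adding 10 bp of flank on each side shifts every outcome by 10
        without changing frequencies, provided the cut is deep enough that
        no new deletion class or microhomology partner enters range."""
        for _ in range(10):
            seq = "".join(rng.choice("ACGT") for _ in range(101))
            pad_l = "".join(rng.choice("ACGT") for _ in range(10))
            pad_r = "".join(rng.choice("ACGT") for _ in range(10))
            base = predict_outcomes(seq, 50)
            shifted = predict_outcomes(pad_l + seq + pad_r, 60)
            a = [(o.kind, o.start, o.length, round(o.freq, 12)) for o in base.outcomes]
            b = [(o.kind, o.start - 10, o.length, round(o.freq, 12)) for o in shifted.outcomes]
            assert a == b


class TestRankingHelpers:
    def _dist(self, freqs):
        outcomes = tuple(
            IndelOutcome(kind="deletion", start=i, length=1, freq=f, label=f"d{i}")
            for i, f in enumerate(freqs)
        )
        return OutcomeDistribution(cut_index=10, outcomes=outcomes, truncated_mass=1 - sum(freqs))

    def test_top_k(self):
        dist = self._dist([0.6, 0.3, 0.1])
        assert [o.freq for o in rank_outcomes(dist, 2)] == [0.6, 0.3]
        assert len(rank_outcomes(dist, 10)) == 3

    def test_tie_break_shorter_then_lexicographic(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(40))
        dist = predict_outcomes(seq, 20)
        # within equal frequencies, shorter indels come first
        for a, b in zip(dist.outcomes, dist.outcomes[1:]):
            if a.freq == b.freq:
                assert a.length <= b.length

    def test_concentration_monotone_and_bounded(self):
        dist = self._dist([0.5, 0.3, 0.2])
        assert concentration(dist, 2) == pytest.approx(0.8)
        vals = [concentration(dist, n) for n in range(1, 5)]
        assert vals == sorted(vals)
        assert concentration(dist, 99) == pytest.approx(1.0 - dist.truncated_mass)


class TestAdapterSeam:
    def test_bundled_predictor_registered(self):
        assert get_predictor("bundled") is predict_outcomes

    def test_unknown_predictor_raises(self):
        with pytest.raises(KeyError):
            get_predictor("no-such-model")

    def test_seam_validation_rejects_bad_distribution(self):
        def bad(seq, cut, params=None):
            return OutcomeDistribution(
                cut_index=cut,
                outcomes=(IndelOutcome(kind="deletion", start=cut, length=1, freq=0.5),),
                truncated_mass=0.0,  # does not sum to 1
            )

        register_predictor("broken-test-model", bad)
        dist = get_predictor("broken-test-model")("ACGT" * 10, 20)
        with pytest.raises(ValueError):
            validate_distribution(dist, "ACGT" * 10)
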