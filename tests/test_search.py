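"""Recursive cascade search: scoring, selection, labels, classification."""

from dataclasses import replace

import pytest

from recedit import (
    Allele,
    Cascade,
    FilterConfig,
    GuideCandidate,
    SearchConfig,
    SequenceWindow,
    SiteReport,
    build_report,
    cascade_to_json,
    classify_site,
    enumerate_guides,
    matches_allele,
    retarget_score,
    retargeting_efficiency,
    run_recursion,
)
from recedit.predict import predict_outcomes, rank_outcomes
from recedit.search import CascadeLevel, GuideSelection, SearchDomainError

from conftest import site_donor, site_window


def _selection(guide, label, mass, alleles=()):
    return GuideSelection(
        guide=guide, label=label, retarget_score=0.0,
        targeted_alleles=tuple(alleles), targeted_mass=mass,
    )


def _dummy_guide(cut=17):
    return GuideCandidate("g", "ACGTACGTACGTACGTACGT", "AGG", "+", cut, 0, on_target=0.8)


class TestRetargetScore:
    def test_empty_frontier_is_a_domain_error(self):
        with pytest.raises(SearchDomainError):
            retarget_score(_dummy_guide(), [])

    def test_unmatched_guide_scores_zero(self):
        frontier = [Allele("T" * 60)]
        score, matched = retarget_score(_dummy_guide(), frontier)
        assert score == 0.0 and matched == []

    def test_score_bounded_by_matched_mass(self, chain_case):
        _, cascade, _ = chain_case
        b1 = cascade.levels[1].selections[0]
        assert 0.0 <= b1.retarget_score <= b1.targeted_mass + 1e-12

    def test_matched_mass_sums_over_frontier(self, chain_case):
        """B1's targeted mass equals the frequency of the -3 child it targets."""
        site, cascade, _ = chain_case
        a = cascade.levels[0].selections[0]
        dist = predict_outcomes(cascade.site.seq, a.guide.cut_index)
        b1 = cascade.levels[1].selections[0]
        assert b1.targeted_mass == pytest.approx(dist.outcomes[0].freq, abs=1e-12)


class TestRunRecursion:
    def test_chain_fixture_produces_three_levels_with_labels(self, chain_case):
        _, cascade, report = chain_case
        assert cascade.n_levels == 3
        letters = [sel.label[0] for lvl in cascade.levels for sel in lvl.selections]
        assert letters[0] == "A"
        labels = [sel.label for lvl in cascade.levels for sel in lvl.selections]
        assert "A1" in labels and "B1" in labels and "C1" in labels

    def test_labels_follow_targeted_mass_ranking(self, planted_reports):
        for cases in planted_reports.values():
            for _, cascade, _ in cases:
                for lvl in cascade.levels:
                    masses = [sel.targeted_mass for sel in lvl.selections]
                    assert masses == sorted(masses, reverse=True)
                    numbers = [int(sel.label[1:]) for sel in lvl.selections]
                    assert numbers == list(range(1, len(numbers) + 1))

    def test_max_levels_one_gives_a_level_only(self, chain_case, genome):
        site, _, _ = chain_case
        window = site_window(site, genome)
        cascade = run_recursion(window, site_donor(site, window), cfg=SearchConfig(max_levels=1))
        assert cascade.n_levels == 1
        assert cascade.levels[0].selections[0].label == "A1"

    def test_no_qualifying_a_guide_reports_reason(self):
        window = SequenceWindow("w", 0, "AT" * 30)  # PAM-free
        cascade = run_recursion(window)
        assert cascade.n_levels == 0 and "A-level" in cascade.reason

    def test_deterministic_byte_identical_cascades(self, chain_case, genome):
        site, cascade, _ = chain_case
        window = site_window(site, genome)
        again = run_recursion(window, site_donor(site, window))
        assert cascade_to_json(cascade) == cascade_to_json(again)

    def test_selected_guides_match_independent_reranking(self, chain_case):
        """Independent re-derivation of the level-B selection: enumerate all
        candidates on the frontier alleles by string search, apply the same
        thresholds through public predicates, rank by (score, on-target,
        cut, strand) and compare with the cascade's choice."""
        site, cascade, _ = chain_case
        wt = Allele(cascade.site.seq)
        a = cascade.levels[0].selections[0]
        dist = predict_outcomes(wt.seq, a.guide.cut_index)
        from recedit import apply_outcome

        frontier = [apply_outcome(wt, a.guide.guide_id, o) for o in rank_outcomes(dist, 2)]
        chosen = {sel.guide.protospacer for sel in cascade.levels[1].selections}
        # every chosen guide matches >=1 frontier allele, misses WT and HDR
        for sel in cascade.levels[1].selections:
            assert any(matches_allele(sel.guide, f) for f in frontier)
            assert not matches_allele(sel.guide, wt)
            assert not matches_allele(sel.guide, cascade.donor.hdr_allele)
        # and each frontier allele with >= min mass is covered by a chosen guide
        for f in frontier:
            if f.mass >= SearchConfig().min_targeted_mass:
                assert any(matches_allele(sel.guide, f) for sel in cascade.levels[1].selections)


class TestEfficiencyAndClassification:
    def _cascade_with_masses(self, masses):
        site = SequenceWindow("s", 0, "ACGT" * 10)
        alleles = [
            Allele("A" * (30 + i), (("g", _outcome(i)),), 1, m) for i, m in enumerate(masses)
        ]
        lvl0 = CascadeLevel(selections=(_selection(_dummy_guide(), "A1", 1.0),), indel_mass_total=1.0)
        lvl1 = CascadeLevel(
            selections=tuple(
                _selection(_dummy_guide(), f"B{i + 1}", a.mass, [a]) for i, a in enumerate(alleles)
            ),
            indel_mass_total=sum(masses),
        )
        return Cascade(site=site, donor=None, levels=(lvl0, lvl1))

    def test_efficiency_is_covered_fraction(self):
        cascade = self._cascade_with_masses([0.6, 0.27])
        assert retargeting_efficiency(cascade, 0) == pytest.approx(0.87)

    def test_shared_target_counted_once(self):
        shared = Allele("A" * 40, (("g", _outcome(0)),), 1, 0.5)
        lvl0 = CascadeLevel(selections=(_selection(_dummy_guide(), "A1", 1.0),), indel_mass_total=1.0)
        lvl1 = CascadeLevel(
            selections=(
                _selection(_dummy_guide(), "B1", 0.5, [shared]),
                _selection(_dummy_guide(), "B2", 0.5, [shared]),
            ),
            indel_mass_total=1.0,
        )
        cascade = Cascade(site=SequenceWindow("s", 0, "ACGT" * 10), donor=None, levels=(lvl0, lvl1))
        assert retargeting_efficiency(cascade, 0) == pytest.approx(0.5)

    def test_no_next_level_gives_zero(self):
        cascade = self._cascade_with_masses([0.6])
        assert retargeting_efficiency(cascade, 1) == 0.0

    @pytest.mark.parametrize(
        "eff,expected",
        [(0.0, False), (0.20, False), (0.2000000001, True), (0.21, True), (1.0, True)],
    )
    def test_recursive_threshold_is_strict(self, eff, expected):
        report = SiteReport(
            cascade=Cascade(SequenceWindow("s", 0, "ACGT" * 10), None, ()),
            retargeting_efficiency_per_level=(eff,),
            is_recursive=False,
            overall_rank_score=0.0,
        )
        assert classify_site(report) is expected

    def test_planted_fixture_classifications(self, planted_reports):
        for site, _, report in planted_reports["mh_deletion_chain"]:
            assert report.is_recursive is True
        for site, _, report in planted_reports["plus1_dup"]:
            assert report.is_recursive is True
        for site, _, report in planted_reports["non_recursive"]:
            assert report.is_recursive is False


def _outcome(i):
    from recedit import IndelOutcome

    return IndelOutcome(kind="deletion", start=5 + i, length=1, freq=0.5)
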