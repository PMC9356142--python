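"""Guide enumeration, on-target heuristic, off-target counting, filters."""

import pytest

from recedit import (
    Allele,
    DonorSpec,
    FilterConfig,
    GuideCandidate,
    IndelOutcome,
    OfftargetIndex,
    SequenceWindow,
    apply_outcome,
    count_offtargets,
    enumerate_guides,
    find_matches,
    matches_allele,
    passes_filters,
    revcomp,
    score_on_target,
)


def oracle_sites(seq):
    """Exhaustive per-offset/strand NGG scan, independent of the enumerator."""
    sites = []
    for p in range(len(seq) - 22):
        if seq[p + 21 : p + 23] == "GG":
            sites.append((p, "+"))
        if seq[p : p + 2] == "CC":
            sites.append((p, "-"))
    return sorted(sites)


class TestEnumeration:
    def test_single_protospacer_window_cut_convention(self):
        seq = "ATGCATGCATGCATGCATGCTGG"  # exactly one 20-mer + TGG
        guides = enumerate_guides(seq)
        assert len(guides) == 1
        g = guides[0]
        assert (g.strand, g.cut_index, g.protospacer, g.pam) == ("+", 17, seq[:20], "TGG")

    def test_minus_strand_cut_maps_to_forward_coordinates(self):
        fwd = "ATGCATGCATGCATGCATGCTGG"
        seq = revcomp(fwd)  # now CCA... on the forward strand
        guides = enumerate_guides(seq)
        assert len(guides) == 1
        g = guides[0]
        assert g.strand == "-" and g.cut_index == 6
        assert g.protospacer == fwd[:20] and g.pam == "TGG"

    def test_reverse_complement_mirror(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(150))
        a = enumerate_guides(seq)
        b = enumerate_guides(revcomp(seq))
        assert len(a) == len(b)
        assert sorted(g.protospacer + g.pam for g in a) == sorted(
            g.protospacer + g.pam for g in b
        )

    def test_matches_exhaustive_oracle_on_random_sequences(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice("ACGT") for _ in range(200))
            got = [(g.start, g.strand) for g in enumerate_guides(seq)]
            assert got == oracle_sites(seq)

    def test_too_short_sequence_yields_nothing(self):
        assert enumerate_guides("ACGTACGTACGTACGTACGTAG") == []


class TestOnTargetScore:
    def _guide(self, proto):
        return GuideCandidate("t", proto, "TGG", "+", 17, 0)

    def test_balanced_gc_scores_high(self):
        proto = "ACGTACGTACGTACGTACGA"  # 50% GC, no homopolymer, no TT end
        assert score_on_target(self._guide(proto)) == pytest.approx(0.8)

    def test_homopolymer_penalty(self):
        assert score_on_target(self._guide("A" * 20)) == pytest.approx(0.4)

    def test_tt_end_penalty(self):
        proto = "ACGTACGTACGTACGTACTT"
        assert score_on_target(self._guide(proto)) == pytest.approx(0.6)

    def test_score_always_in_unit_interval(self, rng):
        for _ in range(200):
            proto = "".join(rng.choice("ACGT") for _ in range(20))
            assert 0.0 <= score_on_target(self._guide(proto)) <= 1.0


class TestOfftargetCounting:
    def test_source_allele_alone_counts_zero(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(120))
        guides = enumerate_guides(seq, "src")
        assert guides, "random 120-mer should contain a PAM"
        g = guides[0]
        assert count_offtargets(g, [SequenceWindow("src", 0, seq)], mm_max=2) == 0

    def test_planted_one_mismatch_site_counts_once(self, rng):
        while True:
            seq = "".join(rng.choice("ACGT") for _ in range(120))
            guides = enumerate_guides(seq, "src")
            if guides:
                g = guides[0]
                break
        site = list(g.protospacer)
        old = site[7]
        site[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        background = seq + "TTTT" + "".join(site) + "AGG" + "TTTT"
        assert count_offtargets(g, [SequenceWindow("src", 0, background)], mm_max=2) == 1
        assert count_offtargets(g, [SequenceWindow("src", 0, background)], mm_max=0) == 0

    def test_reverse_complement_background_symmetric(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(150))
        g = enumerate_guides(seq, "other")[0]
        bg = "".join(rng.choice("ACGT") for _ in range(300))
        n_fwd = count_offtargets(g, [SequenceWindow("bg", 0, bg)], mm_max=3)
        n_rev = count_offtargets(g, [SequenceWindow("bg", 0, revcomp(bg))], mm_max=3)
        assert n_fwd == n_rev

    def test_index_n_bases_never_match(self):
        g = GuideCandidate("t", "ACGTACGTACGTACGTACGT", "AGG", "+", 17, 0, source_id="x")
        bg = "N" * 20 + "AGG" + "ACGT" * 10
        idx = OfftargetIndex([("bg", bg)])
        assert idx.count(g.protospacer, mm_max=2) == 0


class TestMatching:
    def test_enumerated_guide_matches_its_allele(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(150))
        wt = Allele(seq)
        for g in enumerate_guides(seq):
            assert matches_allele(g, wt)

    def test_guide_spanning_insertion_does_not_match_parent(self):
        wt_seq = "ATGCATGCATGCATGCATGCTGGACGTACGT"
        wt = Allele(wt_seq)
        out = IndelOutcome(kind="insertion", start=17, length=1, inserted_seq="T", freq=0.5)
        child = apply_outcome(wt, "gA", out)
        child_guides = [
            g for g in enumerate_guides(child.seq) if g.start <= 17 <= g.start + 23
        ]
        spanning = [g for g in child_guides if matches_allele(g, child) and not matches_allele(g, wt)]
        assert spanning, "a guide spanning the novel +1 junction must exist and not match WT"

    def test_find_matches_reports_both_strands(self):
        fwd = "ATGCATGCATGCATGCATGCTGG"
        seq = fwd + "TTTT" + revcomp(fwd)
        g = enumerate_guides(fwd)[0]
        hits = find_matches(g, seq)
        assert [(h[1]) for h in hits] == ["+", "-"]


class TestFilters:
    def _annotated(self, seq, on=0.8, hits=0):
        g = enumerate_guides(seq, "w")[0]
        object.__setattr__(g, "on_target", on)
        object.__setattr__(g, "offtarget_hits", hits)
        return g

    def test_low_on_target_rejected(self, rng):
        seq = "ATGCATGCATGCATGCATGCTGGACGTACGTAC"
        g = self._annotated(seq, on=0.4)
        assert not passes_filters(g, FilterConfig(), Allele("T" * 40), None, None, level=1)

    def test_guide_matching_hdr_allele_rejected_at_any_level(self):
        seq = "ATGCATGCATGCATGCATGCTGGACGTACGTAC"
        g = self._annotated(seq)
        donor = DonorSpec(edit=IndelOutcome(kind="insertion", start=50, length=1, inserted_seq="A"),
                          hdr_allele=seq)  # HDR allele contains the guide site
        assert not passes_filters(g, FilterConfig(), Allele("T" * 40), donor, None, level=0)
        assert not passes_filters(g, FilterConfig(), Allele("T" * 40), donor, None, level=2)

    def test_wildtype_avoidance_applies_from_level_b(self):
        seq = "ATGCATGCATGCATGCATGCTGGACGTACGTAC"
        g = self._annotated(seq)
        wt = Allele(seq)
        assert passes_filters(g, FilterConfig(), wt, None, None, level=0)  # A level exempt
        assert not passes_filters(g, FilterConfig(), wt, None, None, level=1)

    def test_proximity_clause(self):
        seq = "ATGCATGCATGCATGCATGCTGGACGTACGTAC"
        g = self._annotated(seq)  # cut at 17
        wt = Allele("T" * 40)
        assert passes_filters(g, FilterConfig(), wt, None, prior_edit_pos=25, level=1)
        assert not passes_filters(g, FilterConfig(), wt, None, prior_edit_pos=40, level=1)
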