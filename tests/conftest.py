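"""Shared fixtures: one synthetic fixture set per session, plus cascades
derived from its planted constructs."""

from __future__ import annotations

import json
import random

import pytest

from recedit import (
    DonorSpec,
    FixtureSpec,
    IndelOutcome,
    OfftargetIndex,
    SequenceWindow,
    build_report,
    generate_fixtures,
    read_fasta,
    run_recursion,
)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(FixtureSpec(seed=FIXTURE_SEED), out)


@pytest.fixture(scope="session")
def genome(fixture_set):
    return read_fasta(fixture_set["genome"])


@pytest.fixture(scope="session")
def ot_index(genome):
    return OfftargetIndex(list(genome.items()))


def site_window(site, genome):
    seq = genome[site.contig]
    return SequenceWindow(site.contig, site.window_start, seq[site.window_start : site.window_end])


def site_donor(site, window):
    cut_local = site.a_cut - site.window_start
    edit = IndelOutcome(kind="insertion", start=cut_local, length=3, inserted_seq="GAT")
    return DonorSpec.from_edit(window.seq, edit)


@pytest.fixture(scope="session")
def planted_reports(fixture_set, genome):
    """construct-type -> list of (site, cascade, report) for every planted site."""
    out: dict = {}
    for site in fixture_set["sites"]:
        window = site_window(site, genome)
        donor = site_donor(site, window)
        cascade = run_recursion(window, donor)
        out.setdefault(site.construct, []).append((site, cascade, build_report(cascade)))
    return out


@pytest.fixture(scope="session")
def chain_case(planted_reports):
    return planted_reports["mh_deletion_chain"][0]


@pytest.fixture(scope="session")
def rng():
    return random.Random(FIXTURE_SEED)
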