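"""Recursive retargeting search: build the cascade of guides over edited alleles.

The search proceeds breadth-wise over recursion levels. Level A targets the
wildtype; its predicted outcomes become the level-1 frontier of indel
alleles. At each subsequent level the search enumerates candidate guides
near the prior edits, scores each candidate by the retargeting score

    score(g) = M(g) * R(g)

where ``M(g)`` is the summed mass of frontier alleles the guide matches
exactly (the abundance of the newly targeted indels) and ``R(g)`` is the
fraction of the guide's own predicted outcome mass whose child alleles can
be retargeted by at least one further qualifying guide (a one-step
look-ahead). Both factors are frequencies in [0, 1]; their product is a
priority metric for comparing reagents at a locus, not a quantitative
predictor of HDR improvement. At the final level, where no further
retargeting is sought, qualifying candidates are re-ranked solely by
efficacy and specificity.

Levels are lettered A, B, C, ...; within a level, guides are numbered by
the predicted abundance of the alleles they target (B1 targets more mass
than B2). A site is classified *recursive* when the guides at level B cover
strictly more than 20% of the indel mass produced by the first cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .core import (
    Allele,
    DonorSpec,
    SequenceWindow,
    apply_outcome,
    apply_to_seq,
    merge_alleles,
    microhomology_length,
)
from .guides import (
    FilterConfig,
    GuideCandidate,
    OfftargetIndex,
    annotate,
    enumerate_guides,
    find_matches,
    matches_allele,
    passes_filters,
)
from .predict import OutcomeDistribution, PredictorParams, predict_outcomes, rank_outcomes

__all__ = [
    "SearchConfig",
    "GuideSelection",
    "CascadeLevel",
    "Cascade",
    "SiteReport",
    "retarget_score",
    "run_recursion",
    "retargeting_efficiency",
    "classify_site",
    "build_report",
]


@dataclass(frozen=True)
class SearchConfig:
    """Recursion depth, branching and qualification thresholds.

    max_levels
        Number of guide levels (3 = A/B/C).
    top_outcomes_per_allele
        Predicted outcomes kept per cut allele when extending the frontier.
    min_targeted_mass
        A candidate must target at least this much frontier mass.
    entry_concentration_min
        Entry-point gate used by the scans: the top-2 outcome frequencies of
        the first cut must sum to at least this for a site to be worth a
        recursive design.
    guides_per_level_max
        Guides selected per retargeting level.
    recursive_threshold
        Strict lower bound on level-0 retargeting efficiency for a site to
        classify as recursive.
    """

    max_levels: int = 3
    top_outcomes_per_allele: int = 2
    min_targeted_mass: float = 0.05
    entry_concentration_min: float = 0.5
    guides_per_level_max: int = 2
    recursive_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        for name in ("min_targeted_mass", "entry_concentration_min", "recursive_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GuideSelection:
    """A chosen guide with its label and targeting bookkeeping."""

    guide: GuideCandidate
    label: str
    retarget_score: float
    targeted_alleles: tuple  # Allele objects from the frontier, mass descending
    targeted_mass: float


@dataclass(frozen=True)
class CascadeLevel:
    selections: tuple  # GuideSelection, ordered by label number
    indel_mass_total: float  # mass cut open at this level (feeds the next frontier)


@dataclass(frozen=True)
class Cascade:
    site: SequenceWindow
    donor: DonorSpec | None
    levels: tuple  # CascadeLevel per level, index 0 == A
    reason: str = ""  # non-empty iff the cascade is empty/truncated early

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def all_selections(self):
        return [sel for lvl in self.levels for sel in lvl.selections]


@dataclass(frozen=True)
class SiteReport:
    cascade: Cascade
    retargeting_efficiency_per_level: tuple
    is_recursive: bool
    overall_rank_score: float


class SearchDomainError(ValueError):
    pass


def _level_letter(level: int) -> str:
    return chr(ord("A") + level)


def retarget_score(
    g: GuideCandidate,
    frontier,
    predictor_params: PredictorParams | None = None,
    filters: FilterConfig | None = None,
    wt: Allele | str | None = None,
    donor: DonorSpec | None = None,
    ot_index: OfftargetIndex | None = None,
):
    """Retargeting score M(g) x R(g) for a guide against a frontier of alleles.

    M(g) sums the mass of matched frontier alleles. R(g) is evaluated on the
    highest-mass matched allele: predict the outcome distribution at the
    guide's cut, and sum the frequencies of outcomes whose child allele is
    matched by at least one next-level candidate passing the filters.
    Returns (score, matched_alleles) with matched alleles mass-descending.
    """
    frontier = list(frontier)
    if not frontier:
        raise SearchDomainError("retarget_score requires a non-empty frontier")
    params = predictor_params or PredictorParams()
    filters = filters or FilterConfig()
    matched = [a for a in frontier if matches_allele(g, a)]
    if not matched:
        return 0.0, []
    matched.sort(key=lambda a: (-a.mass, a.seq))
    m_mass = min(sum(a.mass for a in matched), 1.0)

    primary = matched[0]
    hits = find_matches(g, primary.seq)
    cut = hits[0][2]
    try:
        dist = predict_outcomes(primary.seq, cut, params)
    except ValueError:
        return 0.0, matched
    r = 0.0
    for outcome in dist.outcomes:
        child = apply_outcome(primary, g.guide_id, outcome)
        interval = edit_interval(primary.seq, outcome)
        if _has_qualifying_guide(child, interval, filters, wt, donor, ot_index):
            r += outcome.freq
    return m_mass * r, matched


def edit_interval(parent_seq: str, outcome) -> tuple:
    """Coordinate interval (in child coordinates) containing the edit.

    A microhomology-flanked deletion is positionally ambiguous: removing any
    of the ``m + 1`` equivalent placements yields the same child, so the
    junction lies anywhere in ``[start, start + m]`` and the affected parent
    span reaches ``start + length + m``. Retargeting proximity is measured
    against this whole interval, not just the leftmost placement.
    """
    if outcome.kind == "deletion":
        m = microhomology_length(parent_seq, outcome)
        return outcome.start, outcome.start + m
    return outcome.start, outcome.start + outcome.length


def _near(cut: int, interval: tuple, proximity: int) -> bool:
    return interval[0] - proximity <= cut <= interval[1] + proximity


def _last_edit_interval(wt_seq: str, allele) -> tuple:
    """Edit interval of an allele's most recent outcome, replaying the
    lineage from wildtype to recover the parent sequence."""
    parent = wt_seq
    for _, outcome in allele.lineage[:-1]:
        parent = apply_to_seq(parent, outcome)
    return edit_interval(parent, allele.lineage[-1][1])


def _has_qualifying_guide(child, interval, filters, wt, donor, ot_index) -> bool:
    """One-step look-ahead: does any filter-passing guide match the child near its edit?"""
    for cand in enumerate_guides(child.seq, source_id="lookahead"):
        if not _near(cand.cut_index, interval, filters.proximity_bp):
            continue
        cand = annotate(cand, ot_index, filters.mm_max)
        if wt is not None and passes_filters(cand, filters, wt, donor, None, level=1):
            return True
        if wt is None:
            # no wildtype context: efficacy/specificity only
            if cand.on_target >= filters.min_on_target and cand.offtarget_hits <= filters.max_offtarget_hits:
                return True
    return False


def _expand_frontier(selections, params, top_k):
    """Children of the chosen guides: top outcomes per matched allele, merged by sequence."""
    children = []
    mass_cut = 0.0
    seen = set()
    for sel in selections:
        for allele in sel.targeted_alleles:
            key = (sel.guide.protospacer, sel.guide.pam, allele.seq)
            if key in seen:
                continue
            seen.add(key)
            mass_cut += allele.mass
            hits = find_matches(sel.guide, allele.seq)
            cut = hits[0][2]
            try:
                dist = predict_outcomes(allele.seq, cut, params)
            except ValueError:
                continue
            for outcome in rank_outcomes(dist, top_k):
                children.append(apply_outcome(allele, sel.guide.guide_id, outcome))
    return merge_alleles(children), mass_cut


def _select(candidates, final_level: bool, cfg: SearchConfig, k: int):
    """Rank qualifying candidates and keep the top k.

    Intermediate levels rank by retargeting score (ties: on-target score,
    then leftmost cut, then + strand). The final level ranks solely by
    efficacy and specificity.
    """
    if final_level:
        key = lambda c: (-c["guide"].on_target, c["guide"].offtarget_hits, c["guide"].cut_index, c["guide"].strand)
    else:
        key = lambda c: (-c["score"], -c["guide"].on_target, c["guide"].cut_index, c["guide"].strand)
    return sorted(candidates, key=key)[:k]


def _label(selections, level: int):
    """Assign A1/B1/B2/... labels: numbers follow targeted mass, descending."""
    letter = _level_letter(level)
    ordered = sorted(
        selections, key=lambda c: (-c["targeted_mass"], c["guide"].cut_index, c["guide"].strand)
    )
    return tuple(
        GuideSelection(
            guide=c["guide"],
            label=f"{letter}{i + 1}",
            retarget_score=c["score"],
            targeted_alleles=tuple(c["matched"]),
            targeted_mass=c["targeted_mass"],
        )
        for i, c in enumerate(ordered)
    )


def run_recursion(
    site: SequenceWindow,
    donor: DonorSpec | None = None,
    predictor_params: PredictorParams | None = None,
    filters: FilterConfig | None = None,
    cfg: SearchConfig | None = None,
    a_guide: GuideCandidate | None = None,
    a_cut_range: tuple | None = None,
    ot_index: OfftargetIndex | None = None,
) -> Cascade:
    """Run the full recursive guide search on one site window.

    The level-A guide is designed from the window unless supplied by the
    caller; ``a_cut_range`` optionally restricts the A cut to a coordinate
    interval (used by the codon/variant scans). ``ot_index`` supplies the
    background for off-target counting (no background: zero hits).
    Deterministic: identical inputs give identical cascades.
    """
    params = predictor_params or PredictorParams()
    filters = filters or FilterConfig()
    cfg = cfg or SearchConfig()
    site.validate_for_design()
    wt = Allele(seq=site.seq)

    # ---- level A -------------------------------------------------------
    if a_guide is not None:
        if not matches_allele(a_guide, wt):
            return Cascade(site, donor, (), reason="supplied A guide does not match the window")
        # a pre-annotated guide (on_target already scored) is taken as-is, so
        # callers can count off-targets in the guide's native coordinate frame
        pool = [a_guide if a_guide.on_target > 0 else annotate(a_guide, ot_index, filters.mm_max)]
    else:
        # window-enumerated guides carry window-local starts; exclude their
        # own genomic site from the off-target count via the window offset
        pool = [
            annotate(g, ot_index, filters.mm_max, exclude_offset=site.start)
            for g in enumerate_guides(site.seq, site.contig_id)
        ]
    a_cands = []
    for g in pool:
        if a_cut_range is not None and not (a_cut_range[0] <= g.cut_index <= a_cut_range[1]):
            continue
        if not (5 <= g.cut_index <= len(site.seq) - 5):
            continue
        # A level is exempt from wildtype avoidance; donor avoidance applies.
        if not passes_filters(g, filters, wt, donor, None, level=0):
            continue
        score, matched = retarget_score(g, [wt], params, filters, wt, donor, ot_index)
        a_cands.append({"guide": g, "score": score, "matched": matched, "targeted_mass": 1.0})
    if not a_cands:
        return Cascade(site, donor, (), reason="no qualifying A-level guide")

    final_a = cfg.max_levels == 1
    chosen = _select(a_cands, final_a, cfg, 1)
    levels = [CascadeLevel(selections=_label(chosen, 0), indel_mass_total=1.0)]

    # ---- retargeting levels -------------------------------------------
    frontier, _ = _expand_frontier(levels[0].selections, params, cfg.top_outcomes_per_allele)
    for level in range(1, cfg.max_levels):
        if not frontier:
            break
        cands = _score_level(frontier, wt, donor, params, filters, cfg, ot_index)
        if not cands:
            break
        final = level == cfg.max_levels - 1
        chosen = _select(cands, final, cfg, cfg.guides_per_level_max)
        selections = _label(chosen, level)
        frontier, mass_cut = _expand_frontier(selections, params, cfg.top_outcomes_per_allele)
        levels.append(CascadeLevel(selections=selections, indel_mass_total=mass_cut))
    return Cascade(site, donor, tuple(levels))


def _score_level(frontier, wt, donor, params, filters, cfg, ot_index):
    """Candidate guides for one retargeting level: enumerate near each
    frontier allele's last edit, deduplicate by protospacer+PAM, filter,
    and compute retargeting scores."""
    by_site: dict[tuple, GuideCandidate] = {}
    intervals = {a.seq: _last_edit_interval(wt.seq, a) for a in frontier}
    for allele in frontier:
        interval = intervals[allele.seq]
        for g in enumerate_guides(allele.seq, source_id="frontier"):
            if not _near(g.cut_index, interval, filters.proximity_bp):
                continue
            key = (g.protospacer, g.pam)
            if key not in by_site:
                by_site[key] = g
    cands = []
    for g in sorted(by_site.values(), key=lambda g: (g.protospacer, g.pam)):
        g = annotate(g, ot_index, filters.mm_max)
        score, matched = retarget_score(g, frontier, params, filters, wt, donor, ot_index)
        if not matched:
            continue
        targeted_mass = min(sum(a.mass for a in matched), 1.0)
        if targeted_mass < cfg.min_targeted_mass:
            continue
        # proximity: the cut must sit near the edit of at least one matched allele
        ok = False
        for allele in matched:
            hits = find_matches(g, allele.seq)
            if any(_near(cut, intervals[allele.seq], filters.proximity_bp) for _, _, cut in hits):
                ok = True
                break
        if not ok:
            continue
        if not passes_filters(g, filters, wt, donor, None, level=1):
            continue
        cands.append({"guide": g, "score": score, "matched": matched, "targeted_mass": targeted_mass})
    return cands


def retargeting_efficiency(cascade: Cascade, level: int) -> float:
    """Fraction of the indel mass produced at ``level`` that the next
    level's guides target.

    The numerator is the union of matched-allele masses across the chosen
    next-level guides (a shared target is counted once), the denominator the
    total mass cut open at ``level``. Returns 0 when there is no next level.
    """
    if level < 0 or level >= cascade.n_levels:
        raise ValueError(f"level {level} outside cascade with {cascade.n_levels} levels")
    if level + 1 >= cascade.n_levels:
        return 0.0
    total = cascade.levels[level].indel_mass_total
    if total <= 0:
        return 0.0
    seen: dict[str, float] = {}
    for sel in cascade.levels[level + 1].selections:
        for allele in sel.targeted_alleles:
            seen[allele.seq] = allele.mass
    return min(sum(seen.values()) / total, 1.0)


def classify_site(report: SiteReport, threshold: float = 0.20) -> bool:
    """Recursive iff level-0 retargeting efficiency strictly exceeds the threshold."""
    if not report.retargeting_efficiency_per_level:
        raise ValueError("report carries no retargeting efficiencies")
    return report.retargeting_efficiency_per_level[0] > threshold


def build_report(cascade: Cascade, cfg: SearchConfig | None = None) -> SiteReport:
    """Summarise a cascade: per-level retargeting efficiencies, the
    recursive classification, and an overall priority score (the A-level
    guide's retargeting score)."""
    cfg = cfg or SearchConfig()
    if cascade.n_levels == 0:
        return SiteReport(cascade, (0.0,), False, 0.0)
    effs = tuple(
        retargeting_efficiency(cascade, lvl) for lvl in range(max(cascade.n_levels - 1, 1))
    )
    a_sel = cascade.levels[0].selections[0]
    report = SiteReport(cascade, effs, False, a_sel.retarget_score)
    return replace(report, is_recursive=classify_site(report, cfg.recursive_threshold))
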