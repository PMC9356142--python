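"""SpCas9 guide enumeration, scoring, off-target counting and filters.

Guides are 20-nt protospacers adjacent to an NGG PAM; the blunt cut falls
3 nt 5' of the PAM (between protospacer positions 17 and 18, so a plus-strand
guide whose protospacer starts at ``p`` cuts at allele coordinate ``p + 17``,
and a minus-strand guide whose 23-mer starts at ``q`` cuts at ``q + 6``).

Off-target counting is exact and exhaustive: every background position on
both strands whose 20-mer is within ``mm_max`` Hamming mismatches of the
protospacer *and* is followed by NGG counts as a hit, minus the intended
on-target occurrence. :class:`OfftargetIndex` vectorises this with numpy so
a whole mini-genome can be queried per guide in microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Allele, DonorSpec, SequenceWindow, revcomp

__all__ = [
    "GuideCandidate",
    "FilterConfig",
    "enumerate_guides",
    "score_on_target",
    "OfftargetIndex",
    "count_offtargets",
    "find_matches",
    "matches_allele",
    "passes_filters",
]

CUT_OFFSET = 17  # nt from protospacer 5' end to the blunt cut
GUIDE_LEN = 20
SITE_LEN = 23  # protospacer + PAM


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer + NGG PAM on a source allele.

    ``start`` is the forward-strand coordinate of the 23-mer site on the
    source sequence; ``cut_index`` the blunt-cut coordinate in the same
    frame. ``protospacer`` and ``pam`` read 5'->3' on ``strand``.
    """

    guide_id: str
    protospacer: str
    pam: str
    strand: str
    cut_index: int
    start: int
    source_id: str = ""
    on_target: float = 0.0
    offtarget_hits: int = 0

    def __post_init__(self) -> None:
        if len(self.protospacer) != GUIDE_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def site(self) -> str:
        """The 23-mer protospacer+PAM, 5'->3' on the guide strand."""
        return self.protospacer + self.pam


def enumerate_guides(allele_seq: str, source_id: str = "") -> list:
    """All protospacer+NGG sites on both strands, ordered by position then strand.

    Plus-strand site at ``p``: protospacer ``seq[p:p+20]``, PAM ``seq[p+20:p+23]``
    with GG at ``p+21``; cut at ``p+17``. Minus-strand site at ``q`` appears as
    CCN + 20-mer on the forward strand; its cut maps to ``q + 6``.
    """
    if len(allele_seq) < SITE_LEN:
        return []
    out = []
    n = len(allele_seq)
    for p in range(n - SITE_LEN + 1):
        if allele_seq[p + 21] == "G" and allele_seq[p + 22] == "G":
            proto = allele_seq[p : p + GUIDE_LEN]
            pam = allele_seq[p + GUIDE_LEN : p + SITE_LEN]
            out.append(
                GuideCandidate(
                    guide_id=f"{source_id or 'seq'}:{p}+",
                    protospacer=proto,
                    pam=pam,
                    strand="+",
                    cut_index=p + CUT_OFFSET,
                    start=p,
                    source_id=source_id,
                )
            )
        if allele_seq[p] == "C" and allele_seq[p + 1] == "C":
            proto = revcomp(allele_seq[p + 3 : p + SITE_LEN])
            pam = revcomp(allele_seq[p : p + 3])
            out.append(
                GuideCandidate(
                    guide_id=f"{source_id or 'seq'}:{p}-",
                    protospacer=proto,
                    pam=pam,
                    strand="-",
                    cut_index=p + 6,
                    start=p,
                    source_id=source_id,
                )
            )
    return out


def _has_homopolymer(seq: str, k: int = 5) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= k:
            return True
    return False


def score_on_target(g: GuideCandidate) -> float:
    """Heuristic on-target efficacy in [0, 1].

    Base 0.6; +0.2 for protospacer GC content in [0.40, 0.70]; -0.2 for a
    homopolymer run of >= 5 nt; -0.2 if the protospacer ends in "TT" right
    before the PAM (a weak-efficacy signature). Clipped to [0, 1]. Pluggable
    by name for external efficacy models.
    """
    proto = g.protospacer
    gc = (proto.count("G") + proto.count("C")) / GUIDE_LEN
    score = 0.6
    if 0.40 <= gc <= 0.70:
        score += 0.2
    if _has_homopolymer(proto):
        score -= 0.2
    if proto.endswith("TT"):
        score -= 0.2
    return min(1.0, max(0.0, score))


_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class OfftargetIndex:
    """Precomputed PAM-adjacent 20-mers of a background sequence set.

    Holds, for both strands of every window, the numpy-encoded 20-mers that
    sit 5' of an NGG; querying a protospacer is a single vectorised Hamming
    comparison. Positions record the forward-strand start of the 23-mer
    site, so the intended on-target occurrence can be excluded by
    (contig, start, strand). N bases never match a protospacer base.
    """

    def __init__(self, windows) -> None:
        mats, keys = [], []
        for w in windows:
            contig, seq = (w.contig_id, w.seq) if isinstance(w, SequenceWindow) else w
            offset = w.start if isinstance(w, SequenceWindow) else 0
            n = len(seq)
            if n < SITE_LEN:
                continue
            enc = _encode(seq)
            sites = np.lib.stride_tricks.sliding_window_view(enc, SITE_LEN)
            g, c = _ENC[ord("G")], _ENC[ord("C")]
            plus = (sites[:, 21] == g) & (sites[:, 22] == g)
            for p in np.nonzero(plus)[0]:
                mats.append(sites[p, :GUIDE_LEN])
                keys.append((contig, offset + int(p), "+"))
            minus = (sites[:, 0] == c) & (sites[:, 1] == c)
            rc = _encode(revcomp(seq))
            for p in np.nonzero(minus)[0]:
                # minus-strand protospacer = revcomp(seq[p+3 : p+23])
                rp = n - (int(p) + SITE_LEN)
                mats.append(rc[rp : rp + GUIDE_LEN])
                keys.append((contig, offset + int(p), "-"))
        self._mat = np.vstack(mats) if mats else np.empty((0, GUIDE_LEN), dtype=np.uint8)
        self._keys = keys
        self._n_mask = self._mat == _ENC[ord("N")]

    def count(self, protospacer: str, mm_max: int, exclude=()) -> int:
        """Hits within ``mm_max`` mismatches, excluding listed (contig, start, strand) sites."""
        if self._mat.shape[0] == 0:
            return 0
        q = _encode(protospacer)
        mism = ((self._mat != q) | self._n_mask).sum(axis=1)
        hit_rows = np.nonzero(mism <= mm_max)[0]
        if not len(hit_rows):
            return 0
        excluded = set(exclude)
        return sum(1 for r in hit_rows if self._keys[r] not in excluded)


def count_offtargets(g: GuideCandidate, background, mm_max: int, index: OfftargetIndex | None = None) -> int:
    """Exhaustive mismatch-count of ``g`` against background windows.

    The intended on-target occurrence — the recorded (source, start, strand)
    site of the guide — is excluded from the count.
    """
    idx = index if index is not None else OfftargetIndex(background)
    return idx.count(g.protospacer, mm_max, exclude=[(g.source_id, g.start, g.strand)])


def find_matches(g: GuideCandidate, seq: str) -> list:
    """Exact protospacer+NGG occurrences of ``g`` in ``seq``.

    Returns (start, strand, cut_index) triples in forward coordinates,
    sorted by position then strand.
    """
    hits = []
    proto = g.protospacer
    n = len(seq)
    # plus strand: protospacer then N G G
    i = seq.find(proto)
    while i != -1:
        if i + SITE_LEN <= n and seq[i + 21] == "G" and seq[i + 22] == "G":
            hits.append((i, "+", i + CUT_OFFSET))
        i = seq.find(proto, i + 1)
    # minus strand: forward-strand pattern C C N + revcomp(protospacer)
    rc = revcomp(proto)
    i = seq.find(rc)
    while i != -1:
        if i >= 3 and seq[i - 3] == "C" and seq[i - 2] == "C":
            hits.append((i - 3, "-", i + 3))
        i = seq.find(rc, i + 1)
    hits.sort()
    return hits


def matches_allele(g: GuideCandidate, allele) -> bool:
    """True iff the guide's protospacer+NGG occurs exactly in the allele (either strand)."""
    seq = allele.seq if isinstance(allele, Allele) else allele
    return bool(find_matches(g, seq))


@dataclass(frozen=True)
class FilterConfig:
    """Guide acceptance thresholds.

    min_on_target
        Minimum heuristic efficacy score.
    max_offtarget_hits / mm_max
        Off-target propensity gate: at most this many background sites
        within ``mm_max`` mismatches (intended site excluded).
    proximity_bp
        Maximum distance from a retargeting guide's cut to the prior edit,
        so the new HDR event overwrites it.
    """

    min_on_target: float = 0.5
    max_offtarget_hits: int = 0
    mm_max: int = 2
    proximity_bp: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_on_target <= 1.0):
            raise ValueError("min_on_target must be in [0, 1]")


def passes_filters(
    g: GuideCandidate,
    cfg: FilterConfig,
    wt: Allele | str,
    donor: DonorSpec | None,
    prior_edit_pos: int | None,
    level: int = 1,
) -> bool:
    """Acceptance test for a candidate guide.

    Requires efficacy and specificity thresholds; guides at retargeting
    levels (level >= 1, i.e. B and beyond) must not match the wildtype —
    otherwise they would re-cut unedited alleles — and no guide at any level
    may match the HDR allele, which the donor is meant to protect. The
    proximity clause keeps the cut within ``proximity_bp`` of the prior edit.
    """
    if g.on_target < cfg.min_on_target:
        return False
    if g.offtarget_hits > cfg.max_offtarget_hits:
        return False
    if level >= 1 and matches_allele(g, wt):
        return False
    if donor is not None and matches_allele(g, donor.hdr_allele):
        return False
    if prior_edit_pos is not None and abs(g.cut_index - prior_edit_pos) > cfg.proximity_bp:
        return False
    return True


def annotate(
    g: GuideCandidate, index: OfftargetIndex | None, mm_max: int, exclude_offset: int = 0
) -> GuideCandidate:
    """Return the guide with on_target and offtarget_hits filled in.

    ``exclude_offset`` shifts the guide's recorded start into the index's
    coordinate frame (window-local guides vs genomic background).
    """
    hits = (
        index.count(
            g.protospacer, mm_max, exclude=[(g.source_id, g.start + exclude_offset, g.strand)]
        )
        if index is not None
        else 0
    )
    return replace(g, on_target=score_on_target(g), offtarget_hits=hits)
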