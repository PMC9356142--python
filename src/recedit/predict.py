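"""Bundled indel-outcome predictor.

Predicts the distribution of repair products at a Cas9 blunt cut. The model
is deliberately simple, deterministic and hand-computable while keeping the
two qualitative features Recursive Editing exploits: microhomology-mediated
deletions whose weight grows with repeat length, and small duplications of
cut-adjacent sequence as the dominant insertion class.

Scoring, for a cut at index ``c`` on an allele sequence:

* every canonical deletion class (leftmost start ``s``, length ``d <= d_max``)
  whose span covers or abuts the cut (some member satisfies
  ``s <= c <= s + d``) gets weight ``(1 + m)^2 * exp(-d / lambda_del)`` where
  ``m`` is the junction microhomology length (capped at ``mh_max``);
* a +1 insertion duplicating the base at ``c - 1`` gets weight ``beta_ins1``;
* a +2 insertion duplicating the dinucleotide at ``[c - 2, c)`` gets weight
  ``beta_ins2``;
* weights are normalised to frequencies; outcomes below ``min_report_freq``
  are pooled into ``truncated_mass``.

External predictors (e.g. published machine-learned models) can be plugged in
through :func:`register_predictor`; whatever is registered must return an
:class:`OutcomeDistribution` satisfying the same invariants, which are
checked at the seam by :func:`validate_distribution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import IndelOutcome, apply_to_seq, canonicalize_deletion, microhomology_length

__all__ = [
    "PredictorParams",
    "OutcomeDistribution",
    "WindowError",
    "predict_outcomes",
    "rank_outcomes",
    "concentration",
    "register_predictor",
    "get_predictor",
    "validate_distribution",
]


class WindowError(ValueError):
    """Cut site too close to the window edge for prediction."""


@dataclass(frozen=True)
class PredictorParams:
    """Tunable weights of the bundled outcome model.

    lambda_del
        Deletion-length decay scale (nt). Larger values flatten the length
        spectrum.
    beta_ins1 / beta_ins2
        Raw weights of the +1 and +2 cut-adjacent duplications.
    d_max
        Longest deletion enumerated.
    mh_max
        Microhomology length cap used in scoring (the measured value may be
        larger; only the score saturates).
    min_report_freq
        Outcomes predicted below this frequency are pooled into
        ``truncated_mass`` rather than reported individually.
    """

    lambda_del: float = 10.0
    beta_ins1: float = 3.0
    beta_ins2: float = 0.3
    d_max: int = 30
    mh_max: int = 15
    min_report_freq: float = 0.01

    def __post_init__(self) -> None:
        if self.lambda_del <= 0 or self.beta_ins1 <= 0 or self.beta_ins2 < 0:
            raise ValueError("predictor weights must be positive (beta_ins2 >= 0)")
        if not (0 <= self.min_report_freq < 1):
            raise ValueError("min_report_freq must be in [0, 1)")


@dataclass(frozen=True)
class OutcomeDistribution:
    """Predicted repair outcomes at one cut, frequencies summing (with
    ``truncated_mass``) to 1. Outcomes are sorted by frequency descending,
    ties broken by shorter indel first then lexicographic child sequence;
    all deletions are canonical (leftmost-aligned)."""

    cut_index: int
    outcomes: tuple
    truncated_mass: float = 0.0


def _outcome_sort_key(seq: str):
    def key(pair):
        outcome, freq = pair
        return (-freq, outcome.length, apply_to_seq(seq, outcome))

    return key


def predict_outcomes(
    allele_seq: str, cut_index: int, params: PredictorParams | None = None
) -> OutcomeDistribution:
    """Outcome distribution of the bundled model at ``cut_index`` on ``allele_seq``."""
    params = params or PredictorParams()
    n = len(allele_seq)
    if not (5 <= cut_index <= n - 5):
        raise WindowError(
            f"cut index {cut_index} too close to the edge of a {n}-nt window"
        )

    scores: dict[tuple, float] = {}
    outcomes: dict[tuple, IndelOutcome] = {}

    # deletion classes: enumerate every (start, length) touching the cut,
    # canonicalise, and score each distinct class once
    for d in range(1, min(params.d_max, n) + 1):
        s_lo = max(0, cut_index - d)
        s_hi = min(cut_index, n - d)
        for s in range(s_lo, s_hi + 1):
            raw = IndelOutcome(kind="deletion", start=s, length=d)
            canon = canonicalize_deletion(allele_seq, raw)
            key = ("deletion", canon.start, d)
            if key in scores:
                continue
            m = min(microhomology_length(allele_seq, canon), params.mh_max)
            scores[key] = (1.0 + m) ** 2 * math.exp(-d / params.lambda_del)
            outcomes[key] = canon

    # insertion classes: duplications of cut-adjacent sequence
    ins1 = IndelOutcome(
        kind="insertion", start=cut_index, length=1,
        inserted_seq=allele_seq[cut_index - 1],
    )
    scores[("insertion", cut_index, 1)] = params.beta_ins1
    outcomes[("insertion", cut_index, 1)] = ins1
    if params.beta_ins2 > 0:
        ins2 = IndelOutcome(
            kind="insertion", start=cut_index, length=2,
            inserted_seq=allele_seq[cut_index - 2 : cut_index],
        )
        scores[("insertion", cut_index, 2)] = params.beta_ins2
        outcomes[("insertion", cut_index, 2)] = ins2

    total = sum(scores.values())
    pairs = [
        (outcomes[k], scores[k] / total)
        for k in scores
    ]
    pairs.sort(key=_outcome_sort_key(allele_seq))

    reported = []
    truncated = 0.0
    for outcome, freq in pairs:
        if freq < params.min_report_freq:
            truncated += freq
        else:
            reported.append(
                IndelOutcome(
                    kind=outcome.kind, start=outcome.start, length=outcome.length,
                    inserted_seq=outcome.inserted_seq, freq=freq, label=outcome.label,
                )
            )
    return OutcomeDistribution(
        cut_index=cut_index, outcomes=tuple(reported), truncated_mass=truncated
    )


def rank_outcomes(dist: OutcomeDistribution, top_k: int):
    """Top ``top_k`` outcomes by frequency (ties: shorter indel, then child sequence).

    Outcomes in a distribution are already stored in rank order, so this is a
    prefix; ``top_k`` larger than the outcome count returns everything.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    return list(dist.outcomes[:top_k])


def concentration(dist: OutcomeDistribution, n: int) -> float:
    """Sum of the top-``n`` outcome frequencies — how peaked the spectrum is.

    Sites where a couple of outcomes carry most of the indel mass are the
    entry points worth retargeting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sum(o.freq for o in dist.outcomes[:n]))


def validate_distribution(dist: OutcomeDistribution, allele_seq: str, tol: float = 1e-9) -> None:
    """Contract check applied at the predictor seam.

    Any predictor (bundled or external) must normalise to 1, sort by
    frequency, and report deletions in canonical form.
    """
    total = sum(o.freq for o in dist.outcomes) + dist.truncated_mass
    if abs(total - 1.0) > tol:
        raise ValueError(f"outcome frequencies + truncated_mass sum to {total}, not 1")
    freqs = [o.freq for o in dist.outcomes]
    if freqs != sorted(freqs, reverse=True):
        raise ValueError("outcomes not sorted by frequency descending")
    for o in dist.outcomes:
        if o.kind == "deletion" and canonicalize_deletion(allele_seq, o).start != o.start:
            raise ValueError(f"non-canonical deletion reported: {o}")


_PREDICTORS: dict[str, object] = {}


def register_predictor(name: str, fn) -> None:
    """Register an outcome predictor callable ``fn(seq, cut_index, params)``.

    Adapters for published predictors go through this seam; the bundled
    model is pre-registered as ``"bundled"``.
    """
    _PREDICTORS[name] = fn


def get_predictor(name: str):
    try:
        return _PREDICTORS[name]
    except KeyError:
        raise KeyError(
            f"unknown predictor {name!r}; registered: {sorted(_PREDICTORS)}"
        ) from None


register_predictor("bundled", predict_outcomes)
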