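"""Deterministic mass-flow simulation of multi-round Recursive Editing.

The allele population is a probability mass distribution over sequences,
plus two absorbing pools: HDR (the desired donor-templated repair product)
and a residual pool holding low-frequency indel outcomes the predictor
truncates. Each round, every allele matched by an active guide loses
``cut_efficiency`` of its mass; of that, ``hdr_fraction`` flows to the HDR
pool and the remainder is redistributed over the predicted indel outcomes
of the cut. The HDR pool and unmatched alleles are inert, so HDR mass never
decreases and total mass is conserved exactly.

Two delivery schedules are modelled: *sequential* (one cascade level active
per round, in order — the experimental regime where the next RNP is
delivered after the previous round has resolved) and *simultaneous* (all
levels active every round, until ``rounds_max`` or the targetable mass
drops below ``min_mass``). These are expectation dynamics, not stochastic
cell sampling: sufficient for ranking cascades, and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import apply_to_seq
from .predict import PredictorParams, predict_outcomes
from .search import Cascade
from .guides import find_matches

__all__ = ["SimConfig", "SimResult", "simulate", "hdr_indel_ratio"]


@dataclass(frozen=True)
class SimConfig:
    """Per-round editing parameters.

    cut_efficiency
        Fraction of a matched allele's mass cut per round per guide exposure.
    hdr_fraction
        Fraction of repair events resolved by HDR when the donor is present.
    schedule
        "sequential" or "simultaneous" guide delivery.
    rounds_max
        Hard cap on rounds (simultaneous mode may stop earlier once the
        targetable mass falls below ``min_mass``).
    """

    cut_efficiency: float = 0.9
    hdr_fraction: float = 0.25
    schedule: str = "sequential"
    rounds_max: int = 10
    min_mass: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.cut_efficiency <= 1.0 and 0.0 <= self.hdr_fraction <= 1.0):
            raise ValueError("cut_efficiency and hdr_fraction must be probabilities")
        if self.schedule not in ("sequential", "simultaneous"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.rounds_max < 1:
            raise ValueError("rounds_max must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Round-by-round mass trajectory.

    ``rounds`` is a list of dicts with keys ``hdr``, ``wt``, ``residual``
    and ``alleles`` (sequence -> mass, edited alleles only); entry 0 is the
    initial state. ``final_*`` summarise the last round.
    """

    rounds: tuple

    @property
    def final(self) -> dict:
        return self.rounds[-1]

    @property
    def final_hdr(self) -> float:
        return self.final["hdr"]

    @property
    def final_indel(self) -> float:
        return sum(self.final["alleles"].values()) + self.final["residual"]

    @property
    def final_wt(self) -> float:
        return self.final["wt"]

    def to_frame(self) -> pd.DataFrame:
        """Long-form (round, pool, mass) table."""
        rows = []
        for i, r in enumerate(self.rounds):
            rows.append({"round": i, "pool": "HDR", "mass": r["hdr"]})
            rows.append({"round": i, "pool": "WT", "mass": r["wt"]})
            rows.append({"round": i, "pool": "residual_indel", "mass": r["residual"]})
            for seq in sorted(r["alleles"]):
                rows.append({"round": i, "pool": f"allele:{seq}", "mass": r["alleles"][seq]})
        return pd.DataFrame(rows, columns=["round", "pool", "mass"])


def simulate(
    cascade: Cascade,
    cfg: SimConfig | None = None,
    predictor_params: PredictorParams | None = None,
) -> SimResult:
    """Run the expectation dynamics of a cascade on a unit wildtype population."""
    cfg = cfg or SimConfig()
    params = predictor_params or PredictorParams()
    if cascade.n_levels == 0:
        raise ValueError("cannot simulate an empty cascade")

    wt_seq = cascade.site.seq
    guides_by_level = [
        [sel.guide for sel in lvl.selections] for lvl in cascade.levels
    ]
    state: dict[str, float] = {wt_seq: 1.0}
    hdr = 0.0
    residual = 0.0
    outcome_cache: dict[tuple, object] = {}

    def snapshot():
        alleles = {s: m for s, m in state.items() if s != wt_seq and m > 0}
        return {
            "hdr": hdr,
            "wt": state.get(wt_seq, 0.0),
            "residual": residual,
            "alleles": alleles,
        }

    rounds = [snapshot()]

    if cfg.schedule == "sequential":
        schedule = [[lvl] for lvl in range(min(cascade.n_levels, cfg.rounds_max))]
    else:
        schedule = [list(range(cascade.n_levels))] * cfg.rounds_max

    for active_levels in schedule:
        active = [g for lvl in active_levels for g in guides_by_level[lvl]]
        cut_plan = []  # (seq, guide, cut_index)
        for seq in sorted(state):
            if state[seq] <= 0:
                continue
            for g in active:
                hits = find_matches(g, seq)
                if hits:
                    cut_plan.append((seq, g, hits[0][2]))
                    break
        if cfg.schedule == "simultaneous":
            targetable = sum(state[s] for s, _, _ in cut_plan)
            if targetable < cfg.min_mass:
                break
        if not cut_plan:
            rounds.append(snapshot())
            continue
        deltas: dict[str, float] = {}
        for seq, g, cut in cut_plan:
            removed = cfg.cut_efficiency * state[seq]
            deltas[seq] = deltas.get(seq, 0.0) - removed
            hdr += cfg.hdr_fraction * removed
            rem = (1.0 - cfg.hdr_fraction) * removed
            if rem <= 0:
                continue
            key = (seq, cut)
            if key not in outcome_cache:
                outcome_cache[key] = predict_outcomes(seq, cut, params)
            dist = outcome_cache[key]
            for outcome in dist.outcomes:
                child = apply_to_seq(seq, outcome)
                deltas[child] = deltas.get(child, 0.0) + rem * outcome.freq
            residual += rem * dist.truncated_mass
        for seq, dm in deltas.items():
            state[seq] = state.get(seq, 0.0) + dm
        rounds.append(snapshot())

    return SimResult(rounds=tuple(rounds))


def hdr_indel_ratio(result: SimResult) -> float:
    """HDR mass divided by total indel mass at the final round.

    Zero indel mass with positive HDR reports +inf; zero HDR reports 0.
    """
    indel = result.final_indel
    hdr = result.final_hdr
    if indel <= 0:
        return float("inf") if hdr > 0 else 0.0
    return hdr / indel
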