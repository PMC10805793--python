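"""Simulated observers for the two-letter-string dual-task paradigm.

Each trial flashes two letter strings, one above and one below fixation,
each independently drawn from a binary category (signal present or
absent with probability 0.5).  On single-task trials one side is precued
and judged; on dual-task trials both sides are judged with a 4-level
confidence response per side.  Three processing regimes are simulated:

``serial``
    All-or-none: on a dual-task trial exactly one side is processed (the
    top with probability ``p_top``); the other side's rating is a guess.
``fixed_capacity``
    Parallel with a shared resource: both sides are processed but each
    side's sensitivity is scaled by the square root of its attention
    share (the sample-size model), ``w_bottom = 1 - w_top``.
``independent``
    Unlimited capacity: both sides processed at full sensitivity.

Evidence for a processed stimulus is equal-variance Gaussian,
Normal(+d'/2, 1) for signal-present and Normal(-d'/2, 1) otherwise,
mapped to ratings 1-4 by three strictly increasing criteria.  Single-task
trials always process the cued side at full d'.

Guessing.  When ``guess_dist`` is None (the default) the unprocessed
side's rating is drawn from that side's *marginal processed rating
distribution* G = (S + N) / 2, where S and N are the rating distributions
for processed present/absent stimuli.  This choice makes the dual-task
A_g of the serial observer exactly linear in ``p_top``: writing A for the
single-task concordance, C(S, G) + C(G, N) = A + 1/2 when G = (S + N)/2,
so the dual-task point falls exactly on the straight serial segment of
the attention operating characteristic.  It is also behaviourally
natural: the guessing hand reuses the observer's overall key-press
habits.  Any explicit 4-vector over ratings is accepted instead.

Selection errors model confusing the two sides: with probability
``selection_error_rate`` a dual-task trial's two reports are swapped,
and a single-task trial's report is generated from the *uncued* side's
stimulus.  Fixation breaks are an exclusion flag only (Bernoulli), with
no effect on behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "REGIMES",
    "ObserverParams",
    "ExperimentDesign",
    "dprime_for_pc",
    "pc_for_dprime",
    "rating_distribution",
    "matched_guess_dist",
    "simulate_observer",
    "simulate_experiment",
]

REGIMES = ("serial", "fixed_capacity", "independent")

# Study conditions: single-task accuracy titrated to 80% correct, a 74%
# bias to process the top string first, 16% of trials lost to fixation
# breaks, mean ISI 84 ms.
DEFAULT_PC = 0.80


def dprime_for_pc(pc: float) -> float:
    """Sensitivity giving proportion correct ``pc`` for an unbiased
    binary judgement: pc = Phi(d'/2)."""
    if not 0.5 < pc < 1.0:
        raise ValueError(f"proportion correct must be in (0.5, 1), got {pc}")
    return float(2.0 * norm.ppf(pc))


def pc_for_dprime(dprime: float) -> float:
    return float(norm.cdf(dprime / 2.0))


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of a simulated observer."""

    regime: str = "serial"
    dprime_top: float = dprime_for_pc(DEFAULT_PC)
    dprime_bottom: float = dprime_for_pc(DEFAULT_PC)
    p_top: float = 0.74
    w_top: float = 0.5
    criteria: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    guess_dist: tuple[float, float, float, float] | None = None
    selection_error_rate: float = 0.0
    fixation_break_rate: float = 0.16

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        crit = np.asarray(self.criteria, dtype=float)
        if crit.shape != (3,) or not np.all(np.diff(crit) > 0):
            raise ValueError("criteria must be 3 strictly increasing thresholds")
        for name in ("p_top", "w_top", "selection_error_rate", "fixation_break_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.guess_dist is not None:
            g = np.asarray(self.guess_dist, dtype=float)
            if g.shape != (4,) or np.any(g < 0) or abs(g.sum() - 1.0) > 1e-9:
                raise ValueError("guess_dist must be 4 nonnegative weights summing to 1")

    def guess_dist_for(self, side: str) -> np.ndarray:
        """Rating distribution used for an unprocessed stimulus on ``side``."""
        if self.guess_dist is not None:
            return np.asarray(self.guess_dist, dtype=float)
        d = self.dprime_top if side == "top" else self.dprime_bottom
        return matched_guess_dist(d, self.criteria)


def rating_distribution(
    dprime: float, criteria: Sequence[float], present: bool
) -> np.ndarray:
    """P(rating = 1..4) for a processed stimulus."""
    mu = dprime / 2.0 if present else -dprime / 2.0
    cdf = norm.cdf(np.asarray(criteria, dtype=float), loc=mu)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


def matched_guess_dist(dprime: float, criteria: Sequence[float]) -> np.ndarray:
    """Marginal processed rating distribution G = (S + N) / 2."""
    s = rating_distribution(dprime, criteria, present=True)
    n = rating_distribution(dprime, criteria, present=False)
    return 0.5 * (s + n)


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure of one subject's session set.

    The default is 60 blocks of 20 trials run in sets of four (one
    single-task top, one single-task bottom, two dual-task, in random
    order within each set): 1,200 trials of which 600 are dual task.
    """

    n_blocks: int = 60
    trials_per_block: int = 20
    isi_ms: float = 84.0
    block_types: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("design must contain at least one block and trial")

    @classmethod
    def dual_only(cls, n_trials: int, trials_per_block: int = 20) -> "ExperimentDesign":
        n_blocks = max(1, int(np.ceil(n_trials / trials_per_block)))
        return cls(
            n_blocks=n_blocks,
            trials_per_block=trials_per_block,
            block_types=("dual",) * n_blocks,
        )

    def block_sequence(self, rng: np.random.Generator) -> list[str]:
        if self.block_types is not None:
            if len(self.block_types) != self.n_blocks:
                raise ValueError("block_types length must equal n_blocks")
            return list(self.block_types)
        base = ["single_top", "single_bottom", "dual", "dual"]
        seq: list[str] = []
        while len(seq) < self.n_blocks:
            seq.extend(rng.permutation(base).tolist())
        return seq[: self.n_blocks]


def _ratings_from_evidence(
    rng: np.random.Generator,
    present: np.ndarray,
    dprime_eff: np.ndarray,
    criteria: np.ndarray,
) -> np.ndarray:
    mu = np.where(present, dprime_eff / 2.0, -dprime_eff / 2.0)
    evidence = rng.normal(loc=mu, scale=1.0)
    return np.searchsorted(criteria, evidence) + 1


def simulate_observer(
    params: ObserverParams,
    design: ExperimentDesign | None = None,
    seed: int | np.random.Generator = 0,
    subject: str = "S01",
) -> pd.DataFrame:
    """Simulate one subject's trials; returns the trial table.

    Columns follow the trial-CSV contract of :mod:`dualcap.pipeline`.
    Seeded runs are bit-reproducible.
    """
    design = design or ExperimentDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    crit = np.asarray(params.criteria, dtype=float)

    blocks = design.block_sequence(rng)
    tpb = design.trials_per_block
    cue = np.repeat(blocks, tpb)
    block_idx = np.repeat(np.arange(1, len(blocks) + 1), tpb)
    n = cue.size
    trial_idx = np.tile(np.arange(1, tpb + 1), len(blocks))

    cat_top = rng.random(n) < 0.5
    cat_bottom = rng.random(n) < 0.5

    is_dual = cue == "dual"
    is_single_top = cue == "single_top"
    is_single_bottom = cue == "single_bottom"

    # Which side(s) get processed, and at what effective sensitivity.
    proc_top = np.zeros(n, dtype=bool)
    proc_bottom = np.zeros(n, dtype=bool)
    d_top = np.full(n, params.dprime_top)
    d_bottom = np.full(n, params.dprime_bottom)

    proc_top[is_single_top] = True
    proc_bottom[is_single_bottom] = True
    if params.regime == "serial":
        serial_top = rng.random(n) < params.p_top
        proc_top[is_dual] = serial_top[is_dual]
        proc_bottom[is_dual] = ~serial_top[is_dual]
    elif params.regime == "fixed_capacity":
        proc_top[is_dual] = True
        proc_bottom[is_dual] = True
        d_top = np.where(is_dual, d_top * np.sqrt(params.w_top), d_top)
        d_bottom = np.where(is_dual, d_bottom * np.sqrt(1.0 - params.w_top), d_bottom)
    else:  # independent
        proc_top[is_dual] = True
        proc_bottom[is_dual] = True

    # Selection errors: on single-task trials the observer attends the
    # wrong side, so the cued report is driven by the uncued stimulus.
    sel_err = rng.random(n) < params.selection_error_rate
    src_top_cat = np.where(is_single_top & sel_err, cat_bottom, cat_top)
    src_bottom_cat = np.where(is_single_bottom & sel_err, cat_top, cat_bottom)

    rat_top = _ratings_from_evidence(rng, src_top_cat, d_top, crit)
    rat_bottom = _ratings_from_evidence(rng, src_bottom_cat, d_bottom, crit)

    guess_top = rng.choice(4, size=n, p=params.guess_dist_for("top")) + 1
    guess_bottom = rng.choice(4, size=n, p=params.guess_dist_for("bottom")) + 1
    rat_top = np.where(proc_top, rat_top, guess_top)
    rat_bottom = np.where(proc_bottom, rat_bottom, guess_bottom)

    # Dual-task selection errors: the two reports are swapped wholesale.
    swap = is_dual & sel_err
    rat_top, rat_bottom = (
        np.where(swap, rat_bottom, rat_top),
        np.where(swap, rat_top, rat_bottom),
    )

    resp_top = np.where(is_single_bottom, np.nan, rat_top.astype(float))
    resp_bottom = np.where(is_single_top, np.nan, rat_bottom.astype(float))

    first_side = np.where(rng.random(n) < 0.5, "top", "bottom")
    first_response_side = pd.Series(first_side, dtype="object").where(is_dual, np.nan)

    fixation_break = rng.random(n) < params.fixation_break_rate

    return pd.DataFrame(
        {
            "subject": subject,
            "block": block_idx,
            "trial": trial_idx,
            "cue": cue,
            "cat_top": np.where(cat_top, "present", "absent"),
            "cat_bottom": np.where(cat_bottom, "present", "absent"),
            "resp_top": resp_top,
            "resp_bottom": resp_bottom,
            "first_response_side": first_response_side,
            "isi_ms": design.isi_ms,
            "fixation_break": fixation_break,
        }
    )


def simulate_experiment(
    params: ObserverParams | Sequence[ObserverParams],
    n_subjects: int = 11,
    design: ExperimentDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full multi-subject experiment.

    ``params`` may be shared across subjects or given per subject.  Each
    subject gets an independent child RNG stream from ``seed``.
    """
    if isinstance(params, ObserverParams):
        params_list = [params] * n_subjects
    else:
        params_list = list(params)
        if len(params_list) != n_subjects:
            raise ValueError("one ObserverParams per subject required")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    frames = [
        simulate_observer(
            p,
            design=design,
            seed=np.random.default_rng(s),
            subject=f"S{i + 1:02d}",
        )
        for i, (p, s) in enumerate(zip(params_list, streams))
    ]
    return pd.concat(frames, ignore_index=True)
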