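"""Stimulus-processing trade-offs on dual-task trials.

The all-or-none serial model predicts a negative interdependence between
the two responses of a dual-task trial: a response is more likely to be
correct when the *other* side's response was incorrect (because the other
side was then the unprocessed, guessed one).  Parallel models predict no
such dependence.

All dual-task responses (both sides, both response orders) are pooled
within subject and partitioned by whether the same trial's other-side
response was correct — binary correctness being (rating >= 3) iff
signal-present.  A_g is then computed within each partition; the
trade-off statistic is A_g(other incorrect) - A_g(other correct).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sdt
from .observer import ExperimentDesign, ObserverParams, dprime_for_pc, simulate_observer

__all__ = ["TradeoffResult", "tradeoff_analysis", "serial_tradeoff_curve"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TradeoffResult:
    """Per-subject trade-off: A_g conditioned on the other response."""

    subject: str
    ag_other_incorrect: float
    ag_other_correct: float
    difference: float
    pc_other_incorrect: float
    pc_other_correct: float
    n_other_incorrect: int
    n_other_correct: int
    flagged: bool


def response_correct(resp: pd.Series, cat: pd.Series) -> pd.Series:
    """Binary correctness: rating >= 3 iff the stimulus was signal-present."""
    return (resp >= 3) == (cat == "present")


def _long_dual_responses(dual: pd.DataFrame) -> pd.DataFrame:
    """One row per scored dual-task response, with the other side's correctness."""
    parts = []
    for side, other in (("top", "bottom"), ("bottom", "top")):
        mask = dual[f"resp_{side}"].notna() & dual[f"resp_{other}"].notna()
        sub = dual[mask]
        parts.append(
            pd.DataFrame(
                {
                    "subject": sub["subject"],
                    "rating": sub[f"resp_{side}"].astype(int),
                    "category": sub[f"cat_{side}"],
                    "other_correct": response_correct(
                        sub[f"resp_{other}"], sub[f"cat_{other}"]
                    ),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _partition_stats(part: pd.DataFrame) -> tuple[float, float, int]:
    counts = sdt.RatingCounts(
        tuple(
            np.bincount(
                part.loc[part["category"] == "present", "rating"] - 1, minlength=4
            ).tolist()
        ),
        tuple(
            np.bincount(
                part.loc[part["category"] == "absent", "rating"] - 1, minlength=4
            ).tolist()
        ),
    )
    pc = float(
        (response_correct(part["rating"], part["category"])).mean()
    )
    return sdt.ag(counts), pc, len(part)


def tradeoff_analysis(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject trade-off table from dual-task trials.

    Input may contain all cue conditions; only dual-task trials with both
    responses are used.  A subject whose partition is degenerate (one set
    empty, or a set missing a stimulus class) is flagged and should be
    excluded from group tests.
    """
    dual = trials[trials["cue"] == "dual"]
    long = _long_dual_responses(dual)
    rows = []
    for subject, sub in long.groupby("subject", sort=True):
        incorrect_set = sub[~sub["other_correct"]]
        correct_set = sub[sub["other_correct"]]
        try:
            ag_inc, pc_inc, n_inc = _partition_stats(incorrect_set)
            ag_cor, pc_cor, n_cor = _partition_stats(correct_set)
            flagged = False
        except ValueError as exc:
            logger.warning("subject %s flagged in trade-off analysis: %s", subject, exc)
            ag_inc = ag_cor = pc_inc = pc_cor = np.nan
            n_inc, n_cor = len(incorrect_set), len(correct_set)
            flagged = True
        rows.append(
            TradeoffResult(
                subject=str(subject),
                ag_other_incorrect=ag_inc,
                ag_other_correct=ag_cor,
                difference=ag_inc - ag_cor,
                pc_other_incorrect=pc_inc,
                pc_other_correct=pc_cor,
                n_other_incorrect=n_inc,
                n_other_correct=n_cor,
                flagged=flagged,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def serial_tradeoff_curve(
    single_accuracy_grid,
    p_top: float = 0.5,
    n_sim: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted trade-off of the serial model across difficulty levels.

    For each single-task proportion correct in the grid, a serial
    observer with matching sensitivity (d' = 2 Phi^-1(pc)) is simulated
    on ``n_sim`` dual-task trials and run through
    :func:`tradeoff_analysis`.  The trade-off grows with single-task
    accuracy: the farther above chance a processed stimulus is judged,
    the larger the gap to the unprocessed (guessed) one.
    """
    grid = np.atleast_1d(np.asarray(single_accuracy_grid, dtype=float))
    if np.any(grid <= 0.5) or np.any(grid >= 1.0):
        raise ValueError("single-task accuracy grid must lie in (0.5, 1)")
    streams = np.random.SeedSequence(seed).spawn(grid.size)
    design = ExperimentDesign.dual_only(n_sim)
    rows = []
    for pc, stream in zip(grid, streams):
        d = dprime_for_pc(pc)
        params = ObserverParams(
            regime="serial",
            dprime_top=d,
            dprime_bottom=d,
            p_top=p_top,
            fixation_break_rate=0.0,
        )
        trials = simulate_observer(
            params, design=design, seed=np.random.default_rng(stream)
        )
        res = tradeoff_analysis(trials).iloc[0]
        rows.append(
            {
                "single_pc": float(pc),
                "ag_other_incorrect": res["ag_other_incorrect"],
                "ag_other_correct": res["ag_other_correct"],
                "difference": res["difference"],
            }
        )
    return pd.DataFrame(rows)
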