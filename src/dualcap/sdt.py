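"""Rating-ROC accuracy (A_g) from 4-level confidence responses.

A_g is the area under the empirical ROC traced by the three rating
criteria, with the corners (0, 0) and (1, 1) appended and the area taken
by the trapezoidal rule.  It equals the concordance probability

    P(rating_present > rating_absent) + 0.5 * P(tie),

is bias-corrected, and runs from 0.5 (chance) to 1.0 (perfect).  Values
below 0.5 are returned as computed, never clipped: clipping would bias
group means near chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["RatingCounts", "rating_counts", "ag"]

N_RATINGS = 4


@dataclass(frozen=True)
class RatingCounts:
    """2 x 4 table of rating counts for signal-present vs signal-absent trials.

    ``present_counts[k]`` is the number of signal-present trials answered
    with rating ``k + 1`` (1 = sure absent ... 4 = sure present); likewise
    for ``absent_counts``.
    """

    present_counts: tuple[int, int, int, int]
    absent_counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name in ("present_counts", "absent_counts"):
            counts = tuple(int(c) for c in getattr(self, name))
            if len(counts) != N_RATINGS:
                raise ValueError(f"{name} must have {N_RATINGS} entries")
            if any(c < 0 for c in counts):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, counts)

    @property
    def n_present(self) -> int:
        return sum(self.present_counts)

    @property
    def n_absent(self) -> int:
        return sum(self.absent_counts)


def rating_counts(
    trials: pd.DataFrame,
    side: str,
    condition_filter: Callable[[pd.DataFrame], pd.Series] | str | None = None,
) -> RatingCounts:
    """Tabulate one side's ratings by that side's true category.

    Parameters
    ----------
    trials
        Trial table (see :mod:`dualcap.pipeline` for the column contract).
        Fixation-break trials are expected to be excluded upstream.
    side
        ``"top"`` or ``"bottom"``: which response/category pair to score.
    condition_filter
        Either a cue label (``"single_top"``, ``"single_bottom"``,
        ``"dual"``), or a callable mapping the trial table to a boolean
        mask, or None for all trials.

    Trials with a missing response on the chosen side are skipped.
    Raises ``ValueError`` if no scorable trials remain.
    """
    if side not in ("top", "bottom"):
        raise ValueError(f"side must be 'top' or 'bottom', got {side!r}")
    sub = trials
    if condition_filter is not None:
        if callable(condition_filter):
            sub = trials[condition_filter(trials)]
        else:
            sub = trials[trials["cue"] == condition_filter]
    resp = sub[f"resp_{side}"]
    cat = sub[f"cat_{side}"]
    scored = resp.notna()
    if not scored.any():
        raise ValueError(
            f"no scorable responses on side {side!r} after filtering "
            f"({len(sub)} trials in subset)"
        )
    resp = resp[scored].to_numpy(dtype=float).astype(int)
    present = (cat[scored] == "present").to_numpy()
    pc = np.bincount(resp[present] - 1, minlength=N_RATINGS)
    ac = np.bincount(resp[~present] - 1, minlength=N_RATINGS)
    return RatingCounts(tuple(pc.tolist()), tuple(ac.tolist()))


def ag(counts: RatingCounts | Sequence[Sequence[int]]) -> float:
    """Area under the empirical rating ROC (trapezoidal rule).

    Accepts a :class:`RatingCounts` or any (present_counts, absent_counts)
    pair.  Both classes must have at least one trial.
    """
    if not isinstance(counts, RatingCounts):
        counts = RatingCounts(tuple(counts[0]), tuple(counts[1]))
    n_p, n_a = counts.n_present, counts.n_absent
    if n_p == 0 or n_a == 0:
        raise ValueError(
            f"A_g undefined: {n_p} signal-present and {n_a} signal-absent trials"
        )
    p = np.asarray(counts.present_counts, dtype=float) / n_p
    a = np.asarray(counts.absent_counts, dtype=float) / n_a
    # Cumulative hit / false-alarm rates for criteria "rating >= k", k = 4..2,
    # swept from strict to lax, then the (0,0) and (1,1) corners.
    hits = np.concatenate([[0.0], np.cumsum(p[::-1])])
    fas = np.concatenate([[0.0], np.cumsum(a[::-1])])
    return float(np.trapezoid(hits, fas))
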