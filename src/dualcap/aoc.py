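"""Attention operating characteristics and capacity-model predictions.

An AOC places dual-task accuracy for the two stimuli as a point in the
plane (x = bottom-side accuracy, y = top-side accuracy), with the
single-task accuracies pinned to the axes.  Three models predict where
that point can lie:

* **all-or-none serial** — only one stimulus is processed per trial
  (the top with probability p); the locus is the straight segment

      ( (1-p)*acc_b + p*0.5 ,  p*acc_t + (1-p)*0.5 ),  p in [0, 1]

* **fixed-capacity parallel** (sample-size model) — both stimuli share
  a fixed resource; converting accuracy to sensitivity via
  z = Phi^-1(acc), the locus is

      ( Phi(sqrt(1-w) * z_b) ,  Phi(sqrt(w) * z_t) ),  w in [0, 1]

* **independent parallel** (unlimited capacity) — the single point
  (acc_b, acc_t): no cost of dividing attention.

The serial and fixed-capacity loci share both endpoints,
(acc_b, 0.5) and (0.5, acc_t), and the fixed-capacity curve lies weakly
outside the serial segment whenever both single-task accuracies exceed
chance.

For each subject we take the minimum Euclidean distance from the
dual-task point to each locus, signed positive when the point lies on
the far side of the locus from chance (0.5, 0.5) — i.e., the subject
outperforms the model — and negative when it falls short.  The serial
locus parameter at the nearest point estimates the top-side processing
bias p_top.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from . import sdt

__all__ = [
    "AOCPoint",
    "ModelCurve",
    "DistanceResult",
    "serial_prediction",
    "fixed_capacity_prediction",
    "independent_prediction",
    "signed_distance",
    "aoc_summary",
]

logger = logging.getLogger(__name__)

CHANCE = np.array([0.5, 0.5])
MODELS = ("serial", "fixed_capacity", "independent")


@dataclass(frozen=True)
class AOCPoint:
    """A point in (bottom accuracy, top accuracy) space."""

    acc_bottom: float
    acc_top: float

    def as_array(self) -> np.ndarray:
        return np.array([self.acc_bottom, self.acc_top], dtype=float)


@dataclass(frozen=True)
class ModelCurve:
    """A capacity model's predicted locus, parametrized on [0, 1].

    ``point_at`` maps the locus parameter (p for serial, w for
    fixed-capacity; ignored by the independent point) to (x, y)
    coordinates; it accepts scalars or arrays.
    """

    model: str
    anchor: AOCPoint
    point_at: Callable[[np.ndarray], np.ndarray]

    def locus(self, n: int = 101) -> np.ndarray:
        """Sample the locus at ``n`` evenly spaced parameter values;
        returns an (n, 2) array."""
        return self.point_at(np.linspace(0.0, 1.0, n))


def _check_accuracies(acc_top: float, acc_bottom: float) -> None:
    for name, a in (("acc_top", acc_top), ("acc_bottom", acc_bottom)):
        if not np.isfinite(a) or not 0.0 <= a <= 1.0:
            raise ValueError(f"{name} must be a finite accuracy in [0, 1], got {a}")
        if a < 0.5:
            warnings.warn(
                f"{name} = {a:.3f} is below chance; model predictions are "
                "constructed as-is",
                stacklevel=3,
            )


def serial_prediction(acc_top_single: float, acc_bottom_single: float) -> ModelCurve:
    """Straight AOC segment of the all-or-none serial model."""
    _check_accuracies(acc_top_single, acc_bottom_single)
    ab, at = float(acc_bottom_single), float(acc_top_single)

    def point_at(p):
        p = np.asarray(p, dtype=float)
        return np.stack(
            [(1.0 - p) * ab + p * 0.5, p * at + (1.0 - p) * 0.5], axis=-1
        )

    return ModelCurve("serial", AOCPoint(ab, at), point_at)


def fixed_capacity_prediction(
    acc_top_single: float, acc_bottom_single: float
) -> ModelCurve:
    """Sample-size (fixed-capacity parallel) AOC curve."""
    _check_accuracies(acc_top_single, acc_bottom_single)
    ab, at = float(acc_bottom_single), float(acc_top_single)
    clamped = []
    for name, a in (("acc_bottom", ab), ("acc_top", at)):
        if a >= 1.0:
            clamped.append(name)
    if clamped:
        warnings.warn(
            f"accuracy of 1.0 implies infinite sensitivity; clamping "
            f"{', '.join(clamped)} to 1 - 1e-6",
            stacklevel=2,
        )
    zb = norm.ppf(min(ab, 1.0 - 1e-6))
    zt = norm.ppf(min(at, 1.0 - 1e-6))

    def point_at(w):
        w = np.asarray(w, dtype=float)
        return np.stack(
            [norm.cdf(np.sqrt(1.0 - w) * zb), norm.cdf(np.sqrt(w) * zt)], axis=-1
        )

    return ModelCurve("fixed_capacity", AOCPoint(ab, at), point_at)


def independent_prediction(
    acc_top_single: float, acc_bottom_single: float
) -> ModelCurve:
    """Unlimited-capacity point: dual equals single for both sides."""
    _check_accuracies(acc_top_single, acc_bottom_single)
    ab, at = float(acc_bottom_single), float(acc_top_single)

    def point_at(p):
        p = np.asarray(p, dtype=float)
        return np.broadcast_to(
            np.array([ab, at]), p.shape + (2,)
        ).copy()

    return ModelCurve("independent", AOCPoint(ab, at), point_at)


@dataclass(frozen=True)
class DistanceResult:
    """Minimum distance from a dual-task point to a model locus."""

    model: str
    signed_distance: float
    nearest_point: AOCPoint
    param_hat: float
    p_top_hat: float | None = None


def _sign(point: np.ndarray, nearest: np.ndarray) -> float:
    """+1 if the point lies beyond the locus (away from chance), -1 inside."""
    v = nearest - CHANCE
    d = point - nearest
    if np.linalg.norm(d) < 1e-15:
        return 0.0
    if np.linalg.norm(v) < 1e-12:
        # Degenerate locus at chance: outward is any direction away from it.
        return 1.0
    s = float(np.dot(d, v))
    if s == 0.0:
        # Tangential displacement; compare radial magnitudes instead.
        s = float(np.linalg.norm(point - CHANCE) - np.linalg.norm(nearest - CHANCE))
    return 1.0 if s > 0 else -1.0


def signed_distance(dual_point: AOCPoint, curve: ModelCurve) -> DistanceResult:
    """Signed minimum Euclidean distance from ``dual_point`` to ``curve``.

    The serial segment is handled in closed form (orthogonal projection,
    clamped); smooth loci use a 1001-point parameter grid refined by
    bounded scalar minimization (tolerance 1e-9).  For the serial model,
    ``p_top_hat`` is the locus parameter of the nearest point.
    """
    p = dual_point.as_array()
    if curve.model == "serial":
        a = curve.point_at(0.0)
        b = curve.point_at(1.0)
        ab = b - a
        denom = float(np.dot(ab, ab))
        if denom < 1e-18:  # degenerate chance anchors
            t = 0.0
        else:
            t = float(np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0))
        nearest = a + t * ab
        param = t
    elif curve.model == "independent":
        nearest = curve.point_at(0.0)
        param = 0.0
    else:
        grid = np.linspace(0.0, 1.0, 1001)
        pts = curve.point_at(grid)
        d2 = np.sum((pts - p) ** 2, axis=1)
        i = int(np.argmin(d2))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]

        def objective(t):
            return float(np.sum((curve.point_at(t) - p) ** 2))

        if hi > lo:
            res = minimize_scalar(
                objective, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-9},
            )
            param = float(np.clip(res.x, 0.0, 1.0))
            if objective(param) > d2[i]:
                param = float(grid[i])
        else:
            param = float(grid[i])
        nearest = curve.point_at(param)

    dist = float(np.linalg.norm(p - nearest))
    signed = dist * _sign(p, nearest)
    return DistanceResult(
        model=curve.model,
        signed_distance=signed,
        nearest_point=AOCPoint(float(nearest[0]), float(nearest[1])),
        param_hat=param,
        p_top_hat=param if curve.model == "serial" else None,
    )


def subject_aoc(
    trials: pd.DataFrame, first_response_only: bool = False
) -> dict[str, float]:
    """Single- and dual-task A_g for one subject, with model distances.

    Raises ``ValueError`` when a condition is missing or degenerate
    (a rating table with an empty stimulus class).
    """
    sub = trials
    if first_response_only:
        sub = sub.copy()
        dual = sub["cue"] == "dual"
        first_top = sub["first_response_side"] == "top"
        sub.loc[dual & first_top, "resp_bottom"] = np.nan
        sub.loc[dual & ~first_top, "resp_top"] = np.nan

    ag_single_top = sdt.ag(sdt.rating_counts(sub, "top", "single_top"))
    ag_single_bottom = sdt.ag(sdt.rating_counts(sub, "bottom", "single_bottom"))
    ag_dual_top = sdt.ag(sdt.rating_counts(sub, "top", "dual"))
    ag_dual_bottom = sdt.ag(sdt.rating_counts(sub, "bottom", "dual"))

    dual_point = AOCPoint(ag_dual_bottom, ag_dual_top)
    row: dict[str, float] = {
        "ag_single_top": ag_single_top,
        "ag_single_bottom": ag_single_bottom,
        "ag_dual_top": ag_dual_top,
        "ag_dual_bottom": ag_dual_bottom,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-chance estimates are expected noise
        curves = {
            "serial": serial_prediction(ag_single_top, ag_single_bottom),
            "fixed_capacity": fixed_capacity_prediction(ag_single_top, ag_single_bottom),
            "independent": independent_prediction(ag_single_top, ag_single_bottom),
        }
    for name, curve in curves.items():
        res = signed_distance(dual_point, curve)
        row[f"dist_{name}"] = res.signed_distance
        if name == "serial":
            row["p_top_hat"] = res.p_top_hat
    return row


def aoc_summary(
    trials: pd.DataFrame, first_response_only: bool = False
) -> pd.DataFrame:
    """Per-subject AOC table: single/dual A_g, signed model distances,
    and the serial top-bias estimate.

    Subjects missing a condition (or with a degenerate rating table) are
    excluded with a logged warning.  Fixation-break trials should be
    excluded upstream.
    """
    rows = []
    for subject, sub in trials.groupby("subject", sort=True):
        try:
            row = subject_aoc(sub, first_response_only=first_response_only)
        except ValueError as exc:
            logger.warning("subject %s excluded from AOC summary: %s", subject, exc)
            continue
        rows.append({"subject": subject, **row})
    return pd.DataFrame(rows)
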