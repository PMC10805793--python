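"""Inferential machinery: bootstrap CIs, t tests, JZS Bayes factors, and
a repeated-measures interaction test.

The Bayes factor is the default JZS (Jeffreys–Zellner–Siow) Bayes factor
for one-sample / paired t tests (Rouder, Speckman, Sun, Morey &
Iverson, 2009): the standardized effect size is given a Cauchy(0, r)
prior under the alternative, and

    BF10 = [ integral over g of
             (1 + N g r^2)^(-1/2)
             * (1 + t^2 / ((1 + N g r^2) nu))^(-(nu+1)/2)
             * (2 pi)^(-1/2) g^(-3/2) exp(-1/(2g)) dg ]
           / (1 + t^2/nu)^(-(nu+1)/2)

with nu = N - 1, using the inverse-chi^2 mixture representation of the
Cauchy prior.  The default prior scale r = sqrt(2)/2 matches the common
toolbox default for "medium" effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "StatResult",
    "bootstrap_ci",
    "one_sample_t",
    "jzs_bf",
    "describe_effect",
    "rm_interaction_test",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class StatResult:
    """A one-sample / paired inference bundle."""

    mean_diff: float
    sem: float
    t: float
    df: int
    p: float
    ci_low: float | None = None
    ci_high: float | None = None
    bf: float | None = None

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v)) for k, v in self.__dict__.items()}


def bootstrap_ci(
    values, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean from resampled means."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap_ci requires at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def one_sample_t(values, mu0: float = 0.0) -> StatResult:
    """Two-sided one-sample t test (also serves paired designs via
    difference scores)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one_sample_t requires at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("one_sample_t undefined for zero-variance data")
    res = sps.ttest_1samp(x, popmean=mu0)
    return StatResult(
        mean_diff=float(x.mean() - mu0),
        sem=float(sd / np.sqrt(x.size)),
        t=float(res.statistic),
        df=int(x.size - 1),
        p=float(res.pvalue),
    )


def jzs_bf(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS Bayes factor (alternative over null) for a one-sample t.

    Computed by adaptive quadrature of the Rouder et al. (2009) integral
    over the Cauchy(0, r) effect-size prior; relative tolerance 1e-10.
    """
    if n < 2:
        raise ValueError("jzs_bf requires n >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    nu = n - 1
    r2 = r * r

    def integrand(g: float) -> float:
        scale = 1.0 + n * g * r2
        return (
            scale ** -0.5
            * (1.0 + t * t / (scale * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, err = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-10, limit=200)
    if num <= 0 or not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise ValueError(f"JZS integral did not converge (value {num}, error {err})")
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return float(num / den)


def describe_effect(
    values,
    mu0: float = 0.0,
    n_boot: int = 1000,
    seed: int = 0,
    with_bf: bool = True,
) -> StatResult:
    """Full inference bundle: t test + bootstrap CI + JZS Bayes factor."""
    base = one_sample_t(values, mu0=mu0)
    lo, hi = bootstrap_ci(values, n_boot=n_boot, seed=seed)
    bf = jzs_bf(base.t, len(np.asarray(values)))if with_bf else None
    return StatResult(
        mean_diff=base.mean_diff,
        sem=base.sem,
        t=base.t,
        df=base.df,
        p=base.p,
        ci_low=lo,
        ci_high=hi,
        bf=bf,
    )


def rm_interaction_test(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factors: tuple[str, str] = ("side", "cue_condition"),
) -> tuple[float, int, int, float]:
    """Two-factor repeated-measures interaction F test.

    ``table`` is long-format with one row per subject x factor cell; the
    table must be complete (every subject contributes all cells; cells
    with replicates are averaged first).  Returns (F, df1, df2, p) for
    the two-way interaction.
    """
    from statsmodels.stats.anova import AnovaRM

    cells = table.groupby([subject, *factors], as_index=False)[dv].mean()
    counts = cells.groupby(subject).size()
    n_cells = cells[factors[0]].nunique() * cells[factors[1]].nunique()
    if (counts != n_cells).any():
        bad = counts.index[counts != n_cells].tolist()
        raise ValueError(f"incomplete repeated-measures table for subjects: {bad}")
    fit = AnovaRM(cells, depvar=dv, subject=subject, within=list(factors)).fit()
    key = f"{factors[0]}:{factors[1]}"
    row = fit.anova_table.loc[key]
    return (
        float(row["F Value"]),
        int(row["Num DF"]),
        int(row["Den DF"]),
        float(row["Pr > F"]),
    )
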