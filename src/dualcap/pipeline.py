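"""End-to-end orchestration: trial CSV I/O, exclusions, and the full
per-experiment analysis (AOC model comparison, trade-offs, congruency,
response order) with group-level inference.

Trial CSV contract
------------------
Header: ``subject,block,trial,cue,cat_top,cat_bottom,resp_top,
resp_bottom,first_response_side,isi_ms,fixation_break``.

* ``cue`` in {single_top, single_bottom, dual}
* ``cat_top`` / ``cat_bottom`` in {present, absent}
* ``resp_*`` ratings 1-4; empty = missing.  Single-task trials carry a
  response on the cued side only; dual-task trials carry both plus a
  ``first_response_side`` in {top, bottom}.
* ``fixation_break`` True/False; flagged trials are dropped before any
  accuracy computation.

Sessions are approximated by contiguous block numbering per subject; an
optional ``session`` column, when present, partitions the block-run
exclusion rule instead.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aoc, sdt, stats, tradeoff

__all__ = [
    "AnalysisConfig",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "apply_exclusions",
    "congruency_analysis",
    "response_order_analysis",
    "run_experiment",
    "validate_report",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "subject",
    "block",
    "trial",
    "cue",
    "cat_top",
    "cat_bottom",
    "resp_top",
    "resp_bottom",
    "first_response_side",
    "isi_ms",
    "fixation_break",
]
CUES = ("single_top", "single_bottom", "dual")
CATEGORIES = ("present", "absent")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings; defaults mirror the study's procedure."""

    experiment: int = 1
    accuracy_window: tuple[float, float] = (0.70, 0.90)
    min_run_length: int = 4
    n_boot: int = 1000
    seed: int = 0
    first_response_only: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.accuracy_window
        if not lo < hi:
            raise ValueError("accuracy_window bounds must be ordered")
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")


# ---------------------------------------------------------------------------
# I/O


def _validate_frame(df: pd.DataFrame) -> list[str]:
    errors: list[str] = []

    def complain(mask: pd.Series, msg: str) -> None:
        # +2: one for the header, one for 0-based indexing.
        for i in df.index[mask][:20]:
            errors.append(f"line {i + 2}: {msg}")

    complain(~df["cue"].isin(CUES), f"cue must be one of {CUES}")
    for col in ("cat_top", "cat_bottom"):
        complain(~df[col].isin(CATEGORIES), f"{col} must be one of {CATEGORIES}")
    for col in ("resp_top", "resp_bottom"):
        bad = df[col].notna() & ~df[col].isin([1.0, 2.0, 3.0, 4.0])
        complain(bad, f"{col} must be a rating 1-4")
    dual = df["cue"] == "dual"
    complain(dual & (df["resp_top"].isna() | df["resp_bottom"].isna()),
             "dual trial lacking a response")
    complain(dual & ~df["first_response_side"].isin(["top", "bottom"]),
             "dual trial lacking first_response_side")
    complain((df["cue"] == "single_top") & df["resp_top"].isna(),
             "single_top trial lacking resp_top")
    complain((df["cue"] == "single_top") & df["resp_bottom"].notna(),
             "single_top trial must not carry resp_bottom")
    complain((df["cue"] == "single_bottom") & df["resp_bottom"].isna(),
             "single_bottom trial lacking resp_bottom")
    complain((df["cue"] == "single_bottom") & df["resp_top"].notna(),
             "single_bottom trial must not carry resp_top")
    return errors


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV; malformed rows raise with line numbers."""
    df = pd.read_csv(path, dtype={"subject": str}, keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("resp_top", "resp_bottom"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["fixation_break"].dtype != bool:
        df["fixation_break"] = (
            df["fixation_break"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
        if df["fixation_break"].isna().any():
            raise ValueError(f"{path}: fixation_break must be boolean")
        df["fixation_break"] = df["fixation_break"].astype(bool)
    errors = _validate_frame(df)
    if errors:
        raise ValueError(f"{path}: invalid trial rows:\n" + "\n".join(errors))
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the documented CSV dialect (empty = missing)."""
    out = trials.copy()
    for col in ("resp_top", "resp_bottom"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["first_response_side"] = out["first_response_side"].fillna("")
    cols = TRIAL_COLUMNS + [c for c in out.columns if c not in TRIAL_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exclusions


def _single_task_correct(df: pd.DataFrame) -> pd.Series:
    """Binary correctness of single-task responses (NaN on dual trials)."""
    out = pd.Series(np.nan, index=df.index)
    top = df["cue"] == "single_top"
    bot = df["cue"] == "single_bottom"
    out[top] = tradeoff.response_correct(
        df.loc[top, "resp_top"], df.loc[top, "cat_top"]
    ).astype(float)
    out[bot] = tradeoff.response_correct(
        df.loc[bot, "resp_bottom"], df.loc[bot, "cat_bottom"]
    ).astype(float)
    return out


def apply_exclusions(
    trials: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop fixation-break trials, then out-of-window block runs.

    A block is classified by its own single-task proportion correct
    (``high`` above the window, ``low`` below, ``ok`` inside; blocks with
    no single-task trials are ``neutral`` and extend a neighbouring run
    without starting one).  Maximal runs of consecutive non-ok blocks of
    at least ``min_run_length`` blocks whose *pooled* single-task
    proportion correct falls outside the window are discarded, mirroring
    the online procedure's discard-and-rerun rule.
    """
    config = config or AnalysisConfig()
    lo, hi = config.accuracy_window
    report = {
        "n_input": int(len(trials)),
        "n_fixation_break": int(trials["fixation_break"].sum()),
        "n_out_of_window": 0,
        "excluded_runs": [],
    }
    kept = trials[~trials["fixation_break"]].copy()

    correct = _single_task_correct(kept)
    group_cols = ["subject"]
    if "session" in kept.columns:
        group_cols.append("session")
    drop_index: list[pd.Index] = []
    for key, sub in kept.groupby(group_cols, sort=True):
        blocks = np.sort(sub["block"].unique())
        # Per-block classification.
        states = []
        for b in blocks:
            c = correct[sub.index[sub["block"] == b]].dropna()
            if c.empty:
                states.append("neutral")
            elif c.mean() > hi:
                states.append("high")
            elif c.mean() < lo:
                states.append("low")
            else:
                states.append("ok")
        # Maximal runs of consecutive non-ok blocks with >= 1 non-neutral.
        i = 0
        while i < len(blocks):
            if states[i] == "ok":
                i += 1
                continue
            j = i
            while j < len(blocks) and states[j] != "ok":
                j += 1
            run = blocks[i:j]
            run_states = states[i:j]
            i = j
            if len(run) < config.min_run_length or all(
                s == "neutral" for s in run_states
            ):
                continue
            run_mask = sub["block"].isin(run)
            pooled = correct[sub.index[run_mask]].dropna()
            if pooled.empty:
                continue
            pc = float(pooled.mean())
            if pc > hi or pc < lo:
                drop_index.append(sub.index[run_mask])
                report["excluded_runs"].append(
                    {
                        "group": key if isinstance(key, str) else list(key),
                        "blocks": [int(b) for b in run],
                        "pooled_single_pc": pc,
                    }
                )
    if drop_index:
        to_drop = drop_index[0]
        for ix in drop_index[1:]:
            to_drop = to_drop.union(ix)
        report["n_out_of_window"] = int(len(to_drop))
        kept = kept.drop(index=to_drop)
    report["n_kept"] = int(len(kept))
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Congruency and response order


def _pooled_ag(frames: list[tuple[pd.Series, pd.Series]]) -> float:
    """A_g over pooled (rating, category) responses from several sides."""
    ratings = pd.concat([r for r, _ in frames])
    cats = pd.concat([c for _, c in frames])
    scored = ratings.notna()
    if not scored.any():
        raise ValueError("no scorable responses")
    ratings = ratings[scored].astype(int)
    cats = cats[scored]
    pc = np.bincount(ratings[cats == "present"] - 1, minlength=4)
    ac = np.bincount(ratings[cats == "absent"] - 1, minlength=4)
    return sdt.ag(sdt.RatingCounts(tuple(pc.tolist()), tuple(ac.tolist())))


def congruency_analysis(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject A_g for congruent vs incongruent trials by cue condition.

    Congruent trials present the same category on both sides.  Responses
    are pooled across sides within each cell.  Subjects with an empty or
    degenerate cell are flagged.
    """
    congruent = trials["cat_top"] == trials["cat_bottom"]
    cue_condition = np.where(trials["cue"] == "dual", "dual", "single")
    rows = []
    for subject, sub in trials.groupby("subject", sort=True):
        for cc in ("single", "dual"):
            for cg_label, cg in (("congruent", True), ("incongruent", False)):
                mask = (
                    (cue_condition == cc)
                    & (congruent == cg)
                    & (trials["subject"] == subject)
                )
                cell = trials[mask]
                try:
                    value = _pooled_ag(
                        [
                            (cell["resp_top"], cell["cat_top"]),
                            (cell["resp_bottom"], cell["cat_bottom"]),
                        ]
                    )
                    flagged = False
                except ValueError as exc:
                    logger.warning(
                        "subject %s flagged in congruency analysis (%s/%s): %s",
                        subject, cc, cg_label, exc,
                    )
                    value, flagged = np.nan, True
                rows.append(
                    {
                        "subject": subject,
                        "cue_condition": cc,
                        "congruency": cg_label,
                        "ag": value,
                        "flagged": flagged,
                    }
                )
    return pd.DataFrame(rows)


def response_order_analysis(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject A_g for first vs second dual-task responses."""
    dual = trials[trials["cue"] == "dual"]
    if dual.empty:
        raise ValueError("no dual-task trials for response-order analysis")
    if dual["first_response_side"].isna().any():
        raise ValueError("dual trials missing first_response_side labels")
    share_top = (dual["first_response_side"] == "top").mean()
    if share_top in (0.0, 1.0):
        warnings.warn(
            "first_response_side is constant; response order should be "
            "randomized by design",
            stacklevel=2,
        )
    rows = []
    for subject, sub in dual.groupby("subject", sort=True):
        first_top = sub["first_response_side"] == "top"
        cells = {}
        for order in ("first", "second"):
            top_mask = first_top if order == "first" else ~first_top
            try:
                cells[order] = _pooled_ag(
                    [
                        (sub.loc[top_mask, "resp_top"], sub.loc[top_mask, "cat_top"]),
                        (sub.loc[~top_mask, "resp_bottom"], sub.loc[~top_mask, "cat_bottom"]),
                    ]
                )
            except ValueError:
                cells[order] = np.nan
        rows.append(
            {
                "subject": subject,
                "ag_first": cells["first"],
                "ag_second": cells["second"],
                "difference": cells["first"] - cells["second"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration


def _model_tests(
    summary: pd.DataFrame, config: AnalysisConfig
) -> dict:
    out = {}
    for i, model in enumerate(aoc.MODELS):
        dists = summary[f"dist_{model}"].to_numpy()
        res = stats.describe_effect(
            dists, n_boot=config.n_boot, seed=config.seed + i
        )
        out[model] = {
            **res.to_dict(),
            "mean_abs_distance": float(np.mean(np.abs(dists))),
            "rejected": bool(res.p < 0.05),
        }
    return out


def run_experiment(
    trials: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Run the full analysis; returns (JSON-ready report, tables).

    Pipeline: exclusions -> per-subject AOC + model distances + p_top ->
    group t / bootstrap CI / BF per model and accept/reject verdicts ->
    side-asymmetry tests -> trade-off analysis -> congruency ->
    response-order analysis (including a first-response-only AOC rerun).
    """
    config = config or AnalysisConfig()
    if trials.empty:
        raise ValueError("empty trial table")
    kept, exclusion_report = apply_exclusions(trials, config)
    if kept.empty:
        raise ValueError("no trials left after exclusions")

    summary = aoc.aoc_summary(kept, first_response_only=config.first_response_only)
    if summary.empty:
        raise ValueError("no subject has all required conditions")
    model_tests = _model_tests(summary, config)
    verdict = {
        m: ("rejected" if r["rejected"] else "not rejected")
        for m, r in model_tests.items()
    }

    p_top = summary["p_top_hat"].to_numpy()
    p_top_ci = stats.bootstrap_ci(p_top, n_boot=config.n_boot, seed=config.seed + 10)

    # Side asymmetry: top - bottom within each cue condition, and the
    # side x cue-condition interaction.
    single_diff = (summary["ag_single_top"] - summary["ag_single_bottom"]).to_numpy()
    dual_diff = (summary["ag_dual_top"] - summary["ag_dual_bottom"]).to_numpy()
    side_long = pd.concat(
        [
            summary.melt(
                id_vars="subject",
                value_vars=["ag_single_top", "ag_single_bottom",
                            "ag_dual_top", "ag_dual_bottom"],
                var_name="cell",
                value_name="value",
            )
        ]
    )
    side_long["cue_condition"] = np.where(
        side_long["cell"].str.contains("single"), "single", "dual"
    )
    side_long["side"] = np.where(side_long["cell"].str.contains("top"), "top", "bottom")
    f, df1, df2, p = stats.rm_interaction_test(side_long)

    trade = tradeoff_analysis_table = tradeoff.tradeoff_analysis(kept)
    trade_ok = trade[~trade["flagged"]]
    trade_test = stats.describe_effect(
        trade_ok["difference"].to_numpy(), n_boot=config.n_boot, seed=config.seed + 20
    )

    congruency = congruency_analysis(kept)
    cong_ok = congruency[~congruency["flagged"]]
    cong_table = cong_ok.rename(columns={"ag": "value"})
    complete = cong_table.groupby("subject").size() == 4
    cong_complete = cong_table[
        cong_table["subject"].isin(complete.index[complete])
    ]
    try:
        cf, cdf1, cdf2, cp = stats.rm_interaction_test(
            cong_complete, factors=("congruency", "cue_condition")
        )
        cong_interaction = {"F": cf, "df1": cdf1, "df2": cdf2, "p": cp}
    except ValueError as exc:
        logger.warning("congruency interaction test skipped: %s", exc)
        cong_interaction = None
    cong_effect = (
        cong_complete.pivot_table(
            index=["subject", "cue_condition"], columns="congruency", values="value"
        )
        .reset_index()
    )
    cong_effect["effect"] = cong_effect["congruent"] - cong_effect["incongruent"]

    order = response_order_analysis(kept)
    order_test = stats.describe_effect(
        order["difference"].dropna().to_numpy(),
        n_boot=config.n_boot,
        seed=config.seed + 30,
    )
    summary_first = aoc.aoc_summary(kept, first_response_only=True)
    first_tests = _model_tests(summary_first, config)

    report = {
        "config": {
            "experiment": config.experiment,
            "accuracy_window": list(config.accuracy_window),
            "min_run_length": config.min_run_length,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "first_response_only": config.first_response_only,
        },
        "exclusions": exclusion_report,
        "n_subjects": int(summary.shape[0]),
        "aoc": {
            "group_means": {
                k: float(summary[k].mean())
                for k in ("ag_single_top", "ag_single_bottom",
                          "ag_dual_top", "ag_dual_bottom")
            },
            "model_tests": model_tests,
            "verdict": verdict,
            "p_top": {
                "mean": float(p_top.mean()),
                "sem": float(p_top.std(ddof=1) / np.sqrt(p_top.size))
                if p_top.size > 1 else None,
                "ci_low": p_top_ci[0],
                "ci_high": p_top_ci[1],
            },
            "side_asymmetry": {
                "single_top_minus_bottom": stats.describe_effect(
                    single_diff, n_boot=config.n_boot, seed=config.seed + 11
                ).to_dict(),
                "dual_top_minus_bottom": stats.describe_effect(
                    dual_diff, n_boot=config.n_boot, seed=config.seed + 12
                ).to_dict(),
                "interaction": {"F": f, "df1": df1, "df2": df2, "p": p},
            },
            "first_response_only": {
                "model_tests": first_tests,
                "verdict": {
                    m: ("rejected" if r["rejected"] else "not rejected")
                    for m, r in first_tests.items()
                },
            },
        },
        "tradeoff": {
            "n_flagged": int(trade["flagged"].sum()),
            "group_test": trade_test.to_dict(),
        },
        "congruency": {
            "n_flagged_cells": int(congruency["flagged"].sum()),
            "interaction": cong_interaction,
            "mean_effect": {
                cc: float(g["effect"].mean())
                for cc, g in cong_effect.groupby("cue_condition")
            },
        },
        "response_order": {"group_test": order_test.to_dict()},
    }
    tables = {
        "aoc_summary": summary,
        "aoc_summary_first_response": summary_first,
        "tradeoff": tradeoff_analysis_table,
        "congruency": congruency,
        "response_order": order,
    }
    return report, tables


# ---------------------------------------------------------------------------
# Report schema


def _schema_path() -> Path:
    return Path(__file__).with_name("report_schema.json")


def validate_report(report: dict) -> None:
    """Structural check of a report against the bundled JSON schema.

    A minimal validator (required keys and primitive types only);
    raises ``ValueError`` on the first violation.
    """
    with open(_schema_path()) as fh:
        schema = json.load(fh)

    def check(obj, spec, path="report"):
        if isinstance(spec, dict) and spec.get("type") == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object, got {type(obj).__name__}")
            for key, subspec in spec.get("required", {}).items():
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
                check(obj[key], subspec, f"{path}.{key}")
        elif isinstance(spec, str):
            kinds = {
                "number": (int, float),
                "integer": int,
                "string": str,
                "boolean": bool,
                "array": list,
                "object": dict,
            }
            if spec.endswith("?") and obj is None:
                return
            base = spec.rstrip("?")
            if not isinstance(obj, kinds[base]) or (
                base == "number" and isinstance(obj, bool)
            ):
                raise ValueError(
                    f"{path}: expected {base}, got {type(obj).__name__}"
                )

    check(report, schema)


def write_report(
    report: dict, tables: dict[str, pd.DataFrame], outdir: str | Path
) -> None:
    """Write the JSON report and CSV tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
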