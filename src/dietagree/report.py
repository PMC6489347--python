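"""Stratified orchestration and table rendering.

Runs the full agreement battery — Spearman correlation, cross-classification
and weighted kappa, plus the five criteria — for every food group, for both
method pairs (app vs FFQ, app vs dietary records), in the whole sample and
in each of the 12 binary strata, and renders the results as the study-style
tables (CSV per table family plus a lossless JSON bundle).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AgreementSummary,
    CategoryScheme,
    CriteriaVerdict,
    Participant,
    STRATUM_AXES,
    UndefinedStatisticError,
    round_half_away,
    stratum_of,
)
from .stats import (
    average_over_groups,
    cross_classification,
    cross_table,
    evaluate_criteria,
    linear_weights,
    spearman,
    weighted_kappa,
)

__all__ = [
    "ReportRow",
    "StudyReport",
    "run_stratified_analysis",
    "tabulate_usability",
    "render_tables",
    "report_to_json",
    "report_from_json",
    "MIN_STRATUM_N",
]

logger = logging.getLogger("dietagree")

METHOD_PAIRS = ("app_vs_ffq", "app_vs_dr")
MIN_STRATUM_N = 4


@dataclass
class ReportRow:
    """One rendered cell-set: summary + verdict, or a flagged reason."""

    stratum_axis: str  # "all" or one of the six axes
    stratum: str  # "all" or the binary label
    method_pair: str
    food_group: str  # group name or "average"
    summary: AgreementSummary | None
    verdict: CriteriaVerdict | None
    reason: str | None = None  # why a statistic is NA, if it is


@dataclass
class StudyReport:
    """All summary rows plus usability tallies and provenance."""

    rows: list[ReportRow]
    usability: pd.DataFrame | None = None  # question, option, count, pct
    provenance: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        """Flat DataFrame of the numeric columns plus verdict booleans."""
        recs = []
        for r in self.rows:
            rec = {
                "stratum_axis": r.stratum_axis,
                "stratum": r.stratum,
                "method_pair": r.method_pair,
                "food_group": r.food_group,
                "reason": r.reason or "",
            }
            if r.summary is not None:
                rec.update(
                    {k: v for k, v in asdict(r.summary).items()
                     if k not in ("food_group", "method_pair", "stratum")}
                )
            if r.verdict is not None:
                rec.update(
                    scc_ok=r.verdict.scc_ok, exact_ok=r.verdict.exact_ok,
                    adjacent_ok=r.verdict.adjacent_ok,
                    extreme_ok=r.verdict.extreme_ok,
                    kappa_ok=r.verdict.kappa_ok, overall=r.verdict.overall,
                )
            recs.append(rec)
        return pd.DataFrame(recs)

    def select(self, **kv) -> list[ReportRow]:
        out = self.rows
        for k, v in kv.items():
            out = [r for r in out if getattr(r, k) == v]
        return out


def _summarize_pair(
    x: Sequence[int],
    y: Sequence[int],
    k: int,
    food_group: str,
    method_pair: str,
    stratum: str,
) -> tuple[AgreementSummary, CriteriaVerdict | None, str | None]:
    """All agreement statistics for one level-vector pair."""
    n = len(x)
    summary = AgreementSummary(
        food_group=food_group, method_pair=method_pair, stratum=stratum, n=n
    )
    reason = None
    t = cross_table(x, y, k)
    cc = cross_classification(t)
    summary.exact_pct = cc.exact_pct
    summary.exact_adjacent_pct = cc.exact_adjacent_pct
    summary.extreme_pct = cc.extreme_pct
    try:
        sp = spearman(x, y)
        summary.scc = sp.rho
        summary.scc_ci_low = sp.ci_low
        summary.scc_ci_high = sp.ci_high
        summary.scc_p = sp.p
    except UndefinedStatisticError as e:
        reason = f"scc undefined: {e}"
        logger.warning("%s / %s / %s: %s", stratum, method_pair, food_group, e)
    try:
        kr = weighted_kappa(t, linear_weights(k))
        summary.kappa_w = kr.kappa
        summary.kappa_se = kr.se0
        summary.kappa_p = kr.p
    except UndefinedStatisticError as e:
        reason = (reason + "; " if reason else "") + f"kappa undefined: {e}"
        logger.warning("%s / %s / %s: %s", stratum, method_pair, food_group, e)
    verdict = evaluate_criteria(summary) if reason is None else None
    return summary, verdict, reason


def run_stratified_analysis(
    app: pd.DataFrame,
    ffq: pd.DataFrame,
    dr: pd.DataFrame,
    participants: Sequence[Participant],
    scheme: CategoryScheme,
    usability: pd.DataFrame | None = None,
    provenance: Mapping | None = None,
    min_stratum_n: int = MIN_STRATUM_N,
) -> StudyReport:
    """Run the agreement battery whole-sample and within every stratum.

    ``app``, ``ffq`` and ``dr`` are participant × food-group frames of
    category levels on ``scheme``, sharing the same index and columns.
    Strata smaller than ``min_stratum_n`` are flagged, never silently
    dropped.
    """
    for name, frame in (("ffq", ffq), ("dr", dr)):
        if not frame.index.equals(app.index) or list(frame.columns) != list(app.columns):
            raise ValueError(f"app and {name} frames must share index and columns")
    by_id = {p.id: p for p in participants}
    missing = [pid for pid in app.index if pid not in by_id]
    if missing:
        raise ValueError(f"no covariates for participants {missing[:5]}")
    groups = list(app.columns)
    refs = {"app_vs_ffq": ffq, "app_vs_dr": dr}

    contexts: list[tuple[str, str, pd.Index]] = [("all", "all", app.index)]
    for axis, labels in STRATUM_AXES.items():
        assign = pd.Series(
            {pid: stratum_of(by_id[pid], axis) for pid in app.index}
        )
        for label in labels:
            contexts.append((axis, label, app.index[assign[app.index] == label]))

    rows: list[ReportRow] = []
    for axis, label, idx in contexts:
        for pair in METHOD_PAIRS:
            ref = refs[pair]
            if len(idx) < min_stratum_n:
                reason = f"stratum has {len(idx)} participants (< {min_stratum_n})"
                logger.warning("%s=%s: %s", axis, label, reason)
                for g in groups + ["average"]:
                    rows.append(
                        ReportRow(axis, label, pair, g, None, None, reason)
                    )
                continue
            per_group: list[AgreementSummary] = []
            for g in groups:
                s, v, reason = _summarize_pair(
                    app.loc[idx, g].to_numpy(),
                    ref.loc[idx, g].to_numpy(),
                    scheme.k, g, pair, label,
                )
                per_group.append(s)
                rows.append(ReportRow(axis, label, pair, g, s, v, reason))
            avg = average_over_groups(per_group)
            avg_verdict = (
                evaluate_criteria(avg)
                if all(
                    getattr(avg, f) is not None
                    for f in ("scc", "exact_pct", "exact_adjacent_pct",
                              "extreme_pct", "kappa_w")
                )
                else None
            )
            rows.append(ReportRow(axis, label, pair, "average", avg, avg_verdict))

    usability_table = tabulate_usability(usability) if usability is not None else None
    return StudyReport(
        rows=rows, usability=usability_table,
        provenance=dict(provenance or {}),
    )


def tabulate_usability(
    responses: pd.DataFrame,
    option_order: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Counts and percentages per option per usability question.

    ``responses`` is long format with columns participant_id, question,
    option.  Percentages are of the question's respondent count, rounded to
    1 decimal half-away-from-zero.
    """
    required = {"participant_id", "question", "option"}
    if not required.issubset(responses.columns):
        raise ValueError(f"responses must have columns {sorted(required)}")
    rows = []
    for q, sub in responses.groupby("question", sort=False):
        n = len(sub)
        counts = sub["option"].value_counts()
        opts = (
            list(option_order[q]) if option_order and q in option_order
            else list(sub["option"].unique())  # first-appearance order
        )
        unknown = set(counts.index) - set(opts)
        if unknown:
            raise ValueError(f"unknown options {sorted(unknown)} for question {q!r}")
        for opt in opts:
            c = int(counts.get(opt, 0))
            rows.append(
                {"question": q, "option": opt, "count": c,
                 "pct": round_half_away(100.0 * c / n, 1)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering

_AXIS_HALVES = (
    ("age", "gender", "occupation"),
    ("smoking", "activity", "bmi"),
)
_STAT_FAMILIES = ("scc", "crossclass", "kappa")


def _fmt(x: float | None, nd: int) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{round_half_away(x, nd):.{nd}f}"


def _family_cell(row: ReportRow, family: str) -> str:
    s = row.summary
    if s is None:
        return "NA"
    if family == "scc":
        if s.scc is None:
            return "NA"
        if s.scc_ci_low is None:
            return f"{_fmt(s.scc, 2)} (—)"
        return f"{_fmt(s.scc, 2)} ({_fmt(s.scc_ci_low, 2)}-{_fmt(s.scc_ci_high, 2)})"
    if family == "crossclass":
        return (
            f"{_fmt(s.exact_pct, 1)}/{_fmt(s.exact_adjacent_pct, 1)}"
            f"/{_fmt(s.extreme_pct, 1)}"
        )
    if family == "kappa":
        if s.kappa_w is None:
            return "NA"
        if s.kappa_se is None:
            return f"{_fmt(s.kappa_w, 2)} (—)"
        return f"{_fmt(s.kappa_w, 2)} ({_fmt(s.kappa_se, 2)})"
    raise ValueError(f"unknown statistic family {family!r}")


def render_tables(
    report: StudyReport,
    outdir: str | Path,
    formats: Sequence[str] = ("csv", "json"),
) -> list[Path]:
    """Write the study-style tables and a lossless JSON bundle.

    Twelve CSVs mirror the report-table layout — one per method pair ×
    statistic family × strata half, each with food-group rows and an "All"
    column plus six stratum columns — plus a usability CSV, a flat summary
    CSV, and the JSON bundle.  Rendering is pure: the same report yields
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    groups = [
        r.food_group
        for r in report.select(stratum_axis="all", method_pair="app_vs_ffq")
    ]

    if "csv" in formats:
        idx = 0
        for pair in METHOD_PAIRS:
            for family in _STAT_FAMILIES:
                for half in _AXIS_HALVES:
                    idx += 1
                    cols: dict[str, dict[str, str]] = {"All": {}}
                    for r in report.select(stratum_axis="all", method_pair=pair):
                        cols["All"][r.food_group] = _family_cell(r, family)
                    for axis in half:
                        for label in STRATUM_AXES[axis]:
                            name = f"{axis}:{label}"
                            cols[name] = {}
                            for r in report.select(
                                stratum_axis=axis, stratum=label, method_pair=pair
                            ):
                                cols[name][r.food_group] = _family_cell(r, family)
                    df = pd.DataFrame(cols).reindex(groups)
                    df.index.name = "food_group"
                    path = outdir / f"table_{idx:02d}_{pair}_{family}.csv"
                    df.to_csv(path)
                    written.append(path)
        flat = outdir / "summary_rows.csv"
        report.frame().to_csv(flat, index=False)
        written.append(flat)
        if report.usability is not None:
            upath = outdir / "usability.csv"
            report.usability.to_csv(upath, index=False)
            written.append(upath)

    if "json" in formats:
        jpath = outdir / "report.json"
        jpath.write_text(report_to_json(report))
        written.append(jpath)
    return written


# ---------------------------------------------------------------------------
# lossless JSON round-trip


def report_to_json(report: StudyReport) -> str:
    def _row(r: ReportRow) -> dict:
        return {
            "stratum_axis": r.stratum_axis,
            "stratum": r.stratum,
            "method_pair": r.method_pair,
            "food_group": r.food_group,
            "summary": asdict(r.summary) if r.summary is not None else None,
            "verdict": (
                asdict(r.verdict) | {"overall": r.verdict.overall}
                if r.verdict is not None else None
            ),
            "reason": r.reason,
        }

    payload = {
        "rows": [_row(r) for r in report.rows],
        "usability": (
            report.usability.to_dict(orient="records")
            if report.usability is not None else None
        ),
        "provenance": report.provenance,
    }
    return json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False)


def report_from_json(text: str) -> StudyReport:
    payload = json.loads(text)
    rows = []
    for d in payload["rows"]:
        summary = AgreementSummary(**d["summary"]) if d["summary"] else None
        verdict = None
        if d["verdict"]:
            v = dict(d["verdict"])
            v.pop("overall", None)
            verdict = CriteriaVerdict(**v)
        rows.append(
            ReportRow(
                d["stratum_axis"], d["stratum"], d["method_pair"],
                d["food_group"], summary, verdict, d.get("reason"),
            )
        )
    usability = (
        pd.DataFrame(payload["usability"])
        if payload.get("usability") is not None else None
    )
    return StudyReport(
        rows=rows, usability=usability,
        provenance=payload.get("provenance", {}),
    )
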