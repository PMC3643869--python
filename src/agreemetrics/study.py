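"""Study-level agreement analysis over a grid of rater pairs x criteria.

Reproduces the full reliability analysis of the bundled SCID-II
personality-disorder study: for each rater pair and each disorder
criterion, percent agreement, Cohen's Kappa and Gwet's AC1 with SEs,
trait prevalence, benchmark labels and a kappa-paradox flag; plus
study-level summaries (ranges, means, SDs) and a prevalence-ordered
comparison table.

The bundled dataset covers 4 rater pairs x 12 personality-disorder
criteria = 48 two-by-two tables, loaded with :func:`load_study_tables`.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from . import benchmarks as _benchmarks
from .contingency import ContingencyTable, build_table_from_counts
from .formatting import round_half_away
from .model import AgreementResults, TwoRaterAgreement

#: Criterion order as the study tables list them.
CRITERION_ORDER = (
    "Avoidant", "Dependent", "Obsessive-Compulsive", "Passive-Aggressive",
    "Depressive", "Paranoid", "Schizotypal", "Schizoid", "Histrionic",
    "Narcissistic", "Borderline", "Antisocial",
)
PAIR_ORDER = ("VU-MN", "US-SP", "TW-SR", "NW-SR")


def load_study_tables(
    path: str | Path | None = None,
) -> dict[str, dict[str, ContingencyTable]]:
    """Load the bundled (or a user-supplied) grid of 2x2 tables.

    Returns ``{pair_id: {criterion: ContingencyTable}}``.  The file is
    CSV with columns pair, criterion, a, b, c, d.
    """
    if path is None:
        source = resources.files("agreemetrics.datasets") / "scid2_tables.csv"
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    grid: dict[str, dict[str, ContingencyTable]] = {}
    for row in csv.DictReader(text.splitlines()):
        raters = tuple(row["pair"].split("-"))
        table = build_table_from_counts(
            int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]),
            rater_ids=raters if len(raters) == 2 else ("rater1", "rater2"),
        )
        grid.setdefault(row["pair"], {})[row["criterion"]] = table
    if not grid:
        raise ValueError("no tables found in study data")
    return grid


def prevalence_rate(table: ContingencyTable, positive_label: str | None = None) -> float:
    """Agreed-positive subjects as a percent of all subjects (2 decimals).

    The positive category is category 2 (cell ``d``) by construction;
    ``positive_label`` may be passed to assert the table's labelling.
    """
    if positive_label is not None and positive_label not in table.labels:
        raise ValueError(f"label {positive_label!r} not in table labels {table.labels}")
    if positive_label is not None and positive_label == table.labels[0]:
        # caller designates category 1 as positive: agreed-positive is cell a
        return round_half_away(100.0 * table.a / table.n, 2)
    return round_half_away(100.0 * table.d / table.n, 2)


@dataclass(frozen=True)
class CriterionResult:
    """All agreement statistics for one (rater pair, criterion) cell."""

    pair_id: str
    criterion: str
    table: ContingencyTable
    results: AgreementResults
    paradox_flag: bool
    benchmark_labels: Mapping[str, Mapping[str, str]]

    @property
    def pct_agreement(self) -> float:
        return self.results.percent_agreement

    @property
    def kappa(self):
        return self.results.kappa

    @property
    def ac1(self):
        return self.results.ac1

    @property
    def prevalence_pct(self) -> float:
        return prevalence_rate(self.table)


def analyze_pair(
    pair_id: str,
    tables: Mapping[str, ContingencyTable],
    paradox_agreement_min: float = 0.80,
    paradox_kappa_max: float = 0.40,
    scales: Sequence[str] = ("landis_koch", "altman", "fleiss"),
) -> list[CriterionResult]:
    """Compute a :class:`CriterionResult` for every criterion of one pair.

    The kappa-paradox flag marks cells with high observed agreement
    (>= ``paradox_agreement_min``) but low chance-corrected kappa
    (< ``paradox_kappa_max``, the Fleiss "Poor" cutoff).
    """
    out = []
    for criterion, table in tables.items():
        try:
            res = TwoRaterAgreement(table).fit(compute_se=table.n >= 2)
        except Exception as exc:  # annotate with grid position
            raise type(exc)(f"[pair {pair_id}, criterion {criterion}] {exc}") from exc
        paradox = (
            res.percent_agreement >= paradox_agreement_min
            and res.kappa.estimate < paradox_kappa_max
        )
        labels = {s: res.benchmark(s) for s in scales}
        out.append(CriterionResult(pair_id, criterion, table, res, paradox, labels))
    return out


@dataclass
class StudyReport:
    """Grid of per-cell results plus study-level summaries."""

    results: list[CriterionResult]
    summaries: dict = field(default_factory=dict)
    criterion_means: dict = field(default_factory=dict)

    def cell(self, pair_id: str, criterion: str) -> CriterionResult:
        for r in self.results:
            if r.pair_id == pair_id and r.criterion == criterion:
                return r
        raise KeyError((pair_id, criterion))

    def to_dict(self) -> dict:
        return {
            "results": [
                {
                    "pair": r.pair_id,
                    "criterion": r.criterion,
                    "paradox_flag": r.paradox_flag,
                    "benchmarks": {k: dict(v) for k, v in r.benchmark_labels.items()},
                    **r.results.to_dict(),
                }
                for r in self.results
            ],
            "summaries": self.summaries,
            "criterion_means": self.criterion_means,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_study(
    grid: Mapping[str, Mapping[str, ContingencyTable]] | None = None,
    rounded_means: bool = True,
    **analyze_kwargs,
) -> StudyReport:
    """Analyze every pair in the grid and attach summaries."""
    if grid is None:
        grid = load_study_tables()
    results: list[CriterionResult] = []
    for pair_id, tables in grid.items():
        results.extend(analyze_pair(pair_id, tables, **analyze_kwargs))
    report = StudyReport(results)
    report.summaries = summarize_study(report)
    report.criterion_means = criterion_means(report, rounded=rounded_means)
    return report


def _summary_stats(values: Sequence[float]) -> dict:
    """min/max/mean/sample-SD; single values get sd 0 with a flag."""
    out = {
        "min": min(values),
        "max": max(values),
        "mean": statistics.fmean(values),
    }
    if len(values) > 1:
        out["sd"] = statistics.stdev(values)
        out["sd_defined"] = True
    else:
        out["sd"] = 0.0
        out["sd_defined"] = False
    return out


def summarize_study(report: StudyReport) -> dict:
    """Study-level min/max/mean/SD per statistic over all grid cells.

    Coefficients enter the summaries rounded to 3 decimals and percent
    agreement rounded to whole percents, matching how the study tables
    report each cell.
    """
    if not report.results:
        raise ValueError("cannot summarize an empty study grid")
    kappas = [round_half_away(r.kappa.estimate, 3) for r in report.results]
    ac1s = [round_half_away(r.ac1.estimate, 3) for r in report.results]
    pcts = [round_half_away(100 * r.pct_agreement, 0) for r in report.results]
    return {
        "cohen_kappa": _summary_stats(kappas),
        "gwet_ac1": _summary_stats(ac1s),
        "pct_agreement": _summary_stats(pcts),
        "n_cells": len(report.results),
    }


def criterion_means(report: StudyReport, rounded: bool = True) -> dict:
    """Per-criterion mean kappa and AC1 across pairs.

    With ``rounded=True`` (default) the mean is taken over per-pair
    estimates rounded to 3 decimals, as the study's per-criterion
    summaries do; ``rounded=False`` averages full-precision estimates.
    """
    by_crit: dict[str, dict[str, list[float]]] = {}
    for r in report.results:
        d = by_crit.setdefault(r.criterion, {"kappa": [], "ac1": []})
        k, a = r.kappa.estimate, r.ac1.estimate
        if rounded:
            k, a = round_half_away(k, 3), round_half_away(a, 3)
        d["kappa"].append(k)
        d["ac1"].append(a)
    return {
        crit: {
            "cohen_kappa": statistics.fmean(v["kappa"]),
            "gwet_ac1": statistics.fmean(v["ac1"]),
            "n_pairs": len(v["kappa"]),
        }
        for crit, v in by_crit.items()
    }


def prevalence_table(report: StudyReport) -> list[dict]:
    """Rows (criterion, prevalence, kappa, AC1, % agreement), sorted
    within each criterion by descending prevalence."""
    rows = []
    crits = [c for c in CRITERION_ORDER if any(r.criterion == c for r in report.results)]
    extra = sorted({r.criterion for r in report.results} - set(crits))
    for crit in list(crits) + extra:
        cells = [r for r in report.results if r.criterion == crit]
        cells.sort(key=lambda r: (-r.prevalence_pct, r.pair_id))
        for r in cells:
            rows.append(
                {
                    "criterion": crit,
                    "pair": r.pair_id,
                    "prevalence_pct": r.prevalence_pct,
                    "cohen_kappa": round_half_away(r.kappa.estimate, 3),
                    "gwet_ac1": round_half_away(r.ac1.estimate, 3),
                    "pct_agreement": round_half_away(100 * r.pct_agreement, 0),
                }
            )
    return rows


def render_report_text(report: StudyReport) -> str:
    """Aligned plain-text rendering of the per-pair coefficient grid and
    the study summaries (stable ordering and formatting)."""
    pairs = [p for p in PAIR_ORDER if any(r.pair_id == p for r in report.results)]
    pairs += sorted({r.pair_id for r in report.results} - set(pairs))
    crits = [c for c in CRITERION_ORDER if any(r.criterion == c for r in report.results)]
    crits += sorted({r.criterion for r in report.results} - set(crits))

    lines = ["Inter-rater reliability by rater pair and criterion", ""]
    header = f"{'criterion':<22}" + "".join(f"{p + ' K':>10}{p + ' AC1':>10}" for p in pairs)
    lines.append(header)
    lines.append("-" * len(header))
    for crit in crits:
        row = f"{crit:<22}"
        for p in pairs:
            try:
                r = report.cell(p, crit)
                row += (f"{round_half_away(r.kappa.estimate, 3):>10.3f}"
                        f"{round_half_away(r.ac1.estimate, 3):>10.3f}")
            except KeyError:
                row += f"{'':>10}{'':>10}"
        lines.append(row)
    lines.append("")
    s = report.summaries
    for name, key in (("Cohen's kappa", "cohen_kappa"), ("Gwet's AC1", "gwet_ac1"),
                      ("% agreement", "pct_agreement")):
        st = s[key]
        lines.append(
            f"{name}: range [{st['min']:.3f}, {st['max']:.3f}], "
            f"mean {st['mean']:.3f} +/- {st['sd']:.3f}"
        )
    paradox = [f"{r.pair_id}/{r.criterion}" for r in report.results if r.paradox_flag]
    lines.append(f"kappa-paradox cells (high agreement, low kappa): "
                 f"{', '.join(paradox) if paradox else 'none'}")
    return "\n".join(lines)
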