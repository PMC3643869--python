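"""Model/results interface for two-rater agreement analysis.

:class:`TwoRaterAgreement` is constructed from rating data (records, a
wide DataFrame, or raw 2x2 counts); :meth:`TwoRaterAgreement.fit`
computes percent agreement, Cohen's Kappa and Gwet's AC1 with their
standard errors and returns an :class:`AgreementResults` carrying the
estimates, benchmark classifications and a text ``summary()``.

Example
-------
>>> from agreemetrics import TwoRaterAgreement
>>> res = TwoRaterAgreement.from_counts(15, 1, 1, 2).fit()
>>> round(res.kappa.estimate, 3), round(res.ac1.estimate, 3)
(0.604, 0.857)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import benchmarks as _benchmarks
from .coefficients import (
    AgreementEstimate,
    cohen_kappa,
    gwet_ac1,
    jackknife_se,
    percent_agreement,
)
from .contingency import (
    ContingencyTable,
    RatingRecord,
    build_table_from_counts,
    build_table_from_records,
)
from .formatting import round_half_away


class TwoRaterAgreement:
    """Agreement model for two raters assigning binary categories.

    Parameters
    ----------
    table
        The 2x2 cross-classification of subjects.
    """

    def __init__(self, table: ContingencyTable):
        self.table = table

    # -- constructors --------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        a: int,
        b: int,
        c: int,
        d: int,
        labels: Sequence[str] = ("No", "Yes"),
        rater_ids: Sequence[str] = ("rater1", "rater2"),
    ) -> "TwoRaterAgreement":
        return cls(build_table_from_counts(a, b, c, d, labels=labels, rater_ids=rater_ids))

    @classmethod
    def from_records(
        cls,
        records: Iterable[RatingRecord],
        positive_label: str = "Yes",
        rater_order: Sequence[str] | None = None,
    ) -> "TwoRaterAgreement":
        return cls(build_table_from_records(records, positive_label, rater_order))

    @classmethod
    def from_dataframe(
        cls,
        data,
        rater1: str,
        rater2: str,
        positive_label: str = "Yes",
        subject: str | None = None,
    ) -> "TwoRaterAgreement":
        """Build from a wide DataFrame with one column per rater."""
        records = []
        for idx, row in data.iterrows():
            sid = str(row[subject]) if subject is not None else str(idx)
            records.append(RatingRecord(sid, rater1, str(row[rater1])))
            records.append(RatingRecord(sid, rater2, str(row[rater2])))
        return cls.from_records(records, positive_label, rater_order=(rater1, rater2))

    # -- estimation ----------------------------------------------------
    def fit(self, compute_se: bool = True) -> "AgreementResults":
        """Estimate all three agreement statistics on the table."""
        t = self.table
        return AgreementResults(
            model=self,
            table=t,
            pct=percent_agreement(t),
            kappa=cohen_kappa(t, compute_se=compute_se and t.n >= 2),
            ac1=gwet_ac1(t, compute_se=compute_se and t.n >= 2),
        )


@dataclass
class AgreementResults:
    """Fitted agreement statistics for one 2x2 table."""

    model: TwoRaterAgreement
    table: ContingencyTable
    pct: AgreementEstimate
    kappa: AgreementEstimate
    ac1: AgreementEstimate
    _jackknife: dict = field(default_factory=dict, repr=False)

    @property
    def percent_agreement(self) -> float:
        return self.pct.estimate

    @property
    def prevalence_pct(self) -> float:
        """Agreed-positive subjects as a percentage of all subjects."""
        return 100.0 * self.table.d / self.table.n

    def benchmark(self, scale: str = "landis_koch") -> dict[str, str]:
        """Benchmark labels for kappa and AC1 under one scale."""
        return {
            "cohen_kappa": _benchmarks.classify(self.kappa.estimate, scale),
            "gwet_ac1": _benchmarks.classify(self.ac1.estimate, scale),
        }

    def jackknife(self, method: str) -> float:
        """Leave-one-subject-out SE for ``cohen_kappa`` or ``gwet_ac1``."""
        if method not in self._jackknife:
            self._jackknife[method] = jackknife_se(self.table, method)
        return self._jackknife[method]

    def summary(self, scale: str = "landis_koch") -> str:
        """Human-readable summary table (fixed formatting, diffable)."""
        t = self.table
        labels = self.benchmark(scale)
        lines = [
            "Two-rater agreement",
            "===================",
            f"raters: {t.rater_ids[0]} vs {t.rater_ids[1]}   "
            f"categories: {t.labels[0]}/{t.labels[1]}   n = {t.n}",
            f"cells [a b; c d] = [{t.a} {t.b}; {t.c} {t.d}]",
            "",
            f"{'statistic':<20}{'estimate':>10}{'chance':>10}{'SE':>8}  benchmark ({scale})",
            "-" * 68,
        ]

        def fmt(x, nd=3):
            return "" if x is None else f"{round_half_away(x, nd):.{nd}f}"

        rows = [
            ("percent agreement", self.pct, ""),
            ("Cohen's kappa", self.kappa, labels["cohen_kappa"]),
            ("Gwet's AC1", self.ac1, labels["gwet_ac1"]),
        ]
        for name, est, label in rows:
            lines.append(
                f"{name:<20}{fmt(est.estimate):>10}"
                f"{fmt(est.chance_agreement):>10}{fmt(est.se):>8}  {label}"
            )
        lines.append("-" * 68)
        lines.append(f"trait prevalence: {round_half_away(self.prevalence_pct, 2):.2f}%")
        flags = {e.method: e.degenerate_flag for e in (self.kappa, self.ac1)
                 if e.degenerate_flag != "none"}
        for method, flag in flags.items():
            lines.append(f"note: {method} degenerate case '{flag}'")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable result record."""
        return {
            "n": self.table.n,
            "cells": {"a": self.table.a, "b": self.table.b,
                      "c": self.table.c, "d": self.table.d},
            "percent_agreement": self.pct.estimate,
            "prevalence_pct": self.prevalence_pct,
            "cohen_kappa": {
                "estimate": self.kappa.estimate,
                "chance_agreement": self.kappa.chance_agreement,
                "se": self.kappa.se,
                "degenerate_flag": self.kappa.degenerate_flag,
            },
            "gwet_ac1": {
                "estimate": self.ac1.estimate,
                "chance_agreement": self.ac1.chance_agreement,
                "se": self.ac1.se,
                "degenerate_flag": self.ac1.degenerate_flag,
            },
        }
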