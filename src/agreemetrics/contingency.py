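"""Two-rater categorical rating data and the 2x2 contingency table.

The unit of analysis for every agreement statistic in this package is a
2x2 cross-classification of ``n`` subjects by two raters, each assigning
one of two categories.  Cell layout (rater 1 in columns, rater 2 in rows)::

                     rater 1
                  cat1    cat2   total
    rater 2 cat1    a       b     b1
            cat2    c       d     b2
        total      a1      a2      n

By default category 1 is the "negative" label (e.g. diagnosis absent) and
category 2 the positive one, so that ``d`` counts the agreed-positive
subjects used by the trait-prevalence definition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class RatingDataError(ValueError):
    """Raised for structurally invalid rating data."""


@dataclass(frozen=True)
class RatingRecord:
    """One observation: a single rater's category for a single subject."""

    subject_id: str
    rater_id: str
    category: str


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cell counts for two raters, with marginals.

    Parameters
    ----------
    a, b, c, d
        Cell counts: ``a`` both raters chose category 1, ``b`` rater 2
        chose category 1 while rater 1 chose category 2, ``c`` the
        reverse, ``d`` both chose category 2.
    labels
        The ordered ``(category 1, category 2)`` label pair.
    """

    a: int
    b: int
    c: int
    d: int
    labels: tuple[str, str] = ("No", "Yes")
    rater_ids: tuple[str, str] = field(default=("rater1", "rater2"))

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise RatingDataError(f"cell {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise RatingDataError(f"cell {name!r} must be non-negative, got {v}")
        if self.n < 1:
            raise RatingDataError("contingency table must contain at least one subject")
        if len(self.labels) != 2 or self.labels[0] == self.labels[1]:
            raise RatingDataError(f"labels must be two distinct categories, got {self.labels!r}")

    # -- marginals -----------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of subjects."""
        return self.a + self.b + self.c + self.d

    @property
    def a1(self) -> int:
        """Rater 1's category-1 marginal (a + c)."""
        return self.a + self.c

    @property
    def a2(self) -> int:
        """Rater 1's category-2 marginal (b + d)."""
        return self.b + self.d

    @property
    def b1(self) -> int:
        """Rater 2's category-1 marginal (a + b)."""
        return self.a + self.b

    @property
    def b2(self) -> int:
        """Rater 2's category-2 marginal (c + d)."""
        return self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def transpose(self) -> "ContingencyTable":
        """Swap the rater roles (b and c exchange; marginals follow)."""
        return ContingencyTable(
            self.a, self.c, self.b, self.d,
            labels=self.labels, rater_ids=(self.rater_ids[1], self.rater_ids[0]),
        )

    def relabel(self) -> "ContingencyTable":
        """Swap category 1 and category 2 (a<->d, b<->c)."""
        return ContingencyTable(
            self.d, self.c, self.b, self.a,
            labels=(self.labels[1], self.labels[0]), rater_ids=self.rater_ids,
        )


def build_table_from_counts(
    a: int,
    b: int,
    c: int,
    d: int,
    labels: Sequence[str] = ("No", "Yes"),
    rater_ids: Sequence[str] = ("rater1", "rater2"),
) -> ContingencyTable:
    """Build a :class:`ContingencyTable` from the four raw cell counts."""
    return ContingencyTable(a, b, c, d, labels=tuple(labels), rater_ids=tuple(rater_ids))


def build_table_from_records(
    records: Iterable[RatingRecord],
    positive_label: str = "Yes",
    rater_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Tabulate paired rating records into a 2x2 table.

    Every subject must be rated exactly once by each of exactly two
    raters.  Category 1 is the *non*-positive label so the agreed-positive
    cell lands in ``d``.

    Parameters
    ----------
    records
        The rating observations.
    positive_label
        The category treated as "positive" (category 2).
    rater_order
        Explicit ``(rater 1, rater 2)`` role assignment.  Required when
        the records contain two raters whose roles should not depend on
        first appearance; if omitted, order of first appearance is used.
    """
    records = list(records)
    if not records:
        raise RatingDataError("no rating records supplied (need at least one subject)")

    raters: list[str] = []
    for r in records:
        if r.rater_id not in raters:
            raters.append(r.rater_id)
    if len(raters) != 2:
        raise RatingDataError(
            f"expected exactly two raters, found {len(raters)}: {sorted(raters)}"
        )
    if rater_order is not None:
        if sorted(rater_order) != sorted(raters):
            raise RatingDataError(
                f"rater_order {tuple(rater_order)!r} does not match raters in data {sorted(raters)}"
            )
        raters = list(rater_order)
    r1, r2 = raters

    by_subject: dict[str, dict[str, str]] = {}
    for rec in records:
        slot = by_subject.setdefault(rec.subject_id, {})
        if rec.rater_id in slot:
            raise RatingDataError(
                f"subject {rec.subject_id!r} rated more than once by rater {rec.rater_id!r}"
            )
        slot[rec.rater_id] = rec.category

    categories = {rec.category for rec in records}
    if positive_label not in categories and len(categories) > 1:
        raise RatingDataError(
            f"positive label {positive_label!r} not among observed categories {sorted(categories)}"
        )
    negative = sorted(categories - {positive_label})
    if len(negative) > 1:
        raise RatingDataError(
            f"ratings must be binary (or binarized): found categories {sorted(categories)}"
        )
    negative_label = negative[0] if negative else ("No" if positive_label != "No" else "Absent")

    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for subject, ratings in sorted(by_subject.items()):
        missing = [r for r in (r1, r2) if r not in ratings]
        if missing:
            raise RatingDataError(
                f"subject {subject!r} lacks a rating from rater(s) {missing}"
            )
        pos1 = ratings[r1] == positive_label
        pos2 = ratings[r2] == positive_label
        if pos1 and pos2:
            cells["d"] += 1
        elif pos1 and not pos2:
            cells["b"] += 1
        elif pos2 and not pos1:
            cells["c"] += 1
        else:
            cells["a"] += 1
    return ContingencyTable(
        cells["a"], cells["b"], cells["c"], cells["d"],
        labels=(negative_label, positive_label), rater_ids=(r1, r2),
    )


def read_ratings(
    path: str | Path,
    dialect: str = "long",
    delimiter: str | None = None,
    subject_column: str = "subject",
    rater_column: str = "rater",
    category_column: str = "category",
) -> list[RatingRecord]:
    """Read rating records from a delimited text file with a header.

    ``dialect="long"`` expects columns (subject, rater, category);
    ``dialect="wide"`` expects a subject column plus one column per
    rater, the column name being the rater id.  The delimiter is
    autodetected (comma or tab) unless given.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise RatingDataError(f"{path}: file is empty")
    if delimiter is None:
        header = text.splitlines()[0]
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    rows = list(csv.DictReader(text.splitlines(), delimiter=delimiter))
    if not rows:
        raise RatingDataError(f"{path}: no data rows below the header")

    records: list[RatingRecord] = []
    seen: set[tuple[str, str]] = set()
    if dialect == "long":
        required = {subject_column, rater_column, category_column}
        if not required.issubset(rows[0].keys()):
            raise RatingDataError(
                f"{path}: long dialect requires columns {sorted(required)}, "
                f"found {sorted(rows[0].keys())}"
            )
        for i, row in enumerate(rows, start=2):
            subject, rater, cat = (row[subject_column], row[rater_column], row[category_column])
            if not subject or not rater or cat is None or cat == "":
                raise RatingDataError(f"{path}: missing value on line {i}")
            key = (subject, rater)
            if key in seen:
                raise RatingDataError(
                    f"{path}: duplicate rating for subject {subject!r} by rater {rater!r} (line {i})"
                )
            seen.add(key)
            records.append(RatingRecord(subject, rater, cat))
    elif dialect == "wide":
        if subject_column not in rows[0]:
            raise RatingDataError(f"{path}: wide dialect requires a {subject_column!r} column")
        rater_cols = [c for c in rows[0].keys() if c != subject_column]
        if len(rater_cols) < 2:
            raise RatingDataError(f"{path}: wide dialect needs at least two rater columns")
        for i, row in enumerate(rows, start=2):
            subject = row[subject_column]
            if not subject:
                raise RatingDataError(f"{path}: missing subject id on line {i}")
            if any(row[c] is None or row[c] == "" for c in rater_cols):
                raise RatingDataError(f"{path}: missing rating on line {i}")
            key0 = (subject, rater_cols[0])
            if key0 in seen:
                raise RatingDataError(f"{path}: duplicate subject {subject!r} (line {i})")
            for rater in rater_cols:
                seen.add((subject, rater))
                records.append(RatingRecord(subject, rater, row[rater]))
    else:
        raise RatingDataError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    return records


def records_from_table(table: ContingencyTable) -> list[RatingRecord]:
    """Expand a table back into one record pair per subject (inverse of
    :func:`build_table_from_records` up to subject naming)."""
    neg, pos = table.labels
    r1, r2 = table.rater_ids
    cats = (
        [(neg, neg)] * table.a + [(pos, neg)] * table.b
        + [(neg, pos)] * table.c + [(pos, pos)] * table.d
    )
    records = []
    for i, (c1, c2) in enumerate(cats, start=1):
        sid = f"S{i:04d}"
        records.append(RatingRecord(sid, r1, c1))
        records.append(RatingRecord(sid, r2, c2))
    return records
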