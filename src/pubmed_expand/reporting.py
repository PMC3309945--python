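"""Increase-in-retrieval reporting.

Turns per-term (q5, q3) hit counts into the study-style increase table:
one row per term with the percent increase q5/q3, a Total row whose
pooled increase is the ratio of the column sums (not the mean of row
percentages), and the fraction of queries that were productive at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Optional, Sequence, Union

__all__ = [
    "IncreaseRow",
    "IncreaseReport",
    "round_half_up",
    "increase_report",
    "productive_fraction",
    "read_counts_tsv",
    "render_report_tsv",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IncreaseRow:
    term: str
    q5_count: int
    q3_count: int

    @property
    def increase(self) -> Optional[float]:
        """Percent increase q5/q3*100 to one decimal; None when q3 = 0."""
        if self.q3_count == 0:
            return None
        return round_half_up(self.q5_count / self.q3_count * 100.0)

    @property
    def increase_text(self) -> str:
        inc = self.increase
        return "-" if inc is None else f"{inc:.1f}%"


@dataclass(frozen=True)
class IncreaseReport:
    rows: tuple[IncreaseRow, ...]

    @property
    def total_q5(self) -> int:
        return sum(r.q5_count for r in self.rows)

    @property
    def total_q3(self) -> int:
        return sum(r.q3_count for r in self.rows)

    @property
    def pooled_increase(self) -> float:
        """Total q5 over total q3, as a percent to one decimal.

        Deliberately the ratio of sums: the arithmetic mean of row
        percentages is a different (and much larger) number.
        """
        if self.total_q3 == 0:
            raise ZeroDivisionError("pooled increase undefined: q3 total is 0")
        return round_half_up(self.total_q5 / self.total_q3 * 100.0)


def increase_report(counts: Iterable[tuple[str, int, int]]) -> IncreaseReport:
    """Build the increase table from (term, q5_count, q3_count) triples."""
    rows = []
    for term, q5_count, q3_count in counts:
        if q5_count < 0 or q3_count < 0:
            raise ValueError(f"negative count for term {term!r}")
        rows.append(IncreaseRow(term=term, q5_count=int(q5_count), q3_count=int(q3_count)))
    return IncreaseReport(rows=tuple(rows))


def productive_fraction(counts: Iterable[tuple[str, int, int]]) -> float:
    """Percent of queries retrieving any new citation (q5 > 0), one decimal."""
    rows = list(counts)
    if not rows:
        raise ValueError("no queries")
    productive = sum(1 for _, q5_count, _ in rows if q5_count > 0)
    return round_half_up(productive / len(rows) * 100.0)


def read_counts_tsv(stream: Union[IO[str], str]) -> list[tuple[str, int, int]]:
    """Read (term, q5, q3) triples from TSV; a leading header row is allowed."""
    text = stream if isinstance(stream, str) else stream.read()
    out: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ValueError(f"counts line {lineno}: expected 3 tab-separated columns")
        if lineno == 1 and not (cols[1].strip().isdigit() and cols[2].strip().isdigit()):
            continue  # header
        out.append((cols[0], int(cols[1]), int(cols[2])))
    return out


def render_report_tsv(report: IncreaseReport) -> str:
    """Increase table as TSV with header and Total row."""
    lines = ["term\tq5\tq3\tincrease"]
    for row in report.rows:
        lines.append(f"{row.term}\t{row.q5_count}\t{row.q3_count}\t{row.increase_text}")
    lines.append(
        f"Total\t{report.total_q5}\t{report.total_q3}\t{report.pooled_increase:.1f}%"
    )
    return "\n".join(lines) + "\n"
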