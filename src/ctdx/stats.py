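"""Cohort-level association between size-profile class and CNA detection.

2x2 contingency table (rows: biphasic/monophasic; columns: copy-number
changes detected yes/no) with row percentages and Pearson's chi-squared
test (df = 1, no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "ContingencyTable2x2",
    "tally_cohort",
    "row_percentages",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a/b = biphasic detected/undetected; c/d = monophasic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(not isinstance(x, (int,)) or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def tally_cohort(size_calls: list, balanced_flags: list) -> ContingencyTable2x2:
    """Cross-tabulate size-profile calls against copy-number detection.

    ``size_calls`` holds :class:`~ctdx.sizing.SizeProfileCall` objects or
    the strings 'biphasic'/'monophasic'; a sample counts as detected when
    its copy-number profile is *not* balanced.
    """
    if len(size_calls) != len(balanced_flags):
        raise ValueError("one size call and one balanced flag required per sample")
    if not size_calls:
        raise ValueError("empty cohort")
    a = b = c = d = 0
    for call, balanced in zip(size_calls, balanced_flags):
        cls = call if isinstance(call, str) else call.profile_class
        if cls not in ("biphasic", "monophasic"):
            raise ValueError(f"unknown size class {cls!r}")
        detected = not balanced
        if cls == "biphasic":
            a += detected
            b += not detected
        else:
            c += detected
            d += not detected
    return ContingencyTable2x2(a, b, c, d)


def row_percentages(table: ContingencyTable2x2) -> tuple:
    """Detected percentage per row, rounded to one decimal."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("zero row total")
    biphasic = 100.0 * table.a / (table.a + table.b)
    monophasic = 100.0 * table.c / (table.c + table.d)
    return round(biphasic, 1), round(monophasic, 1)


def chi_square_2x2(table: ContingencyTable2x2, correction: bool = False) -> tuple:
    """Pearson chi-squared test on a 2x2 table: (statistic, df, p).

    ``correction=True`` applies the Yates continuity correction.  Any
    zero margin makes the statistic undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins()
    if 0 in (r1, r2, c1, c2):
        raise ValueError(
            "chi-squared statistic undefined: a table margin is zero "
            f"(margins {r1}, {r2}, {c1}, {c2})"
        )
    n = table.n
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(stat, 1))
    return float(stat), 1, p
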