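"""Maturity-by-fate association for adult trout.

Spawning-state fish caught at tagging are more likely to turn transient
(post-spawning movements out of the reach).  A single-stratum
Mantel-Haenszel chi-squared test with continuity correction checks the
2x2 association between maturity (spawning/spent) and detection-history
class (transient/resident); the descriptive effect is the ratio of
transient proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

__all__ = ["ContingencyTable2x2", "mantel_haenszel", "risk_ratio", "maturity_fate_table"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (spawning, spent) x (transient, resident).

    a = spawning transients, b = spawning residents,
    c = spent transients,    d = spent residents.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def mantel_haenszel(table: ContingencyTable2x2, correction: bool = True) -> tuple[float, float]:
    """Continuity-corrected Mantel-Haenszel chi-square for one 2x2 stratum.

    Under the hypergeometric null the top-left cell has
    E[a] = row1 * col1 / n  and  Var(a) = row1*row2*col1*col2 / (n^2 (n-1));
    the statistic is (|a - E[a]| - 1/2)^2 / Var(a), referred to chi^2(1).
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all table margins must be positive")
    n = table.total
    expected = r1 * c1 / n
    var = r1 * r2 * c1 * c2 / (n**2 * (n - 1))
    dev = abs(table.a - expected)
    if correction:
        dev = max(0.0, dev - 0.5)
    stat = dev**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def risk_ratio(table: ContingencyTable2x2) -> float:
    """Ratio of transient proportions, spawning vs spent."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ValueError("both maturity rows must be non-empty")
    p_spawning = table.a / (table.a + table.b)
    p_spent = table.c / (table.c + table.d)
    if p_spent == 0:
        raise ValueError("no transients among spent fish; ratio undefined")
    return p_spawning / p_spent


def maturity_fate_table(registry) -> ContingencyTable2x2:
    """Build the 2x2 table from a registry with assigned fates (adult trout)."""
    counts = np.zeros((2, 2), dtype=int)
    for fish in registry:
        if fish.maturity not in ("spawning", "spent") or fish.fate == "unassigned":
            continue
        i = 0 if fish.maturity == "spawning" else 1
        j = 0 if fish.fate == "transient" else 1
        counts[i, j] += 1
    return ContingencyTable2x2(*counts.ravel().tolist())
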