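"""Small arithmetic and table-shaping helpers for run reports.

The published style of 3'-end surveys reports per-source read/site
counters (raw reads, tailed reads, mapped reads, pA events, clusters)
with per-source columns summed into a grand total, percentages printed
to two decimals, and per-chromosome site/gene ratios; these helpers keep
that arithmetic in one tested place.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = ["per_source_total", "percentage", "ratio", "counter_table"]


def per_source_total(counts: Mapping[str, int]) -> int:
    """Grand total of per-source counts (sources are additive: each
    cluster belongs to exactly one source)."""
    return sum(int(v) for v in counts.values())


def percentage(part: float, whole: float, ndigits: int = 2) -> float:
    """``part`` as a percentage of ``whole``, rounded for printing."""
    if whole == 0:
        raise ZeroDivisionError("percentage undefined for whole == 0")
    return round(100.0 * part / whole, ndigits)


def ratio(numerator: float, denominator: float, ndigits: int = 2) -> float | None:
    """Plain ratio rounded for printing; None when undefined."""
    if denominator == 0:
        return None
    return round(numerator / denominator, ndigits)


def counter_table(counters: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Per-source counter rows plus a total column.

    ``counters`` maps row label -> {source: count}."""
    sources = sorted({s for row in counters.values() for s in row})
    rows = []
    for label, row in counters.items():
        vals = [int(row.get(s, 0)) for s in sources]
        rows.append([label, *vals, sum(vals)])
    return pd.DataFrame(rows, columns=["counter", *sources, "total"])
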