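"""Shared numeric formatting: exact rounding and table rendering helpers.

All model arithmetic is carried as :class:`fractions.Fraction`; these helpers
are the single place where exact values are turned into reported integers or
display strings.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

Number = int | Fraction


def round_half_away(x: Number) -> int:
    """Round to the nearest integer, ties away from zero.

    Exact for :class:`Fraction` inputs (no float detour).
    """
    x = Fraction(x)
    if x >= 0:
        return int((2 * x + 1) // 2)
    return -int((-2 * x + 1) // 2)


def _to_decimal(value: Fraction) -> Decimal:
    return Decimal(value.numerator) / Decimal(value.denominator)


def format_percent(value: Fraction, decimals: int = 4) -> str:
    """Format a fraction as a percentage with a fixed number of decimals."""
    pct = _to_decimal(value) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(quantum, rounding=ROUND_HALF_UP)}%"


def format_percent_sig(value: Fraction, sig_figs: int = 2) -> str:
    """Format a fraction as a percentage with ``sig_figs`` significant figures."""
    if value == 0:
        return "0%"
    pct = _to_decimal(value) * 100
    quantum = Decimal(1).scaleb(pct.adjusted() - sig_figs + 1)
    q = pct.quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{q.normalize()}%"


def format_count(n: int) -> str:
    """Thousands-grouped integer, negatives parenthesized (oversupply style)."""
    if n < 0:
        return f"({abs(n):,})"
    return f"{n:,}"


def markdown_table(headers: Sequence[str], rows: Iterable[Sequence[object]]) -> str:
    rows = [[str(c) for c in row] for row in rows]
    widths = [len(h) for h in headers]
    for row in rows:
        for i, cell in enumerate(row):
            widths[i] = max(widths[i], len(cell))
    def line(cells: Sequence[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(list(headers)), "| " + " | ".join("-" * w for w in widths) + " |"]
    out.extend(line(row) for row in rows)
    return "\n".join(out) + "\n"


def delimited_table(
    headers: Sequence[str], rows: Iterable[Sequence[object]], sep: str = ","
) -> str:
    lines = [sep.join(headers)]
    lines.extend(sep.join(str(c) for c in row) for row in rows)
    return "\n".join(lines) + "\n"
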