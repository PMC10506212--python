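"""Per-table association and descriptive statistics.

For a 2x2 table of TLR8 x TLR7 positivity with cells a, b, c, d and
N = a+b+c+d, this module computes:

* Yule's Q = (ad - bc)/(ad + bc), a [-1, 1] association coefficient
  (-1 mutually exclusive transcription, 0 independence, +1 complete
  co-dependence);
* the obs/exp ratio a*N / ((a+b)(a+c)), the observed double-positive
  count over its expectation p7*p8*N under independent transcription;
* the full expected table under independence (margin products / N);
* escape percentages (escape cells / gene-positive cells).

Sparse Xi tables routinely produce zero margins; statistics that are
undefined there are returned as ``None`` with a reason code carried in
:class:`AssocResult`, never as silent zeros.  No continuity correction
is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scoring import ContingencyTable2x2, EscapeCounts


@dataclass(frozen=True)
class AssocResult:
    """Association statistics for one table; ``None`` means undefined."""

    q: float | None
    obs_exp: float | None
    p7: float | None
    p8: float | None
    p_joint_expected: float | None
    n_double_expected: float | None
    q_undefined_reason: str | None = None
    obs_exp_undefined_reason: str | None = None


def yules_q(table: ContingencyTable2x2) -> float | None:
    """Yule's Q; ``None`` when ad + bc = 0 (both diagonals empty)."""
    a, b, c, d = table.as_tuple()
    denom = a * d + b * c
    if denom == 0:
        return None
    return (a * d - b * c) / denom


def obs_exp_ratio(table: ContingencyTable2x2) -> float | None:
    """Observed/expected double-positive ratio; ``None`` on zero margin."""
    a, b, c, _ = table.as_tuple()
    n = table.n_total
    denom = (a + b) * (a + c)
    if n == 0 or denom == 0:
        return None
    return a * n / denom


def expected_table(
    table: ContingencyTable2x2,
) -> tuple[float, float, float, float]:
    """Expected cell frequencies under independence (margins / N products).

    Preserves both margins and the grand total exactly.
    """
    a, b, c, d = table.as_tuple()
    n = table.n_total
    if n == 0:
        return (0.0, 0.0, 0.0, 0.0)
    r1, r2 = a + b, c + d  # TLR8+ / TLR8- rows
    c1, c2 = a + c, b + d  # TLR7+ / TLR7- columns
    return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def escape_percent(counts: EscapeCounts) -> float | None:
    """Escape fraction (biallelic + Xi-only) / gene-positive; ``None``
    when no cell is positive for the gene."""
    if counts.n_positive_total == 0:
        return None
    return counts.n_escape / counts.n_positive_total


def assoc_result(table: ContingencyTable2x2) -> AssocResult:
    """All association statistics for one table with undefined reasons."""
    a, b, c, _ = table.as_tuple()
    n = table.n_total
    q = yules_q(table)
    oe = obs_exp_ratio(table)
    if n == 0:
        return AssocResult(
            q=None, obs_exp=None, p7=None, p8=None,
            p_joint_expected=None, n_double_expected=None,
            q_undefined_reason="empty_table",
            obs_exp_undefined_reason="empty_table",
        )
    p7 = (a + c) / n
    p8 = (a + b) / n
    return AssocResult(
        q=q,
        obs_exp=oe,
        p7=p7,
        p8=p8,
        p_joint_expected=p7 * p8,
        n_double_expected=n * p7 * p8,
        q_undefined_reason=None if q is not None else "zero_diagonal_products",
        obs_exp_undefined_reason=None if oe is not None else "zero_margin",
    )
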