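"""Monte Carlo chi-square tests of independence for sparse count tables.

The asymptotic chi-square reference is unreliable when expected cell
counts are small, which is the norm for Xi-restricted FISH counts.
Instead, the null distribution of the Pearson statistic is simulated by
drawing replicate tables uniformly over all tables with the observed
row and column margins (Patefield's algorithm, as in R's
``chisq.test(simulate.p.value=TRUE)``), and

    p = (1 + #{chi2_rep >= chi2_obs}) / (replications + 1),

the add-one estimator that keeps p positive and the test valid.

The headline application is the Xa-vs-Xi comparison: per donor, a 3x2
table of TLR7+TLR8+, TLR7-TLR8+ and TLR7+TLR8- cell counts on the Xa
versus the Xi, testing whether the co-transcription pattern differs
between the two chromosomes.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scoring import CellScore, Karyotype

__all__ = [
    "ZeroMarginError",
    "PatternTable3x2",
    "MonteCarloResult",
    "chi2_statistic",
    "monte_carlo_chi2_p",
    "xa_vs_xi_test",
]

#: replicate batch size; caps memory for 10^6-replication runs
_BATCH = 200_000


class ZeroMarginError(ValueError):
    """A row or column margin is zero: the table is untestable."""


@dataclass(frozen=True)
class PatternTable3x2:
    """Counts of TLR7+TLR8+, TLR7-TLR8+, TLR7+TLR8- cells (rows) on the
    Xa and the Xi (columns) for one donor."""

    donor_id: str
    xa: tuple[int, int, int]
    xi: tuple[int, int, int]

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.xa, self.xi]).astype(np.int64)

    @property
    def testable(self) -> bool:
        m = self.as_array()
        return bool(m.sum(axis=0).min() > 0 and m.sum(axis=1).min() > 0)


@dataclass(frozen=True)
class MonteCarloResult:
    donor_id: str
    chi2: float
    p: float
    replications: int
    seed: int | None


def _as_matrix(table) -> np.ndarray:
    m = np.asarray(table, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("expected an r x c count matrix with r, c >= 2")
    if (m < 0).any():
        raise ValueError("counts must be nonnegative")
    return m


def chi2_statistic(table) -> float:
    """Pearson chi-square statistic, sum (O - E)^2 / E, with expected
    counts from the margin products.  Zero margins are untestable."""
    m = _as_matrix(table)
    if m.sum(axis=0).min() == 0 or m.sum(axis=1).min() == 0:
        raise ZeroMarginError("table has a zero margin; statistic undefined")
    expected = stats.contingency.expected_freq(m)
    return float(((m - expected) ** 2 / expected).sum())


def _chi2_batch(tables: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Pearson statistic for a (k, r, c) stack against fixed expecteds."""
    return ((tables - expected) ** 2 / expected).sum(axis=(1, 2))


def monte_carlo_chi2_p(
    table,
    replications: int = 1_000_000,
    seed: int | np.random.SeedSequence | None = None,
) -> float:
    """Monte Carlo p-value for independence, conditioning on both margins.

    Replicate tables are drawn by Patefield's algorithm; the same seed
    always yields the same p.
    """
    if replications < 1:
        raise ValueError("replications must be positive")
    m = _as_matrix(table)
    observed = chi2_statistic(m)  # raises ZeroMarginError when untestable
    expected = stats.contingency.expected_freq(m)
    row, col = m.sum(axis=1), m.sum(axis=0)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row, col)

    exceed = 0
    left = replications
    # small tolerance absorbs float noise when replicate == observed
    threshold = observed - 1e-9
    while left > 0:
        k = min(left, _BATCH)
        reps = dist.rvs(k, method="patefield", random_state=rng)
        if k == 1:  # rvs squeezes the leading axis for size 1
            reps = reps.reshape(1, *m.shape)
        exceed += int((_chi2_batch(reps, expected) >= threshold).sum())
        left -= k
    return (1 + exceed) / (replications + 1)


def pattern_tables(cells: Sequence[CellScore]) -> list[PatternTable3x2]:
    """Per-donor 3x2 pattern tables of Xa- vs Xi-attributed positives.

    Rows count cells positive for both genes, TLR8 only, and TLR7 only
    on the chromosome class in question; double-negative cells carry no
    signal on either chromosome and do not enter the comparison.
    """
    if any(c.group is Karyotype.XY for c in cells):
        raise ValueError("Xa-vs-Xi comparison requires XX or XXY donors")
    by_donor: dict[str, list[CellScore]] = {}
    for c in cells:
        by_donor.setdefault(c.donor_id, []).append(c)
    out = []
    for donor_id in sorted(by_donor):
        counts = {"xa": [0, 0, 0], "xi": [0, 0, 0]}
        for cell in by_donor[donor_id]:
            for chrom in ("xa", "xi"):
                p7 = getattr(cell, f"tlr7_{chrom}")
                p8 = getattr(cell, f"tlr8_{chrom}")
                if p7 and p8:
                    counts[chrom][0] += 1
                elif p8:
                    counts[chrom][1] += 1
                elif p7:
                    counts[chrom][2] += 1
        out.append(
            PatternTable3x2(
                donor_id=donor_id,
                xa=tuple(counts["xa"]),
                xi=tuple(counts["xi"]),
            )
        )
    return out


def xa_vs_xi_test(
    cells: Sequence[CellScore],
    replications: int = 1_000_000,
    seed: int | None = None,
) -> dict[str, MonteCarloResult | None]:
    """Monte Carlo chi-square test of Xa-vs-Xi co-transcription patterns.

    Returns one result per donor; donors whose 3x2 table has a zero
    margin are reported as ``None`` (not testable), never as a p-value.
    """
    results: dict[str, MonteCarloResult | None] = {}
    ss = np.random.SeedSequence(seed)
    tables = pattern_tables(cells)
    for sub_ss, pt in zip(ss.spawn(len(tables)), tables):
        if not pt.testable:
            results[pt.donor_id] = None
            continue
        m = pt.as_array()
        results[pt.donor_id] = MonteCarloResult(
            donor_id=pt.donor_id,
            chi2=chi2_statistic(m),
            p=monte_carlo_chi2_p(m, replications=replications, seed=sub_ss),
            replications=replications,
            seed=seed,
        )
    return results
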