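"""Donor-level confidence distributions (CDs).

A confidence distribution is a sample-dependent cumulative distribution
function on a parameter: every pair of its quantiles is a confidence
interval, and CDs from independent donors can be combined like evidence
(see :mod:`xcifish.meta`).  Two constructions are provided:

* :func:`binomial_cd` — the exact mid-p CD for a binomial proportion,
  H(p) = P(X > x; n, p) + 1/2 P(X = x; n, p), evaluated on a dense grid
  over [0, 1].  Used for per-donor proportions (escape fraction,
  double-positive fraction).
* :func:`bootstrap_cd` — the nonparametric bootstrap CD for statistics
  of a 2x2 table (Yule's Q, obs/exp): cells are resampled with
  replacement from the four-category multinomial given by the observed
  table, and the CD is the empirical distribution of the resampled
  statistic.

Point estimates are CD medians; intervals are equal-tail quantile pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scoring import ContingencyTable2x2

__all__ = [
    "ConfidenceDistribution",
    "BootstrapConfig",
    "DegenerateResampleError",
    "binomial_cd",
    "bootstrap_cd",
    "normal_cd",
    "cd_point_and_interval",
    "cd_probability_at",
]

#: Statistics supported by the bootstrap machinery.  ``q`` and
#: ``obs_exp`` are the association statistics; the proportion statistics
#: are convenience labels for the same resampling scheme.
BOOTSTRAP_STATISTICS = ("q", "obs_exp", "p7", "p8", "p_double")


class DegenerateResampleError(RuntimeError):
    """Raised when too many bootstrap resamples leave the statistic undefined."""


@dataclass(frozen=True)
class ConfidenceDistribution:
    """A monotone cumulative-confidence curve on a parameter grid.

    ``kind`` records the construction: ``binomial`` (exact mid-p),
    ``bootstrap`` (empirical), or ``normal`` (meta-analytic summary).
    """

    grid: np.ndarray
    cdf: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        cdf = np.asarray(self.cdf, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "cdf", cdf)
        if grid.ndim != 1 or grid.shape != cdf.shape or grid.size == 0:
            raise ValueError("grid and cdf must be matching 1-D arrays")
        if np.any(np.diff(grid) < 0):
            raise ValueError("grid must be sorted ascending")
        if np.any(np.diff(cdf) < -1e-12):
            raise ValueError("cdf must be nondecreasing")
        if cdf.min() < -1e-12 or cdf.max() > 1 + 1e-12:
            raise ValueError("cdf values must lie in [0, 1]")

    @property
    def is_degenerate(self) -> bool:
        """True when all confidence mass sits on a single atom."""
        return self.grid.size == 1 or bool(
            np.isclose(self.grid[0], self.grid[-1])
        )

    def probability_at(self, value: float) -> float:
        """H(value) by monotone interpolation, clipped to [0, 1]."""
        if self.is_degenerate:
            atom = float(self.grid[0])
            if value < atom:
                return 0.0
            if value > atom:
                return 1.0
            return 0.5
        p = float(np.interp(value, self.grid, self.cdf,
                            left=0.0, right=1.0))
        return min(1.0, max(0.0, p))

    def quantile(self, q: float) -> float:
        """Inverse of the confidence curve by monotone interpolation."""
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile level must be in [0, 1]")
        if self.is_degenerate:
            return float(self.grid[0])
        # Collapse flat cdf stretches so np.interp sees increasing xp;
        # keep the first grid point of each flat run (lower quantile
        # convention on empirical CDs).
        cdf, idx = np.unique(self.cdf, return_index=True)
        grid = self.grid[idx]
        if q <= cdf[0]:
            return float(grid[0])
        if q >= cdf[-1]:
            return float(grid[-1])
        return float(np.interp(q, cdf, grid))

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = 1.0 - level
        return (self.quantile(alpha / 2), self.quantile(1 - alpha / 2))


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: replication count (10,000 default; 50,000 for
    final reporting), RNG seed, and a cap on redraw rounds for resamples
    on which the statistic is undefined."""

    replications: int = 10_000
    seed: int | np.random.SeedSequence | None = None
    max_redraws: int = 100
    #: abort when more than this fraction of draws is degenerate
    max_degenerate_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be positive")
        if self.max_redraws < 0:
            raise ValueError("max_redraws must be nonnegative")


def binomial_cd(x: int, n: int, grid_size: int = 2001) -> ConfidenceDistribution:
    """Exact mid-p binomial CD for a proportion from x successes in n trials.

    H(p) = P(X > x; n, p) + 1/2 P(X = x; n, p), a strictly increasing
    function of p whose median is the point estimate and whose
    equal-tail quantiles are exact-style confidence limits.
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("x and n must be integers")
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    grid = np.linspace(0.0, 1.0, grid_size)
    cdf = stats.binom.sf(x, n, grid) + 0.5 * stats.binom.pmf(x, n, grid)
    # sf/pmf at the p = 0 and 1 endpoints are exact; clip fp noise only.
    cdf = np.clip(cdf, 0.0, 1.0)
    return ConfidenceDistribution(grid=grid, cdf=np.maximum.accumulate(cdf),
                                  kind="binomial")


def _stat_values(counts: np.ndarray, statistic: str) -> np.ndarray:
    """Vectorized statistic over an (m, 4) array of (a, b, c, d) counts.

    Returns NaN where the statistic is undefined.
    """
    a = counts[:, 0].astype(float)
    b = counts[:, 1].astype(float)
    c = counts[:, 2].astype(float)
    d = counts[:, 3].astype(float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "q":
            denom = a * d + b * c
            return np.where(denom > 0, (a * d - b * c) / denom, np.nan)
        if statistic == "obs_exp":
            denom = (a + b) * (a + c)
            return np.where(denom > 0, a * n / denom, np.nan)
        if statistic == "p7":
            return np.where(n > 0, (a + c) / n, np.nan)
        if statistic == "p8":
            return np.where(n > 0, (a + b) / n, np.nan)
        if statistic == "p_double":
            return np.where(n > 0, a / n, np.nan)
    raise ValueError(
        f"unknown statistic {statistic!r}; expected one of {BOOTSTRAP_STATISTICS}"
    )


def bootstrap_cd(
    table: ContingencyTable2x2,
    statistic: str,
    config: BootstrapConfig | None = None,
) -> ConfidenceDistribution:
    """Nonparametric bootstrap CD of a 2x2-table statistic.

    The resampling unit is the cell: each replicate draws N cells with
    replacement from the four-category multinomial defined by the
    observed table.  Replicates on which the statistic is undefined
    (e.g. a zero margin under ``obs_exp``) are redrawn; if the total
    degenerate fraction exceeds the configured cap the table is too
    sparse to bootstrap and an error reports that fraction.
    """
    if config is None:
        config = BootstrapConfig()
    if statistic not in BOOTSTRAP_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; expected one of {BOOTSTRAP_STATISTICS}"
        )
    n = table.n_total
    if n < 2:
        raise ValueError("bootstrap requires a table with N >= 2 cells")
    observed = _stat_values(np.array([table.as_tuple()]), statistic)[0]
    if np.isnan(observed):
        raise ValueError(
            f"statistic {statistic!r} is undefined on the observed table "
            f"{table.as_tuple()}; cannot bootstrap"
        )
    rng = np.random.default_rng(config.seed)
    probs = np.array(table.as_tuple(), dtype=float) / n
    reps = config.replications

    counts = rng.multinomial(n, probs, size=reps)
    values = _stat_values(counts, statistic)
    n_degenerate = int(np.isnan(values).sum())
    redraws = 0
    while np.isnan(values).any():
        if redraws >= config.max_redraws:
            raise DegenerateResampleError(
                f"redraw cap reached with {np.isnan(values).sum()} degenerate "
                f"resamples outstanding ({n_degenerate / reps:.1%} degenerate overall)"
            )
        bad = np.isnan(values)
        counts_new = rng.multinomial(n, probs, size=int(bad.sum()))
        values[bad] = _stat_values(counts_new, statistic)
        n_degenerate += int(np.isnan(values[bad]).sum())
        if n_degenerate > config.max_degenerate_fraction * reps:
            raise DegenerateResampleError(
                f"{n_degenerate} of {reps + n_degenerate} resamples left "
                f"{statistic!r} undefined "
                f"(> {config.max_degenerate_fraction:.0%}); table too sparse"
            )
        redraws += 1

    grid, counts_unique = np.unique(values, return_counts=True)
    cdf = np.cumsum(counts_unique) / reps
    return ConfidenceDistribution(grid=grid, cdf=cdf, kind="bootstrap")


def normal_cd(
    mean: float, sd: float, half_width_se: float = 8.0, grid_size: int = 4001
) -> ConfidenceDistribution:
    """Normal-kind CD with the given center and spread (sd > 0)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    grid = np.linspace(mean - half_width_se * sd, mean + half_width_se * sd,
                       grid_size)
    return ConfidenceDistribution(
        grid=grid, cdf=stats.norm.cdf(grid, loc=mean, scale=sd), kind="normal"
    )


def cd_point_and_interval(
    cd: ConfidenceDistribution, level: float = 0.95
) -> tuple[float, float, float]:
    """(median, lower, upper) with an equal-tail interval at ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo, hi = cd.interval(level)
    return (cd.median, lo, hi)


def cd_probability_at(cd: ConfidenceDistribution, value: float) -> float:
    """Cumulative confidence H(value); 0/1 outside the grid."""
    return cd.probability_at(value)


def write_cd(cd: ConfidenceDistribution, path) -> None:
    """Serialize a CD as a two-column TSV with a ``# kind`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={cd.kind}\n")
        fh.write("grid\tcdf\n")
        for g, p in zip(cd.grid, cd.cdf):
            fh.write(f"{g:.12g}\t{p:.12g}\n")


def read_cd(path) -> ConfidenceDistribution:
    """Inverse of :func:`write_cd`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# kind="):
            raise ValueError(f"{path}: missing '# kind=' header line")
        kind = header.split("=", 1)[1]
        colnames = fh.readline().strip().split("\t")
        if colnames != ["grid", "cdf"]:
            raise ValueError(f"{path}: expected columns grid, cdf")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ConfidenceDistribution(grid=data[:, 0], cdf=data[:, 1], kind=kind)
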