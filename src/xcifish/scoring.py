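"""Per-cell RNA FISH scoring records and their cross-classification.

A scored nucleus carries, for each of the two X-linked genes (TLR7, TLR8),
a count of primary-transcript foci (0--2, one per transcribing allele) and
flags attributing individual foci to the active X (Xa, identified by a
pooled marker probe for three non-escaping genes) or to an inactive X (Xi).
Cells are cross-classified per donor into 2x2 contingency tables of
TLR8 x TLR7 positivity under three scoring regimes:

``ANY_X``
    every cell in random microscopic fields counts; a gene is positive
    when it shows at least one focus, regardless of chromosome of origin.
``XA_ONLY``
    only cells with a detected Xa marker count, and only foci
    co-localizing with the Xa marker make a gene positive.
``XI_ONLY``
    all cells of the donor count; a gene is positive when a focus is
    attributed to an Xi.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd


class FormatError(ValueError):
    """A cell table file does not conform to the expected layout."""


class ValidationError(ValueError):
    """A record violates the scoring-data invariants."""


class Karyotype(str, Enum):
    XX = "XX"
    XY = "XY"
    XXY = "XXY"

    @property
    def n_xi(self) -> int:
        """Number of inactive X chromosomes per cell."""
        return {"XX": 1, "XY": 0, "XXY": 1}[self.value]


class CellType(str, Enum):
    MONOCYTE = "monocyte"
    CD4_T = "cd4_t"


class Stratum(str, Enum):
    """Scoring regime selecting which cells and which foci count."""

    ANY_X = "any_x"
    XA_ONLY = "xa_only"
    XI_ONLY = "xi_only"


#: Column order of the cell-table TSV dialect (UTF-8, tab-separated,
#: booleans serialized as 0/1).
CELL_TABLE_COLUMNS = (
    "donor_id",
    "group",
    "cell_type",
    "xa_marker",
    "tlr7_foci",
    "tlr8_foci",
    "tlr7_xa",
    "tlr8_xa",
    "tlr7_xi",
    "tlr8_xi",
)

CONTINGENCY_COLUMNS = ("donor_id", "stratum", "a", "b", "c", "d")


@dataclass(frozen=True)
class CellScore:
    """One scored nucleus.

    Focus counts are per gene (0, 1 or 2 transcribing alleles); the
    ``*_xa`` / ``*_xi`` flags attribute at least one focus to the active
    or an inactive X.  Validation enforces biological consistency: XY
    cells have a single X (no Xi, at most one focus per gene); Xa
    co-localization requires a detected Xa marker; and a lone focus can
    only be called Xi when it is seen separate from a patent Xa.
    """

    donor_id: str
    group: Karyotype
    cell_type: CellType
    xa_marker_detected: bool
    tlr7_foci: int
    tlr8_foci: int
    tlr7_xa: bool
    tlr8_xa: bool
    tlr7_xi: bool
    tlr8_xi: bool

    def __post_init__(self) -> None:
        for gene in ("tlr7", "tlr8"):
            foci = getattr(self, f"{gene}_foci")
            on_xa = getattr(self, f"{gene}_xa")
            on_xi = getattr(self, f"{gene}_xi")
            if not isinstance(foci, int) or not 0 <= foci <= 2:
                raise ValidationError(
                    f"{gene}_foci must be an integer in 0..2, got {foci!r}"
                )
            if self.group is Karyotype.XY:
                if foci > 1:
                    raise ValidationError(
                        f"XY cell cannot have {foci} {gene} foci (single X)"
                    )
                if on_xi:
                    raise ValidationError(f"XY cell cannot have an Xi {gene} focus")
            if on_xa and not self.xa_marker_detected:
                raise ValidationError(
                    f"{gene}_xa requires a detected Xa marker (co-localization)"
                )
            if on_xa and on_xi and foci != 2:
                raise ValidationError(
                    f"{gene} on both Xa and Xi requires two foci, got {foci}"
                )
            if (on_xa or on_xi) and foci < 1:
                raise ValidationError(f"{gene} attribution flags set but no focus")
            if on_xi and foci == 1 and not self.xa_marker_detected:
                raise ValidationError(
                    f"single {gene} focus cannot be Xi-attributed without a "
                    "patent Xa marker"
                )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cross-classification of TLR8 x TLR7 positivity for one donor/stratum.

    Layout matches the 2x2 matrix convention with columns TLR7+/TLR7-
    and rows TLR8+/TLR8-::

                TLR7+  TLR7-
        TLR8+     a      b
        TLR8-     c      d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"cell {name} must be a nonnegative integer")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EscapeCounts:
    """Escape bookkeeping for one gene in one donor's cells.

    A cell counts as escaping X inactivation when it shows bi-allelic
    foci or a single focus attributed to the Xi; the denominator is the
    total of cells positive for the gene.
    """

    gene: str
    n_biallelic: int
    n_xi_only: int
    n_positive_total: int

    def __post_init__(self) -> None:
        if self.gene not in ("TLR7", "TLR8"):
            raise ValidationError(f"unknown gene {self.gene!r}")
        if min(self.n_biallelic, self.n_xi_only, self.n_positive_total) < 0:
            raise ValidationError("escape counts must be nonnegative")
        if self.n_biallelic + self.n_xi_only > self.n_positive_total:
            raise ValidationError(
                "escape cells cannot outnumber gene-positive cells"
            )

    @property
    def n_escape(self) -> int:
        return self.n_biallelic + self.n_xi_only


def _parse_bool(value: object, column: str, row: int) -> bool:
    s = str(value).strip()
    if s in ("0", "False", "false"):
        return False
    if s in ("1", "True", "true"):
        return True
    raise FormatError(f"row {row}: column {column!r} is not a 0/1 boolean: {value!r}")


def read_cell_table(path: str | Path) -> list[CellScore]:
    """Read a cell-table TSV into validated :class:`CellScore` records.

    Row order is preserved.  Raises :class:`FormatError` for a missing
    column or unparseable value, :class:`ValidationError` (with the
    0-based data row index) for records violating the invariants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table {path} is missing column(s): {missing}")
    cells: list[CellScore] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            group = Karyotype(getattr(row, "group"))
            cell_type = CellType(getattr(row, "cell_type"))
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from exc
        try:
            foci7 = int(getattr(row, "tlr7_foci"))
            foci8 = int(getattr(row, "tlr8_foci"))
        except ValueError as exc:
            raise FormatError(f"row {i}: focus counts must be integers") from exc
        try:
            cells.append(
                CellScore(
                    donor_id=str(getattr(row, "donor_id")),
                    group=group,
                    cell_type=cell_type,
                    xa_marker_detected=_parse_bool(row.xa_marker, "xa_marker", i),
                    tlr7_foci=foci7,
                    tlr8_foci=foci8,
                    tlr7_xa=_parse_bool(row.tlr7_xa, "tlr7_xa", i),
                    tlr8_xa=_parse_bool(row.tlr8_xa, "tlr8_xa", i),
                    tlr7_xi=_parse_bool(row.tlr7_xi, "tlr7_xi", i),
                    tlr8_xi=_parse_bool(row.tlr8_xi, "tlr8_xi", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return cells


def write_cell_table(cells: Iterable[CellScore], path: str | Path) -> None:
    """Serialize cells to the TSV dialect; round-trips with read_cell_table."""
    rows = [
        {
            "donor_id": c.donor_id,
            "group": c.group.value,
            "cell_type": c.cell_type.value,
            "xa_marker": int(c.xa_marker_detected),
            "tlr7_foci": c.tlr7_foci,
            "tlr8_foci": c.tlr8_foci,
            "tlr7_xa": int(c.tlr7_xa),
            "tlr8_xa": int(c.tlr8_xa),
            "tlr7_xi": int(c.tlr7_xi),
            "tlr8_xi": int(c.tlr8_xi),
        }
        for c in cells
    ]
    df = pd.DataFrame(rows, columns=list(CELL_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def _positive(cell: CellScore, gene: str, stratum: Stratum) -> bool:
    if stratum is Stratum.ANY_X:
        return getattr(cell, f"{gene}_foci") >= 1
    if stratum is Stratum.XA_ONLY:
        return getattr(cell, f"{gene}_xa")
    return getattr(cell, f"{gene}_xi")


def cross_classify(
    cells: Sequence[CellScore], stratum: Stratum
) -> ContingencyTable2x2:
    """Cross-classify one donor's cells into a 2x2 TLR8 x TLR7 table.

    Under ``XA_ONLY`` only cells with a detected Xa marker enter the
    table; under ``ANY_X`` and ``XI_ONLY`` every cell does (the Xi table
    keeps double-negative cells in its denominator, matching the 2x2
    layout of the deposited Xi count tables).  An empty input yields a
    zero table; cells from more than one donor or cell type are an error.
    """
    stratum = Stratum(stratum)
    if len({c.donor_id for c in cells}) > 1:
        raise ValidationError("cross_classify expects cells from a single donor")
    if len({c.cell_type for c in cells}) > 1:
        raise ValidationError("cross_classify expects cells of a single cell type")
    if stratum is Stratum.XA_ONLY:
        cells = [c for c in cells if c.xa_marker_detected]
    a = b = c_ = d = 0
    for cell in cells:
        p7 = _positive(cell, "tlr7", stratum)
        p8 = _positive(cell, "tlr8", stratum)
        if p8 and p7:
            a += 1
        elif p8:
            b += 1
        elif p7:
            c_ += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c_, d)


def escape_counts(cells: Sequence[CellScore], gene: str) -> EscapeCounts:
    """Tally XCI-escape evidence for one gene over one donor's cells.

    Escape cells show either two transcript foci (bi-allelic) or a
    single focus attributed to the Xi.  XY donors have no Xi to score
    and are rejected.
    """
    gene_u = gene.upper()
    if gene_u not in ("TLR7", "TLR8"):
        raise ValidationError(f"unknown gene {gene!r}")
    key = gene_u.lower()
    if any(c.group is Karyotype.XY for c in cells):
        raise ValidationError("escape scoring is undefined for XY donors (no Xi)")
    n_bi = sum(1 for c in cells if getattr(c, f"{key}_foci") == 2)
    n_xi_only = sum(
        1
        for c in cells
        if getattr(c, f"{key}_foci") == 1 and getattr(c, f"{key}_xi")
    )
    n_pos = sum(1 for c in cells if getattr(c, f"{key}_foci") >= 1)
    return EscapeCounts(gene_u, n_bi, n_xi_only, n_pos)


def write_contingency_tables(
    entries: Iterable[tuple[str, Stratum, ContingencyTable2x2]],
    path: str | Path,
) -> None:
    """Write (donor_id, stratum, table) entries as a TSV mirroring the
    deposited per-donor count-table layout."""
    rows = [
        {
            "donor_id": donor,
            "stratum": Stratum(stratum).value,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
        }
        for donor, stratum, t in entries
    ]
    pd.DataFrame(rows, columns=list(CONTINGENCY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_contingency_tables(
    path: str | Path,
) -> list[tuple[str, Stratum, ContingencyTable2x2]]:
    """Inverse of :func:`write_contingency_tables`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CONTINGENCY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contingency table {path} is missing column(s): {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            table = ContingencyTable2x2(
                int(row.a), int(row.b), int(row.c), int(row.d)
            )
            out.append((str(row.donor_id), Stratum(row.stratum), table))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"row {i}: {exc}") from exc
    return out
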