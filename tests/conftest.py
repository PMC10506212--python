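import pytest
from hypothesis import HealthCheck, settings

from xcifish import CellScore, CellType, Karyotype

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cell(
    donor="d1",
    group="XX",
    cell_type="monocyte",
    marker=True,
    foci7=0,
    foci8=0,
    xa7=False,
    xa8=False,
    xi7=False,
    xi8=False,
):
    """Compact CellScore constructor for tests."""
    return CellScore(
        donor_id=donor,
        group=Karyotype(group),
        cell_type=CellType(cell_type),
        xa_marker_detected=marker,
        tlr7_foci=foci7,
        tlr8_foci=foci8,
        tlr7_xa=xa7,
        tlr8_xa=xa8,
        tlr7_xi=xi7,
        tlr8_xi=xi8,
    )


@pytest.fixture
def four_pattern_cells():
    """One cell in each 2x2 positivity category (whole-cell scoring)."""
    return [
        make_cell(foci7=1, foci8=1, xa7=True, xa8=True),
        make_cell(foci7=1, foci8=0, xa7=True),
        make_cell(foci7=0, foci8=1, xa8=True),
        make_cell(foci7=0, foci8=0),
    ]
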