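"""Synthetic-data generator: Plackett coupling, donor and cohort draws."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xcifish import (
    Karyotype,
    SimParams,
    Stratum,
    cross_classify,
    draw_dependent_pair,
    paper_like_preset,
    plackett_joint,
    simulate_cohort,
    simulate_donor,
    true_q_2x2,
    yules_q,
)

probs = st.floats(0.0, 1.0, allow_nan=False)
psis = st.floats(0.01, 100.0, allow_nan=False)


class TestPlackett:
    def test_independence_limit(self):
        assert plackett_joint(0.3, 0.7, 1.0) == pytest.approx(0.21)

    @given(p1=probs, p2=probs, psi=psis)
    def test_root_within_frechet_bounds(self, p1, p2, psi):
        p11 = plackett_joint(p1, p2, psi)
        assert max(0.0, p1 + p2 - 1.0) - 1e-9 <= p11 <= min(p1, p2) + 1e-9

    @given(p1=st.floats(0.05, 0.95), p2=st.floats(0.05, 0.95),
           psi=st.floats(0.05, 20.0))
    def test_root_satisfies_odds_ratio_identity(self, p1, p2, psi):
        """psi = p11*p00 / (p10*p01), i.e. the root solves the Plackett
        quadratic (psi-1)p11^2 - [1+(p1+p2)(psi-1)]p11 + psi*p1*p2 = 0."""
        p11 = plackett_joint(p1, p2, psi)
        resid = (
            (psi - 1) * p11**2
            - (1 + (p1 + p2) * (psi - 1)) * p11
            + psi * p1 * p2
        )
        assert resid == pytest.approx(0.0, abs=1e-9)
        p10, p01 = p1 - p11, p2 - p11
        p00 = 1 - p1 - p2 + p11
        if p10 > 1e-6 and p01 > 1e-6:
            assert p11 * p00 / (p10 * p01) == pytest.approx(psi, rel=1e-6)

    def test_comonotone_limit(self):
        # psi -> infinity with equal marginals: both outcomes coincide
        p11 = plackett_joint(0.5, 0.5, 1e9)
        assert p11 == pytest.approx(0.5, abs=1e-4)
        assert true_q_2x2(0.5, 0.5, 1e6) == pytest.approx(1.0, abs=1e-3)

    def test_empirical_correlation_near_zero_at_psi_one(self):
        rng = np.random.default_rng(3)
        x, y = draw_dependent_pair(0.4, 0.6, 1.0, rng, size=100_000)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.01

    def test_empirical_odds_ratio_matches_psi(self):
        rng = np.random.default_rng(8)
        x, y = draw_dependent_pair(0.4, 0.3, 4.0, rng, size=400_000)
        n11 = np.sum(x & y)
        n10 = np.sum(x & ~y)
        n01 = np.sum(~x & y)
        n00 = np.sum(~x & ~y)
        assert n11 * n00 / (n10 * n01) == pytest.approx(4.0, rel=0.05)

    def test_scalar_draw_returns_booleans(self):
        rng = np.random.default_rng(0)
        x, y = draw_dependent_pair(0.5, 0.5, 2.0, rng)
        assert isinstance(x, bool) and isinstance(y, bool)


class TestSimulateDonor:
    def test_zero_escape_means_no_xi_flags(self):
        params = SimParams(group=Karyotype.XX, n_cells=500, e7=0.0, e8=0.0,
                           heterogeneity=0.0)
        cells, _ = simulate_donor(params, rng=1)
        assert not any(c.tlr7_xi or c.tlr8_xi for c in cells)
        assert not any(c.tlr7_foci == 2 or c.tlr8_foci == 2 for c in cells)

    def test_certain_detection_gives_all_biallelic(self):
        params = SimParams(
            group=Karyotype.XX, n_cells=200,
            p7_xa=1.0, p8_xa=1.0, e7=1.0, e8=1.0,
            psi_xa=1.0, psi_xi=1.0, heterogeneity=0.0,
        )
        cells, _ = simulate_donor(params, rng=2)
        assert all(c.tlr7_foci == 2 and c.tlr8_foci == 2 for c in cells)

    def test_xy_independent_genes_give_near_zero_q(self):
        params = SimParams(
            group=Karyotype.XY, n_cells=20_000,
            p7_xa=0.3, p8_xa=0.3, e7=0.0, e8=0.0,
            psi_xa=1.0, heterogeneity=0.0,
        )
        cells, _ = simulate_donor(params, rng=4)
        q = yules_q(cross_classify(cells, Stratum.ANY_X))
        assert q == pytest.approx(0.0, abs=0.03)

    def test_xy_params_with_escape_rejected(self):
        with pytest.raises(ValueError, match="no Xi"):
            SimParams(group=Karyotype.XY, e7=0.1, e8=0.0)

    def test_all_cells_satisfy_scoring_invariants(self):
        # CellScore validates in __post_init__, so construction succeeding
        # over a stress grid is the check.
        for psi in (0.2, 1.0, 5.0):
            for m_xa in (0.0, 0.35, 1.0):
                params = SimParams(
                    group=Karyotype.XXY, n_cells=300,
                    p7_xa=0.5, p8_xa=0.5, e7=0.3, e8=0.3,
                    psi_xa=psi, psi_xi=psi, m_xa=m_xa, heterogeneity=10.0,
                )
                cells, _ = simulate_donor(params, rng=7)
                assert len(cells) == 300

    def test_realized_params_returned_without_jitter_flag(self):
        params = SimParams(group=Karyotype.XX, heterogeneity=20.0)
        _, realized = simulate_donor(params, rng=9, jitter=False)
        assert realized.p7_xa == params.p7_xa

    def test_empirical_q_tracks_ground_truth(self):
        params = SimParams(
            group=Karyotype.XY, n_cells=30_000,
            p7_xa=0.3, p8_xa=0.4, e7=0.0, e8=0.0,
            psi_xa=0.3, heterogeneity=0.0,
        )
        cells, _ = simulate_donor(params, rng=10)
        q = yules_q(cross_classify(cells, Stratum.ANY_X))
        assert q == pytest.approx(true_q_2x2(0.3, 0.4, 0.3), abs=0.03)


class TestSimulateCohort:
    def test_bookkeeping(self):
        specs = [(SimParams(group=Karyotype.XX, n_cells=300), 6)]
        cells, truth = simulate_cohort(specs, seed=1)
        assert len(cells) == 1800
        assert len({c.donor_id for c in cells}) == 6
        assert len(truth["groups"][0]["donors"]) == 6

    def test_same_seed_identical_cohort(self):
        specs = paper_like_preset(n_cells=50)
        c1, t1 = simulate_cohort(specs, seed=33)
        c2, t2 = simulate_cohort(specs, seed=33)
        assert c1 == c2
        assert t1 == t2

    def test_different_seeds_differ(self):
        specs = [(SimParams(group=Karyotype.XX, n_cells=200), 2)]
        c1, _ = simulate_cohort(specs, seed=1)
        c2, _ = simulate_cohort(specs, seed=2)
        assert c1 != c2

    def test_duplicate_donor_ids_rejected(self):
        p = SimParams(group=Karyotype.XX, n_cells=10)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort([(p, 2), (p, 1)], seed=0)

    def test_increasing_psi_increases_group_q(self):
        """Expected group Q rises monotonically with the in-cis odds ratio."""
        medians = []
        for psi in (0.25, 1.0, 4.0):
            qs = []
            params = SimParams(
                group=Karyotype.XY, n_cells=800,
                p7_xa=0.35, p8_xa=0.45, e7=0.0, e8=0.0,
                psi_xa=psi, heterogeneity=0.0,
            )
            for i in range(20):
                cells, _ = simulate_donor(params, rng=1000 + i)
                qs.append(yules_q(cross_classify(cells, Stratum.ANY_X)))
            medians.append(np.median(qs))
        assert medians[0] < medians[1] < medians[2]

    def test_escape_fraction_converges_to_closed_form(self):
        """With certain Xa detection, every positive cell is positive and
        escape cells are exactly the Xi-transcribing ones: the escape
        fraction converges to e7."""
        e7 = 0.2
        params = SimParams(
            group=Karyotype.XX, n_cells=50_000,
            p7_xa=1.0, p8_xa=1.0, e7=e7, e8=e7,
            psi_xa=1.0, psi_xi=1.0, heterogeneity=0.0,
        )
        cells, _ = simulate_donor(params, rng=5)
        from xcifish import escape_counts, escape_percent

        frac = escape_percent(escape_counts(cells, "TLR7"))
        assert frac == pytest.approx(e7, abs=0.01)
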