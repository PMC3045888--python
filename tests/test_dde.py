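"""AC exact test, R statistic, DE selection and profile clustering."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estmine import (
    DeConfig,
    ParameterError,
    ac_pvalue,
    profile_cluster,
    r_statistic,
    select_de_contigs,
)
from estmine.dde import correlation_distance_matrix, linkage_to_newick, merge_libraries


def ac_oracle(x, y, n1, n2):
    """Exact-rational two-sided AC p-value (independent brute-force oracle).

    Mirrors the implementation's canonical orientation, then sums the tails
    of the conditional law in exact rational arithmetic.
    """
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    r = Fraction(n2, n1)

    def term(yy):
        return (
            r ** yy
            * comb(x + yy, yy)
            / (1 + r) ** (x + yy + 1)
        )

    lower = sum(term(t) for t in range(y + 1))
    upper = 1 - sum(term(t) for t in range(y))  # total probability is 1
    return float(min(1, 2 * min(lower, upper)))


class TestAcPvalue:
    def test_zero_zero_equal_totals_is_one(self):
        assert ac_pvalue(0, 0, 1000, 1000) == 1.0

    def test_equal_counts_equal_totals_is_exactly_one(self):
        for x in (0, 1, 5, 17):
            assert ac_pvalue(x, x, 500, 500) == 1.0

    def test_geometric_closed_form_x_zero(self):
        # upper tail for x=0, n1=n2 is the geometric series sum 2^-y
        from estmine.dde import ac_tails

        for y in range(31):
            _, upper = ac_tails(0, y, 1000, 1000)
            assert upper == pytest.approx(2.0 ** -y, rel=1e-12)

    def test_matches_exact_oracle_on_grid(self):
        for n1, n2 in [(500, 500), (500, 1000), (1000, 5000)]:
            for x in range(0, 21, 4):
                for y in range(0, 21, 3):
                    got = ac_pvalue(x, y, n1, n2)
                    want = ac_oracle(x, y, n1, n2)
                    assert got == pytest.approx(want, abs=1e-10)

    def test_symmetry_for_equal_totals(self):
        for x, y in [(0, 10), (3, 7), (12, 2)]:
            assert ac_pvalue(x, y, 800, 800) == pytest.approx(
                ac_pvalue(y, x, 800, 800), abs=1e-12
            )

    @given(st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_pvalues_in_unit_interval(self, x, y):
        p = ac_pvalue(x, y, 2000, 3000)
        assert 0.0 <= p <= 1.0

    def test_monotone_in_count_difference(self):
        x = 5
        ps = [ac_pvalue(x, y, 1000, 1000) for y in range(x, 40)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ParameterError):
            ac_pvalue(11, 0, 10, 100)
        with pytest.raises(ParameterError):
            ac_pvalue(0, 0, 0, 10)


class TestRStatistic:
    def test_proportional_counts_give_zero(self):
        r, p = r_statistic([5, 10, 15], [500, 1000, 1500])
        assert r == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        r, p = r_statistic([0, 20], [1000, 1000])
        assert r == pytest.approx(20 * np.log(2))

    def test_nonnegative_on_random_vectors(self, rng):
        for _ in range(200):
            m = rng.integers(2, 6)
            totals = rng.integers(300, 3000, size=m)
            counts = rng.poisson(10, size=m)
            r, p = r_statistic(counts, totals)
            assert r >= 0.0
            assert 0.0 <= p <= 1.0

    def test_single_library_rejected(self):
        with pytest.raises(ParameterError):
            r_statistic([5], [100])


class TestSelectDeContigs:
    def _matrix(self):
        libs = [f"L{i}" for i in range(3)]
        data = {
            "flat1": [10, 10, 10],
            "flat2": [3, 3, 4],
            "tiny": [1, 1, 0],          # < 3 ESTs: never tested
            "extreme": [60, 0, 0],      # planted DE
            "flat3": [5, 6, 5],
        }
        m = pd.DataFrame(data, index=libs).T
        return m

    def _totals_ok_cfg(self):
        return DeConfig(min_library_ests=0, min_contig_ests=3)

    def test_planted_extreme_contig_is_the_only_hit(self):
        m = self._matrix()
        # give every library enough depth via a filler row
        m.loc["filler"] = [400, 400, 400]
        res = select_de_contigs(m, DeConfig())
        assert [r.contig_id for r in res] == ["extreme"]
        assert res[0].significant_by >= {"AC"}

    def test_hand_executed_selection_steps(self):
        """Membership equals a by-hand run of merge/filter/test/union."""
        m = self._matrix()
        m.loc["filler"] = [400, 400, 400]
        totals = m.sum(axis=0)
        tested = m[m.sum(axis=1) >= 3]
        n_tested = len(tested)
        expected = set()
        for cid, row in tested.iterrows():
            r, p = r_statistic(row.to_numpy(), totals.to_numpy())
            if p < 0.05 / n_tested:
                expected.add(cid)
            ac_sig = False
            for i in range(3):
                ps = [
                    ac_pvalue(int(row.iloc[i]), int(row.iloc[j]),
                              int(totals.iloc[i]), int(totals.iloc[j]))
                    for j in range(3) if j != i
                ]
                if all(q < 0.05 for q in ps):
                    ac_sig = True
            if ac_sig:
                expected.add(cid)
        got = {r.contig_id for r in select_de_contigs(m, DeConfig())}
        assert got == expected

    def test_shallow_library_dropped_before_testing(self):
        m = self._matrix()
        m.loc["filler"] = [400, 400, 250]  # L2 total < 300
        res = select_de_contigs(m, DeConfig())
        assert all(set(r.profile.index) == {"L0", "L1"} for r in res)

    def test_low_count_contig_never_tested(self):
        m = self._matrix()
        m.loc["filler"] = [400, 400, 400]
        res = select_de_contigs(m, DeConfig())
        assert "tiny" not in {r.contig_id for r in res}

    def test_merge_map_pools_libraries(self):
        m = self._matrix()
        merged = merge_libraries(m, {"L0": "G", "L1": "G"})
        assert list(merged.columns) == ["G", "L2"]
        assert merged.loc["flat1", "G"] == 20

    def test_profile_sums_to_one(self):
        m = self._matrix()
        m.loc["filler"] = [400, 400, 400]
        for r in select_de_contigs(m, DeConfig()):
            assert r.profile.sum() == pytest.approx(1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            select_de_contigs(pd.DataFrame())


class TestProfileCluster:
    class _R:
        def __init__(self, cid, profile):
            self.contig_id = cid
            self.profile = profile

    def _results(self, rows):
        return [
            self._R(cid, pd.Series(v, index=[f"L{i}" for i in range(len(v))]))
            for cid, v in rows.items()
        ]

    def test_identical_profiles_merge_first(self):
        res = self._results({
            "a": [0.5, 0.5, 0.0], "b": [0.5, 0.5, 0.0], "c": [0.0, 0.0, 1.0],
        })
        z, order, mat = profile_cluster(res)
        assert z[0, 2] == pytest.approx(0.0)  # first merge at distance 0
        first_pair = {int(z[0, 0]), int(z[0, 1])}
        assert first_pair == {0, 1}

    def test_anticorrelated_profiles_at_distance_two(self):
        res = self._results({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        dist = correlation_distance_matrix(
            pd.DataFrame({r.contig_id: r.profile for r in res}).T
        )
        assert dist[0] == pytest.approx(2.0)

    def test_row_normalization_example(self):
        row = pd.Series([2, 2, 4], index=["L0", "L1", "L2"], dtype=float)
        norm = row / row.sum()
        assert list(norm) == pytest.approx([0.25, 0.25, 0.5])

    def test_zero_variance_profile_distance_one(self):
        res = self._results({"a": [0.5, 0.5], "b": [0.9, 0.1]})
        dist = correlation_distance_matrix(
            pd.DataFrame({r.contig_id: r.profile for r in res}).T
        )
        assert dist[0] == pytest.approx(1.0)

    def test_leaf_order_covers_all_and_newick_valid(self):
        res = self._results({
            "a": [0.9, 0.1, 0.0], "b": [0.8, 0.2, 0.0],
            "c": [0.0, 0.1, 0.9], "d": [0.1, 0.0, 0.9],
        })
        z, order, mat = profile_cluster(res)
        assert sorted(order) == ["a", "b", "c", "d"]
        nwk = linkage_to_newick(z, list(mat.index))
        for label in "abcd":
            assert label in nwk
        assert nwk.endswith(";")
        # condition blocks separate
        pos = {lab: i for i, lab in enumerate(order)}
        assert abs(pos["a"] - pos["b"]) == 1
        assert abs(pos["c"] - pos["d"]) == 1

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ParameterError):
            profile_cluster(self._results({"a": [1.0, 0.0]}))


class TestNullCalibration:
    def test_ac_type_one_error_at_most_nominal(self, rng):
        """Null Poisson counts: AC rejects at most ~5% (the test is
        conservative)."""
        n1, n2 = 1500, 2500
        lam = 8.0
        n_sim = 2000
        x = rng.poisson(lam, n_sim)
        y = rng.poisson(lam * n2 / n1, n_sim)
        ps = np.array([ac_pvalue(int(a), int(b), n1, n2) for a, b in zip(x, y)])
        frac = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert frac <= 0.05 + 3 * se
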