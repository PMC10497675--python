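import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phagedyn.abundance import AbundanceTable
from phagedyn.dynamics import (
    InteractionPoint,
    bh_adjust,
    donor_shared_fraction,
    host_enrichment,
    interaction_correlation,
    interaction_points,
    novel_fraction,
    spearman,
)
from phagedyn.host_linkage import HostLink


def vp_table(values, samples, features):
    return AbundanceTable(
        data=pd.DataFrame(np.asarray(values, dtype=float), index=samples, columns=features),
        value_kind="rpkm",
    )


META = pd.DataFrame(
    [
        {"sample_id": "p1_d0", "participant_id": "p1", "arm": "FFT", "day": 0, "donor_id": "d1", "fraction": "WGS"},
        {"sample_id": "p1_d2", "participant_id": "p1", "arm": "FFT", "day": 2, "donor_id": "d1", "fraction": "WGS"},
        {"sample_id": "p1_d28", "participant_id": "p1", "arm": "FFT", "day": 28, "donor_id": "d1", "fraction": "WGS"},
        {"sample_id": "d1_base", "participant_id": "d1", "arm": "donor", "day": None, "donor_id": "", "fraction": "WGS"},
    ]
)


class TestDonorShared:
    def test_no_shared_vp(self):
        t = vp_table(
            [[1, 1, 0], [2, 2, 0], [1, 1, 0], [0, 0, 5]],
            ["p1_d0", "p1_d2", "p1_d28", "d1_base"],
            ["v1", "v2", "v3"],
        )
        assert donor_shared_fraction(t, META, "p1", 2) == 0.0

    def test_all_abundance_on_donor_vps(self):
        t = vp_table(
            [[0, 0, 1], [0, 0, 4], [0, 0, 1], [0, 0, 5]],
            ["p1_d0", "p1_d2", "p1_d28", "d1_base"],
            ["v1", "v2", "v3"],
        )
        assert donor_shared_fraction(t, META, "p1", 2) == 100.0

    def test_empty_sample_zero(self):
        t = vp_table(
            [[1, 0, 0], [0, 0, 0], [1, 0, 0], [0, 0, 5]],
            ["p1_d0", "p1_d2", "p1_d28", "d1_base"],
            ["v1", "v2", "v3"],
        )
        assert donor_shared_fraction(t, META, "p1", 2) == 0.0

    def test_partial_share(self):
        t = vp_table(
            [[1, 1, 0], [3, 0, 1], [1, 1, 0], [0, 0, 5]],
            ["p1_d0", "p1_d2", "p1_d28", "d1_base"],
            ["v1", "v2", "v3"],
        )
        assert donor_shared_fraction(t, META, "p1", 2) == pytest.approx(25.0)

    def test_missing_donor_sample_raises(self):
        meta = META[META["arm"] != "donor"]
        t = vp_table([[1], [1], [1]], ["p1_d0", "p1_d2", "p1_d28"], ["v1"])
        with pytest.raises(KeyError):
            donor_shared_fraction(t, meta, "p1", 2)


class TestNovelFraction:
    T = vp_table(
        [[2, 3, 0], [2, 3, 0], [0, 1, 3], [0, 0, 5]],
        ["p1_d0", "p1_d2", "p1_d28", "d1_base"],
        ["v1", "v2", "v3"],
    )

    def test_identical_to_baseline_zero(self):
        assert novel_fraction(self.T, META, "p1", 2) == 0.0

    def test_mixed(self):
        assert novel_fraction(self.T, META, "p1", 28) == pytest.approx(75.0)

    def test_day0_is_zero_by_definition(self):
        assert novel_fraction(self.T, META, "p1", 0) == 0.0

    def test_all_new(self):
        t = vp_table(
            [[5, 0, 0], [0, 1, 3], [0, 0, 0], [0, 0, 5]],
            ["p1_d0", "p1_d2", "p1_d28", "d1_base"],
            ["v1", "v2", "v3"],
        )
        assert novel_fraction(t, META, "p1", 2) == 100.0

    def test_missing_baseline_raises(self):
        meta = META[META["day"] != 0]
        with pytest.raises(KeyError):
            novel_fraction(self.T, meta, "p1", 2)

    def test_bounds(self):
        for day in (0, 2, 28):
            assert 0.0 <= novel_fraction(self.T, META, "p1", day) <= 100.0


class TestInteractionPoints:
    def _tables(self):
        # proportions already: one VP + one MAG species; VP 0.10 -> 0.20,
        # MAG 0.30 -> 0.10 between day 0 and 2
        vp = vp_table(
            [[0.10, 0.90], [0.20, 0.80]], ["p1_d0", "p1_d2"], ["v1", "vx"]
        )
        mag = AbundanceTable(
            data=pd.DataFrame(
                [[0.30, 0.70], [0.10, 0.90]], index=["p1_d0", "p1_d2"], columns=["m1", "mx"]
            ),
            value_kind="count",
        )
        meta = META[META["day"].isin([0, 2])]
        links = [HostLink("v1", "m1", "Sp", "crispr")]
        return vp, mag, meta, links

    def test_single_pair_definition(self):
        vp, mag, meta, links = self._tables()
        (pt,) = interaction_points(vp, mag, links, meta, 0, 2)
        assert pt.delta_vp == pytest.approx(0.10)
        assert pt.delta_mag == pytest.approx(-0.20)
        assert pt.species == "Sp"

    def test_two_vps_mean(self):
        vp = vp_table(
            [[0.10, 0.30, 0.60], [0.20, 0.20, 0.60]], ["p1_d0", "p1_d2"], ["v1", "v2", "vx"]
        )
        mag = AbundanceTable(
            data=pd.DataFrame([[1.0], [1.0]], index=["p1_d0", "p1_d2"], columns=["m1"]),
            value_kind="count",
        )
        links = [HostLink("v1", "m1", "Sp", "crispr"), HostLink("v2", "m1", "Sp", "crispr")]
        meta = META[META["day"].isin([0, 2])]
        (pt,) = interaction_points(vp, mag, links, meta, 0, 2)
        assert pt.delta_vp == pytest.approx(0.0)  # (+0.10 - 0.10) / 2

    def test_silent_species_omitted(self):
        vp = vp_table([[0.0, 1.0], [0.0, 1.0]], ["p1_d0", "p1_d2"], ["v1", "vx"])
        mag = AbundanceTable(
            data=pd.DataFrame([[1.0], [1.0]], index=["p1_d0", "p1_d2"], columns=["m1"]),
            value_kind="count",
        )
        links = [HostLink("v1", "m1", "Sp", "crispr")]
        meta = META[META["day"].isin([0, 2])]
        assert interaction_points(vp, mag, links, meta, 0, 2) == []

    def test_clr_scale_runs(self):
        vp, mag, meta, links = self._tables()
        (pt,) = interaction_points(vp, mag, links, meta, 0, 2, scale="clr")
        assert math.isfinite(pt.delta_vp) and math.isfinite(pt.delta_mag)

    def test_bad_scale(self):
        vp, mag, meta, links = self._tables()
        with pytest.raises(ValueError):
            interaction_points(vp, mag, links, meta, 0, 2, scale="log")


def pts(xs, ys, participant="p1"):
    return [
        InteractionPoint(participant, f"sp{i}", (0, 2), x, y) for i, (x, y) in enumerate(zip(xs, ys))
    ]


class TestSpearman:
    def test_strictly_decreasing_rho_minus_one(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 8, 5, 3, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_for_perfect_monotone_n5(self):
        # only the two perfectly monotone rank orders reach |rho| = 1
        rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_constant_input_nan(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])

    def test_t_approx_path(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        assert -1 <= rho <= 1 and 0 <= p <= 1


class TestInteractionCorrelation:
    def test_identical_groups_identical_results(self):
        xs, ys = [1, 2, 3, 4], [4, 1, 3, 2]
        points = pts(xs, ys, "p1") + pts(xs, ys, "p2")
        out = interaction_correlation(points, {"p1": "FFT", "p2": "placebo"})
        assert out["FFT"] == out["placebo"]

    def test_groups_below_three_points_skipped(self):
        out = interaction_correlation(pts([1, 2], [2, 1]), {"p1": "FFT"})
        assert out == {}


def enumeration_enrichment_p(universe, species_vps, da, q):
    """Oracle: exhaustive count of k-subsets with >= q species members."""
    k = len(da)
    hits = 0
    total = 0
    for draw in itertools.combinations(sorted(universe), k):
        total += 1
        if len(set(draw) & species_vps) >= q:
            hits += 1
    return hits / total


class TestHostEnrichment:
    def test_hand_value(self):
        # m=5, n=15, k=4, q=3 -> (C(5,3)C(15,1)+C(5,4)C(15,0))/C(20,4)
        host = {f"v{i}": {"A"} for i in range(5)}
        host.update({f"v{i}": {"B"} for i in range(5, 20)})
        da = ["v0", "v1", "v2", "v5"]
        res = {r.species: r for r in host_enrichment(da, host)}
        assert res["A"].q == 3 and res["A"].m == 5 and res["A"].n == 15 and res["A"].k == 4
        assert res["A"].p == pytest.approx(155 / 4845)
        assert res["A"].p == pytest.approx(0.03199, abs=1e-5)

    def test_single_species_universe_p1(self):
        host = {f"v{i}": {"A"} for i in range(10)}
        res = host_enrichment(["v0", "v1", "v2"], host)
        assert len(res) == 1 and res[0].p == pytest.approx(1.0)

    def test_species_without_da_vp_not_tested(self):
        host = {"v1": {"A"}, "v2": {"B"}}
        res = host_enrichment(["v1"], host)
        assert [r.species for r in res] == ["A"]

    def test_unhosted_da_vps_excluded_from_k(self):
        host = {"v1": {"A"}, "v2": {"A"}, "v3": {"B"}}
        res = host_enrichment(["v1", "vUNLINKED"], host)
        assert res[0].k == 1

    def test_multi_species_vp_counts_in_each(self):
        host = {"v1": {"A", "B"}, "v2": {"A"}, "v3": {"B"}}
        res = {r.species: r for r in host_enrichment(["v1"], host)}
        assert res["A"].m == 2 and res["B"].m == 2
        assert res["A"].q == 1 and res["B"].q == 1

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(8):
            n_universe = int(rng.integers(6, 13))
            universe = [f"v{i}" for i in range(n_universe)]
            m = int(rng.integers(2, n_universe - 1))
            species_vps = set(universe[:m])
            host = {v: ({"A"} if v in species_vps else {"B"}) for v in universe}
            k = int(rng.integers(2, n_universe))
            da = list(rng.choice(universe, size=k, replace=False))
            res = {r.species: r for r in host_enrichment(da, host)}
            q = len(set(da) & species_vps)
            if q == 0:
                assert "A" not in res
                continue
            oracle = enumeration_enrichment_p(universe, species_vps, da, q)
            assert res["A"].p == pytest.approx(oracle, abs=1e-12)

    def test_p_adj_at_least_p(self):
        host = {f"v{i}": {f"S{i % 4}"} for i in range(20)}
        res = host_enrichment([f"v{i}" for i in range(6)], host)
        assert all(r.p_adj >= r.p - 1e-12 for r in res)


class TestBhAdjust:
    def test_hand_example(self):
        p = [0.01, 0.04, 0.03, 0.50]
        adj = bh_adjust(p)
        # sorted p: .01,.03,.04,.5 -> raw adj .04,.06,.053->.06? monotone from top:
        # rank4: .5; rank3: .04*4/3=.0533; rank2: .03*2=.06->min(.0533)=.0533; rank1: .04
        assert adj[0] == pytest.approx(0.04)
        assert adj[1] == pytest.approx(0.05333333, abs=1e-6)
        assert adj[2] == pytest.approx(0.05333333, abs=1e-6)
        assert adj[3] == pytest.approx(0.5)

    def test_matches_scipy(self):
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        assert np.allclose(bh_adjust(p), false_discovery_control(p, method="bh"))
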