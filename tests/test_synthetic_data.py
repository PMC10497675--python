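import numpy as np
import pandas as pd
import pytest

from phagedyn.abundance import to_proportions
from phagedyn.clinical import ogtt_auc, time_in_range
from phagedyn.dynamics import donor_shared_fraction
from phagedyn.host_linkage import filter_spacer_hits
from phagedyn.synthetic_data import (
    ScenarioConfig,
    SyntheticTruth,
    expected_novel_fraction,
    generate_ani_pairs,
    generate_cgm_trace,
    generate_community,
    generate_ogtt_curve,
    generate_spacer_hits,
    generate_triage_fixture,
    make_truth,
)
from phagedyn.viral_triage import classify_viral


SMALL = ScenarioConfig(n_participants=3, days=(0, 2, 28), n_vps=30, n_mags=8, n_species=4, seed=11)


class TestScenarioConfig:
    def test_days_must_increase(self):
        with pytest.raises(ValueError):
            ScenarioConfig(days=(0, 2, 2))

    def test_day0_required(self):
        with pytest.raises(ValueError):
            ScenarioConfig(days=(2, 7))

    def test_positive_counts(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_vps=0)


class TestSyntheticTruth:
    def test_sign_must_match_regime(self):
        kw = dict(
            viral_labels={"c": True},
            cluster_assignment={"c": "v"},
            true_links=set(),
            engraftment_fraction=0.1,
            novelty_rate=0.1,
            noise_sd=0.5,
        )
        with pytest.raises(ValueError):
            SyntheticTruth(coupling_beta=0.5, regime="antagonistic", **kw)
        with pytest.raises(ValueError):
            SyntheticTruth(coupling_beta=-0.5, regime="protagonistic", **kw)
        with pytest.raises(ValueError):
            SyntheticTruth(coupling_beta=0.1, regime="null", **kw)

    def test_labels_and_clusters_cover_same_contigs(self):
        with pytest.raises(ValueError):
            SyntheticTruth(
                viral_labels={"c1": True},
                cluster_assignment={"c1": "v", "c2": "v"},
                true_links=set(),
                engraftment_fraction=0.0,
                novelty_rate=0.0,
                coupling_beta=0.0,
                noise_sd=0.5,
                regime="null",
            )


class TestTriageFixture:
    def test_all_16_evidence_combinations(self):
        annotations, _ = generate_triage_fixture(16, seed=1)
        combos = {
            (
                a.viral_gene_count >= 1,
                a.host_gene_count >= 1,
                a.vs_score is not None and a.vs_score >= 0.95,
                a.hallmark_count >= 2,
            )
            for a in annotations
        }
        assert len(combos) == 16

    def test_label_is_or_of_criteria(self):
        annotations, truth = generate_triage_fixture(64, seed=2)
        for a in annotations:
            assert truth.viral_labels[a.contig_id] == classify_viral(a)

    def test_single_viral_gene_labels_true(self):
        annotations, truth = generate_triage_fixture(64, seed=3)
        for a in annotations:
            if a.viral_gene_count >= 1:
                assert truth.viral_labels[a.contig_id] is True

    def test_fails_all_disjuncts_labels_false(self):
        annotations, truth = generate_triage_fixture(64, seed=4)
        negatives = [
            a
            for a in annotations
            if a.viral_gene_count == 0
            and a.host_gene_count >= 1
            and (a.vs_score is None or a.vs_score < 0.95)
            and a.hallmark_count < 2
        ]
        assert negatives
        assert all(truth.viral_labels[a.contig_id] is False for a in negatives)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            generate_triage_fixture(0, seed=1)

    def test_determinism(self):
        a1, t1 = generate_triage_fixture(32, seed=9)
        a2, t2 = generate_triage_fixture(32, seed=9)
        assert a1 == a2 and t1.viral_labels == t2.viral_labels


class TestAniPairs:
    def test_two_clusters_of_three(self):
        assignment = {f"c{i}": ("A" if i < 3 else "B") for i in range(6)}
        pairs = generate_ani_pairs(assignment, 95.0, seed=0)
        within = [p for p in pairs if assignment[p.query_id] == assignment[p.subject_id]]
        between = [p for p in pairs if assignment[p.query_id] != assignment[p.subject_id]]
        assert len(within) == 12  # 2 clusters x C(3,2) x 2 orientations
        assert all(p.ani_pct >= 95.0 for p in within)
        assert all(p.ani_pct < 95.0 for p in between)
        assert all(p.query_id != p.subject_id for p in pairs)

    def test_singleton_cluster_no_within_pairs(self):
        assignment = {"c0": "A", "c1": "B", "c2": "B"}
        pairs = generate_ani_pairs(assignment, 95.0, seed=0)
        assert not any(
            assignment[p.query_id] == assignment[p.subject_id] and "c0" in (p.query_id, p.subject_id)
            for p in pairs
        )

    def test_determinism(self):
        assignment = {f"c{i}": f"K{i % 2}" for i in range(6)}
        assert generate_ani_pairs(assignment, 95.0, seed=3) == generate_ani_pairs(assignment, 95.0, seed=3)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            generate_ani_pairs({"c": "A"}, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_ani_pairs({}, 95.0, seed=0)


class TestCommunity:
    def test_determinism(self):
        t = make_truth(SMALL, regime="antagonistic")
        fx1 = generate_community(SMALL, t)
        fx2 = generate_community(SMALL, t)
        pd.testing.assert_frame_equal(fx1.vp_counts.data, fx2.vp_counts.data)
        pd.testing.assert_frame_equal(fx1.mag_counts.data, fx2.mag_counts.data)
        pd.testing.assert_frame_equal(fx1.metadata, fx2.metadata)
        assert fx1.coverage == fx2.coverage

    def test_counts_nonnegative_integers(self):
        t = make_truth(SMALL)
        fx = generate_community(SMALL, t)
        vals = fx.vp_counts.data.to_numpy()
        assert (vals >= 0).all()
        assert np.array_equal(vals, vals.astype(int))

    def test_proportions_close_to_one(self):
        t = make_truth(SMALL)
        fx = generate_community(SMALL, t)
        props = to_proportions(fx.vp_counts)
        sums = props.data.sum(axis=1).to_numpy()
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)

    def test_library_sizes_recorded(self):
        t = make_truth(SMALL)
        fx = generate_community(SMALL, t)
        for s in fx.vp_counts.sample_ids:
            assert fx.vp_counts.library_size[s] == fx.vp_counts.data.loc[s].sum()

    def test_zero_engraftment_means_zero_donor_share(self):
        t = make_truth(SMALL, engraftment_fraction=0.0)
        fx = generate_community(SMALL, t)
        rpkm_like = fx.vp_counts  # counts are fine for a share of zero
        meta = fx.metadata
        for p in [f"FFT{i:02d}" for i in range(1, 4)]:
            for day in (2, 28):
                assert donor_shared_fraction(rpkm_like, meta, p, day) == 0.0

    def test_dimension_mismatch_rejected(self):
        t = make_truth(SMALL)
        other = ScenarioConfig(n_participants=3, days=(0, 2), n_vps=31, n_mags=8, n_species=4)
        with pytest.raises(ValueError):
            generate_community(other, t)

    def test_novel_vps_absent_at_day0(self):
        t = make_truth(SMALL, novelty_rate=0.2)
        fx = generate_community(SMALL, t)
        meta = fx.metadata
        day0 = meta[(meta["day"] == 0) & meta["arm"].isin(["FFT", "placebo"])]["sample_id"]
        novel_cols = fx.vp_counts.data.columns[-5:]  # novel pool is the id tail
        assert fx.vp_counts.data.loc[day0, novel_cols].to_numpy().sum() == 0

    def test_expected_novel_fraction_closed_form(self):
        t = make_truth(SMALL, engraftment_fraction=0.25, novelty_rate=0.1)
        assert expected_novel_fraction(t, "FFT") == pytest.approx(0.35)
        assert expected_novel_fraction(t, "placebo") == pytest.approx(0.1)


class TestSpacerHitGeneration:
    LINKS = {("VP0001", "MAG0001"), ("VP0002", "MAG0002"), ("VP0003", "MAG0001")}

    def test_zero_decoys_reproduce_links(self):
        hits, flags = generate_spacer_hits(self.LINKS, 0.0, seed=1)
        assert not any(flags)
        links = filter_spacer_hits(hits, {v: v for v, _ in self.LINKS})
        assert {(l.vp_id, l.mag_id) for l in links} == self.LINKS

    def test_decoys_violate_exactly_one_filter(self):
        hits, flags = generate_spacer_hits(self.LINKS, 0.5, seed=2)
        for h, is_decoy in zip(hits, flags):
            length_ok = 20 <= h.spacer_len <= 30
            mm_ok = h.mismatches <= 2
            if is_decoy:
                assert length_ok != mm_ok  # exactly one violated
            else:
                assert length_ok and mm_ok

    def test_empty_links_returns_only_decoys(self):
        hits, flags = generate_spacer_hits(set(), 0.4, seed=3)
        assert hits and all(flags)

    def test_bad_decoy_rate(self):
        with pytest.raises(ValueError):
            generate_spacer_hits(self.LINKS, 1.0, seed=0)


class TestClinicalFixtures:
    def test_constant_trace_full_tir(self):
        trace = generate_cgm_trace(seed=0, minutes=600, mean=5.0, sd=0.0)
        assert time_in_range(trace) == 100.0

    def test_spacing_is_15_minutes(self):
        trace = generate_cgm_trace(seed=0, minutes=600, mean=5.0, sd=1.0)
        assert np.allclose(np.diff(trace.timestamps_min), 15.0)

    def test_reproducible(self):
        assert generate_cgm_trace(seed=5, minutes=300, mean=6, sd=1) == generate_cgm_trace(
            seed=5, minutes=300, mean=6, sd=1
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_cgm_trace(seed=0, minutes=0, mean=5, sd=1)
        with pytest.raises(ValueError):
            generate_cgm_trace(seed=0, minutes=60, mean=5, sd=-1)

    def test_ogtt_grid_and_auc(self):
        curve = generate_ogtt_curve(seed=4)
        assert curve.minutes == (0, 15, 30, 45, 60, 90, 120)
        assert ogtt_auc(curve) > 0
        assert generate_ogtt_curve(seed=4) == generate_ogtt_curve(seed=4)
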