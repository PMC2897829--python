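import numpy as np
import pandas as pd
import pytest

from cnvclass import features, simulate
from cnvclass.calling import GAIN, LOSS, NORMAL, ArrayStats
from cnvclass.features import (
    FEATURE_COLUMNS,
    build_feature_matrix,
    cohort_features,
    database_score,
    database_score_ii,
    demographic_features,
    probe_variant_counts,
    spatial_features,
)
from cnvclass.genome_io import DGVRecord, ValidationError
from cnvclass.pipeline import call_cohort
from conftest import make_called, make_candidate, make_profile


def dgv_record(vid, chrom, start, end, study="s1", n_ind=None):
    return DGVRecord(variation_id=vid, chromosome=chrom, start=start, end=end,
                     study_id=study, n_individuals=n_ind)


def brute_force_counts(dgv, profile):
    """Independent per-probe recount: scan every record for every probe."""
    nv, ni = {}, {}
    for chrom in profile.chromosome_names:
        pos, _ = profile.chrom_data(chrom)
        for p in pos:
            v = [r for r in dgv if r.chromosome == chrom and r.start <= p < r.end]
            nv[(chrom, int(p))] = len(v)
            ni[(chrom, int(p))] = sum(r.n_individuals or 0 for r in v)
    return nv, ni


def random_dgv(rng, chroms=("1", "2"), n=30, span_max=5000):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, 50_000))
        out.append(dgv_record(
            f"V{i}", chrom, start, start + int(rng.integers(100, span_max)),
            study=f"s{int(rng.integers(0, 4))}",
            n_ind=int(rng.integers(0, 50)) if rng.random() < 0.7 else None,
        ))
    return out


class TestProbeVariantCounts:
    def test_uncovered_probe_is_zero(self):
        prof = make_profile("S1", {"1": [100, 5000]}, {"1": [0.0, 0.0]})
        counts = probe_variant_counts([dgv_record("V1", "1", 200, 400)], prof)
        assert counts.at("1", 100) == (0, 0)

    def test_three_variants_summed(self):
        prof = make_profile("S1", {"1": [250]}, {"1": [0.0]})
        dgv = [
            dgv_record("V1", "1", 200, 400, n_ind=10),
            dgv_record("V2", "1", 100, 300, n_ind=20),
            dgv_record("V3", "1", 0, 1000, n_ind=0),
        ]
        assert probe_variant_counts(dgv, prof).at("1", 250) == (3, 30)

    def test_half_open_containment_at_converted_end(self):
        prof = make_profile("S1", {"1": [400]}, {"1": [0.0]})
        assert probe_variant_counts([dgv_record("V1", "1", 200, 400)], prof).at(
            "1", 400) == (0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(100, 60_000, 7), 40, replace=False))
        prof = make_profile("S1", {"1": pos, "2": pos + 3}, None, rng)
        dgv = random_dgv(rng)
        counts = probe_variant_counts(dgv, prof)
        nv, ni = brute_force_counts(dgv, prof)
        for chrom in ("1", "2"):
            p, _ = prof.chrom_data(chrom)
            for x in p:
                assert counts.at(chrom, int(x)) == (nv[(chrom, int(x))], ni[(chrom, int(x))])


class TestDatabaseScores:
    def _candidate_with_counts(self, per_probe):
        pos = np.array([1000 * (i + 1) for i in range(len(per_probe))])
        prof = make_profile("S1", {"1": pos}, {"1": np.zeros(len(pos))})
        dgv = []
        vid = 0
        for p, (n_var, n_ind_each) in zip(pos, per_probe):
            for _ in range(n_var):
                dgv.append(dgv_record(f"V{vid}", "1", int(p) - 1, int(p) + 1,
                                      n_ind=n_ind_each))
                vid += 1
        cand = make_candidate(start=int(pos[0]) - 10, end=int(pos[-1]) + 10)
        return cand, probe_variant_counts(dgv, prof)

    def test_mean_of_variant_counts(self):
        cand, counts = self._candidate_with_counts([(2, 0), (3, 0), (4, 0)])
        assert database_score(cand, counts) == 3.0

    def test_no_overlap_scores_zero(self):
        cand, counts = self._candidate_with_counts([(0, 0), (0, 0)])
        assert database_score(cand, counts) == 0.0
        assert database_score_ii(cand, counts) == 0.0

    def test_score_ii_averages_individuals(self):
        cand, counts = self._candidate_with_counts([(1, 10), (1, 30)])
        assert database_score_ii(cand, counts) == 20.0

    def test_no_probes_is_error(self):
        prof = make_profile("S1", {"1": [100]}, {"1": [0.0]})
        counts = probe_variant_counts([], prof)
        cand = make_candidate(chrom="1", start=500, end=600)
        with pytest.raises(ValidationError):
            database_score(cand, counts)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_recount(self, seed):
        rng = np.random.default_rng(100 + seed)
        pos = np.sort(rng.choice(np.arange(100, 60_000, 11), 30, replace=False))
        prof = make_profile("S1", {"1": pos}, None, rng)
        dgv = random_dgv(rng, chroms=("1",))
        counts = probe_variant_counts(dgv, prof)
        cand = make_candidate(start=int(pos[5]) - 1, end=int(pos[20]) + 1)
        nv, ni = brute_force_counts(dgv, prof)
        in_cand = [int(p) for p in pos if cand.start <= p < cand.end]
        assert database_score(cand, counts) == pytest.approx(
            np.mean([nv[("1", p)] for p in in_cand]))
        assert database_score_ii(cand, counts) == pytest.approx(
            np.mean([ni[("1", p)] for p in in_cand]))

    def test_adding_covering_variant_adds_exactly_one(self):
        rng = np.random.default_rng(3)
        pos = np.arange(1000, 30_000, 1000)
        prof = make_profile("S1", {"1": pos}, None, rng)
        dgv = random_dgv(rng, chroms=("1",), n=10)
        cand = make_candidate(start=5000, end=20_000)
        before = database_score(cand, probe_variant_counts(dgv, prof))
        dgv2 = dgv + [dgv_record("Vcover", "1", 0, 30_000)]
        after = database_score(cand, probe_variant_counts(dgv2, prof))
        assert after == pytest.approx(before + 1.0)


class TestDemographicFeatures:
    def _called(self):
        return make_called("S1", "1", [
            (0, 1_000_000, 100, 0.1, NORMAL),
            (1_000_000, 1_100_000, 10, 0.5, GAIN),
            (1_100_000, 3_000_000, 190, 0.4, NORMAL),
        ])

    def test_break_score_hand_computation(self, bare_annotation):
        stats = ArrayStats("S1", 0.0, 0.1, 0.1)
        cand = make_candidate(start=1_000_000, end=1_100_000, mean=0.5)
        f = demographic_features(cand, self._called(), stats, bare_annotation)
        assert f["break_score"] == pytest.approx(abs(0.1 - 0.4) / 0.1)
        assert f["height"] == 0.5
        assert f["relative_height"] == pytest.approx(5.0)
        assert f["length_bp"] == 100_000
        assert f["sign"] == 1

    def test_near_centromere_window(self, bare_annotation):
        stats = ArrayStats("S1", 0.0, 0.1, 0.1)
        # centromere at 14.5-15.5 Mb; candidate end within 2 Mb of its start
        cand = make_candidate(start=12_400_000, end=12_600_000)
        f = demographic_features(cand, [], stats, bare_annotation)
        assert f["near_centromere"] == 1
        far = make_candidate(start=5_000_000, end=5_100_000)
        assert demographic_features(far, [], stats, bare_annotation)["near_centromere"] == 0

    def test_near_telomere_uses_chromosome_ends(self, bare_annotation):
        stats = ArrayStats("S1", 0.0, 0.1, 0.1)
        f = demographic_features(
            make_candidate(start=1_500_000, end=1_600_000), [], stats, bare_annotation)
        assert f["near_telomere"] == 1
        f = demographic_features(
            make_candidate(start=28_500_000, end=28_600_000), [], stats, bare_annotation)
        assert f["near_telomere"] == 1
        f = demographic_features(
            make_candidate(start=10_000_000, end=10_100_000), [], stats, bare_annotation)
        assert f["near_telomere"] == 0

    def test_one_aberrant_flank_not_surrounded(self, bare_annotation):
        stats = ArrayStats("S1", 0.0, 0.1, 0.1)
        cand = make_candidate(left=LOSS)
        f = demographic_features(cand, [], stats, bare_annotation)
        assert f["surrounded_by_normals"] == 0

    def test_scale_invariance_of_normalised_features(self, bare_annotation):
        called = self._called()
        cand = make_candidate(start=1_000_000, end=1_100_000, mean=0.5)
        stats = ArrayStats("S1", 0.0, 0.1, 0.1)
        f1 = demographic_features(cand, called, stats, bare_annotation)
        scale = 4.0
        called_s = make_called("S1", "1", [
            (s.start, s.end, s.n_markers, s.mean * scale, s.status) for s in called])
        cand_s = make_candidate(start=1_000_000, end=1_100_000, mean=0.5 * scale)
        stats_s = ArrayStats("S1", 0.0, 0.1 * scale, 0.1 * scale)
        f2 = demographic_features(cand_s, called_s, stats_s, bare_annotation)
        assert f2["relative_height"] == pytest.approx(f1["relative_height"])
        assert f2["break_score"] == pytest.approx(f1["break_score"])


class TestCohortFeatures:
    def test_mixed_signs_give_gl_and_full_overlap(self):
        cand = make_candidate(sample="P1", start=100_000, end=200_000, status=GAIN)
        cohort = {
            "P1": [cand],
            "P2": [make_candidate(sample="P2", start=150_000, end=250_000, status=GAIN)],
            "P3": [make_candidate(sample="P3", start=90_000, end=160_000,
                                  status=LOSS, mean=-0.5)],
        }
        f = cohort_features(cand, cohort, {})
        assert f["overlap_pattern"] == "GL"
        assert f["overlap_pct"] == 1.0

    def test_no_overlap_gives_none_pattern(self):
        cand = make_candidate(sample="P1")
        cohort = {"P1": [cand], "P2": [], "P3": []}
        f = cohort_features(cand, cohort, {})
        assert f["overlap_pattern"] == "None"
        assert f["overlap_pct"] == 0.0 and f["matching_bkpt_pct"] == 0.0

    def test_exact_breakpoint_counting_on_toy_cohort(self):
        cand = make_candidate(sample="P1", start=100_000, end=200_000)
        cohort = {
            "P1": [cand],
            # abuts: its end equals our start (matching breakpoint, no intersection)
            "P2": [make_candidate(sample="P2", start=50_000, end=100_000)],
            # intersects without matching breakpoints
            "P3": [make_candidate(sample="P3", start=150_000, end=260_000)],
            # no overlap at all
            "P4": [make_candidate(sample="P4", start=900_000, end=950_000)],
        }
        f = cohort_features(cand, cohort, {})
        assert f["matching_bkpt_pct"] == pytest.approx(1 / 3)
        assert f["overlap_pct"] == pytest.approx(1 / 3)

    def test_cna_overlap_counts_same_sign_patients(self):
        cand = make_candidate(sample="P1", start=100_000, end=200_000, status=GAIN)
        noncand = {
            "P2": make_called("P2", "1", [(0, 5_000_000, 100, 0.4, GAIN)]),
            "P3": make_called("P3", "1", [(0, 5_000_000, 100, -0.4, LOSS)]),
        }
        cohort = {"P1": [cand], "P2": [], "P3": []}
        f = cohort_features(cand, cohort, noncand)
        assert f["overlap_with_cnas"] == 1

    def test_cohort_of_one_patient_degenerates_to_zeros(self):
        cand = make_candidate(sample="P1")
        f = cohort_features(cand, {"P1": [cand]}, {})
        assert f["overlap_pct"] == 0.0 and f["overlap_pattern"] == "None"


class TestSpatialFeatures:
    def test_lone_candidate(self):
        cand = make_candidate()
        segs = make_called("S1", "1", [(0, 10_000_000, 1000, 0.0, NORMAL)])
        f = spatial_features(cand, [cand], segs, {cand.key: 2.0})
        assert f["close_to_other_candidates"] == 0
        assert f["ds_other_candidates"] == 0.0

    def test_candidate_400kb_away_is_close(self):
        cand = make_candidate(start=1_000_000, end=1_100_000)
        other = make_candidate(start=1_500_000, end=1_600_000)
        f = spatial_features(cand, [cand, other], [], {cand.key: 0.0, other.key: 3.0})
        assert f["close_to_other_candidates"] == 1
        assert f["ds_other_candidates"] == 3.0

    def test_pct_normal_marker_weighted(self):
        segs = make_called("S1", "1", [
            (0, 9_000_000, 900, 0.0, NORMAL),
            (9_000_000, 10_000_000, 100, 0.5, GAIN),
        ])
        f = spatial_features(make_candidate(), [], segs, {})
        assert f["pct_normal"] == pytest.approx(0.9)


@pytest.fixture(scope="module")
def cohort_inputs():
    spec = simulate.small_spec(seed=21)
    cohort = simulate.generate_cohort(spec)
    ann = simulate.default_annotation(spec)
    dgv = simulate.generate_dgv(spec, extra_noise_records=10)
    samples = call_cohort(
        {p.tumor.sample_id: p.tumor for p in cohort.patients},
        {p.tumor.sample_id: p.tumor_segments for p in cohort.patients},
        ann,
    )
    return samples, dgv, ann


class TestFeatureMatrix:
    def test_shape_and_completeness(self, cohort_inputs):
        samples, dgv, ann = cohort_inputs
        m = build_feature_matrix(samples, dgv, ann)
        n_cands = sum(len(c.candidates) for c in samples.values())
        assert len(m) == n_cands
        assert list(m.columns[5:]) == FEATURE_COLUMNS
        assert len(FEATURE_COLUMNS) == 18
        numeric = m[[c for c in FEATURE_COLUMNS if c != "overlap_pattern"]]
        assert not numeric.isna().any().any()
        assert ((m["overlap_pct"] >= 0) & (m["overlap_pct"] <= 1)).all()
        assert ((m["matching_bkpt_pct"] >= 0) & (m["matching_bkpt_pct"] <= 1)).all()

    def test_patient_order_invariance_and_determinism(self, cohort_inputs):
        samples, dgv, ann = cohort_inputs
        m1 = build_feature_matrix(samples, dgv, ann)
        reordered = dict(reversed(list(samples.items())))
        m2 = build_feature_matrix(reordered, dgv, ann)
        pd.testing.assert_frame_equal(m1, m2)
        m3 = build_feature_matrix(samples, dgv, ann)
        pd.testing.assert_frame_equal(m1, m3)
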