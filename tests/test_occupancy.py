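import numpy as np
import pytest
from scipy import stats

from stallscan import (
    AnalysisParams,
    BASIC,
    CoverageTrack,
    Transcript,
    TractWindow,
    apply_filters,
    compare_occupancy,
    define_regions,
    dropoff_report,
    find_tracts,
    metaprofile,
    occupancy_ratio,
    sample_matched_controls,
    score_windows,
)
from stallscan.occupancy import RegionPair, included_ratios
from stallscan.synthetic import (
    StallModel,
    TractSpec,
    make_transcriptome,
    tracks_from_rates,
)
from conftest import make_transcript, uniform_track

from oracles import brute_included_set, brute_regions, ks_distance, pooled_ttest


def tract_on(transcript: Transcript, start: int, width: int = 10) -> TractWindow:
    protein = transcript.protein
    seg = protein[start:start + width]
    n = sum(1 for aa in seg if aa in "KR")
    last = max(i for i in range(start, start + width) if protein[i] in "KR")
    return TractWindow(transcript.id, start, width, n, "basic", last, "tract")


@pytest.fixture
def stall_transcript() -> Transcript:
    # 300 sense codons, K-run at residues 100..109
    return make_transcript("t1", "A" * 100 + "K" * 10 + "A" * 190)


class TestDefineRegions:
    def test_methods_arithmetic(self, params):
        # 500 sense codons + stop, last target residue 199
        transcript = make_transcript("big", "A" * 190 + "K" * 10 + "A" * 300)
        tract = tract_on(transcript, 190)
        assert tract.last_target_res == 199
        regions = define_regions(tract, transcript, params)
        assert regions.post == (3 * 240, 3 * 480)
        assert regions.pre == (3 * 20, 3 * 240)

    def test_grid_matches_brute_force(self, params):
        for n_res in (80, 120, 200, 500):
            transcript = make_transcript("g", "A" * n_res)
            for last in range(9, n_res, 7):
                start = max(0, last - 9)
                tract = TractWindow("g", start, 10, 6, "basic", last, "tract")
                got = define_regions(tract, transcript, params)
                want = brute_regions(transcript.n_codons, last)
                if want is None:
                    assert got is None
                else:
                    assert (got.pre, got.post) == want

    def test_too_close_to_stop_unanalyzable(self, params):
        transcript = make_transcript("t", "A" * 100 + "K" * 10 + "A" * 10)
        tract = tract_on(transcript, 100)
        assert define_regions(tract, transcript, params) is None

    def test_pre_ends_at_post_start(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        assert regions.pre[1] == regions.post[0]

    def test_regionpair_invariant(self):
        with pytest.raises(ValueError):
            RegionPair(pre=(0, 10), post=(11, 20))


class TestOccupancyRatio:
    def test_uniform_ratio_one(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        track = uniform_track(stall_transcript, 2)
        rec = occupancy_ratio(track, regions, tract)
        assert rec.ratio == pytest.approx(1.0)

    def test_hand_computed_quarter(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        counts = np.zeros(stall_transcript.n_nt, dtype=int)
        counts[regions.pre[0]:regions.pre[1]] = 4
        counts[regions.post[0]:regions.post[1]] = 1
        rec = occupancy_ratio(CoverageTrack("t1", counts), regions, tract)
        assert rec.ratio == pytest.approx(0.25)

    def test_zero_post(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        counts = np.zeros(stall_transcript.n_nt, dtype=int)
        counts[regions.pre[0]:regions.pre[1]] = 1
        rec = occupancy_ratio(CoverageTrack("t1", counts), regions, tract)
        assert rec.ratio == 0.0

    def test_zero_pre_excluded(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        counts = np.zeros(stall_transcript.n_nt, dtype=int)
        counts[regions.post[0]:regions.post[1]] = 1
        rec = occupancy_ratio(CoverageTrack("t1", counts), regions, tract)
        assert rec.ratio is None
        assert rec.exclusion_reason == "zero_pre"
        assert not rec.included

    def test_scale_invariance(self, params, stall_transcript, rng):
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        counts = rng.poisson(2, size=stall_transcript.n_nt) + 1
        r1 = occupancy_ratio(CoverageTrack("t1", counts), regions, tract)
        r2 = occupancy_ratio(CoverageTrack("t1", counts * 7), regions, tract)
        assert r1.ratio == pytest.approx(r2.ratio)


class TestApplyFilters:
    def _setup(self, params, wt_per_nt=1):
        transcript = make_transcript("t1", "A" * 100 + "K" * 10 + "A" * 190)
        tract = tract_on(transcript, 100)
        track = uniform_track(transcript, 2)
        recs = score_windows([tract], {"t1": track}, [transcript], params)
        wt = {"t1": uniform_track(transcript, wt_per_nt)}
        return transcript, recs, wt

    def test_wt_read_threshold_boundary(self, params):
        transcript = make_transcript("t1", "A" * 100 + "K" * 10 + "A" * 190)
        tract = tract_on(transcript, 100)
        track = uniform_track(transcript, 2)
        for total, expect in ((24, False), (25, True)):
            counts = np.zeros(transcript.n_nt, dtype=int)
            counts[:total] = 1
            wt = {"t1": CoverageTrack("t1", counts)}
            recs = score_windows([tract], {"t1": track}, [transcript], params)
            recs = apply_filters(recs, wt, [transcript], params,
                                 reference_ratios=[1.0, 1.0, 1.0])
            assert recs[0].filters["min_reads_wt"] is expect

    def test_missing_wt_fails_closed(self, params):
        transcript, recs, _ = self._setup(params)
        recs = apply_filters(recs, {}, [transcript], params,
                             reference_ratios=[1.0, 1.0])
        assert recs[0].filters["min_reads_wt"] is False
        assert not recs[0].included

    def test_terminal_first_5pct(self, params):
        # 100-residue protein: first 5% is residues 0..4, start 2 violates
        transcript = make_transcript("t1", "AA" + "K" * 10 + "A" * 88)
        tract = tract_on(transcript, 2)
        track = uniform_track(transcript, 5)
        recs = score_windows([tract], {"t1": track}, [transcript], params)
        recs = apply_filters(recs, {"t1": track}, [transcript], params,
                             reference_ratios=[1.0, 1.0])
        assert recs[0].filters["terminal_5pct"] is False

    def test_dist_to_stop(self, params):
        # window ends at 171; 200 sense codons -> gap = 200 - 171 = 29 < 30
        transcript = make_transcript("t1", "A" * 161 + "K" * 10 + "A" * 29)
        tract = tract_on(transcript, 161)
        track = uniform_track(transcript, 5)
        recs = score_windows([tract], {"t1": track}, [transcript], params)
        recs = apply_filters(recs, {"t1": track}, [transcript], params,
                             reference_ratios=[1.0, 1.0])
        assert recs[0].filters["dist_to_stop"] is False

    def test_sd_boundary(self, params, stall_transcript):
        # reference mean 1.0, sd 0.2 -> cutoff 1.4: ratio 1.3 kept, 1.5 dropped
        ref = [0.8, 1.2, 0.8, 1.2, 0.8, 1.2, 0.8, 1.2]
        tract = tract_on(stall_transcript, 100)
        regions = define_regions(tract, stall_transcript, params)
        wt = {"t1": uniform_track(stall_transcript, 1)}

        def rec_with_ratio(ratio):
            counts = np.zeros(stall_transcript.n_nt, dtype=int)
            counts[regions.pre[0]:regions.pre[1]] = 10
            counts[regions.post[0]:regions.post[1]] = int(round(10 * ratio))
            return occupancy_ratio(CoverageTrack("t1", counts), regions, tract)

        recs = [rec_with_ratio(1.3), rec_with_ratio(1.5)]
        recs = apply_filters(recs, wt, [stall_transcript], params,
                             reference_ratios=ref)
        assert recs[0].filters["control_sd_outlier"] is True
        assert recs[1].filters["control_sd_outlier"] is False

    def test_audit_flags_retained_when_excluded(self, params):
        transcript, recs, wt = self._setup(params, wt_per_nt=0)
        wt = {"t1": uniform_track(transcript, 0)}
        recs = apply_filters(recs, wt, [transcript], params,
                             reference_ratios=[1.0, 1.0])
        assert set(recs[0].filters) == {
            "min_reads_wt", "terminal_5pct", "dist_to_stop", "control_sd_outlier",
        }
        assert recs[0].filters["terminal_5pct"] is True

    def test_included_set_matches_brute_force(self, params, rng):
        transcripts, truth = make_transcriptome(
            60, (150, 500), TractSpec(n_target=8, min_margin=5), seed=21)
        model = StallModel(lambda_pre=1.0, readthrough=0.5)
        tracks = tracks_from_rates(transcripts, truth, model, seed=22)
        # wt totals: some transcripts starved below threshold
        wt = {}
        for i, t in enumerate(transcripts):
            per_nt = 0 if i % 7 == 0 else 1
            wt[t.id] = uniform_track(t, per_nt)
        by_id = {t.id: t for t in transcripts}
        windows = []
        for r in truth.itertuples():
            windows.append(tract_on(by_id[r.transcript_id], r.start_res))
        recs = score_windows(windows, tracks, transcripts, params)
        recs = apply_filters(recs, wt, transcripts, params)
        got = {i for i, r in enumerate(recs) if r.included}
        want = brute_included_set(
            recs,
            wt_totals={tid: tr.total_reads for tid, tr in wt.items()},
            protein_lengths={t.id: len(t.protein) for t in transcripts},
            n_codons={t.id: t.n_codons for t in transcripts},
        )
        assert got == want


class TestMetaprofile:
    def test_delta_profile(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        center = 3 * (100 + 5)
        counts = np.zeros(stall_transcript.n_nt, dtype=int)
        counts[center] = 10
        profile = metaprofile({"t1": CoverageTrack("t1", counts)}, [tract], params)
        assert profile.n_windows == 1
        assert profile.mean_frequency[150] == pytest.approx(1.0)
        assert profile.mean_frequency.sum() == pytest.approx(1.0)

    def test_low_read_window_excluded(self, params, stall_transcript):
        tract = tract_on(stall_transcript, 100)
        counts = np.zeros(stall_transcript.n_nt, dtype=int)
        counts[3 * 105] = 9  # below the 10-read floor
        with pytest.raises(ValueError, match="10 reads"):
            metaprofile({"t1": CoverageTrack("t1", counts)}, [tract], params)

    def test_two_uniform_windows_flat(self, params):
        t1 = make_transcript("t1", "A" * 100 + "K" * 10 + "A" * 190)
        t2 = make_transcript("t2", "A" * 120 + "K" * 10 + "A" * 170)
        tracks = {"t1": uniform_track(t1, 1), "t2": uniform_track(t2, 1)}
        tracts = [tract_on(t1, 100), tract_on(t2, 120)]
        profile = metaprofile(tracks, tracts, params)
        assert profile.n_windows == 2
        assert np.allclose(profile.mean_frequency, 1 / 301)

    def test_edge_window_excluded(self, params):
        t = make_transcript("t1", "K" * 10 + "A" * 290)
        tracks = {"t1": uniform_track(t, 1)}
        with pytest.raises(ValueError, match="edge"):
            metaprofile(tracks, [tract_on(t, 0)], params)

    def test_contributing_vectors_sum_to_one(self, params, rng):
        transcripts, truth = make_transcriptome(
            20, (200, 400), TractSpec(n_target=8), seed=31)
        tracks = tracks_from_rates(transcripts, truth, StallModel(lambda_pre=1.0), seed=32)
        by_id = {t.id: t for t in transcripts}
        tracts = [tract_on(by_id[r.transcript_id], r.start_res) for r in truth.itertuples()]
        profile = metaprofile(tracks, tracts, params)
        assert profile.mean_frequency.sum() == pytest.approx(1.0, abs=1e-9)
        assert (profile.mean_frequency >= 0).all()


class TestMatchedControls:
    def _records(self, params, n_transcripts, seed, skew):
        """Occupancy records on a synthetic transcriptome; position-skewed tracts."""
        transcripts, truth = make_transcriptome(n_transcripts, (200, 600), None, seed=seed)
        tracks = tracks_from_rates(transcripts, truth, StallModel(lambda_pre=1.0), seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        recs = []
        for t in transcripts:
            n = len(t.protein)
            if skew:  # tracts biased toward the 3' half
                start = int(n * (0.5 + 0.4 * rng.beta(2, 2)))
            else:
                start = int(rng.uniform(0.1, 0.9) * n)
            start = min(start, n - 10)
            tract = TractWindow(t.id, start, 10, 0, "basic", start + 9, "control")
            recs.append(score_windows([tract], tracks, [t], params)[0])
        return transcripts, tracks, recs

    def test_identity_pool_exact(self, params):
        transcripts, tracks, recs = self._records(params, 40, seed=41, skew=True)
        sampled = sample_matched_controls(
            recs, recs, transcripts, tracks, n=len(recs), seed=9)
        got = sorted((r.transcript_id, r.tract.start_res) for r in sampled)
        want = sorted((r.transcript_id, r.tract.start_res) for r in recs)
        assert got == want  # exact multiset => KS distance 0 for every feature

    def test_seed_determinism(self, params):
        transcripts, tracks, trecs = self._records(params, 30, seed=51, skew=True)
        _, _, crecs = self._records(params, 30, seed=52, skew=False)
        s1 = sample_matched_controls(trecs, crecs, transcripts, tracks, n=20, seed=3)
        s2 = sample_matched_controls(trecs, crecs, transcripts, tracks, n=20, seed=3)
        assert [(r.transcript_id, r.tract.start_res) for r in s1] == \
               [(r.transcript_id, r.tract.start_res) for r in s2]

    def test_empty_pool_rejected(self, params):
        transcripts, tracks, trecs = self._records(params, 5, seed=61, skew=False)
        with pytest.raises(ValueError, match="empty control pool"):
            sample_matched_controls(trecs, [], transcripts, tracks, n=3, seed=0)


class TestCompareOccupancy:
    def test_identical_groups(self):
        with pytest.warns(UserWarning):
            t, p, means = compare_occupancy([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0
        assert p == 1.0

    def test_matches_formula_oracle(self):
        a = [0.1, 0.2, 0.15]
        b = [0.9, 1.0, 1.1]
        t, p, means = compare_occupancy(a, b)
        t0, p0 = pooled_ttest(a, b)
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)
        assert means == (pytest.approx(0.15), pytest.approx(1.0))

    def test_swap_symmetry(self, rng):
        a = rng.normal(0.5, 0.1, size=10).tolist()
        b = rng.normal(1.0, 0.1, size=12).tolist()
        t1, p1, _ = compare_occupancy(a, b)
        t2, p2, _ = compare_occupancy(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_occupancy([1.0], [1.0, 2.0])


class TestDropoffReport:
    def _rec(self, tid, ratio, pre=1.0):
        tract = TractWindow(tid, 50, 10, 8, "basic", 57, "tract")
        rec_pre = pre
        rec = __import__("stallscan").occupancy.OccupancyRecord(
            transcript_id=tid, tract=tract,
            pre_density=rec_pre, post_density=ratio * rec_pre, ratio=ratio,
        )
        rec.filters = {name: True for name in
                       ("min_reads_wt", "terminal_5pct", "dist_to_stop",
                        "control_sd_outlier")}
        return rec

    def test_no_drop(self):
        trecs = [self._rec("a", 1.0), self._rec("b", 1.0)]
        crecs = [self._rec("c", 1.0), self._rec("d", 1.0)]
        out = dropoff_report({"wt": (trecs, crecs)}, pooled=False)
        assert out.loc[0, "percent_drop"] == pytest.approx(0.0)

    def test_75_percent_drop(self):
        trecs = [self._rec("a", 0.25), self._rec("b", 0.25)]
        crecs = [self._rec("c", 1.0), self._rec("d", 1.0)]
        out = dropoff_report({"wt": (trecs, crecs)}, pooled=False)
        assert out.loc[0, "percent_drop"] == pytest.approx(75.0)
        assert out.loc[0, "n_windows"] == 2
        assert out.loc[0, "n_genes"] == 2

    def test_gene_deduplication(self):
        trecs = [self._rec("a", 0.5), self._rec("a", 0.5), self._rec("b", 0.5)]
        crecs = [self._rec("c", 1.0), self._rec("d", 1.0)]
        out = dropoff_report({"wt": (trecs, crecs)}, pooled=False)
        assert out.loc[0, "n_windows"] == 3
        assert out.loc[0, "n_genes"] == 2

    def test_pooled_row(self):
        g1 = ([self._rec("a", 0.5)] * 2, [self._rec("c", 1.0)] * 2)
        g2 = ([self._rec("b", 0.3)] * 2, [self._rec("d", 1.0)] * 2)
        out = dropoff_report({"x": g1, "y": g2}, pooled=True)
        assert list(out["group"]) == ["x", "y", "pooled"]
        pooled = out[out["group"] == "pooled"].iloc[0]
        assert pooled["n_windows"] == 4
        assert pooled["percent_drop"] == pytest.approx(60.0)

    def test_empty_group_row(self):
        out = dropoff_report({"wt": ([], [])}, pooled=False)
        assert out.loc[0, "n_windows"] == 0
        assert np.isnan(out.loc[0, "percent_drop"])
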