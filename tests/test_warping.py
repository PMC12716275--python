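"""Open-ended DTW, barycenter averaging, and cohort-level dissimilarity."""

import numpy as np
import pandas as pd
import pytest

import sleepwarp as sw
from sleepwarp.core import QCError
from sleepwarp.warping import NightFeatures

from _oracles import oe_dtw_brute


def _features(matrix, night_id="n", subject_id="s", night_index=0, stages=None):
    return NightFeatures(
        matrix=matrix, bin_s=60.0, night_id=night_id, subject_id=subject_id,
        night_index=night_index, stages=stages,
    )


class TestOeDtw:
    def test_identity_gives_zero_and_diagonal_path(self, cohort_features):
        feats = cohort_features[1][0]
        res = sw.oe_dtw(feats, feats)
        assert res.dissimilarity == 0.0
        assert np.array_equal(res.path[:, 0], res.path[:, 1])
        assert res.matched_len == feats.length

    def test_prefix_match_gives_zero(self, cohort_features):
        feats = cohort_features[1][0]
        cut = int(feats.length * 0.6)
        prefix = _features(feats.matrix[:, :cut])
        assert sw.oe_dtw(prefix, feats).dissimilarity == 0.0
        assert sw.oe_dtw(feats, prefix).dissimilarity == 0.0

    def test_matches_exhaustive_enumeration(self):
        """DP dissimilarity equals brute-force minimum over all admissible
        open-ended paths for short random sequences."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            la, lb = rng.integers(2, 9, size=2)
            a = rng.normal(size=(5, la))
            b = rng.normal(size=(5, lb))
            assert sw.oe_dtw(a, b).dissimilarity == pytest.approx(
                oe_dtw_brute(a, b), rel=1e-9
            )

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=(5, int(rng.integers(10, 40))))
            b = rng.normal(size=(5, int(rng.integers(10, 40))))
            dab = sw.oe_dtw(a, b).dissimilarity
            dba = sw.oe_dtw(b, a).dissimilarity
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-12)

    def test_band_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 20))
        b = rng.normal(size=(5, 30))
        perm = rng.permutation(5)
        assert sw.oe_dtw(a, b).dissimilarity == pytest.approx(
            sw.oe_dtw(a[perm], b[perm]).dissimilarity, rel=1e-12
        )

    def test_temporal_shuffling_increases_dissimilarity(self, cohort_features):
        feats = cohort_features[1]
        a, b = feats[0], feats[1]
        rng = np.random.default_rng(7)
        shuffled = _features(b.matrix[:, rng.permutation(b.length)])
        assert (
            sw.oe_dtw(a, shuffled).dissimilarity > sw.oe_dtw(a, b).dissimilarity
        )

    def test_path_shape_constraints(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(5, 15))
        b = rng.normal(size=(5, 25))
        path = sw.oe_dtw(a, b).path
        assert tuple(path[0]) == (0, 0)
        steps = np.diff(path, axis=0)
        assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}
        assert path[-1, 0] == 14  # shorter sequence fully consumed

    def test_resolution_mismatch_raises(self, cohort_features):
        f = cohort_features[1][0]
        other = NightFeatures(
            matrix=f.matrix, bin_s=12.0, night_id="x", subject_id="s", night_index=1
        )
        with pytest.raises(ValueError, match="resolution"):
            sw.oe_dtw(f, other)


class TestBuildNightFeatures:
    def test_single_cycle_night_rejected(self):
        labels = ["W"] * 4 + ["N2"] * 120 + ["REM"] * 20 + ["W"] * 4
        hyp = sw.Hypnogram(np.array(labels, dtype=object))
        p = sw.make_profile(2, 1)
        bp = sw.simulate_bandpower(hyp, p, 1)
        with pytest.raises(QCError) as err:
            sw.build_night_features(bp, hyp)
        assert err.value.reason == "min-cycles"

    def test_length_matches_resolution(self, night):
        f = sw.build_night_features(night.bandpower, night.hypnogram, resolution_s=60.0)
        sleep = np.isin(night.hypnogram.labels, ["N1", "N2", "N3", "REM"])
        idx = np.flatnonzero(sleep)
        expected = (idx[-1] + 1 - idx[0]) * 30.0 / 60.0
        assert abs(f.length - expected) <= 1

    def test_disconnected_night_rejected(self, night):
        bp = night.bandpower.copy()
        bp.valid[: int(0.4 * bp.n_bins)] = False
        with pytest.raises(QCError) as err:
            sw.build_night_features(bp, night.hypnogram)
        assert err.value.reason == "disconnection"

    def test_output_is_zscored_and_gap_free(self, night):
        bp = night.bandpower.copy()
        bp.valid[500:510] = False  # small interior gap, below rejection level
        f = sw.build_night_features(bp, night.hypnogram)
        assert np.isfinite(f.matrix).all()
        assert np.allclose(f.matrix.mean(axis=1), 0.0, atol=1e-9)


class TestPairwise:
    def test_adjacent_same_subject_pairs_excluded(self):
        rng = np.random.default_rng(0)
        nights = [
            _features(rng.normal(size=(5, 20)), f"n{i}", "s1", night_index=i)
            for i in range(2)
        ] + [_features(rng.normal(size=(5, 20)), "n2", "s2", night_index=5)]
        mat, tidy = sw.pairwise_dissimilarity(nights)
        assert np.isnan(mat.loc["n0", "n1"])
        assert tidy["excluded_adjacent"].sum() == 1
        assert tidy["D"].notna().sum() == 2

    def test_matrix_symmetric_with_zero_diagonal(self, cohort_features):
        feats = cohort_features[1][:12]
        mat, _ = sw.pairwise_dissimilarity(feats)
        arr = mat.to_numpy()
        assert np.allclose(np.diag(arr), 0.0)
        m = ~np.isnan(arr)
        assert np.allclose(arr[m], arr.T[m], atol=1e-9)

    def test_within_subject_less_than_across(self, cohort_features):
        """Planted subject traits make nights of one subject mutually more
        similar than nights of different subjects."""
        _, feats = cohort_features
        _, tidy = sw.pairwise_dissimilarity(feats)
        res = sw.compare_within_across(tidy)
        assert res.mean_within < res.mean_across
        assert res.p < 0.05


class TestCompareWithinAcross:
    @staticmethod
    def _tidy(within_vals, across_vals):
        rows = []
        for i, d in enumerate(within_vals):
            rows.append(
                dict(night_a=f"a{i}", night_b=f"b{i}", subject_a=f"s{i}",
                     subject_b=f"s{i}", within_subject=True,
                     excluded_adjacent=False, D=d)
            )
        for i, d in enumerate(across_vals):
            rows.append(
                dict(night_a=f"c{i}", night_b=f"d{i}", subject_a=f"s{i}",
                     subject_b=f"t{i}", within_subject=False,
                     excluded_adjacent=False, D=d)
            )
        return pd.DataFrame(rows)

    def test_identical_groups_give_t_zero(self):
        res = sw.compare_within_across(self._tidy([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_reports_means_with_sd(self):
        res = sw.compare_within_across(self._tidy([1.0, 2.0], [3.0, 5.0]))
        assert res.mean_within == pytest.approx(1.5)
        assert res.sd_within == pytest.approx(np.std([1, 2], ddof=1))
        assert res.mean_across == pytest.approx(4.0)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            sw.compare_within_across(self._tidy([1.0], [2.0, 3.0]))

    def test_planted_separation_detected_at_cohort_size(self):
        """Power check: a 2-SD group shift is detected at n = 8 subjects."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            within = rng.normal(2.5, 0.5, 8)
            across = rng.normal(3.5, 0.5, 28)
            res = sw.compare_within_across(self._tidy(within, across))
            hits += res.p < 0.05
        assert hits / 50 >= 0.9


class TestDba:
    def test_single_night_returns_it(self, cohort_features):
        f = cohort_features[1][0]
        arch = sw.oe_dba([f])
        assert np.allclose(arch.matrix, f.matrix)
        assert arch.objective_trace[-1] == pytest.approx(0.0)

    def test_identical_nights_return_the_template(self, cohort_features):
        f = cohort_features[1][0]
        copies = [
            _features(f.matrix.copy(), f"c{i}", "s", night_index=i) for i in range(4)
        ]
        arch = sw.oe_dba(copies)
        assert np.allclose(arch.matrix, f.matrix)
        assert arch.objective_trace[-1] == pytest.approx(0.0)

    @staticmethod
    def _jittered_copies(n=20, length=60, seed=0):
        rng = np.random.default_rng(seed)
        template = rng.normal(size=(5, length))
        nights = []
        for k in range(n):
            # time-jitter: random small expansions/contractions
            idx = np.sort(rng.choice(length, size=length - 6, replace=False))
            warped = template[:, idx]
            warped = warped + rng.normal(0, 0.05, size=warped.shape)
            nights.append(_features(warped, f"j{k}", "s", night_index=k))
        return template, nights

    def test_objective_trace_non_increasing_and_beats_arithmetic_mean(self):
        template, nights = self._jittered_copies()
        arch = sw.oe_dba(nights, max_iter=10)
        trace = np.asarray(arch.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        min_len = min(n.length for n in nights)
        arith = np.mean([n.matrix[:, :min_len] for n in nights], axis=0)
        arith_obj = sum(
            sw.oe_dtw(arith, n.matrix).dissimilarity for n in nights
        )
        assert trace[-1] <= arith_obj

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            sw.oe_dba([])


class TestStageConditioned:
    def test_identical_pair_diagonal_zero(self, cohort_features):
        f = cohort_features[1][0]
        twin = _features(f.matrix.copy(), "twin", "s9", stages=f.stages)
        means, counts = sw.stage_conditioned_dissimilarity([f, twin])
        for s in set(f.stages):
            assert means.loc[s, s] == pytest.approx(0.0, abs=1e-12)

    def test_counts_conserve_path_length(self, cohort_features):
        feats = cohort_features[1][:3]
        means, counts = sw.stage_conditioned_dissimilarity(feats)
        total = sum(
            sw.oe_dtw(feats[i], feats[j]).path.shape[0]
            for i in range(3) for j in range(i + 1, 3)
        )
        assert counts.to_numpy().sum() == total

    def test_inconsistent_stages_cost_more_than_neighbours(self, cohort_features):
        """Aligned-but-differently-staged bins cost more the further apart
        the stages are spectrally: REM-vs-NREM alignments exceed the
        neighbouring N2-vs-N3 mismatch, which exceeds same-stage cells.
        (Fully antagonistic N3-vs-REM alignments are avoided outright by
        the optimal path on clean synthetic nights.)"""
        feats = cohort_features[1][:20]
        means, counts = sw.stage_conditioned_dissimilarity(feats)
        assert means.loc["N2", "REM"] > means.loc["N2", "N3"]
        for s in ("N2", "N3", "REM"):
            assert means.loc[s, s] < means.loc["N2", "N3"]
        # the costliest combination is (nearly) never chosen by the path
        assert counts.loc["N3", "REM"] + counts.loc["REM", "N3"] < counts.loc["N2", "N3"]


class TestClustering:
    def test_duplicate_subject_merges_first(self, cohort_features):
        feats = cohort_features[1]
        archs = []
        for sid in ("s01", "s02", "s03"):
            archs.append(sw.oe_dba([f for f in feats if f.subject_id == sid], subject_id=sid))
        dup = sw.Archetype(
            matrix=archs[0].matrix.copy(), bin_s=archs[0].bin_s,
            member_ids=archs[0].member_ids, objective_trace=[0.0], subject_id="dup",
        )
        res = sw.cluster_archetypes(archs + [dup], k=3)
        assert res.labels["s01"] == res.labels["dup"]
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_linkage_heights_non_decreasing(self, cohort_features):
        feats = cohort_features[1]
        archs = [
            sw.oe_dba([f for f in feats if f.subject_id == sid], subject_id=sid)
            for sid in sorted({f.subject_id for f in feats})
        ]
        res = sw.cluster_archetypes(archs)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_planted_clusters_recovered(self, cohort_features):
        """Flat 2-cut of the archetype dendrogram recovers the generator's
        two trait clusters exactly."""
        from sklearn.metrics import rand_score

        profiles, feats = cohort_features
        archs = [
            sw.oe_dba([f for f in feats if f.subject_id == sid], subject_id=sid)
            for sid in sorted({f.subject_id for f in feats})
        ]
        res = sw.cluster_archetypes(archs, k=2)
        planted = {p.subject_id: p.cluster for p in profiles}
        ids = sorted(planted)
        assert rand_score([planted[i] for i in ids], [res.labels[i] for i in ids]) == 1.0

    def test_shared_archetypes_differ_in_sigma_alpha_profile(self, cohort_features):
        """Cluster-2 (slow-spindle) shared archetype shows higher relative
        alpha in deep sleep than cluster 1."""
        profiles, feats = cohort_features
        planted = {p.subject_id: p.cluster for p in profiles}
        sh = {}
        for cid in (1, 2):
            members = [f for f in feats if planted[f.subject_id] == cid][:20]
            sh[cid] = sw.shared_archetype(members, max_iter=5)
        # mean z-scored alpha over the first half (NREM-dominated) bins
        half = min(sh[1].matrix.shape[1], sh[2].matrix.shape[1]) // 2
        alpha1 = sh[1].matrix[2, :half].mean()
        alpha2 = sh[2].matrix[2, :half].mean()
        assert alpha2 > alpha1
        assert set(sh[1].member_ids).isdisjoint(sh[2].member_ids)
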