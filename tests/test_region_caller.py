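"""Differential-region inference: differences, candidates, null, p, q."""

import numpy as np
import pandas as pd
import pytest

from mprna.region_caller import (
    CallerParams,
    CandidateRegion,
    PermutationScheme,
    bh_adjust,
    call_drs,
    difference_track,
    empirical_pvalues,
    find_candidates,
    permutation_null,
    region_stat,
)
from mprna.signal_model import NucleotideTrack


def sample_meta(n_rep=6):
    rows = []
    for r in range(1, n_rep + 1):
        rows.append({"sample_id": f"nuclear_{r}", "condition": "nuclear", "replicate": r})
    for r in range(1, n_rep + 1):
        rows.append({"sample_id": f"total_{r}", "condition": "total", "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def make_track(nuclear: np.ndarray, total: np.ndarray, tid="t", step=10):
    """Track from positions x replicates matrices for each condition."""
    n_pos, n_rep = nuclear.shape
    positions = np.arange(0, n_pos * step, step)
    cols = {f"nuclear_{r + 1}": nuclear[:, r] for r in range(n_rep)}
    cols.update({f"total_{r + 1}": total[:, r] for r in range(n_rep)})
    values = pd.DataFrame(cols, index=positions)
    return NucleotideTrack(tid, positions, values, coverage=np.full(n_pos, 11))


class TestDifferenceTrack:
    def test_median_of_paired_differences(self):
        nuc = np.array([[5.0, 6.0, 7.0]])
        tot = np.array([[1.0, 2.0, 3.0]])
        track = make_track(nuc, tot)
        dt = difference_track(track, sample_meta(3))
        assert dt.d.tolist() == [4.0]

    def test_null_identity_when_conditions_equal(self):
        x = np.abs(np.random.default_rng(0).normal(5, 1, size=(20, 6)))
        dt = difference_track(make_track(x, x.copy()), sample_meta())
        assert np.allclose(dt.d, 0.0)

    def test_matches_brute_force_pairing_oracle(self):
        rng = np.random.default_rng(3)
        nuc, tot = rng.gamma(2, 10, (30, 6)), rng.gamma(2, 10, (30, 6))
        dt = difference_track(make_track(nuc, tot), sample_meta())
        expected = np.median(nuc - tot, axis=1)
        assert np.allclose(dt.d, expected)

    def test_log_transform_applied_before_differencing(self):
        nuc = np.full((5, 2), 3.0)
        tot = np.full((5, 2), 1.0)
        dt = difference_track(make_track(nuc, tot), sample_meta(2), transform="log2p1")
        assert np.allclose(dt.d, np.log2(4) - np.log2(2))

    def test_unbalanced_design_rejected(self):
        track = make_track(np.ones((3, 2)), np.ones((3, 2)))
        meta = sample_meta(2).drop("total_2")
        track.values = track.values.drop(columns="total_2")
        with pytest.raises(ValueError, match="unbalanced"):
            difference_track(track, meta)


def diff_from_values(d_values, step=10, n_rep=6):
    """DifferenceTrack with requested d and all pairs agreeing in sign."""
    d = np.asarray(d_values, dtype=float)
    nuc = np.tile(d[:, None], (1, n_rep)) + 10.0
    tot = np.full_like(nuc, 10.0)
    return difference_track(make_track(nuc, tot), sample_meta(n_rep))


class TestFindCandidates:
    def test_single_run_detection(self):
        diff = diff_from_values([0, 0, 5, 6, 7, 0, 0])
        regions = find_candidates(diff, threshold=4, min_positions=1)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end, regions[0].n_positions) == (20, 50, 3)

    def test_all_below_threshold_yields_nothing(self):
        assert find_candidates(diff_from_values([1, 2, 1]), threshold=4) == []

    def test_gap_bridging_semantics(self):
        d = [9, 9, 0, 0, 9, 9]
        assert len(find_candidates(diff_from_values(d), 4, max_gap=1, min_positions=1)) == 2
        merged = find_candidates(diff_from_values(d), 4, max_gap=2, min_positions=1)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 60)

    def test_min_positions_filters_short_runs(self):
        d = [9, 0, 9, 9, 0]
        regions = find_candidates(diff_from_values(d), 4, min_positions=2)
        assert [(r.start, r.end) for r in regions] == [(20, 40)]

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValueError):
            find_candidates(diff_from_values([1]), float("nan"))


class TestRegionStat:
    def test_area_times_consistency_all_pairs_positive(self):
        diff = diff_from_values([5, 6, 7])
        region = CandidateRegion("t", 0, 30, 3, 0.0)
        assert region_stat(region, diff) == pytest.approx(18.0)
        assert region_stat(region, diff, "area") == pytest.approx(18.0)

    def test_half_consistent_pairs_halve_the_stat(self):
        # pair differences {-2, -2, 10, 10}: median d = 4, half the pairs positive
        nuc = np.array([[8.0, 8.0, 20.0, 20.0]])
        tot = np.full((1, 4), 10.0)
        diff = difference_track(make_track(nuc, tot), sample_meta(4))
        region = CandidateRegion("t", 0, 10, 1, 0.0)
        assert diff.d[0] == 4.0
        assert region_stat(region, diff) == pytest.approx(2.0)

    def test_area_mode_equals_brute_force_sum(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0, 3, size=40)
        diff = diff_from_values(d)
        region = CandidateRegion("t", 50, 210, 16, 0.0)
        assert region_stat(region, diff, "area") == pytest.approx(d[5:21].sum())

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty region"):
            region_stat(CandidateRegion("t", 500, 510, 1, 0.0), diff_from_values([1, 2]))


class TestPermutationNull:
    def test_pair_flip_exhaustive_count_and_determinism(self):
        rng = np.random.default_rng(1)
        nuc, tot = rng.gamma(2, 10, (50, 6)), rng.gamma(2, 10, (50, 6))
        tracks = {"t": make_track(nuc, tot)}
        meta = sample_meta()
        a = permutation_null(tracks, meta, PermutationScheme("pair-flip", None, 0), 1.0)
        b = permutation_null(tracks, meta, PermutationScheme("pair-flip", None, 99), 1.0)
        assert a == b  # exhaustive enumeration ignores the seed

    def test_identical_samples_give_empty_null(self):
        x = np.abs(np.random.default_rng(0).normal(5, 1, (30, 6)))
        tracks = {"t": make_track(x, x.copy())}
        null = permutation_null(tracks, sample_meta(), PermutationScheme(), threshold=0.5)
        assert null == []

    def test_balanced_shuffle_is_seeded(self):
        rng = np.random.default_rng(2)
        nuc, tot = rng.gamma(2, 10, (50, 6)), rng.gamma(2, 10, (50, 6))
        tracks = {"t": make_track(nuc, tot)}
        meta = sample_meta()
        scheme = PermutationScheme("balanced-shuffle", 25, 7)
        assert permutation_null(tracks, meta, scheme, 0.5) == permutation_null(tracks, meta, scheme, 0.5)

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            PermutationScheme(n_perm=0)


class TestEmpiricalP:
    def test_add_one_formula(self):
        null = list(range(99))
        assert empirical_pvalues([1000.0], null)[0] == pytest.approx(1 / 100)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(4)
        null = rng.normal(size=200)
        obs = rng.normal(size=20)
        p = empirical_pvalues(obs, null)
        brute = [(1 + sum(n >= o for n in null)) / (1 + len(null)) for o in obs]
        assert np.allclose(p, brute)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            empirical_pvalues([1.0], [])


class TestBH:
    def test_closed_form_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(0.001, 1, size=rng.integers(2, 30))
            m = len(p)
            order = np.argsort(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            for i in range(m - 2, -1, -1):
                q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
            brute = np.empty(m)
            brute[order] = np.minimum(q_sorted, 1)
            assert np.allclose(bh_adjust(p), brute)

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


class TestCallDrs:
    def _tracks_with_bump(self, offset_steps=0, seed=0, n_pos=120):
        rng = np.random.default_rng(seed)
        base = rng.gamma(20, 50, size=(n_pos, 1))
        nuc = base + rng.normal(0, 20, (n_pos, 6))
        tot = base + rng.normal(0, 20, (n_pos, 6))
        lo, hi = 40 + offset_steps, 60 + offset_steps
        nuc[lo:hi] += 800.0
        return {"t": make_track(nuc, tot)}

    def test_fdr_zero_returns_nothing(self):
        tracks = self._tracks_with_bump()
        res = call_drs(tracks, sample_meta(), CallerParams(fdr=0.0))
        assert res.regions == []
        assert len(res.candidates) > 0

    def test_planted_bump_is_called(self):
        res = call_drs(self._tracks_with_bump(), sample_meta(), CallerParams())
        assert any(r.start <= 450 and r.end >= 550 for r in res.regions)

    def test_translation_equivariance(self):
        r0 = call_drs(self._tracks_with_bump(0), sample_meta(), CallerParams())
        r3 = call_drs(self._tracks_with_bump(3), sample_meta(), CallerParams())
        best0 = max(r0.regions, key=lambda r: r.stat)
        best3 = max(r3.regions, key=lambda r: r.stat)
        assert (best3.start - best0.start, best3.end - best0.end) == (30, 30)

    def test_common_scaling_preserves_stat_order_and_pvalues(self):
        tracks = self._tracks_with_bump()
        meta = sample_meta()
        res1 = call_drs(tracks, meta, CallerParams())
        scaled = {
            tid: NucleotideTrack(t.transcript_id, t.positions, t.values * 3.0, t.coverage)
            for tid, t in tracks.items()
        }
        res2 = call_drs(scaled, meta, CallerParams())
        assert [r.p_emp for r in res1.candidates] == [r.p_emp for r in res2.candidates]
        order1 = np.argsort([r.stat for r in res1.candidates])
        order2 = np.argsort([r.stat for r in res2.candidates])
        assert (order1 == order2).all()

    def test_deterministic(self):
        tracks = self._tracks_with_bump()
        meta = sample_meta()
        a = call_drs(tracks, meta, CallerParams())
        b = call_drs(tracks, meta, CallerParams())
        assert [(r.start, r.end, r.stat, r.p_emp, r.q) for r in a.candidates] == [
            (r.start, r.end, r.stat, r.p_emp, r.q) for r in b.candidates
        ]
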