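import numpy as np
import pytest

from suredec import (
    CoefficientTrack,
    Region,
    grouped_validation,
    optimal_fragment,
    predict_batch,
    predict_fragment,
    promoter_map,
)


def constant_track(c, n=2000, theta_L=0.0, strand="+"):
    t = CoefficientTrack(theta_L=theta_L)
    t.add("chr1", strand, np.arange(n), np.full(n, float(c)))
    return t


class TestPredictFragment:
    def test_constant_coefficient_closed_form(self):
        c, th_L, L = 0.01, -0.002, 150
        track = constant_track(c, theta_L=th_L)
        pred = predict_fragment(track, Region("chr1", 100, 100 + L))
        assert pred == pytest.approx(np.exp(L * (c + th_L)))

    def test_zero_track_zero_theta_gives_one(self):
        track = constant_track(0.0)
        assert predict_fragment(track, Region("chr1", 10, 400)) == pytest.approx(1.0)

    def test_log_additivity_over_splits(self, rng):
        track = CoefficientTrack(theta_L=-0.001)
        track.add("chr1", "+", np.arange(1000), rng.normal(scale=0.02, size=1000))
        a, b, c = 100, 400, 900
        lp = lambda s, e: np.log(predict_fragment(track, Region("chr1", s, e)))
        assert lp(a, c) == pytest.approx(lp(a, b) + lp(b, c), abs=1e-9)

    def test_uncovered_positions_contribute_zero_and_are_counted(self):
        track = CoefficientTrack(theta_L=0.01)
        track.add("chr1", "+", np.arange(0, 50), np.full(50, 0.1))
        pred, unc = predict_fragment(track, Region("chr1", 40, 70), return_uncovered=True)
        assert unc == 20
        assert pred == pytest.approx(np.exp(10 * 0.1 + 0.01 * 30))

    def test_unknown_contig_errors(self):
        with pytest.raises(ValueError, match="contig"):
            predict_fragment(constant_track(0.0), Region("chrX", 0, 10))

    def test_strand_matched_lookup(self):
        t = CoefficientTrack()
        t.add("chr1", "+", np.arange(10), np.full(10, 1.0))
        t.add("chr1", "-", np.arange(10), np.full(10, -1.0))
        plus = predict_fragment(t, Region("chr1", 0, 10, "+"))
        minus = predict_fragment(t, Region("chr1", 0, 10, "-"))
        assert np.log(plus) == pytest.approx(10.0)
        assert np.log(minus) == pytest.approx(-10.0)


class TestPredictBatch:
    def test_order_preserved_and_duplicates_identical(self):
        track = constant_track(0.01)
        regions = [Region("chr1", 0, 100), Region("chr1", 50, 60), Region("chr1", 0, 100)]
        table = predict_batch(track, regions)
        assert list(table["start"]) == [0, 50, 0]
        assert table["prediction"][0] == table["prediction"][2]

    def test_region_outside_coverage(self):
        track = constant_track(0.01, n=100, theta_L=-0.003)
        table = predict_batch(track, [Region("chr1", 500, 600)])
        assert table["uncovered_bp"][0] == 100
        assert table["prediction"][0] == pytest.approx(np.exp(-0.003 * 100))

    def test_per_region_errors_do_not_stop_the_run(self):
        track = constant_track(0.01, n=100)
        table = predict_batch(track, [Region("chrX", 0, 10), Region("chr1", 0, 10)])
        assert table["error"][0] != ""
        assert table["error"][1] == ""
        assert np.isfinite(table["prediction"][1])


class TestPromoterMap:
    def test_entries_match_direct_prediction(self, rng):
        track = CoefficientTrack(theta_L=-0.002)
        track.add("chr1", "+", np.arange(400), rng.normal(scale=0.02, size=400))
        pmap = promoter_map(track, "chr1", 200, max_len=60, min_len=5)
        for start, end, value in pmap.entries():
            direct = predict_fragment(track, Region("chr1", start, end))
            assert value == pytest.approx(direct, rel=1e-12)

    def test_spike_argmax_matches_enumeration_oracle(self):
        n = 400
        values = np.zeros(n)
        values[200] = 0.5  # single positive spike
        th_L = -0.01  # |theta_L| * min_len < spike
        track = CoefficientTrack(theta_L=th_L)
        track.add("chr1", "+", np.arange(n), values)
        max_len, min_len = 50, 5
        # exhaustive enumeration oracle
        best, best_iv = -np.inf, None
        for length in range(min_len, max_len + 1):
            for s in range(200 - max_len, 200 + max_len - length + 1):
                v = values[s : s + length].sum() + th_L * length
                if v > best or (v == best and (length, s) < (best_iv[1] - best_iv[0], best_iv[0])):
                    best, best_iv = v, (s, s + length)
        pmap = promoter_map(track, "chr1", 200, max_len=max_len, min_len=min_len)
        region, value = optimal_fragment(pmap)
        assert (region.start, region.end) == best_iv
        assert 200 in range(region.start, region.end)
        assert region.length == min_len

    def test_all_negative_track_yields_min_length_optimum(self):
        track = CoefficientTrack(theta_L=-0.001)
        track.add("chr1", "+", np.arange(300), np.full(300, -0.05))
        pmap = promoter_map(track, "chr1", 150, max_len=40, min_len=3)
        region, _ = optimal_fragment(pmap)
        assert region.length == 3

    def test_tie_breaks_prefer_shorter_then_leftmost(self):
        # zero coefficients, zero theta_L: every fragment predicts 1.0
        track = constant_track(0.0, n=100)
        pmap = promoter_map(track, "chr1", 50, max_len=10, min_len=2)
        region, value = optimal_fragment(pmap)
        assert value == pytest.approx(1.0)
        assert region.length == 2
        assert region.start == pmap.window_start

    def test_step_coarsens_grid(self):
        track = constant_track(0.01, n=400)
        pmap = promoter_map(track, "chr1", 200, max_len=30, min_len=1, step=5)
        defined = ~np.isnan(pmap.log_pred)
        assert defined[0].any() and not defined[1].any()


class TestGroupedValidation:
    def test_worked_example(self):
        # same 50 bp start/end bins: preds e^2, e^4; obs 2, 4
        regions = [Region("chr1", 10, 110), Region("chr1", 20, 120),
                   Region("chr1", 200, 320), Region("chr1", 400, 520)]
        preds = np.exp([2.0, 4.0, 1.0, 1.0])
        obs = np.array([2.0, 4.0, 1.0, 1.0])
        table, r = grouped_validation(preds, obs, regions, bin_size=50)
        g0 = table.iloc[0]
        assert g0["n_elements"] == 2
        assert g0["mean_log_pred"] == pytest.approx(3.0)
        assert g0["log_mean_obs"] == pytest.approx(np.log(3.0))

    def test_start_bin_boundary_at_multiples_of_50(self):
        regions = [Region("chr1", 0, 100), Region("chr1", 49, 100), Region("chr1", 50, 100),
                   Region("chr1", 300, 400), Region("chr1", 500, 600)]
        table, _ = grouped_validation(np.ones(5), np.ones(5), regions, bin_size=50)
        first_two = table[(table["start_bin"] == 0)]
        assert int(first_two["n_elements"].iloc[0]) == 2  # starts 0 and 49 share bin 0
        assert (table["start_bin"] == 1).sum() == 1  # start 50 does not

    def test_zero_observation_groups_dropped(self):
        regions = [Region("chr1", i * 100, i * 100 + 60) for i in range(4)]
        preds = np.full(4, 2.0)
        obs = np.array([1.0, 2.0, 3.0, 0.0])
        table, _ = grouped_validation(preds, obs, regions)
        assert len(table) == 3
        assert table.attrs["n_dropped_zero_obs"] == 1

    def test_too_few_groups_errors(self):
        regions = [Region("chr1", 0, 60), Region("chr1", 100, 160)]
        with pytest.raises(ValueError, match="groups"):
            grouped_validation(np.ones(2), np.ones(2), regions)

    def test_poisson_simulation_recovers_group_correlation(self, rng):
        """Observations drawn Poisson from predictions over 10 TSS windows:
        group-level log-space correlation is high."""
        regions, preds = [], []
        for w in range(10):
            base = w * 2000
            for _ in range(50):
                start = base + int(rng.integers(0, 900))
                end = start + int(rng.integers(100, 600))
                regions.append(Region("chr1", start, end))
                preds.append(np.exp(rng.uniform(0.0, 4.0)))
        preds = np.array(preds)
        obs = rng.poisson(preds).astype(float)
        table, r = grouped_validation(preds, obs, regions, bin_size=50)
        assert len(table) >= 100
        assert r >= 0.9
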