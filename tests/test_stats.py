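"""Agreement statistics: frozen hand examples, algebraic identities,
and agreement with independent direct-summation oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mfyeval.errors import DegenerateInputError
from mfyeval.stats import concordance, evaluate, grouped_regression, rmse_partition


# ---------------------------------------------------------------------------
# Independent oracles: plain-Python direct summation, population moments.
def _pop_stats(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return mx, my, vx, vy, cov


def ccc_oracle(obs, pred):
    mx, my, vx, vy, cov = _pop_stats(obs, pred)
    ccc = 2 * cov / (vx + vy + (mx - my) ** 2)
    r = cov / math.sqrt(vx * vy)
    return ccc, r, ccc / r


def partition_oracle(obs, pred):
    n = len(obs)
    mse = sum((p - o) ** 2 for o, p in zip(obs, pred)) / n
    mx, my, vx, vy, cov = _pop_stats(obs, pred)
    r = cov / math.sqrt(vx * vy)
    ect = (my - mx) ** 2
    er = (math.sqrt(vy) - r * math.sqrt(vx)) ** 2
    ed = (1 - r * r) * vx
    return mse, ect, er, ed


finite_pairs = st.integers(5, 60).flatmap(
    lambda n: st.tuples(
        hnp.arrays(np.float64, n, elements=st.floats(-100, 100)),
        hnp.arrays(np.float64, n, elements=st.floats(-100, 100)),
    )
)


class TestConcordance:
    def test_perfect_agreement(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        ccc, r, cb = concordance(v, v)
        assert (ccc, r, cb) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_constant_shift_example(self):
        # Pure location shift: full precision, accuracy penalty only.
        # Population moments: vx = vy = cov = 2/3, shift^2 = 1 -> 4/7;
        # sample (n-1) moments: vx = vy = cov = 1 -> 2/3.
        ccc, r, cb = concordance([1, 2, 3], [2, 3, 4])
        assert r == pytest.approx(1.0)
        assert ccc == pytest.approx(4.0 / 7.0)
        assert cb == pytest.approx(4.0 / 7.0)
        ccc_s, r_s, cb_s = concordance([1, 2, 3], [2, 3, 4], "sample")
        assert r_s == pytest.approx(1.0)
        assert ccc_s == pytest.approx(2.0 / 3.0)
        assert cb_s == pytest.approx(2.0 / 3.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            concordance([1, 2], [1, 2])
        with pytest.raises(DegenerateInputError):
            concordance([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateInputError):
            concordance([1, 2, np.nan], [1, 2, 3])

    def test_ccc_equals_r_times_cb_and_bounds(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 100))
            obs = rng.normal(0, rng.uniform(0.5, 5), n)
            pred = obs * rng.uniform(-2, 2) + rng.normal(0, 1, n)
            if np.var(pred) == 0:
                continue
            ccc, r, cb = concordance(obs, pred)
            assert ccc == pytest.approx(r * cb, rel=1e-12)
            assert -1 <= ccc <= 1
            assert 0 < cb <= 1 + 1e-12
            assert abs(ccc) <= abs(r) + 1e-12

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            obs = rng.uniform(-50, 50, n)
            pred = rng.uniform(-50, 50, n)
            if np.var(obs) == 0 or np.var(pred) == 0:
                continue
            got = concordance(obs, pred)
            want = ccc_oracle(obs.tolist(), pred.tolist())
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-10, abs=1e-12)

    def test_sample_convention_close_at_large_n(self, rng):
        obs = rng.normal(1200, 370, 541)
        pred = obs + rng.normal(0, 250, 541)
        pop = concordance(obs, pred, "population")[0]
        samp = concordance(obs, pred, "sample")[0]
        assert pop == pytest.approx(samp, abs=5e-3)


class TestRmsePartition:
    def test_pure_mean_shift(self):
        rmse, pct, ect, er, ed = rmse_partition([1, 2, 3], [2, 3, 4])
        assert rmse == pytest.approx(1.0)
        assert (ect, er, ed) == (pytest.approx(100.0), pytest.approx(0.0), pytest.approx(0.0))
        assert pct == pytest.approx(50.0)  # rmse / mean(obs=2) * 100

    def test_perfect_negative_correlation_is_regression_bias(self):
        rmse, _, ect, er, ed = rmse_partition([1, 2, 3], [3, 2, 1])
        assert rmse**2 == pytest.approx(8.0 / 3.0)
        assert (ect, er, ed) == (pytest.approx(0.0), pytest.approx(100.0), pytest.approx(0.0))

    def test_zero_mse_reports_null_partition(self):
        rmse, pct, ect, er, ed = rmse_partition([1, 2, 3], [1, 2, 3])
        assert rmse == 0.0 and pct == 0.0
        assert math.isnan(ect) and math.isnan(er) and math.isnan(ed)

    @given(pair=finite_pairs)
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_components_sum_to_mse(self, pair):
        obs, pred = pair
        if np.var(obs) == 0 or np.var(pred) == 0 or np.allclose(obs, pred):
            return
        rmse, _, ect, er, ed = rmse_partition(obs, pred)
        assert ect + er + ed == pytest.approx(100.0, rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            obs = rng.uniform(1, 100, n)
            pred = rng.uniform(1, 100, n)
            if np.var(obs) == 0 or np.var(pred) == 0:
                continue
            rmse, pct, ect, er, ed = rmse_partition(obs, pred)
            mse, o_ect, o_er, o_ed = partition_oracle(obs.tolist(), pred.tolist())
            assert rmse == pytest.approx(math.sqrt(mse), rel=1e-10)
            assert ect == pytest.approx(o_ect / mse * 100, rel=1e-10, abs=1e-10)
            assert er == pytest.approx(o_er / mse * 100, rel=1e-10, abs=1e-10)
            assert ed == pytest.approx(o_ed / mse * 100, rel=1e-10, abs=1e-10)

    def test_additive_offset_moves_only_central_tendency(self, rng):
        obs = rng.normal(50, 10, 200)
        pred = obs + rng.normal(0, 5, 200)
        _, _, _, er0, ed0 = rmse_partition(obs, pred)
        _, _, _, er1, ed1 = rmse_partition(obs, pred + 7.0)
        # ER and ED are invariant in absolute terms; compare unnormalised.
        mse0 = np.mean((pred - obs) ** 2)
        mse1 = np.mean((pred + 7.0 - obs) ** 2)
        assert er0 * mse0 == pytest.approx(er1 * mse1, rel=1e-9)
        assert ed0 * mse0 == pytest.approx(ed1 * mse1, rel=1e-9)


class TestGroupedRegression:
    def test_identity_fit(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        herds = np.array(["A", "A", "B", "B"])
        (slope, intercept), fits = grouped_regression(v, v, herds, min_herd_n=2)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)
        for fit in fits:
            assert fit.slope == pytest.approx(1.0)
            assert fit.intercept == pytest.approx(0.0)

    def test_shifted_predictions_closed_form(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = obs + 1.0
        (slope, intercept), fits = grouped_regression(obs, pred, ["H"] * 3)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(-1.0)
        assert fits[0].slope == pytest.approx(1.0)

    def test_small_and_degenerate_herds_flagged_not_fatal(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pred = np.array([1.0, 2.0, 3.0, 2.0, 2.0, 2.0])
        herds = np.array(["A", "A", "A", "B", "B", "B"])
        _, fits = grouped_regression(obs, pred, herds)
        by_id = {f.herd_id: f for f in fits}
        assert not by_id["A"].flagged
        assert by_id["B"].flagged and by_id["B"].slope is None
        _, fits = grouped_regression(obs, pred, ["A", "A", "A", "A", "B", "B"])
        assert {f.herd_id: f.flagged for f in fits}["B"]

    def test_herd_intercept_noise_widens_slope_spread(self, rng):
        n_herds, per = 10, 40
        herds = np.repeat([f"H{i}" for i in range(n_herds)], per)
        pred = rng.normal(1200, 250, n_herds * per)
        clean_obs = pred + rng.normal(0, 60, pred.size)
        noisy_obs = clean_obs + np.repeat(rng.normal(0, 300, n_herds), per)
        def slope_var(obs):
            _, fits = grouped_regression(obs, pred, herds)
            return np.var([f.slope for f in fits])
        assert slope_var(noisy_obs) > slope_var(clean_obs)


def test_evaluate_assembles_consistent_report(rng):
    obs = rng.normal(1200, 370, 300)
    pred = obs + rng.normal(0, 250, 300)
    herds = np.repeat([f"H{i}" for i in range(10)], 30)
    rep = evaluate(obs, pred, herds, dmi=np.full(300, 24.0), dmi_source="observed")
    assert rep.n == 300
    assert rep.ccc == pytest.approx(rep.r * rep.cb, rel=1e-12)
    assert rep.ect_pct + rep.er_pct + rep.ed_pct == pytest.approx(100.0, rel=1e-9)
    assert rep.rmse_pct_mean == pytest.approx(rep.rmse / rep.mean_obs * 100, rel=1e-12)
    assert len(rep.per_herd_fits) == 10
    rows = rep.display_rows()
    assert rows["DMI, kg/d"].startswith("24.0")
    assert set(rep.ROW_LABELS.values()) == set(rows)
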