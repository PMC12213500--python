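"""The asymmetric-peak desirability curve and its least-squares fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import algiscore as a
from algiscore.binning import FrequencyTable
from algiscore.desirability import InsufficientDataError


def make_table(xs, ys):
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    return FrequencyTable(xs, ys, "continuous", int(round(ys.sum())),
                          bin_width=float(xs[1] - xs[0]))


class TestEvaluate:
    def test_peak_value_is_o_plus_a_at_b(self):
        p = a.DesirabilityParams(o=0.1, a=0.8, b=42.0, c=3.0, descriptor="mw")
        assert a.evaluate_desirability(p, 42.0) == pytest.approx(0.9, abs=1e-15)

    def test_closed_form_at_unit_offset(self):
        p = a.DesirabilityParams(o=0.0, a=1.0, b=0.0, c=1.0, descriptor="logp")
        assert a.evaluate_desirability(p, 1.0) == pytest.approx(
            np.exp(-np.exp(-1.0)), abs=1e-12)

    def test_both_tails_approach_baseline(self):
        p = a.DesirabilityParams(o=0.05, a=0.9, b=300.0, c=50.0, descriptor="mw")
        for x in (p.b + 20 * p.c, p.b - 20 * p.c):
            assert a.evaluate_desirability(p, x) == pytest.approx(0.05, abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(b=st.floats(-50, 50), c=st.floats(0.1, 10))
    def test_unimodal_on_dense_grid(self, b, c):
        p = a.DesirabilityParams(o=0.02, a=0.95, b=b, c=c, descriptor="logp")
        # left edge kept above t ~ -3.5: further out the doubly-exponential
        # tail drops below o * machine-eps and the sum is flat at o
        xs = np.linspace(b - 3.5 * c, b + 8 * c, 801)
        ys = a.evaluate_desirability(p, xs)
        i = int(np.argmin(np.abs(xs - b)))
        assert np.all(np.diff(ys[: i + 1]) > 0)
        assert np.all(np.diff(ys[i:]) < 0)

    def test_total_function_far_left_tail(self):
        p = a.DesirabilityParams(o=0.1, a=0.8, b=0.0, c=1.0, descriptor="logp")
        assert a.evaluate_desirability(p, -1e4) == pytest.approx(0.1)

    def test_zero_c_rejected(self):
        with pytest.raises(ValueError):
            a.DesirabilityParams(o=0.1, a=0.8, b=0.0, c=0.0, descriptor="mw")


class TestFit:
    def test_noise_free_self_samples_recovered_within_one_percent(self):
        truth = a.DesirabilityParams(o=0.05, a=0.9, b=3.0, c=0.8, descriptor="logp")
        xs = np.linspace(0, 8, 25)
        fit = a.fit_desirability(make_table(xs, a.evaluate_desirability(truth, xs)),
                                 "logp")
        for k in "oabc":
            assert getattr(fit, k) == pytest.approx(getattr(truth, k), rel=0.01)
        assert fit.fit_rmse < 1e-6

    def test_left_skew_recovered_with_negative_c(self):
        truth = a.DesirabilityParams(o=0.1, a=0.85, b=4.0, c=-1.2, descriptor="mw")
        xs = np.linspace(0, 8, 30)
        fit = a.fit_desirability(make_table(xs, a.evaluate_desirability(truth, xs)),
                                 "mw")
        assert fit.c == pytest.approx(-1.2, rel=0.01)
        assert fit.b == pytest.approx(4.0, rel=0.01)

    def test_four_points_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            a.fit_desirability(make_table([0, 1, 2, 3.0], [1, 2, 2, 1.0]), "mw")

    def test_fitted_peak_near_empirical_mode_of_unimodal_sample(self):
        rng = np.random.default_rng(5)
        values = rng.normal(10.0, 2.0, size=2000)
        ft = a.continuous_frequencies(values)
        fit = a.fit_desirability(ft, "logp")
        mode = ft.xs[int(np.argmax(ft.counts))]
        assert abs(fit.b - mode) <= ft.bin_width

    def test_noisy_replicates_recover_peak_location(self):
        # median relative error of b under 5% over 50 noisy draws
        rng = np.random.default_rng(202)
        errs = []
        for _ in range(50):
            o = rng.uniform(0, 0.2)
            truth = a.DesirabilityParams(
                o=o, a=1 - o, b=rng.uniform(2, 6),
                c=rng.uniform(0.5, 2) * rng.choice([1, -1]), descriptor="mw")
            xs = np.linspace(truth.b - 6 * abs(truth.c), truth.b + 6 * abs(truth.c), 30)
            ys = np.clip(a.evaluate_desirability(truth, xs)
                         + rng.normal(0, 0.05, xs.size), 0, None)
            fit = a.fit_desirability(make_table(xs, ys), "mw")
            errs.append(abs(fit.b - truth.b) / abs(truth.b))
        assert np.median(errs) < 0.05

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(9)
        values = rng.lognormal(1.2, 0.4, 600)
        ft = a.continuous_frequencies(values)
        f1 = a.fit_desirability(ft, "logp")
        f2 = a.fit_desirability(ft, "logp")
        assert f1.to_dict() == f2.to_dict()

    def test_raw_counts_are_normalized_to_unit_peak(self):
        rng = np.random.default_rng(4)
        ft = a.integer_frequencies(rng.poisson(3, 500))
        fit = a.fit_desirability(ft, "hba")
        assert 0 < fit.o + fit.a <= 1.05

    def test_fit_no_worse_than_any_initial_guess(self):
        # the optimiser may never regress past its own multi-start grid
        from algiscore.desirability import _curve

        rng = np.random.default_rng(8)
        values = rng.lognormal(1.0, 0.5, 800)
        ft = a.continuous_frequencies(values)
        fit = a.fit_desirability(ft, "logp")
        y = ft.counts / ft.counts.max()
        w = ft.counts / ft.counts.sum()
        mean = float(np.sum(w * ft.xs))
        sigma = float(np.sqrt(np.sum(w * (ft.xs - mean) ** 2)))
        mode = float(ft.xs[int(np.argmax(ft.counts))])
        for b0 in (mode, mean):
            for c0 in (sigma / 2, -sigma / 2, sigma, -sigma):
                for o0 in (0.0, float(y.min())):
                    start_rmse = float(np.sqrt(np.mean(
                        (_curve(np.array([min(o0, 0.5), min(1 - o0, 1.2), b0, c0]),
                                ft.xs) - y) ** 2)))
                    assert fit.fit_rmse <= start_rmse + 1e-12

    def test_params_roundtrip_through_dict(self):
        p = a.DesirabilityParams(o=0.1, a=0.9, b=2.5, c=-0.7, descriptor="hbd",
                                 fit_rmse=0.01, fit_range=(0.0, 9.0), kind="discrete")
        assert a.DesirabilityParams.from_dict(p.to_dict()) == p
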