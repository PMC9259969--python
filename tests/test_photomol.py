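"""Mass-photometry analysis: calibration, histogram, truncated-mixture fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitriqc.photomol import (
    CalibrationStandard,
    MassHistogram,
    MPEventSet,
    TruncatedGaussianMixture,
    _bin_expectations,
    apply_calibration,
    assign_stoichiometry,
    build_histogram,
    detect_peaks,
    fit_calibration,
    fit_truncated_mixture,
    qc_event_count,
)
from vitriqc.synth import MPComponentSpec, gen_mp_events


def model_histogram(mu, sigma, n, t, edges):
    """Histogram whose counts equal the truncated-Gaussian expectations."""
    params = np.array([mu, sigma, n], dtype=float)
    counts = _bin_expectations(params, edges[:-1], edges[1:], t, True)
    return MassHistogram(
        bin_edges=edges, counts=counts, window=(edges[0], edges[-1]),
        bin_width=edges[1] - edges[0],
    )


class TestCalibration:
    def test_exact_line_recovered(self):
        masses = [66.0, 146.0, 480.0]
        standards = [
            CalibrationStandard(f"NM{i+1}", m, -m / 20000.0)
            for i, m in enumerate(masses)
        ]
        model = fit_calibration(standards)
        assert model.slope == pytest.approx(-20000.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.max_rel_error == pytest.approx(0.0, abs=1e-9)
        assert model.is_valid

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(7)
        c = np.array([-3.3e-3, -7.3e-3, -2.4e-2]) * (1 + 0.01 * rng.standard_normal(3))
        m = np.array([66.0, 146.0, 480.0])
        model = fit_calibration(
            [CalibrationStandard(str(i), mi, ci) for i, (mi, ci) in enumerate(zip(m, c))]
        )
        # independent closed-form OLS
        a = np.sum((c - c.mean()) * (m - m.mean())) / np.sum((c - c.mean()) ** 2)
        b = m.mean() - a * c.mean()
        assert model.slope == pytest.approx(a, rel=1e-10)
        assert model.intercept == pytest.approx(b, rel=1e-10)

    def test_force_origin_fixes_intercept(self):
        standards = [
            CalibrationStandard("a", 100.0, -0.005),
            CalibrationStandard("b", 200.0, -0.0101),
        ]
        model = fit_calibration(standards, force_origin=True)
        assert model.intercept == 0.0

    def test_validity_rule_five_percent(self):
        # one standard 10% off the line trips the validity bound
        standards = [
            CalibrationStandard("a", 66.0, -66 / 20000),
            CalibrationStandard("b", 146.0, -146 / 20000),
            CalibrationStandard("c", 480.0, -480 * 1.2 / 20000),
        ]
        with pytest.warns(UserWarning, match="calibration"):
            model = fit_calibration(standards)
        assert not model.is_valid
        assert model.max_rel_error >= 5.0

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_calibration([CalibrationStandard("a", 66.0, -0.003)])
        with pytest.raises(ValueError):
            fit_calibration(
                [CalibrationStandard("a", 66.0, -0.003),
                 CalibrationStandard("b", 146.0, -0.003)]
            )

    def test_apply_calibration_maps_standards_back(self):
        standards = [
            CalibrationStandard(f"s{i}", m, -(m + 5.0) / 20000.0)
            for i, m in enumerate([66.0, 146.0, 480.0])
        ]
        model = fit_calibration(standards)
        events = MPEventSet([s.mean_contrast for s in standards], kind="contrast")
        calibrated = apply_calibration(events, model)
        assert calibrated.kind == "mass"
        for value, s in zip(calibrated.values, standards):
            assert abs(value - s.known_mass) / s.known_mass <= (
                model.max_rel_error / 100.0 + 1e-12
            )

    def test_apply_refuses_double_calibration(self):
        model = fit_calibration(
            [CalibrationStandard("a", 66.0, -0.0033),
             CalibrationStandard("b", 480.0, -0.024)]
        )
        with pytest.raises(ValueError, match="refus"):
            apply_calibration(MPEventSet([66.0], kind="mass"), model)

    def test_identity_model_preserves_values(self):
        from vitriqc.photomol import CalibrationModel

        model = CalibrationModel(slope=1.0, intercept=0.0)
        events = MPEventSet([0.5, -0.2, 3.0], kind="contrast")
        out = apply_calibration(events, model)
        np.testing.assert_allclose(out.values, events.values)


class TestHistogram:
    def test_hand_counted_bins(self):
        events = MPEventSet([50.0, 50.0, 70.0], kind="mass")
        hist = build_histogram(events, bin_width=20.0, window=(40.0, 80.0))
        np.testing.assert_array_equal(hist.counts, [2, 1])

    def test_empty_window_warns(self):
        events = MPEventSet([500.0, 600.0], kind="mass")
        with pytest.warns(UserWarning, match="0 events"):
            hist = build_histogram(events, bin_width=10.0, window=(0.0, 100.0))
        assert hist.counts.sum() == 0
        assert hist.n_excluded == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        events = MPEventSet(rng.uniform(-100, 900, 1000), kind="mass")
        hist = build_histogram(events, bin_width=25.0, window=(0.0, 500.0))
        assert hist.counts.sum() + hist.n_excluded == events.n

    def test_invalid_parameters(self):
        events = MPEventSet([50.0], kind="mass")
        with pytest.raises(ValueError):
            build_histogram(events, bin_width=0.0)
        with pytest.raises(ValueError):
            build_histogram(events, window=(100.0, 100.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_event_permutation(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(30, 700, 200)
        h1 = build_histogram(MPEventSet(values, kind="mass"), 10.0, (0.0, 700.0))
        h2 = build_histogram(
            MPEventSet(rng.permutation(values), kind="mass"), 10.0, (0.0, 700.0)
        )
        np.testing.assert_array_equal(h1.counts, h2.counts)


class TestPeakDetection:
    def test_single_populated_bin(self):
        edges = np.arange(0.0, 710.0, 10.0)
        counts = np.zeros(70)
        counts[48] = 100  # bin [480, 490)
        hist = MassHistogram(edges, counts, (0.0, 700.0), 10.0)
        guesses = detect_peaks(hist)
        assert len(guesses) == 1
        assert guesses[0][0] == pytest.approx(485.0)

    def test_flat_histogram_has_no_peaks(self):
        edges = np.arange(0.0, 710.0, 10.0)
        hist = MassHistogram(edges, np.full(70, 7), (0.0, 700.0), 10.0)
        assert detect_peaks(hist) == []

    def test_two_component_sample_gives_two_guesses(self):
        events = gen_mp_events(
            [MPComponentSpec(66, 0.08 * 66, 2500), MPComponentSpec(480, 0.08 * 480, 2500)],
            detection_limit=30, seed=5,
        )
        hist = build_histogram(events, 10.0, (0.0, 700.0))
        guesses = detect_peaks(hist)
        assert len(guesses) == 2
        assert abs(guesses[0][0] - 66) <= hist.bin_width
        assert abs(guesses[1][0] - 480) <= hist.bin_width


class TestTruncatedMixtureFit:
    def test_recovers_exact_model(self):
        edges = np.arange(0.0, 310.0, 10.0)
        hist = model_histogram(100.0, 10.0, 1000.0, 30.0, edges)
        res = fit_truncated_mixture(
            hist, guesses=[(95.0, 12.0, 900.0)], truncation_limit=30.0
        )
        c = res.components[0]
        assert c.mu == pytest.approx(100.0, rel=1e-6)
        assert c.sigma == pytest.approx(10.0, rel=1e-6)
        assert c.n_counts == pytest.approx(1000.0, rel=1e-6)
        assert res.residual_norm == pytest.approx(0.0, abs=1e-10)
        assert res.converged

    def test_truncation_off_limit_equals_plain_gaussian_fit(self):
        # t far below the window: truncated model reduces to a plain
        # Gaussian; compare against an independent untruncated fit
        from scipy.optimize import least_squares
        from scipy.stats import norm as norm_dist

        rng = np.random.default_rng(11)
        values = rng.normal(200.0, 25.0, 4000)
        hist = build_histogram(MPEventSet(values, kind="mass"), 10.0, (0.0, 400.0))
        t_off = hist.window[0] - 10 * 25.0
        res = fit_truncated_mixture(
            hist, guesses=[(190.0, 30.0, 3500.0)], truncation_limit=t_off
        )

        lo, hi = hist.bin_edges[:-1], hist.bin_edges[1:]

        def plain_resid(p):
            mu, sigma, n = p
            return (
                n * (norm_dist.cdf((hi - mu) / sigma) - norm_dist.cdf((lo - mu) / sigma))
                - hist.counts
            )

        sol = least_squares(plain_resid, x0=[190.0, 30.0, 3500.0],
                            ftol=1e-12, xtol=1e-12, gtol=1e-12)
        c = res.components[0]
        assert c.mu == pytest.approx(sol.x[0], rel=1e-6)
        assert c.sigma == pytest.approx(sol.x[1], rel=1e-6)
        assert c.n_counts == pytest.approx(sol.x[2], rel=1e-6)

    def test_model_zero_below_truncation(self):
        edges = np.arange(0.0, 310.0, 10.0)
        hist = model_histogram(100.0, 30.0, 1000.0, 50.0, edges)
        est = TruncatedGaussianMixture(truncation_limit=50.0).fit(
            hist, guesses=[(100.0, 30.0, 1000.0)]
        )
        model = est.predict(hist)
        below = edges[1:] <= 50.0
        np.testing.assert_array_equal(model[below], 0.0)

    @pytest.mark.parametrize(
        "mus,counts",
        [
            ([66.0, 146.0, 480.0], [3000, 3000, 3000]),
            ([106.0, 274.0, 461.0], [4000, 3000, 2000]),
            ([147.0, 278.0], [4000, 4000]),
        ],
    )
    def test_parameter_recovery_on_seeded_samples(self, mus, counts):
        specs = [MPComponentSpec(m, 0.08 * m, c) for m, c in zip(mus, counts)]
        events = gen_mp_events(specs, detection_limit=40.0, seed=19)
        hist = build_histogram(events, 10.0, (0.0, 700.0))
        res = fit_truncated_mixture(hist, truncation_limit=40.0)
        assert len(res.components) == len(mus)
        for comp, mu_true, n_true in zip(res.components, mus, counts):
            assert abs(comp.mu - mu_true) / mu_true <= 0.015
            assert abs(comp.n_counts - n_true) / n_true <= 0.05

    def test_count_conservation_and_fraction_sum(self):
        events = gen_mp_events(
            [MPComponentSpec(150, 15, 3000), MPComponentSpec(480, 40, 2000)],
            detection_limit=30.0, seed=23,
        )
        hist = build_histogram(events, 10.0, (0.0, 700.0))
        est = TruncatedGaussianMixture(truncation_limit=30.0).fit(hist)
        assert est.fractions_.sum() == pytest.approx(1.0, abs=1e-9)
        # N_k is the observable count: model expectations over all bins
        # above t must total Sum N_k (up to window leakage)
        model_total = est.predict(hist).sum()
        assert model_total == pytest.approx(est.counts_.sum(), rel=1e-3)

    def test_result_invariant_under_event_order(self):
        values = gen_mp_events(
            [MPComponentSpec(200, 20, 2000)], detection_limit=30.0, seed=31
        ).values
        h1 = build_histogram(MPEventSet(values, kind="mass"), 10.0, (0.0, 400.0))
        h2 = build_histogram(
            MPEventSet(values[::-1].copy(), kind="mass"), 10.0, (0.0, 400.0)
        )
        r1 = fit_truncated_mixture(h1, truncation_limit=30.0)
        r2 = fit_truncated_mixture(h2, truncation_limit=30.0)
        assert r1.components[0].mu == pytest.approx(r2.components[0].mu, rel=1e-12)

    def test_no_guesses_raises(self):
        edges = np.arange(0.0, 110.0, 10.0)
        hist = MassHistogram(edges, np.zeros(10), (0.0, 100.0), 10.0)
        with pytest.raises(ValueError, match="guess"):
            fit_truncated_mixture(hist, guesses=[])


class TestStoichiometry:
    def test_hexamer_assignment(self):
        res = assign_stoichiometry(108.0, 18.5)
        assert res.n == 6
        assert res.rel_deviation == pytest.approx(0.027, abs=0.001)
        assert res.accepted

    def test_monomer_identity(self):
        res = assign_stoichiometry(100.0, 100.0)
        assert res.n == 1
        assert res.rel_deviation == 0.0

    def test_round_matches_exhaustive_search(self):
        rng = np.random.default_rng(101)
        for _ in range(1000):
            monomer = rng.uniform(10.0, 200.0)
            peak = rng.uniform(monomer * 0.6, monomer * 45.0)
            n_best = min(range(1, 51), key=lambda n: abs(peak - n * monomer))
            assert assign_stoichiometry(peak, monomer).n == n_best

    def test_rejects_nonpositive_masses(self):
        with pytest.raises(ValueError):
            assign_stoichiometry(-1.0, 10.0)
        with pytest.raises(ValueError):
            assign_stoichiometry(100.0, 0.0)


class TestEventCountQC:
    def test_too_many_events_regular_fov(self):
        events = MPEventSet(np.ones(3500), kind="mass")
        qc = qc_event_count(events, fov="regular")
        assert qc.too_many and not qc.too_few

    def test_binding_ratio(self):
        values = np.concatenate([np.ones(1350), -np.ones(150)])
        qc = qc_event_count(MPEventSet(values, kind="mass"))
        assert not qc.too_many and not qc.too_few
        assert qc.binding_unbinding_ratio == pytest.approx(9.0)

    def test_too_few_events(self):
        qc = qc_event_count(MPEventSet(np.ones(50), kind="mass"))
        assert qc.too_few
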