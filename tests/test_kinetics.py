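"""ThT curve processing: blank subtraction, normalisation, t50, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phosphozip.kinetics import (
    AssemblyCall,
    DegenerateStartError,
    GridMismatchError,
    InsufficientReplicatesError,
    KineticCurve,
    NoCrossingError,
    NonAggregatorError,
    ReplicateSet,
    ThTKineticsModel,
    classify_assembly,
    compute_t50,
    normalize_to_plateau,
    subtract_blank,
    summarize_t50,
)
from phosphozip.simulate import ThTSimParams, simulate_tht_replicates


def _curve(t, y, well="w"):
    return KineticCurve(np.asarray(t, float), np.asarray(y, float), well)


def _repset(curves, blank, **kw):
    return ReplicateSet(tuple(curves), blank, **kw)


class TestSubtractBlank:
    def test_self_subtraction_gives_zero(self):
        c = _curve([0, 1, 2], [3.0, 4.0, 5.0])
        out = subtract_blank(_repset([c], c))
        assert np.allclose(out.curves[0].intensities, 0.0)

    def test_constant_offset(self):
        c = _curve([0, 1, 2], [10, 20, 30])
        b = _curve([0, 1, 2], [1, 1, 1])
        out = subtract_blank(_repset([c], b))
        assert np.allclose(out.curves[0].intensities, [9, 19, 29])

    def test_round_trip_identity(self, rng):
        t = np.arange(20.0)
        y = rng.normal(size=20)
        b = rng.normal(size=20)
        out = subtract_blank(_repset([_curve(t, y)], _curve(t, b)))
        assert np.allclose(out.curves[0].intensities + b, y)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            _repset([_curve([0, 1, 2], [1, 2, 3])], _curve([0, 1, 2.5], [0, 0, 0]))


class TestNormalizeToPlateau:
    def test_ratio(self):
        y = np.concatenate([np.full(8, 25.0), np.full(2, 50.0)])
        out = normalize_to_plateau(_curve(np.arange(10.0), y), 0.2)
        assert out.intensities[4] == pytest.approx(0.5)
        assert np.mean(out.intensities[-2:]) == pytest.approx(1.0)

    def test_idempotent(self):
        y = np.linspace(0, 1, 30)
        once = normalize_to_plateau(_curve(np.arange(30.0), y))
        twice = normalize_to_plateau(once)
        assert np.allclose(once.intensities, twice.intensities)

    def test_nonpositive_plateau_rejected(self):
        with pytest.raises(NonAggregatorError):
            normalize_to_plateau(_curve([0, 1, 2], [0.0, 0.0, 0.0]))

    def test_sigmoid_plateau_near_one(self):
        reps, _ = simulate_tht_replicates(ThTSimParams(seed=0))
        sub = subtract_blank(reps)
        out = normalize_to_plateau(sub.curves[0])
        assert abs(out.intensities.max() - 1.0) < 0.1


class TestComputeT50:
    def test_symmetric_bracket_midpoint(self):
        est = compute_t50(_curve([4.0, 6.0], [0.0, 1.0]))
        assert est.t50 == pytest.approx(5.0)
        assert (est.t1, est.t2) == (4.0, 6.0)

    def test_hand_computed_interpolation(self):
        # t50 = 1 + 2 * (0.5 - 0.4) / (0.9 - 0.4) = 1.4
        est = compute_t50(_curve([1.0, 3.0], [0.4, 0.9]))
        assert est.t50 == pytest.approx(1.4)

    @pytest.mark.parametrize("n", [51, 201, 801])
    def test_logistic_midpoint_converges_to_tau(self, n):
        tau, k = 11.0, 1.7
        t = np.linspace(0, 30, n)
        y = 1.0 / (1.0 + np.exp(-k * (t - tau)))
        err = abs(compute_t50(_curve(t, y)).t50 - tau)
        assert err < 30.0 / (n - 1)  # within one sample spacing

    def test_never_crossing_raises(self):
        with pytest.raises(NoCrossingError):
            compute_t50(_curve([0, 1, 2], [0.1, 0.2, 0.3]))

    def test_degenerate_start_raises(self):
        with pytest.raises(DegenerateStartError):
            compute_t50(_curve([0, 1, 2], [0.8, 0.9, 1.0]))

    def test_noise_spike_before_minimum_ignored(self):
        y = [0.6, 0.05, 0.2, 0.7, 1.0]
        est = compute_t50(_curve([0, 1, 2, 3, 4], y))
        assert est.t1 >= 2.0

    @given(
        t1=st.floats(0, 100),
        dt=st.floats(0.01, 50),
        y1=st.floats(0, 0.499),
        y2=st.floats(0.5, 2.0),
    )
    def test_exact_on_any_two_point_bracket(self, t1, dt, y1, y2):
        """Linear interpolation is algebraically exact on a bracket."""
        est = compute_t50(_curve([t1, t1 + dt], [y1, y2]))
        expected = t1 + dt * (0.5 - y1) / (y2 - y1)
        assert est.t50 == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_time_translation_equivariance(self):
        t = np.linspace(0, 20, 101)
        y = 1 / (1 + np.exp(-(t - 9.0)))
        base = compute_t50(_curve(t, y)).t50
        shifted = compute_t50(_curve(t + 7.5, y)).t50
        assert shifted == pytest.approx(base + 7.5)

    def test_invariant_under_rescale_then_renormalise(self):
        t = np.linspace(0, 20, 101)
        y = 1 / (1 + np.exp(-(t - 9.0)))
        base = compute_t50(_curve(t, y)).t50
        scaled = normalize_to_plateau(_curve(t, 37.0 * y))
        assert compute_t50(scaled).t50 == pytest.approx(base, abs=1e-3)


class TestSummarizeT50:
    def test_degenerate_identical_values(self):
        s = summarize_t50([2.0] * 40)
        assert (s.mean_t50, s.sd_t50) == (2.0, 0.0)
        assert s.method == "degenerate"

    def test_normal_draws_recovered(self, rng):
        x = rng.normal(10, 1, size=40)
        s = summarize_t50(x)
        assert abs(s.mean_t50 - 10) < 3 / np.sqrt(40) + abs(x.mean() - 10)

    def test_bimodal_falls_back_with_warning(self, rng):
        x = np.concatenate([rng.normal(5, 0.1, 20), rng.normal(15, 0.1, 20)])
        with pytest.warns(UserWarning, match="falling back"):
            s = summarize_t50(x)
        assert s.method == "sample_stats"
        assert s.mean_t50 == pytest.approx(x.mean())

    def test_requires_five_values(self):
        with pytest.raises(ValueError):
            summarize_t50([1.0, 2.0, 3.0])

    def test_mean_scales_under_time_dilation(self, rng):
        x = rng.normal(10, 1, size=40)
        s1 = summarize_t50(x)
        s2 = summarize_t50(3.0 * x)
        assert s2.mean_t50 == pytest.approx(3.0 * s1.mean_t50, rel=1e-6)


class TestClassifyAssembly:
    def test_flat_curves_are_no_fibrils(self):
        t = np.arange(50.0)
        curves = [_curve(t, np.zeros(50), f"w{i}") for i in range(5)]
        blank = _curve(t, np.zeros(50))
        call = classify_assembly(_repset(curves, blank))
        assert call.outcome == "no_fibrils"
        assert call.censored_at == 49.0

    def test_sigmoids_are_fibrils(self):
        t = np.linspace(0, 30, 100)
        y = 100 / (1 + np.exp(-(t - 10)))
        curves = [_curve(t, y, f"w{i}") for i in range(5)]
        call = classify_assembly(_repset(curves, _curve(t, np.zeros(100))))
        assert call.outcome == "fibrils"
        assert call.censored_at is None

    def test_requires_three_curves(self):
        t = np.arange(10.0)
        with pytest.raises(InsufficientReplicatesError):
            classify_assembly(_repset([_curve(t, np.zeros(10))], _curve(t, np.zeros(10))))

    def test_zero_plateau_simulation_is_no_fibrils(self):
        reps, _ = simulate_tht_replicates(ThTSimParams(plateau_mean=0.0, seed=4))
        sub = subtract_blank(reps)
        assert classify_assembly(sub).outcome == "no_fibrils"

    def test_call_deterministic_given_seed(self):
        params = ThTSimParams(plateau_mean=10.0, noise_sd=1.0, seed=11)
        calls = set()
        for _ in range(3):
            reps, _ = simulate_tht_replicates(params)
            calls.add(classify_assembly(subtract_blank(reps)).outcome)
        assert len(calls) == 1

    def test_assembly_call_invariant(self):
        with pytest.raises(ValueError):
            AssemblyCall("no_fibrils")  # censored_at required
        with pytest.raises(ValueError):
            AssemblyCall("fibrils", censored_at=4.0)


class TestPipelineRecovery:
    def test_recovers_truth_on_default_simulation(self):
        """Mean within 2%, SD within 25% of generator truth (seeds 1-10)."""
        mus, sds = [], []
        for seed in range(1, 11):
            reps, _ = simulate_tht_replicates(ThTSimParams(seed=seed))
            res = ThTKineticsModel(reps).fit()
            assert res.call.outcome == "fibrils"
            mus.append(res.mean_t50)
            sds.append(res.sd_t50)
        assert abs(np.mean(mus) / 10.0 - 1) < 0.02
        assert abs(np.mean(sds) / 1.0 - 1) < 0.25

    def test_noiseless_limit_exact(self):
        params = ThTSimParams(true_t50_sd=0.0, noise_sd=0.0, plateau_cv=0.0, seed=0)
        reps, truth = simulate_tht_replicates(params)
        res = ThTKineticsModel(reps).fit()
        # interpolation error bounded by curvature over one sample spacing
        assert abs(res.t50s.mean() - truth.t50.mean()) < 0.01
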