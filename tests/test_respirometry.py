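"""Trace fitting: rate recovery, decision rule, detection limit, I/O."""

import numpy as np
import pytest

from pirtfield import (
    OxygenTrace,
    TraceSpec,
    detection_limit,
    fit_trace,
    flag_below_detection,
    make_trace,
)
from pirtfield.errors import InputError, InsufficientReplicationError
from pirtfield.respirometry import fit_batch, read_manifest, read_trace, write_trace


def _trace(rate=5.0, curvature=0.0, noise=0.0, seed=0, duration=18.0, o2_start=300.0):
    return make_trace(TraceSpec(duration_h=duration, o2_start=o2_start,
                                linear_rate=rate, curvature=curvature,
                                noise_sd=noise, seed=seed))


class TestFitTrace:
    def test_noiseless_line_recovers_rate_exactly(self):
        res = fit_trace(_trace(rate=5.0))
        assert res.model_used == "linear"
        assert res.rate == pytest.approx(5.0, abs=1e-9)
        assert res.monotonic_decline

    def test_noiseless_curve_recovers_derivative_at_one_hour(self):
        # O2(t) = 300 - 5t - 12t^2 (t in days): -dO2/dt at 1 h is 5 + 24/24 = 6
        res = fit_trace(_trace(rate=5.0, curvature=24.0))
        assert res.model_used == "quadratic"
        assert res.r2_quadratic - res.r2_linear > 0.02
        assert res.rate == pytest.approx(6.0, abs=1e-9)

    @pytest.mark.parametrize("curvature", [0.0, 24.0])
    def test_noiseless_recovery_matches_generator_truth(self, curvature):
        trace = _trace(rate=4.0, curvature=curvature)
        res = fit_trace(trace)
        assert res.rate == pytest.approx(trace.meta["true_rate_at_1h"], abs=1e-9)

    def test_invariant_to_oxygen_offset(self):
        trace = _trace(rate=5.0, curvature=30.0, noise=0.4, seed=3)
        shifted = OxygenTrace(times_h=trace.times_h, o2=trace.o2 + 50.0)
        assert fit_trace(shifted).rate == pytest.approx(fit_trace(trace).rate, abs=1e-9)

    def test_declining_oxygen_gives_positive_rate(self):
        assert fit_trace(_trace(rate=2.0, noise=0.1, seed=4)).rate > 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        traces = [
            _trace(rate=3.0, curvature=float(rng.uniform(0, 40)),
                   noise=float(rng.uniform(0.05, 0.5)), seed=i)
            for i in range(60)
        ]
        counts = []
        for thr in [0.0, 0.005, 0.02, 0.05, 0.1]:
            counts.append(sum(fit_trace(t, nonlinearity_threshold=thr).model_used
                              == "quadratic" for t in traces))
        assert counts == sorted(counts, reverse=True)

    def test_batch_statistics_match_per_trace_oracle(self):
        """Nonlinear fraction and linear-model underestimate vs a re-fit of each trace."""
        traces = [_trace(rate=3.0, curvature=30.0, noise=0.3, seed=100 + i)
                  for i in range(100)]
        table = fit_batch(traces)
        # oracle: refit every trace from scratch with numpy.polyfit
        n_nonlin = 0
        underest = []
        for tr, rate in zip(traces, table["rate_umol_dm3_d"]):
            t = tr.times_h / 24.0
            lin = np.polyfit(t, tr.o2, 1)
            quad = np.polyfit(t, tr.o2, 2)
            r2 = []
            for coeff in (lin, quad):
                resid = tr.o2 - np.polyval(coeff, t)
                r2.append(1 - resid.var() / tr.o2.var())
            if r2[1] - r2[0] >= 0.02:
                n_nonlin += 1
                expected = -(quad[1] + 2 * quad[0] / 24.0)
            else:
                expected = -lin[0]
            assert rate == pytest.approx(expected, rel=1e-9)
            underest.append(-lin[0] / expected - 1.0)
        assert n_nonlin == (table["model_used"] == "quadratic").sum()

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            OxygenTrace(times_h=np.array([0.0, 1.0]), o2=np.array([3.0, 2.0]))

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(InputError):
            OxygenTrace(times_h=np.array([0.0, 2.0, 1.0]), o2=np.array([3.0, 2.0, 1.0]))


class TestDetectionLimit:
    def test_flat_noiseless_controls_give_zero(self):
        controls = [_trace(rate=0.0, seed=i) for i in range(3)]
        assert detection_limit(controls) == pytest.approx(0.0, abs=1e-12)

    def test_two_opposite_drifts_closed_form(self):
        # rates +a and -a with zero within-trace error: limit = sample SD = a*sqrt(2)
        a = 0.4
        controls = [_trace(rate=a), _trace(rate=-a, o2_start=280.0)]
        assert detection_limit(controls) == pytest.approx(a * np.sqrt(2), rel=1e-9)

    def test_monte_carlo_matches_analytic_expectation(self):
        noise, drift = 0.5, 0.6
        controls = [make_trace(TraceSpec(duration_h=12.0, linear_rate=0.0,
                                         noise_sd=noise, drift_sd=drift, seed=i))
                    for i in range(50)]
        t_days = controls[0].times_h / 24.0
        sxx = np.sum((t_days - t_days.mean()) ** 2)
        se_slope2 = noise**2 / sxx
        expected = np.sqrt(2 * se_slope2 + drift**2)
        assert detection_limit(controls) == pytest.approx(expected, rel=0.2)

    def test_single_control_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            detection_limit([_trace()])


class TestFlagBelowDetection:
    @pytest.mark.parametrize("rate, flagged", [(0.5, True), (0.9, False), (5.0, False)])
    def test_strict_boundary_at_published_limit(self, rate, flagged):
        res = fit_trace(_trace(rate=rate))
        out = flag_below_detection(res, 0.9)
        assert out.below_detection is flagged
        assert out.rate == res.rate  # value preserved


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        trace = make_trace(TraceSpec(noise_sd=0.2, seed=9, sample_id="S3-deep",
                                     temperature=13.5))
        path = tmp_path / "trace.tsv"
        write_trace(trace, path)
        back = read_trace(path)
        assert back.sample_id == "S3-deep"
        assert back.temperature == 13.5
        assert np.allclose(back.o2, trace.o2)
        assert float(back.meta["true_rate_at_1h"]) == pytest.approx(
            trace.meta["true_rate_at_1h"])

    def test_manifest_requires_known_roles(self, tmp_path):
        p = tmp_path / "manifest.tsv"
        p.write_text("path\trole\nx.tsv\tblank\n")
        with pytest.raises(InputError):
            read_manifest(p)

    def test_batch_flags_against_control_limit(self):
        samples = [_trace(rate=5.0, noise=0.05, seed=i) for i in range(3)]
        samples.append(_trace(rate=0.01, noise=0.05, seed=30))
        controls = [make_trace(TraceSpec(linear_rate=0.0, noise_sd=0.05,
                                         drift_sd=0.1, seed=50 + i)) for i in range(4)]
        table = fit_batch(samples, controls)
        assert table.attrs["detection_limit"] > 0
        assert not table["below_detection"].iloc[:3].any()
        assert table["below_detection"].iloc[3]
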