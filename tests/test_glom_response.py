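import math

import numpy as np
import pytest

from osn_stream.glom_response import (
    DegenerateBaselineError,
    ResponseMetrics,
    analyze_dataset,
    average_trials,
    blank_subtract,
    compute_response,
    glomerular_density,
    responder_fraction,
)
from osn_stream.model import TrialTrace, ValidationError
from osn_stream.synthetic import GlomGenConfig, doexp_kernel, generate_glom_dataset
from conftest import make_step_trace


def _trials(sched, arrays):
    return [
        TrialTrace("r1", sched.stimulus_label, i + 1, a, sched)
        for i, a in enumerate(arrays)
    ]


class TestAverageTrials:
    def test_identical_trials_average_to_themselves(self, sched15):
        tr = make_step_trace(sched15)
        avg = average_trials(_trials(sched15, [tr, tr, tr]))
        np.testing.assert_array_equal(avg, tr)

    def test_constant_trials_average(self, sched15):
        n = sched15.n_samples
        avg = average_trials(_trials(sched15, [np.zeros(n), np.full(n, 2.0)]))
        np.testing.assert_array_equal(avg, np.ones(n))

    def test_noise_reduction_scales_as_sqrt_n(self, sched15):
        # averaging 3 iid-noise trials shrinks the SD by ~1/sqrt(3)
        rng = np.random.default_rng(0)
        sigma, n = 4.0, 1000
        long_sched = type(sched15)(
            "s", "od", 0.01, False, 4.0, 1.0, n / 15.0, 15.0
        )
        trials = _trials(long_sched, [100 + rng.normal(0, sigma, n) for _ in range(3)])
        avg = average_trials(trials)
        assert avg.std() == pytest.approx(sigma / math.sqrt(3), rel=0.10)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            average_trials([])

    def test_off_by_one_lengths_trimmed(self, sched15):
        n = sched15.n_samples
        trials = _trials(sched15, [np.ones(n), np.ones(n - 1)])
        assert len(average_trials(trials)) == n - 1


class TestComputeResponse:
    def test_clean_step_gives_exact_dff(self, sched15, cfg):
        m = compute_response(make_step_trace(sched15, 100.0, 50.0), sched15, cfg)
        assert m.is_responder
        assert m.dff_pct == pytest.approx(50.0)
        assert m.baseline_sd == 0.0

    def test_pure_noise_not_a_responder(self, sched15, cfg):
        rng = np.random.default_rng(1)
        # tiny bump, far below 3 SD of the baseline
        trace = 100 + rng.normal(0, 5.0, sched15.n_samples)
        m = compute_response(trace, sched15, cfg)
        if not m.is_responder:
            assert m.dff_pct == 0.0
            assert math.isnan(m.latency_s)

    def test_transient_amplitude_and_latency_vs_scan_oracle(self, sched15, cfg):
        rng = np.random.default_rng(2)
        amp_pct, f0, sigma = 80.0, 100.0, 2.0
        n = sched15.n_samples
        t = np.arange(n) / sched15.sampling_rate_hz
        k = doexp_kernel(t - sched15.onset_s - 0.3, 0.2, 1.0)
        k = k / k.max()
        trials = [f0 * (1 + amp_pct / 100 * k) + rng.normal(0, sigma, n) for _ in range(3)]
        avg = np.mean(trials, axis=0)
        m = compute_response(avg, sched15, cfg)
        assert m.is_responder
        # recovered amplitude within the 3-SD-of-baseline detection bound
        bound = 3 * 100 * m.baseline_sd / m.baseline_mean
        assert abs(m.dff_pct - amp_pct) < max(bound, 1.0)
        # latency: brute-force sample scan with the identical threshold
        base = avg[(t >= sched15.onset_s - 1.0) & (t < sched15.onset_s)]
        thr = base.mean() + 3 * base.std()
        oracle = next(
            ti for ti, v in zip(t, avg) if ti > sched15.onset_s and v > thr
        ) - sched15.onset_s
        assert m.latency_s == pytest.approx(oracle, abs=1e-12)

    def test_latency_never_exceeds_time_to_peak(self, sched15, cfg):
        rng = np.random.default_rng(3)
        n = sched15.n_samples
        t = np.arange(n) / sched15.sampling_rate_hz
        for i in range(30):
            k = doexp_kernel(t - sched15.onset_s - rng.uniform(0, 1), 0.2, 1.0)
            trace = 100 * (1 + rng.uniform(0.2, 3) * k) + rng.normal(0, 2, n)
            m = compute_response(trace, sched15, cfg)
            if m.is_responder:
                assert m.latency_s <= m.time_to_peak_s

    def test_dff_gain_invariance(self, sched15, cfg):
        rng = np.random.default_rng(4)
        trace = make_step_trace(sched15, 100.0, 60.0) + rng.normal(0, 1, sched15.n_samples)
        m1 = compute_response(trace, sched15, cfg)
        m2 = compute_response(trace * 7.3, sched15, cfg)
        assert m2.dff_pct == pytest.approx(m1.dff_pct, rel=1e-12)
        assert m2.delta_f == pytest.approx(m1.delta_f * 7.3, rel=1e-12)

    def test_responder_monotone_in_amplitude(self, sched15, cfg):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 2, sched15.n_samples)
        seen_true = False
        for amp in np.linspace(0, 60, 25):
            trace = make_step_trace(sched15, 100.0, amp) + noise
            m = compute_response(trace, sched15, cfg)
            if seen_true:
                assert m.is_responder, "increasing amplitude flipped responder off"
            seen_true = seen_true or m.is_responder
        assert seen_true

    def test_degenerate_baseline_errors(self, sched15, cfg):
        with pytest.raises(DegenerateBaselineError):
            compute_response(np.zeros(sched15.n_samples), sched15, cfg)


class TestBlankSubtract:
    @staticmethod
    def _metrics(dff, responder=True, label="odorA_0.01"):
        return ResponseMetrics(
            roi_id="r1", stimulus_label=label, baseline_mean=100.0,
            baseline_sd=1.0, delta_f=dff, dff_pct=dff, is_responder=responder,
        )

    @pytest.mark.parametrize(
        "odor_dff, blank_dff, expected_sub, expected_responder",
        [
            (10.0, 2.0, 8.0, True),
            (10.0, 0.0, 10.0, True),   # non-responding blank: identity
            (2.0, 5.0, -3.0, False),   # blank exceeds odor: responder revoked
            (5.0, 5.0, 0.0, False),    # exact tie: not odorant-driven
        ],
    )
    def test_sign_cases(self, odor_dff, blank_dff, expected_sub, expected_responder):
        metrics = {
            "odorA_0.01": self._metrics(odor_dff),
            "blank": self._metrics(blank_dff, label="blank"),
        }
        out = blank_subtract(metrics, "blank")
        m = out["odorA_0.01"]
        assert m.dff_blanksub_pct == pytest.approx(expected_sub)
        assert m.is_responder == expected_responder

    def test_missing_blank_errors(self):
        with pytest.raises(ValidationError):
            blank_subtract({"odorA_0.01": self._metrics(10.0)}, "blank")


def test_responder_fraction_counts():
    import pandas as pd
    df = pd.DataFrame({
        "mouse_id": ["m1"] * 10,
        "stimulus_label": ["eb"] * 10,
        "is_responder": [True] * 4 + [False] * 6,
    })
    out = responder_fraction(df)
    assert out.loc[0, "fraction"] == pytest.approx(0.4)
    df["is_responder"] = False
    assert responder_fraction(df).loc[0, "fraction"] == 0.0


def test_responder_fraction_matches_ground_truth_at_high_snr():
    sim = generate_glom_dataset(GlomGenConfig(
        n_mice=1, n_glomeruli_per_mouse=30, odorant_panel=("eb", "hex", "iaa"),
        concentration_ladder=(0.01,), tuning_sparsity=0.4, noise_sd=0.5,
        a_max_pct=300.0, ec50=0.01, hill_n=1.0, seed=6,
    ))
    metrics = analyze_dataset(sim.datasets[0])
    frac = responder_fraction(metrics, sim.schedule).set_index("stimulus_label")["fraction"]
    truth = sim.ground_truth.groupby("stimulus_label")["true_responder"].mean()
    for label in truth.index:
        assert frac[label] == pytest.approx(truth[label])


class TestGlomerularDensity:
    def test_known_field(self):
        # 30 glomeruli in a 266 x 266 um field -> 30 / 0.070756 mm^2
        assert glomerular_density(30, 266.0 ** 2) == pytest.approx(424.0, abs=0.05)

    def test_zero_count(self):
        assert glomerular_density(0, 1e5) == 0.0

    def test_doubling_area_halves_density(self):
        assert glomerular_density(10, 2e5) == pytest.approx(glomerular_density(10, 1e5) / 2)

    def test_zero_area_errors(self):
        with pytest.raises(ValidationError):
            glomerular_density(10, 0.0)
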