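"""Patch-clamp quantification: I-V extraction, AUC, amplitudes, NPo, tau."""

import numpy as np
import pytest

from sweepfunc import ephys as ep
from sweepfunc.simulate import (
    GatingConfig,
    IVModelConfig,
    simulate_gating_trace,
    simulate_iv_recording,
)


@pytest.fixture(scope="module")
def protocol():
    return ep.StepProtocol()


# ---------------------------------------------------------------------------
# step-response extraction
# ---------------------------------------------------------------------------

def test_constant_trace_density(protocol):
    n = protocol.n_pre + protocol.n_test + protocol.n_post
    traces = [ep.CurrentTrace(10_000.0, np.full(n, 100.0), voltage_mV=v,
                              capacitance_pF=10.0)
              for v in protocol.test_voltages_mV]
    iv = ep.extract_step_responses(traces, protocol)
    assert np.allclose(iv.steady_state_pA_pF, 10.0)
    assert np.allclose(np.abs(iv.tail_pA_pF), 10.0)


def test_missing_capacitance_rejected(protocol):
    n = protocol.n_pre + protocol.n_test + protocol.n_post
    traces = [ep.CurrentTrace(10_000.0, np.zeros(n), voltage_mV=v)
              for v in protocol.test_voltages_mV]
    with pytest.raises(ValueError, match="capacitance"):
        ep.extract_step_responses(traces, protocol)


def test_zero_capacitance_rejected():
    with pytest.raises(ValueError, match="capacitance"):
        ep.CurrentTrace(10_000.0, np.zeros(10), capacitance_pF=0.0)


def test_missing_voltage_step_is_an_error(protocol):
    n = protocol.n_pre + protocol.n_test + protocol.n_post
    traces = [ep.CurrentTrace(10_000.0, np.zeros(n), voltage_mV=v, capacitance_pF=5.0)
              for v in protocol.test_voltages_mV[:-1]]
    with pytest.raises(ValueError, match="missing"):
        ep.extract_step_responses(traces, protocol)


def test_synthetic_recording_recovers_truth(protocol):
    model = IVModelConfig(g_max_nS=1.0, noise_sd_pA=1.0, capacitance_pF=10.0)
    traces = simulate_iv_recording(model, protocol, seed=11)
    iv = ep.extract_step_responses(traces, protocol)
    for trace, ss, tail in zip(traces, iv.steady_state_pA_pF, iv.tail_pA_pF):
        truth_ss = trace.metadata["steady_state_truth_pA"] / 10.0
        if abs(truth_ss) > 2.0:
            assert ss == pytest.approx(truth_ss, rel=0.02, abs=0.15)
        truth_tail = trace.metadata["tail_truth_pA"] / 10.0
        if abs(truth_tail) > 2.0:
            assert tail == pytest.approx(truth_tail, rel=0.05, abs=0.3)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_constant_current():
    v = np.arange(0.0, 161.0, 10.0)
    iv = ep.IVRelation(v, np.ones_like(v), np.ones_like(v))
    assert ep.iv_auc(iv, "steady_state") == pytest.approx(160.0)


def test_auc_linear_current_exact():
    v = np.arange(-100.0, 161.0, 10.0)
    iv = ep.IVRelation(v, v.copy(), v.copy())
    # positive voltages only: integral of V dV over [0, 160]
    assert ep.iv_auc(iv, "steady_state") == pytest.approx(12_800.0)
    # tail uses the full range including negative areas
    assert ep.iv_auc(iv, "tail") == pytest.approx((160**2 - 100**2) / 2)


def test_auc_matches_trapezoid_oracle(rng):
    v = np.arange(-100.0, 161.0, 10.0)
    y = rng.normal(size=v.size)
    iv = ep.IVRelation(v, y, y)
    expected = sum(0.5 * (y[i] + y[i + 1]) * (v[i + 1] - v[i])
                   for i in range(v.size - 1))
    assert ep.iv_auc(iv, "tail") == pytest.approx(expected, abs=1e-12)


def test_auc_linearity(rng):
    v = np.arange(0.0, 161.0, 10.0)
    a, b = rng.normal(size=v.size), rng.normal(size=v.size)
    iv_a = ep.IVRelation(v, a, a)
    iv_b = ep.IVRelation(v, b, b)
    iv_ab = ep.IVRelation(v, 2 * a + 3 * b, 2 * a + 3 * b)
    assert ep.iv_auc(iv_ab, "steady_state") == pytest.approx(
        2 * ep.iv_auc(iv_a, "steady_state") + 3 * ep.iv_auc(iv_b, "steady_state"))


def test_auc_needs_two_points():
    iv = ep.IVRelation(np.array([10.0]), np.array([1.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        ep.iv_auc(iv, "steady_state")


# ---------------------------------------------------------------------------
# amplitude histogram + NPo
# ---------------------------------------------------------------------------

def test_noiseless_two_level_amplitude():
    rng = np.random.default_rng(0)
    levels = rng.random(20_000) < 0.3
    trace = ep.CurrentTrace(10_000.0, np.where(levels, -12.0, 0.0))
    fit = ep.fit_amplitude_histogram(trace, components=2, seed=0)
    assert fit.unitary_amplitude_pA == pytest.approx(12.0, abs=1e-3)


def test_single_level_trace_not_resolvable():
    rng = np.random.default_rng(1)
    trace = ep.CurrentTrace(10_000.0, rng.normal(0.0, 1.0, 20_000))
    with pytest.raises(ValueError, match="not resolvable"):
        ep.fit_amplitude_histogram(trace, components=2, seed=0)


def test_simulated_single_channel_amplitude_within_5pct():
    cfg = GatingConfig(n_channels=1, k_open=5.0, k_close=20.0, conductance_pS=150.0,
                       holding_mV=-80.0, duration_s=20.0, noise_sd_pA=1.0, seed=2)
    assert cfg.unitary_current_pA == pytest.approx(-12.0)
    trace = simulate_gating_trace(cfg)
    fit = ep.fit_amplitude_histogram(trace, components=2, seed=0)
    assert fit.unitary_amplitude_pA == pytest.approx(12.0, rel=0.05)


def test_npo_direct_ratio():
    trace = ep.CurrentTrace(10_000.0, np.full(100, 10.0))
    rec = ep.compute_npo(trace, unitary_amplitude_pA=5.0, baseline_pA=0.0)
    assert rec.npo == pytest.approx(2.0)


def test_npo_all_closed_near_zero():
    rng = np.random.default_rng(3)
    trace = ep.CurrentTrace(10_000.0, rng.normal(0.0, 0.5, 50_000))
    rec = ep.compute_npo(trace, unitary_amplitude_pA=12.0)
    assert rec.npo < 0.05


def test_npo_requires_positive_amplitude():
    with pytest.raises(ValueError):
        ep.compute_npo(ep.CurrentTrace(10.0, np.zeros(5)), 0.0)


def test_npo_estimate_converges_with_duration():
    """|NPo_hat - N*Po| shrinks from 4 s to 40 s recordings."""
    truth = 3 * 0.2
    errors = []
    for dur in (4.0, 40.0):
        estimates = []
        for seed in range(5):
            cfg = GatingConfig(n_channels=3, k_open=5.0, k_close=20.0,
                               conductance_pS=150.0, holding_mV=-80.0,
                               duration_s=dur, noise_sd_pA=0.0, seed=seed)
            tr = simulate_gating_trace(cfg)
            npo = ep.compute_npo(tr, 12.0)
            estimates.append(npo.npo)
        errors.append(np.mean(np.abs(np.asarray(estimates) - truth)))
    assert errors[1] < errors[0]


# ---------------------------------------------------------------------------
# slope conductance
# ---------------------------------------------------------------------------

def test_slope_conductance_exact_on_linear_input():
    v = np.array([-60.0, -80.0, -100.0])
    fit = ep.slope_conductance(v, 0.15 * v)
    assert fit.conductance_pS == pytest.approx(150.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)


def test_slope_conductance_reversal_absorbed_by_intercept():
    v = np.array([-60.0, -80.0, -100.0])
    g = 0.2  # nS
    fit = ep.slope_conductance(v, g * (v - 10.0))
    assert fit.conductance_pS == pytest.approx(200.0, abs=1e-9)
    assert fit.intercept_pA == pytest.approx(-2.0)


def test_slope_conductance_degenerate_rejected():
    with pytest.raises(ValueError):
        ep.slope_conductance([-60.0, -60.0, -60.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        ep.slope_conductance([-60.0, -80.0], [1.0, 2.0])


def test_slope_conductance_recovered_from_gating_traces():
    unitary = []
    voltages = (-60.0, -80.0, -100.0)
    for v in voltages:
        cfg = GatingConfig(n_channels=1, k_open=5.0, k_close=20.0,
                           conductance_pS=200.0, holding_mV=v,
                           duration_s=20.0, noise_sd_pA=1.0, seed=int(-v))
        fit = ep.fit_amplitude_histogram(simulate_gating_trace(cfg),
                                         components=2, seed=0)
        # the open level deflects by -i_u, so i_u = -(open - closed) spacing
        unitary.append(-fit.unitary_amplitude_pA)
    cf = ep.slope_conductance(voltages, unitary)
    assert cf.conductance_pS == pytest.approx(200.0, rel=0.10)


# ---------------------------------------------------------------------------
# deactivation fits
# ---------------------------------------------------------------------------

def test_deactivation_noiseless_exact():
    t = np.arange(0, 0.2, 1e-4)
    i = 50.0 * np.exp(-t / 0.020) + 3.0
    fit = ep.fit_deactivation(t, i)
    assert fit.tau_ms == pytest.approx(20.0, rel=1e-6)
    assert fit.amplitude_pA == pytest.approx(50.0, rel=1e-6)


def test_deactivation_median_within_5pct_at_5pct_noise():
    t = np.arange(0, 0.2, 1e-4)
    taus = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        i = 50.0 * np.exp(-t / 0.020) + rng.normal(0, 2.5, t.size)
        taus.append(ep.fit_deactivation(t, i).tau_ms)
    assert np.median(taus) == pytest.approx(20.0, rel=0.05)


def test_deactivation_constant_segment_rejected():
    with pytest.raises(ValueError, match="degenerate|constant"):
        ep.fit_deactivation(np.arange(0, 0.1, 1e-3), np.full(100, 5.0))


def test_generated_tail_tau_recovered_within_5pct(protocol):
    model = IVModelConfig(tau_deact_ms=20.0, noise_sd_pA=1.0)
    traces = simulate_iv_recording(model, protocol, seed=4)
    t, seg = ep.tail_segment(traces[-1], protocol)
    fit = ep.fit_deactivation(t, seg)
    assert fit.tau_ms == pytest.approx(20.0, rel=0.05)


# ---------------------------------------------------------------------------
# I/O and config plumbing
# ---------------------------------------------------------------------------

def test_trace_tsv_round_trip(tmp_path):
    trace = ep.CurrentTrace(10_000.0, np.sin(np.arange(1000) / 50.0))
    path = tmp_path / "trace.tsv"
    trace.to_tsv(path)
    back = ep.CurrentTrace.from_tsv(path)
    assert back.sampling_rate_hz == pytest.approx(10_000.0, rel=1e-4)
    assert np.allclose(back.current_pA, trace.current_pA, atol=1e-6)


def test_protocol_yaml_round_trip(tmp_path):
    proto = ep.StepProtocol()
    path = tmp_path / "protocol.yaml"
    proto.to_yaml(path)
    back = ep.StepProtocol.from_yaml(path)
    assert np.array_equal(back.test_voltages_mV, proto.test_voltages_mV)
    assert back.post_pulse_mV == -100.0


def test_protocol_validation():
    with pytest.raises(ValueError):
        ep.StepProtocol(test_voltages_mV=[0.0, 0.0, 10.0])


def test_gating_config_validation_and_warning():
    with pytest.raises(ValueError):
        GatingConfig(k_open=0.0)
    cfg = GatingConfig(k_open=5_000.0, k_close=5_000.0, sampling_rate_hz=10_000.0,
                       duration_s=0.01)
    trace = simulate_gating_trace(cfg)
    assert any("coarse" in w for w in trace.metadata["warnings"])


def test_symmetric_two_state_open_fraction():
    cfg = GatingConfig(n_channels=1, k_open=50.0, k_close=50.0, duration_s=30.0,
                       noise_sd_pA=0.0, seed=8)
    trace = simulate_gating_trace(cfg)
    open_fraction = np.mean(trace.current_pA != 0.0)
    assert open_fraction == pytest.approx(0.5, abs=0.05)


def test_zero_conductance_iv_traces_are_flat(protocol):
    model = IVModelConfig(g_max_nS=0.0, noise_sd_pA=0.0)
    traces = simulate_iv_recording(model, protocol, seed=0)
    assert all(np.allclose(t.current_pA, 0.0) for t in traces)


def test_ohmic_configuration_gives_linear_iv(protocol):
    model = IVModelConfig(g_max_nS=1.0, v_half_mV=-1_000.0, noise_sd_pA=0.0,
                          tau_act_ms=0.01)
    traces = simulate_iv_recording(model, protocol, seed=0)
    iv = ep.extract_step_responses(traces, protocol)
    slope, intercept = np.polyfit(iv.voltages_mV, iv.steady_state_pA_pF, 1)
    pred = slope * iv.voltages_mV + intercept
    ss_res = np.sum((iv.steady_state_pA_pF - pred) ** 2)
    ss_tot = np.sum((iv.steady_state_pA_pF - iv.steady_state_pA_pF.mean()) ** 2)
    assert 1 - ss_res / ss_tot > 0.999
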