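"""Quantifying synthetic whole-cell recordings.

Generates a step-protocol recording (-100..+160 mV, 400 ms pulses, 200 ms
post-pulse at -100 mV) and a 40 s single-channel gating trace, then runs
the full quantification: capacitance-normalized I-V, AUC, unitary
amplitude, NPo, slope conductance and the deactivation time constant.
"""

import numpy as np

from sweepfunc import ephys as ep
from sweepfunc.simulate import (
    GatingConfig,
    IVModelConfig,
    simulate_gating_trace,
    simulate_iv_recording,
)

protocol = ep.StepProtocol()
model = IVModelConfig(g_max_nS=1.0, tau_deact_ms=20.0, noise_sd_pA=1.0,
                      capacitance_pF=10.0)
traces = simulate_iv_recording(model, protocol, seed=1)
iv = ep.extract_step_responses(traces, protocol)
print(f"AUC of the steady-state I-V (positive voltages): "
      f"{ep.iv_auc(iv, 'steady_state'):.0f} pA/pF*mV")
print(f"AUC of the tail I-V (full range):               "
      f"{ep.iv_auc(iv, 'tail'):.0f} pA/pF*mV")

t, seg = ep.tail_segment(traces[-1], protocol)
tau = ep.fit_deactivation(t, seg)
print(f"Deactivation tau: {tau.tau_ms:.1f} ms (generator truth 20 ms)")

cfg = GatingConfig(n_channels=3, k_open=5.0, k_close=20.0, conductance_pS=150.0,
                   holding_mV=-80.0, duration_s=40.0, noise_sd_pA=1.0, seed=2)
trace = simulate_gating_trace(cfg)
fit = ep.fit_amplitude_histogram(trace, components=4, seed=0)
npo = ep.compute_npo(trace, fit.unitary_amplitude_pA, ep.baseline_from_fit(fit))
print(f"\nUnitary amplitude from the Gaussian mixture: "
      f"{fit.unitary_amplitude_pA:.1f} pA (truth {abs(cfg.unitary_current_pA):.0f})")
print(f"NPo over 40 s: {npo.npo:.2f} (truth N*Po = {3 * cfg.open_probability:.1f})")

unitary = []
for v in (-60.0, -80.0, -100.0):
    c = GatingConfig(n_channels=1, k_open=5.0, k_close=20.0, conductance_pS=150.0,
                     holding_mV=v, duration_s=20.0, noise_sd_pA=1.0, seed=int(-v))
    f = ep.fit_amplitude_histogram(simulate_gating_trace(c), components=2, seed=0)
    unitary.append(-f.unitary_amplitude_pA)
cf = ep.slope_conductance(np.array([-60.0, -80.0, -100.0]), unitary)
print(f"Slope conductance at negative potentials: {cf.conductance_pS:.0f} pS "
      f"(truth 150), R2 = {cf.r_squared:.4f}")
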