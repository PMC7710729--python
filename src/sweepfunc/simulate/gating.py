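"""Stochastic ion-channel current generators.

Two generators feed the quantification stage:

* :func:`simulate_gating_trace` — ``N`` independent two-state (closed/open)
  Markov channels advanced at the sampling interval, producing the kind of
  spontaneous single-channel activity seen in whole-cell recordings at
  negative holding potentials. The long-run expectation of the estimated
  channel activity is ``N * Po`` with ``Po = k_open / (k_open + k_close)``.
* :func:`simulate_iv_recording` — a family of step-pulse traces with an
  outwardly rectifying steady-state level and a mono-exponential tail after
  repolarization, for exercising I-V extraction, AUC and deactivation fits.

Currents are in pA throughout; the unitary current of one open channel is
``i_u = g * (V - E_rev)`` and an open channel contributes ``-i_u`` to the
sampled trace (so openings at negative potentials appear as upward
deflections, mirroring how amplitude histograms are usually displayed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ephys import CurrentTrace, StepProtocol

__all__ = ["GatingConfig", "IVModelConfig", "simulate_gating_trace", "simulate_iv_recording"]


@dataclass
class GatingConfig:
    """Two-state Markov gating parameters for ``n_channels`` identical channels."""

    n_channels: int = 1
    k_open: float = 5.0  # opening rate, 1/s
    k_close: float = 20.0  # closing rate, 1/s
    conductance_pS: float = 150.0
    reversal_mV: float = 0.0
    holding_mV: float = -80.0
    sampling_rate_hz: float = 10_000.0
    duration_s: float = 40.0
    noise_sd_pA: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_open <= 0 or self.k_close <= 0:
            raise ValueError("rates must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if not (0.0 < self.open_probability < 1.0):
            raise ValueError("implied open probability must be in (0, 1)")

    @property
    def open_probability(self) -> float:
        return self.k_open / (self.k_open + self.k_close)

    @property
    def unitary_current_pA(self) -> float:
        """i_u = g (V - E_rev); pS * mV = 1e-3 pA."""
        return self.conductance_pS * (self.holding_mV - self.reversal_mV) * 1e-3


def simulate_gating_trace(config: GatingConfig) -> CurrentTrace:
    """Sampled current of N independent two-state channels plus Gaussian noise.

    Channels are advanced at the sampling interval ``dt`` with transition
    probabilities ``1 - exp(-k dt)``; the sample current is
    ``-(open count) * i_u + noise``. The discrete-time update is only
    faithful while ``k dt`` is small; if ``max(k) * dt > 0.1`` a warning is
    recorded in the trace metadata (not raised).
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate_hz
    n_samples = int(round(config.duration_s * config.sampling_rate_hz))
    p_open = 1.0 - np.exp(-config.k_open * dt)
    p_close = 1.0 - np.exp(-config.k_close * dt)
    warnings_list = []
    if max(config.k_open, config.k_close) * dt > 0.1:
        warnings_list.append(
            f"sampling too coarse: k*dt = {max(config.k_open, config.k_close) * dt:.3f} > 0.1"
        )
    # start each channel from its stationary distribution
    state = (rng.random(config.n_channels) < config.open_probability)
    open_counts = np.empty(n_samples, dtype=np.int16)
    u = rng.random((n_samples, config.n_channels))
    for t in range(n_samples):
        open_counts[t] = state.sum()
        flip_open = ~state & (u[t] < p_open)
        flip_close = state & (u[t] < p_close)
        state = (state | flip_open) & ~flip_close
    current = -open_counts * config.unitary_current_pA
    if config.noise_sd_pA > 0:
        current = current + rng.normal(0.0, config.noise_sd_pA, size=n_samples)
    return CurrentTrace(
        sampling_rate_hz=config.sampling_rate_hz,
        current_pA=current.astype(float),
        voltage_mV=config.holding_mV,
        metadata={
            "generator": "two_state_gating",
            "seed": config.seed,
            "n_channels": config.n_channels,
            "open_probability": config.open_probability,
            "unitary_current_pA": config.unitary_current_pA,
            "warnings": warnings_list,
        },
    )


@dataclass
class IVModelConfig:
    """Macroscopic conductance model for synthetic step-protocol recordings.

    Steady-state current ``I(V) = g_max (V - E_rev) P_inf(V)`` with Boltzmann
    activation ``P_inf(V) = 1 / (1 + exp(-(V - v_half)/slope))`` (set
    ``v_half`` far negative for an ohmic channel). Activation during the test
    pulse and deactivation of the tail are mono-exponential with time
    constants ``tau_act_ms`` and ``tau_deact_ms``.
    """

    g_max_nS: float = 1.0
    e_rev_mV: float = 0.0
    v_half_mV: float = 40.0
    slope_mV: float = 30.0
    tau_act_ms: float = 5.0
    tau_deact_ms: float = 20.0
    noise_sd_pA: float = 2.0
    capacitance_pF: float = 10.0

    def p_inf(self, v: float) -> float:
        return 1.0 / (1.0 + np.exp(-(v - self.v_half_mV) / self.slope_mV))

    def steady_state_pA(self, v: float) -> float:
        return self.g_max_nS * (v - self.e_rev_mV) * self.p_inf(v)


def simulate_iv_recording(
    model: IVModelConfig,
    protocol: StepProtocol,
    seed: int = 0,
) -> list[CurrentTrace]:
    """One trace per protocol step voltage: pre-pulse, test pulse, post-pulse tail.

    The tail after repolarization is
    ``g_max (V_post - E_rev) P_inf(V_test) exp(-t/tau_deact)``, i.e. its
    instantaneous amplitude reflects the open fraction reached at the end of
    the test pulse.
    """
    protocol.validate()
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate_hz
    n_pre = int(round(protocol.pre_duration_ms * fs / 1000.0))
    n_test = int(round(protocol.test_duration_ms * fs / 1000.0))
    n_post = int(round(protocol.post_duration_ms * fs / 1000.0))
    traces = []
    for v in protocol.test_voltages_mV:
        pre = np.full(n_pre, model.steady_state_pA(protocol.pre_pulse_mV))
        t_test = np.arange(n_test) / fs * 1000.0  # ms
        i_ss = model.steady_state_pA(v)
        i_start = model.steady_state_pA(protocol.pre_pulse_mV)
        test = i_ss + (i_start - i_ss) * np.exp(-t_test / model.tau_act_ms)
        t_post = np.arange(n_post) / fs * 1000.0
        tail0 = model.g_max_nS * (protocol.post_pulse_mV - model.e_rev_mV) * model.p_inf(v)
        tail_inf = model.steady_state_pA(protocol.post_pulse_mV)
        post = tail_inf + (tail0 - tail_inf) * np.exp(-t_post / model.tau_deact_ms)
        current = np.concatenate([pre, test, post])
        if model.noise_sd_pA > 0:
            current = current + rng.normal(0.0, model.noise_sd_pA, size=current.size)
        traces.append(CurrentTrace(
            sampling_rate_hz=fs,
            current_pA=current,
            voltage_mV=float(v),
            capacitance_pF=model.capacitance_pF,
            metadata={
                "generator": "iv_step",
                "seed": seed,
                "steady_state_truth_pA": i_ss,
                "tail_truth_pA": tail0,
                "tau_deact_ms": model.tau_deact_ms,
            },
        ))
    return traces
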