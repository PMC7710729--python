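"""Quantification of whole-cell patch-clamp recordings.

Implements the estimators used to summarize channel behaviour from raw
current traces: capacitance-normalized current-voltage (I-V) relations from
step protocols, area under the I-V curve, single-channel (unitary) amplitude
from Gaussian fits of amplitude histograms, channel activity NPo, slope
conductance at negative potentials, and mono-exponential deactivation fits
of tail currents.

Traces are plain sampled current arrays in pA; on disk they are TSV files
with ``time_s`` and ``current_pA`` columns, and step protocols are YAML
documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

__all__ = [
    "StepProtocol",
    "CurrentTrace",
    "IVRelation",
    "SingleChannelFit",
    "NPoRecord",
    "ConductanceFit",
    "DeactivationFit",
    "extract_step_responses",
    "iv_auc",
    "fit_amplitude_histogram",
    "compute_npo",
    "slope_conductance",
    "fit_deactivation",
]


@dataclass
class StepProtocol:
    """Voltage-step protocol: pre-pulse, ascending test steps, fixed post-pulse.

    The default protocol steps from -100 to +160 mV in 10 mV increments
    (400 ms test pulses) with a 200 ms post-pulse to -100 mV, sampled at
    10 kHz.
    """

    test_voltages_mV: np.ndarray = field(
        default_factory=lambda: np.arange(-100.0, 161.0, 10.0)
    )
    pre_pulse_mV: float = -100.0
    pre_duration_ms: float = 50.0
    test_duration_ms: float = 400.0
    post_pulse_mV: float = -100.0
    post_duration_ms: float = 200.0
    sampling_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        self.test_voltages_mV = np.asarray(self.test_voltages_mV, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.test_voltages_mV) <= 0):
            raise ValueError("test voltages must be strictly increasing")
        for d in (self.pre_duration_ms, self.test_duration_ms, self.post_duration_ms):
            if d <= 0:
                raise ValueError("durations must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")

    # segment boundaries in samples
    @property
    def n_pre(self) -> int:
        return int(round(self.pre_duration_ms * self.sampling_rate_hz / 1000.0))

    @property
    def n_test(self) -> int:
        return int(round(self.test_duration_ms * self.sampling_rate_hz / 1000.0))

    @property
    def n_post(self) -> int:
        return int(round(self.post_duration_ms * self.sampling_rate_hz / 1000.0))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "pre_pulse_mV": self.pre_pulse_mV,
            "pre_duration_ms": self.pre_duration_ms,
            "test_voltages_mV": [float(v) for v in self.test_voltages_mV],
            "test_duration_ms": self.test_duration_ms,
            "post_pulse_mV": self.post_pulse_mV,
            "post_duration_ms": self.post_duration_ms,
            "sampling_rate_hz": self.sampling_rate_hz,
        }))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StepProtocol":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            test_voltages_mV=np.asarray(data["test_voltages_mV"], dtype=float),
            pre_pulse_mV=float(data.get("pre_pulse_mV", -100.0)),
            pre_duration_ms=float(data.get("pre_duration_ms", 50.0)),
            test_duration_ms=float(data.get("test_duration_ms", 400.0)),
            post_pulse_mV=float(data.get("post_pulse_mV", -100.0)),
            post_duration_ms=float(data.get("post_duration_ms", 200.0)),
            sampling_rate_hz=float(data.get("sampling_rate_hz", 10_000.0)),
        )


@dataclass
class CurrentTrace:
    """A sampled current recording (pA) at a command voltage."""

    sampling_rate_hz: float
    current_pA: np.ndarray
    voltage_mV: float | None = None
    capacitance_pF: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.capacitance_pF is not None and self.capacitance_pF <= 0:
            raise ValueError("capacitance must be > 0 pF")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.current_pA.size) / self.sampling_rate_hz

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s\tcurrent_pA\n")
            for t, i in zip(self.time_s, self.current_pA):
                fh.write(f"{t:.6f}\t{i:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, voltage_mV: float | None = None,
                 capacitance_pF: float | None = None) -> "CurrentTrace":
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        t, i = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size and (dt.max() - dt.min()) > 1e-9:
            raise ValueError(f"{path}: unevenly sampled trace")
        fs = 1.0 / dt[0] if dt.size else 1.0
        return cls(sampling_rate_hz=float(fs), current_pA=i,
                   voltage_mV=voltage_mV, capacitance_pF=capacitance_pF)


@dataclass
class IVRelation:
    """Capacitance-normalized current densities per protocol voltage (pA/pF)."""

    voltages_mV: np.ndarray
    steady_state_pA_pF: np.ndarray
    tail_pA_pF: np.ndarray


@dataclass
class SingleChannelFit:
    """Gaussian-mixture fit of an amplitude histogram."""

    component_means_pA: np.ndarray  # sorted ascending
    component_sds_pA: np.ndarray
    component_weights: np.ndarray
    unitary_amplitude_pA: float  # mean spacing of adjacent component means
    converged: bool


@dataclass
class NPoRecord:
    """Channel activity NPo = mean |current - baseline| / unitary amplitude."""

    holding_mV: float | None
    mean_current_pA: float
    unitary_amplitude_pA: float
    npo: float


@dataclass
class ConductanceFit:
    """Least-squares slope of unitary current on voltage, in pS."""

    voltages_mV: np.ndarray
    unitary_currents_pA: np.ndarray
    conductance_pS: float
    intercept_pA: float
    r_squared: float


@dataclass
class DeactivationFit:
    """Mono-exponential fit ``I(t) = A exp(-t/tau) + C`` of a tail segment."""

    tau_ms: float
    amplitude_pA: float
    offset_pA: float
    residual_rms_pA: float


# ---------------------------------------------------------------------------

def extract_step_responses(
    traces: list[CurrentTrace],
    protocol: StepProtocol,
    steady_fraction: float = 0.10,
    blank_ms: float = 0.5,
    tail_window_ms: float = 5.0,
) -> IVRelation:
    """Per-voltage steady-state and instantaneous tail current densities.

    Steady state is the mean over the final ``steady_fraction`` of the test
    pulse; the instantaneous tail is the extremum (largest |I|) within
    ``tail_window_ms`` after repolarization, after skipping a ``blank_ms``
    capacitive blanking window. Both are divided by membrane capacitance.
    Missing or extra voltage steps are an error — no silent reindexing.
    """
    by_voltage = {t.voltage_mV: t for t in traces}
    missing = [v for v in protocol.test_voltages_mV if v not in by_voltage]
    if missing:
        raise ValueError(f"missing traces for voltage step(s): {missing}")
    fs = protocol.sampling_rate_hz
    ss, tails = [], []
    for v in protocol.test_voltages_mV:
        trace = by_voltage[v]
        if trace.capacitance_pF is None:
            raise ValueError(f"trace at {v} mV has no membrane capacitance")
        i = trace.current_pA
        test_end = protocol.n_pre + protocol.n_test
        n_ss = max(1, int(round(steady_fraction * protocol.n_test)))
        ss_val = float(np.mean(i[test_end - n_ss:test_end]))
        blank = int(round(blank_ms * fs / 1000.0))
        window = int(round(tail_window_ms * fs / 1000.0))
        seg = i[test_end + blank:test_end + window]
        if seg.size == 0:
            raise ValueError("tail window empty; check protocol/trace alignment")
        tail_val = float(seg[np.argmax(np.abs(seg))])
        ss.append(ss_val / trace.capacitance_pF)
        tails.append(tail_val / trace.capacitance_pF)
    return IVRelation(
        voltages_mV=np.asarray(protocol.test_voltages_mV, dtype=float),
        steady_state_pA_pF=np.asarray(ss),
        tail_pA_pF=np.asarray(tails),
    )


def iv_auc(iv: IVRelation, component: str = "steady_state",
           positive_only: bool | None = None) -> float:
    """Trapezoidal area under the I-V curve over voltage.

    For the steady-state component only positive voltages are integrated by
    default; the tail component uses the full voltage range (tail areas are
    typically negative). Units: (pA/pF) * mV.
    """
    if component == "steady_state":
        y = iv.steady_state_pA_pF
        if positive_only is None:
            positive_only = True
    elif component == "tail":
        y = iv.tail_pA_pF
        if positive_only is None:
            positive_only = False
    else:
        raise ValueError("component must be 'steady_state' or 'tail'")
    v = iv.voltages_mV
    if positive_only:
        mask = v >= 0
        v, y = v[mask], y[mask]
    if v.size < 2:
        raise ValueError("AUC needs at least two voltage points in range")
    return float(np.trapezoid(y, v))


def fit_amplitude_histogram(
    trace: CurrentTrace,
    components: int = 2,
    seed: int = 0,
    max_samples: int = 100_000,
) -> SingleChannelFit:
    """Unitary amplitude as the peak-to-peak spacing of Gaussian mixture means.

    A ``components``-component Gaussian mixture is fitted to the sample
    amplitudes (closed level plus open levels); the unitary amplitude is the
    mean distance between adjacent component means. Raises when the fitted
    components are not resolvable (separation below 3x the narrowest
    component, i.e. a single-level trace).
    """
    if components < 2:
        raise ValueError("need at least 2 mixture components (closed + open)")
    x = trace.current_pA
    if x.size > max_samples:
        stride = x.size // max_samples
        x = x[::stride]
    gm = GaussianMixture(n_components=components, random_state=seed, n_init=3)
    gm.fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    spacings = np.diff(means)
    min_sd = float(sds.min())
    if np.any(spacings < 3.0 * min_sd) or np.any(weights < 5e-4):
        raise ValueError(
            "components not resolvable: trace does not span distinct closed "
            "and open levels"
        )
    return SingleChannelFit(
        component_means_pA=means,
        component_sds_pA=sds,
        component_weights=weights,
        unitary_amplitude_pA=float(spacings.mean()),
        converged=bool(gm.converged_),
    )


def baseline_from_fit(fit: SingleChannelFit) -> float:
    """Closed-level current: the mean of the largest-weight mixture component."""
    return float(fit.component_means_pA[np.argmax(fit.component_weights)])


def compute_npo(trace: CurrentTrace, unitary_amplitude_pA: float,
                baseline_pA: float = 0.0) -> NPoRecord:
    """NPo = mean(|current - baseline|) / unitary amplitude.

    ``baseline_pA`` should be the closed-level mean (e.g. from
    :func:`baseline_from_fit`); the unitary amplitude must be positive.
    """
    if unitary_amplitude_pA <= 0:
        raise ValueError("unitary amplitude must be > 0")
    mean_dev = float(np.mean(np.abs(trace.current_pA - baseline_pA)))
    return NPoRecord(
        holding_mV=trace.voltage_mV,
        mean_current_pA=mean_dev,
        unitary_amplitude_pA=unitary_amplitude_pA,
        npo=mean_dev / unitary_amplitude_pA,
    )


def slope_conductance(voltages_mV, unitary_currents_pA) -> ConductanceFit:
    """Ordinary least squares of unitary current on voltage; slope in pS.

    pA/mV equals nS, so the slope is multiplied by 1000 to report pS. The
    intercept absorbs any reversal-potential offset. Needs >= 3 distinct
    voltages.
    """
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(unitary_currents_pA, dtype=float)
    if v.size < 3 or i.size != v.size:
        raise ValueError("need >= 3 (voltage, amplitude) pairs")
    if np.unique(v).size < 2:
        raise ValueError("degenerate fit: voltages are collinear")
    slope, intercept = np.polyfit(v, i, 1)
    pred = slope * v + intercept
    ss_res = float(np.sum((i - pred) ** 2))
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ConductanceFit(
        voltages_mV=v,
        unitary_currents_pA=i,
        conductance_pS=float(slope * 1000.0),
        intercept_pA=float(intercept),
        r_squared=r2,
    )


def fit_deactivation(time_s: np.ndarray, current_pA: np.ndarray) -> DeactivationFit:
    """Least-squares mono-exponential ``I(t) = A exp(-t/tau) + C`` of a tail.

    Time is taken relative to the first sample. Raises on degenerate
    (constant) segments or non-convergence; tau is bounded positive.
    """
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if t.size < 4:
        raise ValueError("tail segment too short to fit")
    t = t - t[0]
    if np.ptp(i) < 1e-12:
        raise ValueError("degenerate fit: constant tail segment")
    c0 = float(i[-1])
    a0 = float(i[0] - c0)
    if a0 == 0.0:
        a0 = float(np.ptp(i))
    tau0 = max(t[-1] / 5.0, 1e-6)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(
            model, t, i, p0=(a0, tau0, c0),
            bounds=((-np.inf, 1e-9, -np.inf), (np.inf, np.inf, np.inf)),
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise ValueError(f"deactivation fit did not converge: {err}") from err
    a, tau, c = popt
    resid = i - model(t, *popt)
    return DeactivationFit(
        tau_ms=float(tau * 1000.0),
        amplitude_pA=float(a),
        offset_pA=float(c),
        residual_rms_pA=float(np.sqrt(np.mean(resid**2))),
    )


def tail_segment(trace: CurrentTrace, protocol: StepProtocol,
                 blank_ms: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(time_s, current_pA) of the post-pulse tail after the blanking window."""
    fs = protocol.sampling_rate_hz
    start = protocol.n_pre + protocol.n_test + int(round(blank_ms * fs / 1000.0))
    seg = trace.current_pA[start:start + protocol.n_post]
    t = np.arange(seg.size) / fs
    return t, seg
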