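"""End-to-end analyses at the package's fixed study conditions.

Bundles the heavyweight composite computations (reduced neutral-null runs,
sweep-detection power, estimator-recovery batteries) behind plain functions
so the test suite and the reproduction script exercise exactly the same
code paths at exactly the same conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ephys as ep
from . import scan as sc
from . import structure as st
from .simulate import (
    EnsembleSpec,
    GatingConfig,
    IVModelConfig,
    PairDistanceSpec,
    SweepConfig,
    example_demography,
    generate_toy_ensemble,
    simulate_gating_trace,
    simulate_iv_recording,
    simulate_sweep_replicates,
)

# Study conditions for the desk-scale selection-scan analyses: the bundled
# example demography, 30 kb windows, >= 10^4 neutral window scores per seed,
# sweeps planted mid-window at 2Ns = 200 and sampled near fixation.
N_NULL_PANELS = 1250  # x 8 windows per 240 kb panel = 10^4 window scores
NULL_SPACING = 300
SWEEP_POSITION = 105_000
SWEEP_STOP_FREQUENCY = 0.75
N_POWER_REPLICATES = 50


def null_runs(seed: int, n_panels: int = N_NULL_PANELS,
              seeds: tuple[int, int] | None = None) -> dict[int, sc.NullRun]:
    """Two independent reduced neutral-null runs of the example demography."""
    demography = example_demography()
    if seeds is None:
        seeds = (seed * 2 + 1, seed * 2 + 2)
    return {
        s: sc.neutral_null_run(demography, n_panels, s, population="AFR",
                               spacing=NULL_SPACING)
        for s in seeds
    }


def bootstrap_se(scores: np.ndarray, percentile: float = 99.99,
                 n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of an empirical percentile."""
    rng = np.random.default_rng(seed)
    reps = [np.percentile(rng.choice(scores, size=scores.size), percentile)
            for _ in range(n_boot)]
    return float(np.std(reps))


@dataclass
class PowerResult:
    n_called: int
    n_replicates: int
    threshold: float
    neutral_call_rate: float
    target_scores: list[float]

    @property
    def power(self) -> float:
        return self.n_called / self.n_replicates


def sweep_power(null: sc.NullRun, seed: int,
                n_replicates: int = N_POWER_REPLICATES,
                two_n_s: float = 200.0) -> PowerResult:
    """Fraction of planted sweeps called above the neutral 99.99th percentile.

    Sweeps start from standing variation on a single haplotype background
    (hard-sweep origin), 2Ns = ``two_n_s`` with dominant selection, and are
    sampled when the selected allele reaches 80% frequency. Windows are
    scored by mean |iHS| (the magnitude-based window score), against the
    same score's neutral threshold; candidate calling uses the window(s)
    overlapping the selected site.
    """
    demography = example_demography()
    n_afr = demography.size_at("AFR", 0)
    sweep = SweepConfig(position=SWEEP_POSITION, s=two_n_s / (2 * n_afr), h=1.0,
                        f0=0.05, population="AFR", origin="standing_hard")
    threshold = null.threshold(99.99, "mean-of-abs")
    pos = SWEEP_POSITION
    n_called = 0
    targets = []
    for res in simulate_sweep_replicates(
            demography, sweep, n_replicates, seed=seed, spacing=200,
            stop_at_frequency=SWEEP_STOP_FREQUENCY,
            min_final_frequency=SWEEP_STOP_FREQUENCY):
        records = sc.ihs_scan(res.panel.subset_population("AFR"), standardize=False)
        sc.standardize_ihs(records, reference=null.reference)
        windows = sc.window_scan(records, score_mode="mean-of-abs")
        sc.call_candidates(windows, threshold)
        overlapping = [w for w in windows
                       if w.start <= pos - 1 < w.end or w.start <= pos < w.end]
        best = max((w.score for w in overlapping), default=0.0)
        targets.append(round(best, 3))
        n_called += best > threshold
    return PowerResult(
        n_called=n_called,
        n_replicates=n_replicates,
        threshold=threshold,
        neutral_call_rate=float(np.mean(null.mean_of_abs > threshold)),
        target_scores=targets,
    )


# ---------------------------------------------------------------------------
# electrophysiology recovery battery
# ---------------------------------------------------------------------------

def ephys_recovery(seed: int) -> dict:
    """Estimator recoveries from synthetic recordings at the study's settings.

    40 s gating traces at 10 kHz (N=3, Po=0.2, g=150 pS, -80 mV), slope
    conductance from -60/-80/-100 mV single-channel traces, step-protocol
    recordings -100..+160 mV with a 20 ms deactivation tail.
    """
    rng = np.random.default_rng(seed)
    cfg = GatingConfig(n_channels=3, k_open=5.0, k_close=20.0,
                       conductance_pS=150.0, holding_mV=-80.0,
                       duration_s=40.0, noise_sd_pA=1.0,
                       seed=int(rng.integers(2**31)))
    trace = simulate_gating_trace(cfg)
    fit = ep.fit_amplitude_histogram(trace, components=cfg.n_channels + 1,
                                     seed=int(rng.integers(2**31)))
    npo = ep.compute_npo(trace, fit.unitary_amplitude_pA, ep.baseline_from_fit(fit))

    voltages = (-60.0, -80.0, -100.0)
    unitary = []
    for v in voltages:
        c = GatingConfig(n_channels=1, k_open=5.0, k_close=20.0,
                         conductance_pS=150.0, holding_mV=v, duration_s=20.0,
                         noise_sd_pA=1.0, seed=int(rng.integers(2**31)))
        f = ep.fit_amplitude_histogram(simulate_gating_trace(c), components=2,
                                       seed=int(rng.integers(2**31)))
        unitary.append(-f.unitary_amplitude_pA)  # open deflection is -i_u
    conductance = ep.slope_conductance(voltages, unitary)

    protocol = ep.StepProtocol()
    model = IVModelConfig(g_max_nS=1.0, tau_deact_ms=20.0, noise_sd_pA=1.0)
    traces = simulate_iv_recording(model, protocol, seed=int(rng.integers(2**31)))
    iv = ep.extract_step_responses(traces, protocol)
    t, seg = ep.tail_segment(traces[-1], protocol)
    tau = ep.fit_deactivation(t, seg)

    # AUC against an independent trapezoid evaluation
    auc = ep.iv_auc(iv, "steady_state")
    v = iv.voltages_mV[iv.voltages_mV >= 0]
    y = iv.steady_state_pA_pF[iv.voltages_mV >= 0]
    auc_oracle = float(sum(0.5 * (y[i] + y[i + 1]) * (v[i + 1] - v[i])
                           for i in range(len(v) - 1)))
    return {
        "npo": npo.npo,
        "npo_truth": cfg.n_channels * cfg.open_probability,
        "unitary_amplitude_pA": fit.unitary_amplitude_pA,
        "conductance_pS": conductance.conductance_pS,
        "conductance_truth_pS": 150.0,
        "tau_ms": tau.tau_ms,
        "tau_truth_ms": 20.0,
        "auc_steady_state": auc,
        "auc_oracle_abs_err": abs(auc - auc_oracle),
        "auc_tail": ep.iv_auc(iv, "tail"),
    }


# ---------------------------------------------------------------------------
# structural-ensemble recovery battery
# ---------------------------------------------------------------------------

def ensemble_recovery(seed: int, out_dir, n_models: int = 2500) -> dict:
    """Toy-ensemble H-bond statistics at the study's scale (2500 models)."""
    spec = EnsembleSpec(n_models=n_models, seed=seed, pairs=[
        PairDistanceSpec(name="D390-K452", bond_probability=0.57),
        PairDistanceSpec(name="D390-K455", distance_mean=8.7, distance_sd=1.9),
    ])
    generate_toy_ensemble(spec, out_dir)
    ensemble = st.load_ensemble(out_dir)
    s452 = st.hbond_summary(ensemble, st.parse_pair_spec("A:390:OD1,OD2-A:452:NZ"))
    s455 = st.hbond_summary(ensemble, st.parse_pair_spec("A:390:OD1,OD2-A:455:NZ"))
    mwu_exact = st.mann_whitney_u([1, 2], [3, 4])
    return {
        "bonded_fraction": s452.accepted_fraction,
        "bonded_truth": 0.57,
        "nonbonded_mean_A": s455.nonbonded_mean_A,
        "nonbonded_sd_A": s455.nonbonded_sd_A,
        "mwu_exact_p": mwu_exact.p_value,
        "n_models": ensemble.n_models,
    }
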