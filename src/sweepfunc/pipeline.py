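"""Pipeline orchestration: run stages from a config, manifest the outputs.

A run configuration (YAML or dict) selects stages and their parameter
blocks; stages execute in dependency order (simulate -> scan / null ->
popstats, with ephys and struct independent). Every stage writes its files
under ``<outdir>/<stage>/`` and appends entries (path + sha256 checksum) to
the run report, so reports are reconstructible from disk alone. All
randomness flows from the single top-level seed through per-stage derived
seeds (a stable hash of the stage name), so any stage can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .panel import read_vcf
from . import popstats as ps
from . import scan as sc
from . import ephys as ep
from . import structure as st
from .simulate import (
    EnsembleSpec,
    GatingConfig,
    PairDistanceSpec,
    SweepConfig,
    demography_from_dict,
    generate_toy_ensemble,
    simulate_panel,
)

STAGE_ORDER = ["simulate", "scan", "null", "popstats", "ephys", "struct"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31: crc32 of the stage name xor the run seed."""
    return (zlib.crc32(stage.encode()) ^ seed) % (2**31)


@dataclass
class RunConfig:
    """Stage selection + parameter blocks + output directory + seed."""

    stages: dict  # stage name -> parameter dict
    outdir: Path
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            stages={k: (v or {}) for k, v in data.get("stages", {}).items()},
            outdir=Path(outdir if outdir is not None else data.get("outdir", "sweepfunc_run")),
            seed=int(seed if seed is not None else data.get("seed", 1)),
            log_level=str(data.get("log_level", "INFO")),
        )

    def config_hash(self) -> str:
        canon = json.dumps({"stages": self.stages, "seed": self.seed}, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage, params in self.stages.items():
            needs = _REQUIRED_INPUTS.get(stage, ())
            for key in needs:
                if key not in params and not self._produced_upstream(stage, key):
                    raise ValueError(f"stage {stage!r} missing required input {key!r}")

    def _produced_upstream(self, stage: str, key: str) -> bool:
        return key in ("vcf", "popmap") and "simulate" in self.stages


_REQUIRED_INPUTS = {
    "scan": ("vcf", "popmap", "pop"),
    "null": ("demography",),
    "struct": ("models", "pair"),
}


@dataclass
class RunReport:
    """Manifest of a pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {"status", "outputs", "error"}
    warnings: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "wall_time_s": round(self.wall_time_s, 3),
            "stages": self.stages,
            "warnings": self.warnings,
        }, indent=1, default=str)

    @property
    def failed(self) -> list[str]:
        return [s for s, d in self.stages.items() if d.get("status") == "failed"]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(paths: list[Path]) -> list[dict]:
    return [{"path": str(p), "sha256": _checksum(p)} for p in paths]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(params: dict, outdir: Path, seed: int) -> list[Path]:
    demography = demography_from_dict(params["demography"])
    sweep_params = params.get("sweep")
    if sweep_params:
        from .simulate import simulate_sweep_panel

        sweep = SweepConfig(**sweep_params)
        result = simulate_sweep_panel(demography, sweep, seed)
        panel = result.panel
        (outdir / "sweep_outcome.json").write_text(json.dumps({
            "outcome": result.outcome,
            "final_frequency": result.final_frequency,
        }))
    else:
        panel = simulate_panel(demography, seed)
    vcf = outdir / "panel.vcf"
    popmap = outdir / "popmap.tsv"
    panel.write_vcf(vcf, popmap)
    out = [vcf, popmap]
    if sweep_params:
        out.append(outdir / "sweep_outcome.json")
    return out


def _stage_scan(params: dict, outdir: Path, seed: int, run_outdir: Path) -> list[Path]:
    vcf = params.get("vcf") or str(run_outdir / "simulate" / "panel.vcf")
    popmap = params.get("popmap") or str(run_outdir / "simulate" / "popmap.tsv")
    if not Path(vcf).exists():
        raise FileNotFoundError(f"scan input VCF not found: {vcf}")
    panel = read_vcf(vcf, popmap)
    pop = params.get("pop") or panel.populations[0]
    sub = panel.subset_population(pop)
    records = sc.ihs_scan(
        sub,
        maf_min=float(params.get("maf", 0.05)),
        ehh_cutoff=float(params.get("ehh_cutoff", 0.05)),
        gap_limit_bp=int(params.get("gap_kb", 20)) * 1000,
    )
    windows = sc.window_scan(
        records,
        window_bp=int(params.get("window_kb", 30)) * 1000,
        chrom=sub.chrom,
        score_mode=params.get("score", "abs-of-mean"),
    )
    threshold = params.get("threshold")
    if threshold is None:
        null_json = run_outdir / "null" / "null_distribution.json"
        if null_json.exists():
            threshold = json.loads(null_json.read_text())["critical_value"]
    if threshold is not None:
        sc.call_candidates(windows, float(threshold))
    snp_tsv = outdir / "ihs_per_snp.tsv"
    with open(snp_tsv, "w") as fh:
        fh.write("position\tderived_freq\tihh_a\tihh_d\tuihs\tihs\texcluded_reason\n")
        for r in records:
            fh.write(f"{r.position}\t{r.derived_frequency:.6g}\t{r.ihh_a:.6g}\t"
                     f"{r.ihh_d:.6g}\t{r.uihs:.6g}\t{r.ihs:.6g}\t{r.excluded_reason}\n")
    win_tsv = outdir / "windows.tsv"
    with open(win_tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tn_snps\tscore\tscore_mode\tcalled\n")
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{w.score:.6g}\t"
                     f"{w.score_mode}\t{int(w.called)}\n")
    return [snp_tsv, win_tsv]


def _stage_null(params: dict, outdir: Path, seed: int) -> list[Path]:
    demography = demography_from_dict(params["demography"])
    n_reps = int(params.get("reps", 100))
    percentile = float(params.get("percentile", 99.99))
    score_mode = params.get("score", "abs-of-mean")
    run = sc.neutral_null_run(
        demography, n_reps, seed,
        population=params.get("pop"),
        maf_min=float(params.get("maf", 0.05)),
        gap_limit_bp=int(params.get("gap_kb", 20)) * 1000,
        window_bp=int(params.get("window_kb", 30)) * 1000,
    )
    scores = (run.abs_of_mean if score_mode == "abs-of-mean"
              else run.mean_of_abs).tolist()
    null = sc.NullDistribution.from_scores(scores, percentile, n_replicates=n_reps)
    out = outdir / "null_distribution.json"
    out.write_text(json.dumps({
        "critical_value": null.critical_value,
        "percentile": percentile,
        "n_replicates": n_reps,
        "n_window_scores": len(scores),
        "seed": seed,
        "scores_digest": hashlib.sha256(np.asarray(sorted(scores)).tobytes()).hexdigest()[:16],
    }, indent=1))
    np.savetxt(outdir / "null_scores.tsv", np.asarray(scores), fmt="%.6g",
               header="window_score", comments="")
    return [out, outdir / "null_scores.tsv"]


def _stage_popstats(params: dict, outdir: Path, seed: int) -> list[Path]:
    outputs = []
    if params.get("freqs", True):
        table = ps.load_genotype_fractions_table(params.get("genotype_table"))
        path = outdir / "allele_frequencies.tsv"
        with open(path, "w") as fh:
            fh.write("variant_id\tderived_frequency\n")
            for vid, g in table.items():
                fh.write(f"{vid}\t{ps.allele_frequency_from_genotypes(g):.6g}\n")
        outputs.append(path)
    if params.get("ld", True):
        tables = ps.load_haplotype_frequency_table(params.get("haplotype_table"))
        path = outdir / "ld_pairs.tsv"
        with open(path, "w") as fh:
            fh.write("population\tdd\tda\tad\taa\tD\tDprime\tr2\n")
            for popname, t in tables.items():
                try:
                    ld = ps.ld_from_haplotype_freqs(t)
                    fh.write(f"{popname}\t{t.dd}\t{t.da}\t{t.ad}\t{t.aa}\t"
                             f"{ld.d:.6g}\t{ld.d_prime:.6g}\t{ld.r_squared:.6g}\n")
                except ValueError as err:
                    fh.write(f"{popname}\t{t.dd}\t{t.da}\t{t.ad}\t{t.aa}\t"
                             f"NA\tNA\tNA\n")
        outputs.append(path)
    fst_params = params.get("fst")
    if fst_params:
        panel = read_vcf(fst_params["vcf"], fst_params["popmap"])
        records = ps.fst_scan(panel, fst_params["pop1"], fst_params["pop2"],
                              estimator=fst_params.get("estimator", "hudson"))
        path = outdir / "fst_per_site.tsv"
        with open(path, "w") as fh:
            fh.write("position\tfst\testimator\tp1\tp2\n")
            for r in records:
                fh.write(f"{r.position}\t{r.fst:.6g}\t{r.estimator}\t{r.p1:.6g}\t{r.p2:.6g}\n")
        outputs.append(path)
    return outputs


def _stage_ephys(params: dict, outdir: Path, seed: int) -> list[Path]:
    from .simulate import IVModelConfig, simulate_iv_recording

    protocol = (ep.StepProtocol.from_yaml(params["protocol"])
                if "protocol" in params else ep.StepProtocol())
    if "traces_dir" in params:
        traces = []
        for v in protocol.test_voltages_mV:
            path = Path(params["traces_dir"]) / f"step_{int(v):+d}mV.tsv"
            traces.append(ep.CurrentTrace.from_tsv(
                path, voltage_mV=float(v),
                capacitance_pF=float(params.get("cm", 10.0))))
    else:
        model = IVModelConfig(**params.get("iv_model", {}))
        traces = simulate_iv_recording(model, protocol, seed=seed)
    iv = ep.extract_step_responses(traces, protocol,
                                   blank_ms=float(params.get("blank_ms", 0.5)),
                                   tail_window_ms=float(params.get("tail_window_ms", 5.0)))
    auc_ss = ep.iv_auc(iv, "steady_state")
    auc_tail = ep.iv_auc(iv, "tail")
    t, seg = ep.tail_segment(traces[-1], protocol)
    tau = ep.fit_deactivation(t, seg)
    from .simulate import simulate_gating_trace

    gating = GatingConfig(**params.get("gating", {"seed": seed}))
    trace = simulate_gating_trace(gating)
    fit = ep.fit_amplitude_histogram(trace, components=gating.n_channels + 1, seed=seed)
    npo = ep.compute_npo(trace, fit.unitary_amplitude_pA, ep.baseline_from_fit(fit))
    results = {
        "auc_steady_state_pApF_mV": auc_ss,
        "auc_tail_pApF_mV": auc_tail,
        "deactivation_tau_ms": tau.tau_ms,
        "unitary_amplitude_pA": fit.unitary_amplitude_pA,
        "npo": npo.npo,
    }
    out = outdir / "ephys_summary.json"
    out.write_text(json.dumps(results, indent=1))
    iv_tsv = outdir / "iv_relation.tsv"
    with open(iv_tsv, "w") as fh:
        fh.write("voltage_mV\tsteady_state_pA_pF\ttail_pA_pF\n")
        for v, s, tl in zip(iv.voltages_mV, iv.steady_state_pA_pF, iv.tail_pA_pF):
            fh.write(f"{v:.1f}\t{s:.6g}\t{tl:.6g}\n")
    return [out, iv_tsv]


def _stage_struct(params: dict, outdir: Path, seed: int) -> list[Path]:
    spec = st.parse_pair_spec(params["pair"])
    policy = st.HBondPolicy(cutoff_A=float(params.get("cutoff", 3.5)),
                            margin_A=float(params.get("margin", 0.5)))
    models = params["models"]
    if isinstance(models, dict):  # generate a toy ensemble in place
        gen_dir = outdir / "toy_ensemble"
        espec = EnsembleSpec(
            n_models=int(models.get("n_models", 100)),
            pairs=[PairDistanceSpec(**p) for p in models["pairs"]],
            seed=derive_seed(seed, "toy_ensemble"),
        )
        generate_toy_ensemble(espec, gen_dir)
        models = str(gen_dir)
    ensemble = st.load_ensemble(models)
    summary = st.hbond_summary(ensemble, spec, policy)
    outputs = []
    dist_tsv = outdir / "pair_distances.tsv"
    with open(dist_tsv, "w") as fh:
        fh.write("model\tdistance_A\tclass\n")
        for model in ensemble.models:
            try:
                d = st.pair_distance(model, spec)
                fh.write(f"{Path(model.source).name}\t{d:.3f}\t{st.classify_hbond(d, policy)}\n")
            except KeyError:
                fh.write(f"{Path(model.source).name}\tNA\tmissing_atoms\n")
    outputs.append(dist_tsv)
    summary_json = outdir / "hbond_summary.json"
    payload = json.loads(st.summary_to_json(summary))
    if "compare" in params:
        other = st.load_ensemble(params["compare"])
        cmp_res = st.compare_ensembles(ensemble, other, spec, policy)
        payload["comparison"] = {
            "other_accepted_fraction": cmp_res["second"].accepted_fraction,
            "mwu_u": cmp_res["mwu"].u,
            "mwu_p": cmp_res["mwu"].p_value,
            "mwu_method": cmp_res["mwu"].method,
        }
    summary_json.write_text(json.dumps(payload, indent=1))
    outputs.append(summary_json)
    return outputs


_STAGE_FUNCS = {
    "simulate": lambda p, d, s, root: _stage_simulate(p, d, s),
    "scan": lambda p, d, s, root: _stage_scan(p, d, s, root),
    "null": lambda p, d, s, root: _stage_null(p, d, s),
    "popstats": lambda p, d, s, root: _stage_popstats(p, d, s),
    "ephys": lambda p, d, s, root: _stage_ephys(p, d, s),
    "struct": lambda p, d, s, root: _stage_struct(p, d, s),
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    A failing stage is recorded (name + cause) and later stages that do not
    depend on it still run; completed-stage outputs are left intact.
    """
    config.validate()
    t0 = time.time()
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    config.outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        stage_dir = config.outdir / stage
        stage_dir.mkdir(exist_ok=True)
        stage_seed = derive_seed(config.seed, stage)
        try:
            outputs = _STAGE_FUNCS[stage](config.stages[stage], stage_dir,
                                          stage_seed, config.outdir)
            report.stages[stage] = {
                "status": "ok",
                "seed": stage_seed,
                "outputs": _manifest(outputs),
            }
        except Exception as err:  # noqa: BLE001 — per-stage isolation is the contract
            report.stages[stage] = {"status": "failed", "seed": stage_seed,
                                    "error": f"{type(err).__name__}: {err}"}
    report.wall_time_s = time.time() - t0
    (config.outdir / "run_report.json").write_text(report.to_json())
    return report


def make_report(outdir: str | Path) -> str:
    """Human-readable Markdown summary rebuilt from on-disk stage outputs.

    Missing stage outputs are listed as absent, never fatal.
    """
    outdir = Path(outdir)
    lines = ["# sweepfunc run report", ""]
    run_json = outdir / "run_report.json"
    if run_json.exists():
        meta = json.loads(run_json.read_text())
        lines += [f"config hash: `{meta['config_hash']}`  seed: {meta['seed']}  "
                  f"version: {meta['version']}", ""]

    def section(title: str, path: Path, fmt) -> None:
        lines.append(f"## {title}")
        if path.exists():
            lines.extend(fmt(path))
        else:
            lines.append("_absent_")
        lines.append("")

    def tsv_table(path: Path, limit: int = 20):
        rows = path.read_text().strip().splitlines()
        head = rows[0].split("\t")
        out = ["| " + " | ".join(head) + " |",
               "|" + "---|" * len(head)]
        for r in rows[1:limit + 1]:
            out.append("| " + " | ".join(r.split("\t")) + " |")
        if len(rows) - 1 > limit:
            out.append(f"... {len(rows) - 1 - limit} more rows")
        return out

    section("Allele frequencies", outdir / "popstats" / "allele_frequencies.tsv", tsv_table)
    section("LD pairs", outdir / "popstats" / "ld_pairs.tsv", tsv_table)
    section("Per-site Fst", outdir / "popstats" / "fst_per_site.tsv", tsv_table)
    section("Windowed iHS scan", outdir / "scan" / "windows.tsv", tsv_table)
    section("Neutral null", outdir / "null" / "null_distribution.json",
            lambda p: ["```json", p.read_text().strip(), "```"])
    section("Ephys summary", outdir / "ephys" / "ephys_summary.json",
            lambda p: ["```json", p.read_text().strip(), "```"])
    section("H-bond summary", outdir / "struct" / "hbond_summary.json",
            lambda p: ["```json", p.read_text().strip(), "```"])
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
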