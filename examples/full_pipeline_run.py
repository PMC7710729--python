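"""Running the orchestrated pipeline from a config dict.

Simulates a small panel, computes the bundled-table population statistics
and a structural summary, then rebuilds the Markdown report from the
on-disk outputs alone.
"""

import tempfile
from pathlib import Path

from sweepfunc.pipeline import RunConfig, make_report, run_pipeline

with tempfile.TemporaryDirectory() as td:
    config = RunConfig(
        stages={
            "simulate": {"demography": {
                "epochs": [{"population": "A", "size": 20}],
                "mutation_rate": 2e-6,
                "sequence_length": 50_000,
                "samples": {"A": 6},
                "burn_in": 200,
            }},
            "popstats": {},
            "struct": {
                "pair": "A:390:OD1,OD2-A:452:NZ",
                "models": {"n_models": 100,
                           "pairs": [{"name": "D390-K452",
                                      "bond_probability": 0.5}]},
            },
        },
        outdir=Path(td) / "run",
        seed=11,
    )
    report = run_pipeline(config)
    for stage, info in report.stages.items():
        print(f"stage {stage}: {info['status']} "
              f"({len(info.get('outputs', []))} files)")
    print("\n--- report.md ---\n")
    print(make_report(config.outdir))
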