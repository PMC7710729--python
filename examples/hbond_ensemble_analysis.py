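"""Hydrogen-bond statistics over a toy conformational ensemble.

Writes a 500-model ensemble in which the D390-K452 contact is bonded in a
configured fraction of models and the D390-K455 distance follows a normal
distribution, then classifies each model against the 3.5 A + 0.5 A margin
criterion and compares the two non-bonded distance distributions with a
Mann-Whitney U test.
"""

import tempfile

from sweepfunc import structure as st
from sweepfunc.simulate import EnsembleSpec, PairDistanceSpec, generate_toy_ensemble

with tempfile.TemporaryDirectory() as td:
    spec = EnsembleSpec(n_models=500, seed=8, pairs=[
        PairDistanceSpec(name="D390-K452", bond_probability=0.57),
        PairDistanceSpec(name="D390-K455", distance_mean=8.7, distance_sd=1.9),
    ])
    generate_toy_ensemble(spec, td)
    ensemble = st.load_ensemble(td)

    pair452 = st.parse_pair_spec("A:390:OD1,OD2-A:452:NZ")
    pair455 = st.parse_pair_spec("A:390:OD1,OD2-A:455:NZ")
    s452 = st.hbond_summary(ensemble, pair452)
    s455 = st.hbond_summary(ensemble, pair455)

    print(f"{ensemble.n_models} models")
    print(f"D390-K452: bond preserved in {100 * s452.accepted_fraction:.0f}% "
          f"of models (planted 57%; cutoff 3.5 A, margin 0.5 A)")
    print(f"D390-K455: non-bonded distances mean {s455.nonbonded_mean_A:.2f} A, "
          f"sd {s455.nonbonded_sd_A:.2f} A (planted 8.7 / 1.9)")

    mwu = st.mann_whitney_u(s452.nonbonded_distances_A, s455.nonbonded_distances_A)
    print(f"Mann-Whitney U comparing the two non-bonded distributions: "
          f"U={mwu.u:.0f}, p={mwu.p_value:.3g} ({mwu.method})")
    print("\nA small p indicates the two contacts sample different open-state")
    print("geometries; the fraction preserved measures how often the salt")
    print("bridge survives in the ensemble.")
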