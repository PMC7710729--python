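"""Ensemble loading, pair distances, H-bond classification, Mann-Whitney U."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from sweepfunc import structure as st
from sweepfunc.simulate import EnsembleSpec, PairDistanceSpec, generate_toy_ensemble

PAIR_452 = st.parse_pair_spec("A:390:OD1,OD2-A:452:NZ")
PAIR_455 = st.parse_pair_spec("A:390:OD1,OD2-A:455:NZ")


@pytest.fixture(scope="module")
def toy_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("ensemble")
    spec = EnsembleSpec(n_models=120, seed=3, pairs=[
        PairDistanceSpec(name="D390-K452", bond_probability=0.5),
        PairDistanceSpec(name="D390-K455", distance_mean=8.7, distance_sd=1.9),
    ])
    manifest = generate_toy_ensemble(spec, out)
    return out, manifest


# ---------------------------------------------------------------------------
# generator + loader round trip
# ---------------------------------------------------------------------------

def test_model_count_matches_spec(toy_dir):
    out, manifest = toy_dir
    ens = st.load_ensemble(out)
    assert ens.n_models == 120 == len(manifest["files"])


def test_round_trip_distances_within_milli_angstrom(toy_dir):
    out, manifest = toy_dir
    ens = st.load_ensemble(out)
    for pair, spec in (("D390-K452", PAIR_452), ("D390-K455", PAIR_455)):
        truth = np.asarray(manifest["truth_distances_A"][pair])
        got = np.asarray([st.pair_distance(m, spec) for m in ens.models])
        assert np.max(np.abs(got - truth)) < 1e-3


def test_all_bonded_when_target_is_3A(tmp_path):
    spec = EnsembleSpec(n_models=10, seed=0, pairs=[
        PairDistanceSpec(name="D390-K452", distance_mean=3.0, distance_sd=0.0)])
    generate_toy_ensemble(spec, tmp_path)
    ens = st.load_ensemble(str(tmp_path / "*.pdb"))
    summary = st.hbond_summary(ens, PAIR_452)
    assert summary.accepted_fraction == 1.0
    assert summary.nonbonded_distances_A.size == 0


def test_missing_atom_flagged_not_fatal(toy_dir, tmp_path):
    out, _ = toy_dir
    ens = st.load_ensemble(out)
    crippled = st.Model(source="x", atoms={
        k: v for k, v in ens.models[0].atoms.items() if k[3] != "NZ"})
    with pytest.raises(KeyError, match="NZ"):
        st.pair_distance(crippled, PAIR_452)
    mixed = st.Ensemble(models=[crippled] + ens.models[:5])
    summary = st.hbond_summary(mixed, PAIR_452)
    assert summary.n_models == 6 and summary.n_usable == 5


def test_unparseable_file_reports_filename(tmp_path):
    bad = tmp_path / "junk.pdb"
    bad.write_text("ATOM this is not a valid pdb line at all\x00\x01")
    with pytest.raises(ValueError, match="junk.pdb"):
        st.load_ensemble([bad])


def test_negative_distance_rejected():
    with pytest.raises(ValueError):
        spec = EnsembleSpec(n_models=2, seed=0, pairs=[
            PairDistanceSpec(name="D390-K452", distance_mean=-5.0, distance_sd=0.0)])
        generate_toy_ensemble(spec, "/tmp/never")


# ---------------------------------------------------------------------------
# pair distances
# ---------------------------------------------------------------------------

def _model(coords: dict) -> st.Model:
    return st.Model(source="synthetic", atoms={
        ("A", res, name, atom): np.asarray(xyz, dtype=float)
        for (res, name, atom), xyz in coords.items()})


def test_minimum_over_cross_pairs():
    m = _model({(390, "ASP", "OD1"): (0, 0, 0), (390, "ASP", "OD2"): (6, 0, 0),
                (452, "LYS", "NZ"): (3, 0, 0)})
    assert st.pair_distance(m, PAIR_452) == pytest.approx(3.0)


def test_coincident_atoms_distance_zero():
    m = _model({(390, "ASP", "OD1"): (1, 2, 3), (390, "ASP", "OD2"): (9, 9, 9),
                (452, "LYS", "NZ"): (1, 2, 3)})
    assert st.pair_distance(m, PAIR_452) == 0.0


def test_distance_symmetric_and_rigid_motion_invariant(rng):
    coords = rng.normal(0, 5, (3, 3))
    m = _model({(390, "ASP", "OD1"): coords[0], (390, "ASP", "OD2"): coords[1],
                (452, "LYS", "NZ"): coords[2]})
    d = st.pair_distance(m, PAIR_452)
    flipped = st.ResiduePairSpec("A", 452, ("NZ",), "A", 390, ("OD1", "OD2"))
    assert st.pair_distance(m, flipped) == pytest.approx(d)
    # rigid-body transform: rotation about z plus translation
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    moved = coords @ rot.T + np.array([10.0, -4.0, 2.0])
    m2 = _model({(390, "ASP", "OD1"): moved[0], (390, "ASP", "OD2"): moved[1],
                 (452, "LYS", "NZ"): moved[2]})
    assert st.pair_distance(m2, PAIR_452) == pytest.approx(d, abs=1e-9)

    brute = min(np.linalg.norm(coords[0] - coords[2]),
                np.linalg.norm(coords[1] - coords[2]))
    assert d == pytest.approx(brute, abs=1e-12)


# ---------------------------------------------------------------------------
# H-bond classification and summaries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("distance,expected", [
    (3.2, "bonded"),
    (3.8, "marginal"),
    (8.7, "nonbonded"),
    (3.5, "bonded"),
    (4.0, "marginal"),
])
def test_classification_thresholds(distance, expected):
    assert st.classify_hbond(distance) == expected


def test_marginal_contacts_accepted_under_margin_policy():
    ens = st.Ensemble(models=[
        _model({(390, "ASP", "OD1"): (0, 0, 0), (390, "ASP", "OD2"): (0, 2.2, 0),
                (452, "LYS", "NZ"): (d, 0, 0)})
        for d in (3.0, 3.8, 9.0)])
    summary = st.hbond_summary(ens, PAIR_452)
    assert summary.n_bonded == 1 and summary.n_marginal == 1
    assert summary.accepted_fraction == pytest.approx(2 / 3)
    strict = st.hbond_summary(ens, PAIR_452,
                              st.HBondPolicy(accept_marginal=False))
    assert strict.accepted_fraction == pytest.approx(1 / 3)
    # non-bonded statistics use the strict > cutoff complement
    assert summary.nonbonded_distances_A.size == 2


def test_bonded_fraction_monotone_in_cutoff_and_margin(rng):
    distances = rng.uniform(2.5, 10.0, 200)
    ens = st.Ensemble(models=[
        _model({(390, "ASP", "OD1"): (0, 0, 0), (390, "ASP", "OD2"): (0, 2.2, 0),
                (452, "LYS", "NZ"): (d, 0, 0)}) for d in distances])
    fractions = [st.hbond_summary(ens, PAIR_452, st.HBondPolicy(cutoff_A=c)).accepted_fraction
                 for c in (3.0, 3.5, 4.0, 5.0)]
    assert all(a <= b for a, b in zip(fractions, fractions[1:]))
    margins = [st.hbond_summary(ens, PAIR_452,
                                st.HBondPolicy(margin_A=m)).accepted_fraction
               for m in (0.0, 0.5, 1.0)]
    assert all(a <= b for a, b in zip(margins, margins[1:]))


def test_concatenated_ensembles_combine_by_counts(rng):
    def ens_from(distances):
        return st.Ensemble(models=[
            _model({(390, "ASP", "OD1"): (0, 0, 0), (390, "ASP", "OD2"): (0, 2.2, 0),
                    (452, "LYS", "NZ"): (d, 0, 0)}) for d in distances])
    d1 = rng.uniform(2.5, 10, 30)
    d2 = rng.uniform(2.5, 10, 50)
    s1 = st.hbond_summary(ens_from(d1), PAIR_452)
    s2 = st.hbond_summary(ens_from(d2), PAIR_452)
    s12 = st.hbond_summary(ens_from(np.concatenate([d1, d2])), PAIR_452)
    combined = (s1.accepted_fraction * 30 + s2.accepted_fraction * 50) / 80
    assert s12.accepted_fraction == pytest.approx(combined)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_identical_samples_give_p_one():
    res = st.mann_whitney_u([1, 3, 5], [1, 3, 5])
    assert res.p_value == pytest.approx(1.0)
    assert res.u == pytest.approx(4.5)  # n^2 / 2 with ties


def test_exact_small_sample_enumeration():
    res = st.mann_whitney_u([1, 2], [3, 4])
    assert res.method == "exact"
    assert res.u == 0.0
    assert res.p_value == pytest.approx(1 / 3)


def test_large_samples_use_asymptotic():
    rng = np.random.default_rng(0)
    res = st.mann_whitney_u(rng.normal(size=200), rng.normal(size=200))
    assert res.method == "asymptotic"
    assert 0 < res.p_value <= 1


def test_exact_and_asymptotic_agree_for_10v10(rng):
    # moderate-p regime; the tie/continuity-corrected normal approximation
    # is only expected to track the exact enumeration away from deep tails
    x = rng.normal(0, 1, 10)
    y = rng.normal(0.2, 1, 10)
    exact = st.mann_whitney_u(x, y, mode="exact")
    approx = st.mann_whitney_u(x, y, mode="asymptotic")
    assert exact.p_value > 0.05
    assert approx.p_value == pytest.approx(exact.p_value, rel=0.10)


def test_asymptotic_p_matches_permutation_oracle(rng):
    x = rng.normal(8.7, 1.9, 400)
    y = rng.normal(8.7, 2.3, 400)
    res = st.mann_whitney_u(x, y)
    pooled = np.concatenate([x, y])
    n_perm = 4000
    u_obs = res.u
    u_null = np.empty(n_perm)
    for b in range(n_perm):
        rng.shuffle(pooled)
        u_null[b] = mannwhitneyu(pooled[:400], pooled[400:],
                                 alternative="two-sided").statistic
    # two-sided permutation p from the distance to the null mean U
    center = 400 * 400 / 2
    p_perm = np.mean(np.abs(u_null - center) >= abs(u_obs - center) - 1e-9)
    se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(res.p_value - p_perm) <= 4 * se + 0.01


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        st.mann_whitney_u([], [1.0])
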