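"""Selection-scan unit and property tests (EHH, iHH, iHS, windows, null)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sweepfunc._kernels as kernels
from sweepfunc import scan as sc
from sweepfunc.scan import (
    BinStats,
    IHSRecord,
    call_candidates,
    compute_ehh,
    compute_ihh,
    filter_sites,
    ihs_scan,
    null_threshold,
    standardize_ihs,
    unstandardized_ihs,
    window_scan,
)

from conftest import make_panel
from oracles import ehh_brute, ihh_brute, ihs_pipeline_brute


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def test_filter_sites_strict_inequality_and_monomorphic():
    # 20 haplotypes: site freqs 0 (monomorphic), 0.05 (= threshold), 0.10
    hap = np.zeros((20, 3), dtype=np.int8)
    hap[0, 1] = 1  # freq 0.05
    hap[:2, 2] = 1  # freq 0.10
    panel = make_panel(hap)
    kept = filter_sites(panel, maf_min=0.05)
    assert list(kept.positions) == [3000]  # only the 0.10 site survives


def test_filter_sites_matches_counting_oracle(random_panel):
    kept = filter_sites(random_panel, 0.05)
    freqs = random_panel.haplotypes.mean(axis=0)
    expected = random_panel.positions[np.minimum(freqs, 1 - freqs) > 0.05]
    assert np.array_equal(kept.positions, expected)


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def test_ehh_identical_carriers_stay_at_one():
    hap = np.zeros((8, 5), dtype=np.int8)
    hap[:4, 2] = 1  # four identical derived haplotypes
    curve = compute_ehh(make_panel(hap), 2, 1)
    assert np.allclose(curve.ehh, 1.0)


def test_ehh_two_carriers_differing_at_adjacent_site():
    hap = np.zeros((4, 3), dtype=np.int8)
    hap[0, 1] = hap[1, 1] = 1  # carriers are rows 0, 1
    hap[0, 2] = 1  # they differ at the next site
    curve = compute_ehh(make_panel(hap), 1, 1)
    right = curve.ehh[curve.offsets > 0]
    assert right[0] == 0.0


def test_ehh_requires_two_carriers():
    hap = np.zeros((4, 2), dtype=np.int8)
    hap[0, 0] = 1
    with pytest.raises(ValueError, match="carrier"):
        compute_ehh(make_panel(hap), 0, 1)


def test_ehh_matches_pair_counting_oracle(random_panel):
    hap = random_panel.haplotypes
    for core in (0, 7, 19):
        for allele in (0, 1):
            if (hap[:, core] == allele).sum() < 2:
                continue
            curve = compute_ehh(random_panel, core, allele)
            off_o, ehh_o = ehh_brute(hap, random_panel.positions, core, allele)
            lookup = dict(zip(off_o, ehh_o))
            for off, val in zip(curve.offsets, curve.ehh):
                assert val == pytest.approx(lookup[off], abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ehh_bounded_and_non_increasing(seed):
    rng = np.random.default_rng(seed)
    hap = (rng.random((12, 15)) < 0.4).astype(np.int8)
    hap[:6, 7] = 1
    hap[6:, 7] = 0
    panel = make_panel(hap)
    for allele in (0, 1):
        curve = compute_ehh(panel, 7, allele)
        assert np.all((curve.ehh >= 0) & (curve.ehh <= 1))
        right = curve.ehh[curve.offsets >= 0]
        left = curve.ehh[curve.offsets <= 0][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)
        assert curve.ehh[curve.offsets == 0] == 1.0


# ---------------------------------------------------------------------------
# iHH
# ---------------------------------------------------------------------------

def test_ihh_rectangle_area():
    # EHH == 1 over exactly 10 kb on each side, then crashes below cutoff
    offsets = np.array([-11_000, -10_000, 0, 10_000, 11_000])
    ehh = np.array([0.01, 1.0, 1.0, 1.0, 0.01])
    curve = sc.EHHCurve(core_index=2, core_position=50_000, allele=1,
                        offsets=offsets, ehh=ehh, n_carriers=10)
    res = compute_ihh(curve, ehh_cutoff=0.05, gap_limit_bp=20_000)
    assert res.value == pytest.approx(20_000.0)


def test_ihh_gap_exclusion():
    offsets = np.array([0, 1_000, 26_000])  # 25 kb between informative sites
    ehh = np.array([1.0, 0.9, 0.8])
    curve = sc.EHHCurve(0, 1, 1, offsets, ehh, 10)
    res = compute_ihh(curve, 0.05, gap_limit_bp=20_000)
    assert res.excluded and "gap" in res.reason


def test_ihh_gap_beyond_truncation_is_ignored():
    # the big gap sits after EHH already dropped below the cutoff
    offsets = np.array([0, 1_000, 2_000, 30_000])
    ehh = np.array([1.0, 0.5, 0.01, 0.0])
    curve = sc.EHHCurve(0, 1, 1, offsets, ehh, 10)
    res = compute_ihh(curve, 0.05, gap_limit_bp=20_000)
    assert not res.excluded
    assert res.value == pytest.approx(0.5 * (1.0 + 0.5) * 1000)


def test_ihh_matches_dense_grid_oracle(rng):
    neg = -np.sort(rng.choice(np.arange(1, 30_001), 10, replace=False))[::-1]
    pos = np.sort(rng.choice(np.arange(1, 30_001), 10, replace=False))
    offsets = np.concatenate([neg, [0], pos])
    ehh = np.clip(1.0 - np.abs(offsets) / 25_000 + rng.normal(0, 0.02, 21), 0, 1)
    ehh[offsets == 0] = 1.0
    curve = sc.EHHCurve(10, 1, 1, offsets, ehh, 12)
    res = compute_ihh(curve, 0.05, gap_limit_bp=50_000)
    val_o, exc_o, _ = ihh_brute(offsets, ehh, 0.05, 50_000)
    assert not exc_o
    assert res.value == pytest.approx(val_o, rel=1e-6)


# ---------------------------------------------------------------------------
# uiHS / standardization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,d,expected", [
    (5.0, 5.0, 0.0),
    (np.e * 3.0, 3.0, 1.0),
])
def test_unstandardized_ihs_values(a, d, expected):
    assert unstandardized_ihs(a, d) == pytest.approx(expected)


def test_unstandardized_ihs_random_pairs(rng):
    for _ in range(20):
        a, d = rng.uniform(0.1, 100, 2)
        assert unstandardized_ihs(a, d) == pytest.approx(np.log(a) - np.log(d))


def test_unstandardized_ihs_rejects_zero():
    with pytest.raises(ValueError):
        unstandardized_ihs(0.0, 1.0)


def test_standardize_bins_have_mean_zero_sd_one(rng):
    records = [IHSRecord(position=i, derived_frequency=rng.uniform(0.06, 0.94),
                         uihs=rng.normal()) for i in range(200)]
    standardize_ihs(records, bin_width=0.05)
    by_bin = {}
    for r in records:
        if not r.excluded:
            by_bin.setdefault(r.bin_id, []).append(r.ihs)
    for vals in by_bin.values():
        if len(vals) >= 2:
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)
            assert np.std(vals) == pytest.approx(1.0, abs=1e-12)


def test_standardize_single_record_bin_flagged():
    records = [
        IHSRecord(position=1, derived_frequency=0.10, uihs=0.5),
        IHSRecord(position=2, derived_frequency=0.90, uihs=1.0),
        IHSRecord(position=3, derived_frequency=0.90, uihs=2.0),
    ]
    standardize_ihs(records, bin_width=0.05)
    assert records[0].excluded and "fewer than 2" in records[0].excluded_reason
    assert not records[1].excluded


def test_standardize_two_bin_toy_hand_computed():
    # bin A: uihs {1, 3} -> mean 2, sd 1 ; bin B: uihs {-2, 0, 2} -> mean 0, sd ~1.633
    recs = [IHSRecord(1, 0.12, uihs=1.0), IHSRecord(2, 0.13, uihs=3.0),
            IHSRecord(3, 0.52, uihs=-2.0), IHSRecord(4, 0.53, uihs=0.0),
            IHSRecord(5, 0.54, uihs=2.0)]
    standardize_ihs(recs, bin_width=0.05)
    assert recs[0].ihs == pytest.approx(-1.0)
    assert recs[1].ihs == pytest.approx(1.0)
    assert recs[2].ihs == pytest.approx(-2.0 / np.sqrt(8.0 / 3.0))
    assert recs[4].ihs == pytest.approx(2.0 / np.sqrt(8.0 / 3.0))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_window_mean_and_score():
    recs = [IHSRecord(1_000, 0.5, uihs=0, ihs=2.0),
            IHSRecord(2_000, 0.5, uihs=0, ihs=3.0)]
    wins = window_scan(recs, window_bp=30_000)
    assert len(wins) == 1
    assert wins[0].mean_ihs == pytest.approx(2.5)
    assert wins[0].score == pytest.approx(2.5)


def test_window_sign_cancellation_documents_modes():
    recs = [IHSRecord(1_000, 0.5, uihs=0, ihs=-2.0),
            IHSRecord(2_000, 0.5, uihs=0, ihs=2.0)]
    win = window_scan(recs)[0]
    assert win.abs_of_mean == pytest.approx(0.0)
    assert win.mean_of_abs == pytest.approx(2.0)


def test_window_grouping_matches_bruteforce(rng):
    recs = [IHSRecord(int(p), 0.5, uihs=0.0, ihs=float(rng.normal()))
            for p in rng.choice(np.arange(1, 200_001), 300, replace=False)]
    wins = window_scan(recs, window_bp=30_000)
    # brute-force grouping
    groups = {}
    for r in recs:
        groups.setdefault((r.position - 1) // 30_000, []).append(r.ihs)
    assert len(wins) == len(groups)
    for w in wins:
        vals = groups[w.start // 30_000]
        assert w.n_snps == len(vals)
        assert w.mean_ihs == pytest.approx(np.mean(vals))


# ---------------------------------------------------------------------------
# null threshold and candidate calling
# ---------------------------------------------------------------------------

def test_null_threshold_median_of_grid():
    scores = np.arange(1, 10_001, dtype=float)
    assert null_threshold(scores, 50) == pytest.approx(5000.5)


def test_null_threshold_percentile_100_is_max():
    with pytest.warns(UserWarning):
        assert null_threshold([3.0, 1.0, 2.0], 100) == 3.0


def test_null_threshold_empty_rejected():
    with pytest.raises(ValueError):
        null_threshold([], 99.99)


def test_null_threshold_monotone_in_percentile(rng):
    scores = rng.exponential(1.0, size=20_000)
    vals = [null_threshold(scores, q) for q in (90, 99, 99.9, 99.99, 100)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_call_candidates_threshold_above_all():
    recs = [IHSRecord(1_000, 0.5, uihs=0, ihs=1.0)]
    wins = window_scan(recs)
    assert call_candidates(wins, critical_value=10.0) == []
    assert wins[0].threshold == 10.0 and not wins[0].called


# ---------------------------------------------------------------------------
# whole-pipeline equivalences
# ---------------------------------------------------------------------------

def test_scan_equals_bruteforce_pipeline(random_panel):
    """Production scan equals the naive pair-counting + dense-grid oracle."""
    records = ihs_scan(random_panel, maf_min=0.05)
    oracle = ihs_pipeline_brute(random_panel.haplotypes, random_panel.positions)
    assert len(records) == len(oracle)
    for rec, orc in zip(records, oracle):
        assert rec.position == orc["position"]
        assert rec.excluded == orc["excluded"]
        if not rec.excluded:
            assert rec.uihs == pytest.approx(orc["uihs"], abs=1e-9)
            if np.isfinite(rec.ihs) and np.isfinite(orc["ihs"]):
                assert rec.ihs == pytest.approx(orc["ihs"], abs=1e-9)


def test_scan_invariant_under_haplotype_permutation(random_panel, rng):
    records = ihs_scan(random_panel)
    perm = rng.permutation(random_panel.n_haplotypes)
    shuffled = make_panel(random_panel.haplotypes[perm],
                          positions=random_panel.positions)
    records_p = ihs_scan(shuffled)
    for a, b in zip(records, records_p):
        assert a.excluded == b.excluded
        if not a.excluded:
            assert a.uihs == pytest.approx(b.uihs, abs=1e-12)


def test_compiled_scan_matches_python_path(random_panel):
    """The numba kernel and the pure-NumPy path produce identical records."""
    if not kernels.HAS_NUMBA:
        fast = slow = ihs_scan(random_panel, standardize=False)
    else:
        fast = ihs_scan(random_panel, standardize=False)
        kernels.HAS_NUMBA = False
        try:
            slow = ihs_scan(random_panel, standardize=False)
        finally:
            kernels.HAS_NUMBA = True
    for a, b in zip(fast, slow):
        assert a.excluded == b.excluded
        if not a.excluded:
            assert a.ihh_a == pytest.approx(b.ihh_a, abs=1e-9)
            assert a.ihh_d == pytest.approx(b.ihh_d, abs=1e-9)
            assert a.truncated == b.truncated
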