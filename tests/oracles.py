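"""Independent brute-force oracles for the scan and LD statistics.

Deliberately naive implementations (explicit pair enumeration, dense-grid
integration, direct counting) kept free of any code from the package's own
computation paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ehh_brute(hap: np.ndarray, positions: np.ndarray, core: int, allele: int):
    """EHH by enumerating all carrier pairs at every offset site.

    Returns (offsets_bp, ehh) over the full panel, including the core at
    offset 0. Assumes a complete (no-missing) panel.
    """
    carriers = [i for i in range(hap.shape[0]) if hap[i, core] == allele]
    n = len(carriers)
    if n < 2:
        raise ValueError("fewer than 2 carriers")
    n_pairs = n * (n - 1) / 2
    offsets, values = [], []
    for j in range(hap.shape[1]):
        lo, hi = min(core, j), max(core, j)
        same = sum(
            1
            for a, b in combinations(carriers, 2)
            if np.array_equal(hap[a, lo:hi + 1], hap[b, lo:hi + 1])
        )
        offsets.append(int(positions[j] - positions[core]))
        values.append(same / n_pairs)
    return np.asarray(offsets), np.asarray(values)


def ihh_brute(offsets: np.ndarray, ehh: np.ndarray, cutoff: float,
              gap_limit: float, n_grid: int = 200_001):
    """iHH via dense-grid numerical integration of the piecewise-linear curve.

    Mirrors the production semantics: each side truncated at the last site
    with EHH >= cutoff, exclusion when a gap larger than ``gap_limit`` is
    walked before truncation. Returns (value, excluded, truncated).
    """
    total = 0.0
    truncated = False
    for sign in (+1, -1):
        sel = offsets * sign >= 0
        d = np.abs(offsets[sel]).astype(float)
        e = ehh[sel]
        order = np.argsort(d)
        d, e = d[order], e[order]
        if len(d) < 2:
            continue
        stop = len(d) - 1
        stopped = False
        for k in range(1, len(d)):
            if d[k] - d[k - 1] > gap_limit:
                return np.nan, True, False
            if e[k] < cutoff:
                stop = k - 1
                stopped = True
                break
        if not stopped:
            truncated = True
        if stop == 0:
            continue
        grid = np.linspace(0.0, d[stop], n_grid)
        total += float(np.trapezoid(np.interp(grid, d[:stop + 1], e[:stop + 1]), grid))
    return total, False, truncated


def ihs_pipeline_brute(hap, positions, maf_min=0.05, cutoff=0.05, gap_limit=20_000,
                       bin_width=0.05):
    """Full scan oracle on a tiny panel: returns list of dict records."""
    n = hap.shape[0]
    freqs = hap.mean(axis=0)
    keep = np.minimum(freqs, 1 - freqs) > maf_min
    hap = hap[:, keep]
    positions = positions[keep]
    freqs = hap.mean(axis=0)
    records = []
    for j in range(hap.shape[1]):
        rec = {"position": int(positions[j]), "freq": float(freqs[j]),
               "uihs": np.nan, "ihs": np.nan, "excluded": False}
        records.append(rec)
        try:
            off_a, e_a = ehh_brute(hap, positions, j, 0)
            off_d, e_d = ehh_brute(hap, positions, j, 1)
        except ValueError:
            rec["excluded"] = True
            continue
        ihh_a, exc_a, _ = ihh_brute(off_a, e_a, cutoff, gap_limit)
        ihh_d, exc_d, _ = ihh_brute(off_d, e_d, cutoff, gap_limit)
        if exc_a or exc_d or not (ihh_a > 0 and ihh_d > 0):
            rec["excluded"] = True
            continue
        rec["uihs"] = float(np.log(ihh_a / ihh_d))
    # standardization within derived-frequency bins
    n_bins = int(round(1 / bin_width))
    for rec in records:
        if rec["excluded"]:
            continue
        b = min(int(rec["freq"] / bin_width), n_bins - 1)
        peers = [r["uihs"] for r in records
                 if not r["excluded"] and min(int(r["freq"] / bin_width), n_bins - 1) == b]
        if len(peers) < 2 or np.std(peers) == 0:
            rec["excluded"] = True
            continue
        rec["ihs"] = (rec["uihs"] - np.mean(peers)) / np.std(peers)
    return records


def ld_brute(haps_a: np.ndarray, haps_b: np.ndarray):
    """D, |D'| and r^2 by direct counting over two phased allele vectors."""
    n = len(haps_a)
    p11 = np.sum((haps_a == 1) & (haps_b == 1)) / n
    p = np.mean(haps_a == 1)
    q = np.mean(haps_b == 1)
    d = p11 - p * q
    d_max = min(p * (1 - q), (1 - p) * q) if d >= 0 else min(p * q, (1 - p) * (1 - q))
    r2 = d * d / (p * (1 - p) * q * (1 - q))
    return d, abs(d) / d_max if d_max > 0 else 0.0, r2


def hudson_fst_brute(p1, n1, p2, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def wf_logistic_recursion(p0: float, s: float, h: float, n_gen: int) -> np.ndarray:
    """Deterministic (infinite-N) allele-frequency recursion under selection."""
    p = p0
    out = [p0]
    for _ in range(n_gen):
        w11, w01, w00 = 1 + s, 1 + h * s, 1.0
        w_bar = p * p * w11 + 2 * p * (1 - p) * w01 + (1 - p) * (1 - p) * w00
        p = (p * p * w11 + p * (1 - p) * w01) / w_bar
        out.append(p)
    return np.asarray(out)
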