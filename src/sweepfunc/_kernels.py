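"""Optional numba-compiled hot loops.

Everything here has a pure-NumPy equivalent in :mod:`sweepfunc.scan` and
:mod:`sweepfunc.simulate.wf`; the compiled kernels only make large
replicate runs (neutral nulls, power analyses) affordable. Equivalence of
the two code paths is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAS_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# status codes shared with scan.ihs_scan
OK = 0
FEW_CARRIERS = 1
GAP = 2


@njit(cache=True)
def scan_all_cores(hap, positions, next_mm_t, prev_mm_t, iu, ju,
                   ehh_cutoff, gap_limit_bp):
    """iHH for both alleles of every core site of a complete panel.

    ``next_mm_t``/``prev_mm_t`` are (n_sites, n_pairs) transposed mismatch
    indexes so each core reads one contiguous row; ``iu``/``ju`` give the
    haplotype members of each pair. Returns (ihh, status, truncated) of
    shape (n_sites, 2), column 0 ancestral / 1 derived. Semantics match
    compute_ehh + compute_ihh: EHH is the fraction of carrier pairs identical
    from the core to the offset site; the integral (trapezoid over bp) stops
    at the last site with EHH >= cutoff; a gap over ``gap_limit_bp`` walked
    before that point excludes the core; hitting the panel edge before the
    cutoff sets the truncated flag.
    """
    n, s = hap.shape
    n_all_pairs = iu.size
    ihh = np.zeros((s, 2))
    status = np.zeros((s, 2), np.int8)
    truncated = np.zeros((s, 2), np.uint8)
    counts0 = np.zeros(s + 1, np.int64)  # first-mismatch histograms per allele
    counts1 = np.zeros(s + 1, np.int64)
    for c in range(s):
        k1 = 0
        for i in range(n):
            if hap[i, c] == 1:
                k1 += 1
        k0 = n - k1
        if k0 < 2:
            status[c, 0] = FEW_CARRIERS
        if k1 < 2:
            status[c, 1] = FEW_CARRIERS
        if k0 < 2 or k1 < 2:
            continue
        for side in range(2):
            m = (s - c - 1) if side == 0 else c
            if m == 0:
                continue
            for j in range(m + 1):
                counts0[j] = 0
                counts1[j] = 0
            col = c + 1 if side == 0 else c - 1
            row = next_mm_t[col] if side == 0 else prev_mm_t[col]
            for p in range(n_all_pairs):
                aa = hap[iu[p], c]
                if aa != hap[ju[p], c]:
                    continue
                f = (row[p] - col) if side == 0 else (col - row[p])
                if aa == 0:
                    counts0[f] += 1
                else:
                    counts1[f] += 1
            for allele in range(2):
                if status[c, allele] != OK:
                    continue
                counts = counts0 if allele == 0 else counts1
                k = k0 if allele == 0 else k1
                n_pairs = k * (k - 1) // 2
                surviving = n_pairs
                ehh_prev = 1.0
                d_prev = 0.0
                stopped = False
                total = 0.0
                for j in range(m):
                    if side == 0:
                        d = float(positions[c + 1 + j] - positions[c])
                    else:
                        d = float(positions[c] - positions[c - 1 - j])
                    gap = d - d_prev
                    if gap > gap_limit_bp:
                        status[c, allele] = GAP
                        break
                    surviving -= counts[j]
                    ehh_j = surviving / n_pairs
                    if ehh_j < ehh_cutoff:
                        stopped = True
                        break
                    total += 0.5 * (ehh_prev + ehh_j) * gap
                    ehh_prev = ehh_j
                    d_prev = d
                if status[c, allele] == OK:
                    ihh[c, allele] += total
                    if not stopped:
                        truncated[c, allele] = 1
    return ihh, status, truncated


@njit(cache=True)
def apply_crossovers(hap, parents, start, cut_counts, cut_sites, out):
    """Overwrite crossover segments of pre-copied gametes.

    ``out`` must already hold each gamete's starting haplotype
    (``hap[2*parent + start]``). ``cut_sites`` is the flat array of
    per-gamete crossover site indices (grouped by gamete, each group
    sorted); segments between cuts alternate between the parent's two
    haplotypes, so every other segment is replaced by the homologue.
    """
    n, s = out.shape
    offset = 0
    for i in range(n):
        k = cut_counts[i]
        if k:
            other = 2 * parents[i] + 1 - start[i]
            t = 0
            while t < k:
                a = cut_sites[offset + t]
                b = cut_sites[offset + t + 1] if t + 1 < k else s
                out[i, a:b] = hap[other, a:b]
                t += 2
            offset += k


@njit(cache=True)
def build_mismatch_index_t(hap, iu, ju):
    """Transposed next/previous mismatch index: shape (n_sites, n_pairs).

    Built in pair blocks so the transposed writes stay cache-friendly; each
    output row (one core column) is then contiguous for the scan kernel.
    """
    n_pairs = iu.size
    s = hap.shape[1]
    next_t = np.empty((s, n_pairs), np.int16)
    prev_t = np.empty((s, n_pairs), np.int16)
    block = 64
    buf_n = np.empty((block, s), np.int16)
    buf_p = np.empty((block, s), np.int16)
    for p0 in range(0, n_pairs, block):
        nb = min(block, n_pairs - p0)
        for b in range(nb):
            a = iu[p0 + b]
            c = ju[p0 + b]
            nxt = s
            for j in range(s - 1, -1, -1):
                if hap[a, j] != hap[c, j]:
                    nxt = j
                buf_n[b, j] = nxt
            prv = -1
            for j in range(s):
                if hap[a, j] != hap[c, j]:
                    prv = j
                buf_p[b, j] = prv
        for j in range(s):
            for b in range(nb):
                next_t[j, p0 + b] = buf_n[b, j]
                prev_t[j, p0 + b] = buf_p[b, j]
    return next_t, prev_t
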