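"""Extended haplotype homozygosity (EHH), iHH, iHS and windowed candidate calling.

The scan follows the classical integrated-haplotype-score recipe: for every
biallelic core SNP passing a minor-allele-frequency filter, the decay of
haplotype homozygosity away from the core is computed separately for carriers
of the ancestral and of the derived allele; each curve is integrated over
physical distance (iHH), the unstandardized score is ``ln(iHH_A / iHH_D)``,
and scores are standardized to mean 0 / sd 1 within derived-allele-frequency
bins. 30 kb windows of the mean standardized score are compared against the
empirical percentile of the same statistic under neutral simulations.

Sign convention: positive uiHS/iHS means extended homozygosity around the
*ancestral* allele; strongly negative scores indicate unusually long derived
haplotypes, the footprint of a recent sweep of the derived allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .panel import MISSING, HaplotypePanel

__all__ = [
    "EHHCurve",
    "IHSRecord",
    "WindowScore",
    "NullDistribution",
    "BinStats",
    "filter_sites",
    "compute_ehh",
    "compute_ihh",
    "unstandardized_ihs",
    "standardize_ihs",
    "ihs_scan",
    "window_scan",
    "null_threshold",
    "call_candidates",
    "NullRun",
    "neutral_null_run",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EHHCurve:
    """EHH values at signed bp offsets from a core site (offset 0 has EHH 1)."""

    core_index: int
    core_position: int
    allele: int  # 0 = ancestral, 1 = derived
    offsets: np.ndarray  # signed bp offsets, ascending
    ehh: np.ndarray
    n_carriers: int

    def side(self, sign: int) -> tuple[np.ndarray, np.ndarray]:
        """(distances, ehh) walking outward on one side, starting at 0."""
        if sign > 0:
            mask = self.offsets >= 0
            return self.offsets[mask], self.ehh[mask]
        mask = self.offsets <= 0
        return -self.offsets[mask][::-1], self.ehh[mask][::-1]


@dataclass
class IHSRecord:
    """Per-core-SNP scan record; ``ihs`` is filled by standardization."""

    position: int
    derived_frequency: float
    ihh_a: float = np.nan
    ihh_d: float = np.nan
    uihs: float = np.nan
    ihs: float = np.nan
    bin_id: int = -1
    excluded: bool = False
    excluded_reason: str = ""
    truncated: bool = False  # EHH hit the panel edge before the cutoff


@dataclass
class WindowScore:
    """Non-overlapping genomic tile of mean iHS.

    ``abs_of_mean`` is |mean(iHS)| and ``mean_of_abs`` is mean(|iHS|); the
    configured one is exposed as ``score``.
    """

    chrom: str
    start: int  # 0-based, half-open
    end: int
    n_snps: int
    mean_ihs: float
    abs_of_mean: float
    mean_of_abs: float
    score_mode: str = "abs-of-mean"
    called: bool = False
    threshold: float = np.nan

    @property
    def score(self) -> float:
        return self.abs_of_mean if self.score_mode == "abs-of-mean" else self.mean_of_abs


@dataclass
class NullDistribution:
    """Empirical neutral distribution of window scores."""

    scores: np.ndarray
    percentile: float
    critical_value: float
    n_replicates: int

    @classmethod
    def from_scores(cls, scores, percentile: float = 99.99,
                    n_replicates: int | None = None) -> "NullDistribution":
        return cls(
            scores=np.asarray(scores, dtype=float),
            percentile=percentile,
            critical_value=null_threshold(scores, percentile),
            n_replicates=n_replicates if n_replicates is not None else len(scores),
        )


@dataclass
class BinStats:
    """Frequency-bin means/sds used to standardize uiHS (pooled reference)."""

    bin_width: float
    means: dict[int, float] = field(default_factory=dict)
    sds: dict[int, float] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def bin_of(self, freq: float) -> int:
        n_bins = int(round(1.0 / self.bin_width))
        return min(int(freq / self.bin_width), n_bins - 1)

    @classmethod
    def from_records(cls, records: list[IHSRecord], bin_width: float = 0.05) -> "BinStats":
        stats = cls(bin_width=bin_width)
        by_bin: dict[int, list[float]] = {}
        for r in records:
            if r.excluded or not np.isfinite(r.uihs):
                continue
            by_bin.setdefault(stats.bin_of(r.derived_frequency), []).append(r.uihs)
        for b, vals in by_bin.items():
            arr = np.asarray(vals)
            stats.means[b] = float(arr.mean())
            stats.sds[b] = float(arr.std(ddof=0))
            stats.counts[b] = len(vals)
        return stats


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_sites(panel: HaplotypePanel, maf_min: float = 0.05) -> HaplotypePanel:
    """Retain sites with minor allele frequency strictly above ``maf_min``.

    Strict inequality: a site at exactly ``maf_min`` is removed. Site order
    is preserved; an empty result only triggers a warning.
    """
    maf = panel.minor_allele_frequencies()
    keep = maf > maf_min
    if not keep.any():
        warnings.warn("MAF filter removed every site")
    return panel.subset_sites(keep)


def _ehh_side(hap: np.ndarray, carriers: np.ndarray, core: int, step: int,
              stop_below: float | None = None) -> tuple[list[int], list[float]]:
    """EHH walking outward from ``core`` in direction ``step`` (site indices, values).

    The walk ends at the panel edge, at the first zero, or at the first value
    below ``stop_below`` (that value is still reported, so integration can
    see the crossing). Complete panels use a vectorized pairwise
    first-difference computation; panels with missing alleles fall back to a
    per-site group refinement where haplotypes drop out of the pair count
    from the first missing call onward.
    """
    sub = hap[carriers]
    if not (sub == MISSING).any():
        return _ehh_side_complete(sub, core, step, stop_below)
    return _ehh_side_missing(hap, carriers, core, step, stop_below)


from functools import lru_cache


@lru_cache(maxsize=256)
def _triu_cached(k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(k, 1)


def _curve_from_first(first: np.ndarray, n_pairs: int, m: int, core: int, step: int,
                      stop_below: float | None) -> tuple[np.ndarray, np.ndarray]:
    """EHH side curve from per-pair first-mismatch offsets (0-based into the side)."""
    counts = np.bincount(first, minlength=m + 1)
    surviving = n_pairs - np.cumsum(counts[:m])
    ehh = surviving / n_pairs
    # truncate after the first zero / first value below the stop threshold
    limit = stop_below if stop_below is not None else np.nextafter(0.0, 1.0)
    below = np.nonzero(ehh < limit)[0]
    cut = (below[0] + 1) if below.size else m
    sites = core + step * np.arange(1, cut + 1)
    return sites, ehh[:cut]


def _ehh_side_complete(sub: np.ndarray, core: int, step: int,
                       stop_below: float | None) -> tuple[list[int], list[float]]:
    n = sub.shape[0]
    n_pairs = n * (n - 1) // 2
    seg = sub[:, core + 1:] if step > 0 else sub[:, :core][:, ::-1]
    m = seg.shape[1]
    if m == 0:
        return [], []
    iu, ju = np.triu_indices(n, 1)
    diff = seg[iu] != seg[ju]
    any_diff = diff.any(axis=1)
    first = np.where(any_diff, diff.argmax(axis=1), m)
    return _curve_from_first(first, n_pairs, m, core, step, stop_below)


class _PairMismatchIndex:
    """Per-panel index of next/previous mismatch positions for every haplotype pair.

    Lets the scan answer "first site at which pair (i, j) differs, walking
    out from any core" with a single gather, instead of re-comparing rows
    for every core SNP. Only valid for panels without missing alleles.
    """

    def __init__(self, hap: np.ndarray):
        n, s = hap.shape
        self.n = n
        iu, ju = _triu_cached(n)
        self.pair_id = np.full((n, n), -1, dtype=np.int32)
        self.pair_id[iu, ju] = np.arange(len(iu), dtype=np.int32)
        self.pair_id[ju, iu] = self.pair_id[iu, ju]
        self.iu, self.ju = iu.astype(np.int64), ju.astype(np.int64)
        # stored transposed: each core reads one contiguous (n_pairs,) row
        if _kernels.HAS_NUMBA and s < 32_000:  # compiled index is int16
            self.next_mm_t, self.prev_mm_t = _kernels.build_mismatch_index_t(
                np.ascontiguousarray(hap), self.iu, self.ju)
        else:
            diff = hap[iu] != hap[ju]
            idx = np.arange(s, dtype=np.int32)
            nm = np.where(diff, idx, np.int32(s))
            next_mm = np.minimum.accumulate(nm[:, ::-1], axis=1)[:, ::-1]
            pm = np.where(diff, idx, np.int32(-1))
            prev_mm = np.maximum.accumulate(pm, axis=1)
            self.next_mm_t = np.ascontiguousarray(next_mm.T)
            self.prev_mm_t = np.ascontiguousarray(prev_mm.T)
        self.n_sites = s

    def side_curve(self, carriers: np.ndarray, core: int, step: int,
                   stop_below: float | None) -> tuple[list[int], list[float]]:
        k = len(carriers)
        n_pairs = k * (k - 1) // 2
        ci, cj = _triu_cached(k)
        pids = self.pair_id[carriers[ci], carriers[cj]]
        if step > 0:
            m = self.n_sites - core - 1
            if m == 0:
                return [], []
            first = self.next_mm_t[core + 1][pids] - (core + 1)
        else:
            m = core
            if m == 0:
                return [], []
            first = (core - 1) - self.prev_mm_t[core - 1][pids]
        return _curve_from_first(first, n_pairs, m, core, step, stop_below)


def _ehh_side_missing(hap: np.ndarray, carriers: np.ndarray, core: int, step: int,
                      stop_below: float | None = None) -> tuple[list[int], list[float]]:
    n0 = len(carriers)
    labels = np.zeros(n0, dtype=np.int64)
    avail = np.ones(n0, dtype=bool)
    sites: list[int] = []
    values: list[float] = []
    j = core + step
    n_sites = hap.shape[1]
    while 0 <= j < n_sites:
        alleles = hap[carriers, j]
        avail &= alleles != MISSING
        n_avail = int(avail.sum())
        if n_avail < 2:
            ehh = 0.0
        else:
            key = labels[avail] * 2 + alleles[avail]
            _, labels_new = np.unique(key, return_inverse=True)
            labels = labels.copy()
            labels[avail] = labels_new
            counts = np.bincount(labels_new)
            ehh = float((counts * (counts - 1)).sum() / (n_avail * (n_avail - 1)))
        sites.append(j)
        values.append(ehh)
        if ehh == 0.0 or (stop_below is not None and ehh < stop_below):
            break
        j += step
    return sites, values


def compute_ehh(panel: HaplotypePanel, core_index: int, allele: int,
                stop_below: float | None = None,
                _index: "_PairMismatchIndex | None" = None) -> EHHCurve:
    """EHH curve for carriers of ``allele`` at ``core_index``.

    At each offset site the EHH is the fraction of carrier pairs whose
    haplotypes are identical over the whole interval between the core and
    that site, computed separately to the left and to the right. Requires at
    least two carriers.
    """
    hap = panel.haplotypes
    carriers = np.nonzero(hap[:, core_index] == allele)[0]
    if len(carriers) < 2:
        raise ValueError(
            f"EHH undefined: {len(carriers)} carrier(s) of allele {allele} "
            f"at site index {core_index}"
        )
    pos = panel.positions
    if _index is not None:
        left_sites, left_vals = _index.side_curve(carriers, core_index, -1, stop_below)
        right_sites, right_vals = _index.side_curve(carriers, core_index, +1, stop_below)
    else:
        left_sites, left_vals = _ehh_side(hap, carriers, core_index, -1, stop_below)
        right_sites, right_vals = _ehh_side(hap, carriers, core_index, +1, stop_below)
    left_sites = np.asarray(left_sites, dtype=np.int64)
    right_sites = np.asarray(right_sites, dtype=np.int64)
    offsets = np.concatenate([
        (pos[left_sites] - pos[core_index])[::-1] if len(left_sites) else np.empty(0, dtype=np.int64),
        [0],
        pos[right_sites] - pos[core_index] if len(right_sites) else np.empty(0, dtype=np.int64),
    ])
    ehh = np.concatenate([np.asarray(left_vals, dtype=float)[::-1], [1.0],
                          np.asarray(right_vals, dtype=float)])
    return EHHCurve(
        core_index=core_index,
        core_position=int(pos[core_index]),
        allele=allele,
        offsets=offsets.astype(np.int64),
        ehh=ehh,
        n_carriers=len(carriers),
    )


@dataclass
class IHHResult:
    value: float
    excluded: bool = False
    reason: str = ""
    truncated: bool = False


def compute_ihh(curve: EHHCurve, ehh_cutoff: float = 0.05,
                gap_limit_bp: int = 20_000) -> IHHResult:
    """Trapezoidal integral of the EHH curve over physical distance.

    Each side is truncated at the last offset where EHH is still >=
    ``ehh_cutoff`` (the segment crossing below the cutoff is not counted).
    If any gap between adjacent informative sites larger than
    ``gap_limit_bp`` is crossed before truncation, the variant is excluded
    (typed outcome, not an exception). If a side reaches the panel edge
    before dropping below the cutoff, the integral stops there and the
    result is flagged ``truncated``.
    """
    total = 0.0
    truncated = False
    for sign in (+1, -1):
        dist, ehh = curve.side(sign)
        if len(dist) < 2:
            continue
        gaps = np.diff(dist)
        below = ehh[1:] < ehh_cutoff
        if below.any():
            stop = int(np.argmax(below))  # first segment whose far end crosses
            checked = stop + 1  # the crossing segment is still walked
            stopped = True
        else:
            stop = checked = len(gaps)
            stopped = False
        big = gaps[:checked] > gap_limit_bp
        if big.any():
            gap = int(gaps[:checked][np.argmax(big)])
            return IHHResult(np.nan, excluded=True,
                             reason=f"gap {gap} bp > {gap_limit_bp} bp")
        total += float(np.sum(0.5 * (ehh[1:stop + 1] + ehh[:stop]) * gaps[:stop]))
        if not stopped:
            truncated = True
    return IHHResult(total, truncated=truncated)


def unstandardized_ihs(ihh_a: float, ihh_d: float) -> float:
    """``ln(iHH_ancestral / iHH_derived)``; both integrals must be positive."""
    if not (ihh_a > 0 and ihh_d > 0):
        raise ValueError("uiHS requires strictly positive iHH on both alleles")
    return float(np.log(ihh_a / ihh_d))


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    gap_limit_bp: int = 20_000,
    standardize: bool = True,
    bin_width: float = 0.05,
    reference: BinStats | None = None,
) -> list[IHSRecord]:
    """Full per-SNP scan: MAF filter, EHH both alleles, iHH, uiHS, iHS.

    Exclusions (too few carriers, a >gap-limit gap, zero integral) are typed
    records, never exceptions. With ``standardize=False`` only uiHS is
    filled; pass ``reference`` to standardize against pooled neutral bin
    statistics instead of the panel's own bins.
    """
    filtered = filter_sites(panel, maf_min)
    freqs = filtered.derived_frequencies()
    complete = filtered.n_sites and not (filtered.haplotypes == MISSING).any()
    records: list[IHSRecord] = []
    if complete and _kernels.HAS_NUMBA:
        index = _PairMismatchIndex(filtered.haplotypes)
        ihh, status, trunc = _kernels.scan_all_cores(
            np.ascontiguousarray(filtered.haplotypes),
            filtered.positions,
            index.next_mm_t, index.prev_mm_t, index.iu, index.ju,
            float(ehh_cutoff), float(gap_limit_bp),
        )
        for j in range(filtered.n_sites):
            rec = IHSRecord(position=int(filtered.positions[j]),
                            derived_frequency=float(freqs[j]))
            records.append(rec)
            if _kernels.FEW_CARRIERS in (status[j, 0], status[j, 1]):
                rec.excluded, rec.excluded_reason = True, "fewer than 2 carriers"
                continue
            if _kernels.GAP in (status[j, 0], status[j, 1]):
                rec.excluded = True
                rec.excluded_reason = f"gap > {gap_limit_bp} bp"
                continue
            rec.ihh_a, rec.ihh_d = float(ihh[j, 0]), float(ihh[j, 1])
            rec.truncated = bool(trunc[j, 0] or trunc[j, 1])
            if rec.ihh_a <= 0 or rec.ihh_d <= 0:
                rec.excluded, rec.excluded_reason = True, "zero iHH integral"
                continue
            rec.uihs = unstandardized_ihs(rec.ihh_a, rec.ihh_d)
    else:
        index = _PairMismatchIndex(filtered.haplotypes) if complete else None
        for j in range(filtered.n_sites):
            rec = IHSRecord(position=int(filtered.positions[j]),
                            derived_frequency=float(freqs[j]))
            records.append(rec)
            try:
                curve_a = compute_ehh(filtered, j, 0, stop_below=ehh_cutoff, _index=index)
                curve_d = compute_ehh(filtered, j, 1, stop_below=ehh_cutoff, _index=index)
            except ValueError:
                rec.excluded, rec.excluded_reason = True, "fewer than 2 carriers"
                continue
            res_a = compute_ihh(curve_a, ehh_cutoff, gap_limit_bp)
            res_d = compute_ihh(curve_d, ehh_cutoff, gap_limit_bp)
            if res_a.excluded or res_d.excluded:
                rec.excluded = True
                rec.excluded_reason = res_a.reason or res_d.reason
                continue
            rec.ihh_a, rec.ihh_d = res_a.value, res_d.value
            rec.truncated = res_a.truncated or res_d.truncated
            if res_a.value <= 0 or res_d.value <= 0:
                rec.excluded, rec.excluded_reason = True, "zero iHH integral"
                continue
            rec.uihs = unstandardized_ihs(res_a.value, res_d.value)
    if standardize:
        standardize_ihs(records, bin_width=bin_width, reference=reference)
    return records


def standardize_ihs(
    records: list[IHSRecord],
    bin_width: float = 0.05,
    reference: BinStats | None = None,
) -> list[IHSRecord]:
    """Standardize uiHS to mean 0 / sd 1 within derived-frequency bins (in place).

    Bins with a single record or zero spread are flagged excluded rather
    than merged. A ``reference`` (e.g. pooled from neutral replicates)
    substitutes its bin means/sds for the sample's own.
    """
    stats = reference if reference is not None else BinStats.from_records(records, bin_width)
    for r in records:
        if r.excluded or not np.isfinite(r.uihs):
            continue
        b = stats.bin_of(r.derived_frequency)
        r.bin_id = b
        mean = stats.means.get(b)
        sd = stats.sds.get(b)
        n = stats.counts.get(b, 0)
        if mean is None or n < 2:
            r.excluded, r.excluded_reason = True, "bin has fewer than 2 records"
            continue
        if sd == 0:
            r.excluded, r.excluded_reason = True, "zero spread in frequency bin"
            continue
        r.ihs = (r.uihs - mean) / sd
    return records


def window_scan(
    records: list[IHSRecord],
    window_bp: int = 30_000,
    chrom: str = "1",
    score_mode: str = "abs-of-mean",
    min_snps: int = 1,
) -> list[WindowScore]:
    """Aggregate standardized scores into non-overlapping ``window_bp`` tiles.

    Tiles are anchored at coordinate 0 and half-open, ``[k*w, (k+1)*w)`` in
    0-based coordinates; 1-based SNP positions are converted internally.
    Windows without scored SNPs are omitted.
    """
    if score_mode not in ("abs-of-mean", "mean-of-abs"):
        raise ValueError("score_mode must be 'abs-of-mean' or 'mean-of-abs'")
    by_window: dict[int, list[float]] = {}
    for r in records:
        if r.excluded or not np.isfinite(r.ihs):
            continue
        by_window.setdefault((r.position - 1) // window_bp, []).append(r.ihs)
    out = []
    for k in sorted(by_window):
        vals = np.asarray(by_window[k])
        if len(vals) < min_snps:
            continue
        mean = float(vals.mean())
        out.append(WindowScore(
            chrom=chrom,
            start=k * window_bp,
            end=(k + 1) * window_bp,
            n_snps=len(vals),
            mean_ihs=mean,
            abs_of_mean=abs(mean),
            mean_of_abs=float(np.abs(vals).mean()),
            score_mode=score_mode,
        ))
    return out


def null_threshold(scores, percentile: float = 99.99) -> float:
    """Empirical percentile of neutral window scores (linear interpolation).

    Warns when fewer than 10^4 scores back a 99.99th percentile.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot take a percentile of an empty score set")
    if percentile >= 99.9 and scores.size < 10_000:
        warnings.warn(
            f"only {scores.size} window scores for the {percentile} percentile; "
            ">= 10^4 recommended"
        )
    return float(np.percentile(scores, percentile, method="linear"))


def call_candidates(windows: list[WindowScore], critical_value: float) -> list[WindowScore]:
    """Windows with score strictly above the neutral critical value (annotated)."""
    called = []
    for w in windows:
        w.threshold = critical_value
        w.called = w.score > critical_value
        if w.called:
            called.append(w)
    return called


@dataclass
class NullRun:
    """Pooled result of a neutral replicate run: reference bins + window scores."""

    reference: BinStats
    abs_of_mean: np.ndarray
    mean_of_abs: np.ndarray
    n_panels: int

    def threshold(self, percentile: float = 99.99, score_mode: str = "abs-of-mean") -> float:
        scores = self.abs_of_mean if score_mode == "abs-of-mean" else self.mean_of_abs
        return null_threshold(scores, percentile)


def neutral_null_run(
    demography,
    n_panels: int,
    seed: int,
    population: str | None = None,
    spacing: int | None = None,
    maf_min: float = 0.05,
    ehh_cutoff: float = 0.05,
    gap_limit_bp: int = 20_000,
    window_bp: int = 30_000,
    bin_width: float = 0.05,
) -> NullRun:
    """Neutral window-score distribution from replicate panels.

    Scans every replicate, pools the unstandardized scores into frequency-bin
    reference statistics, standardizes each panel against that pooled
    reference (the replicate-run analogue of genome-wide standardization)
    and collects both window score variants.
    """
    from .simulate import simulate_replicate_panels

    per_panel = []
    all_records: list[IHSRecord] = []
    for panel in simulate_replicate_panels(demography, n_panels, seed, spacing=spacing):
        sub = panel.subset_population(population) if population else panel
        records = ihs_scan(sub, maf_min=maf_min, ehh_cutoff=ehh_cutoff,
                           gap_limit_bp=gap_limit_bp, standardize=False,
                           bin_width=bin_width)
        per_panel.append((sub.chrom, records))
        all_records.extend(records)
    reference = BinStats.from_records(all_records, bin_width)
    abs_scores, mabs_scores = [], []
    for chrom, records in per_panel:
        standardize_ihs(records, bin_width=bin_width, reference=reference)
        for w in window_scan(records, window_bp=window_bp, chrom=chrom):
            abs_scores.append(w.abs_of_mean)
            mabs_scores.append(w.mean_of_abs)
    return NullRun(
        reference=reference,
        abs_of_mean=np.asarray(abs_scores),
        mean_of_abs=np.asarray(mabs_scores),
        n_panels=n_panels,
    )
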