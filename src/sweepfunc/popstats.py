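"""Allele/genotype/haplotype frequencies, two-locus LD and per-site Fst.

Small, closed-form population-genetic summaries operating either on a phased
:class:`~sweepfunc.panel.HaplotypePanel` or directly on frequency tables of
the kind printed in study supplements (genotype fractions, two-locus
haplotype frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypePanel

__all__ = [
    "GenotypeFractions",
    "HaplotypeFreqTable",
    "LDPair",
    "FstRecord",
    "allele_frequency_from_genotypes",
    "haplotype_frequencies",
    "ld_from_haplotype_freqs",
    "ld_between_sites",
    "fst_per_site",
    "fst_scan",
    "load_genotype_fractions_table",
    "load_haplotype_frequency_table",
]

_SUM_TOL = 1e-9


@dataclass
class GenotypeFractions:
    """Population fractions of the three diploid genotypes at a biallelic site."""

    ancestral_hom: float
    heterozygous: float
    derived_hom: float

    def __post_init__(self) -> None:
        vals = (self.ancestral_hom, self.heterozygous, self.derived_hom)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("genotype fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > _SUM_TOL:
            raise ValueError(f"genotype fractions must sum to 1 (got {sum(vals)})")


@dataclass
class HaplotypeFreqTable:
    """Frequencies of the four two-locus haplotype classes.

    Order: derived-derived, derived-ancestral, ancestral-derived,
    ancestral-ancestral (locus A state first).
    """

    dd: float
    da: float
    ad: float
    aa: float
    n_haplotypes: int | None = None

    def __post_init__(self) -> None:
        vals = self.as_array()
        if (vals < -_SUM_TOL).any():
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"haplotype frequencies must sum to 1 (got {vals.sum()})")

    def as_array(self) -> np.ndarray:
        return np.asarray([self.dd, self.da, self.ad, self.aa], dtype=float)

    @property
    def p_derived_a(self) -> float:
        """Derived-allele frequency at locus A."""
        return self.dd + self.da

    @property
    def p_derived_b(self) -> float:
        """Derived-allele frequency at locus B."""
        return self.dd + self.ad


@dataclass
class LDPair:
    """Two-locus linkage disequilibrium: D, |D'| and r^2."""

    d: float
    d_prime: float
    r_squared: float
    p_a: float
    p_b: float


@dataclass
class FstRecord:
    """Per-site Fst between two populations."""

    position: int
    estimator: str
    fst: float
    n1: int
    n2: int
    p1: float
    p2: float


# ---------------------------------------------------------------------------

def allele_frequency_from_genotypes(g: GenotypeFractions) -> float:
    """Derived allele frequency implied by genotype fractions.

    ``freq = derived_hom + heterozygous / 2`` — e.g. fractions
    (0.04, 0.5, 0.46) give 0.71.
    """
    return g.derived_hom + g.heterozygous / 2.0


def haplotype_frequencies(
    panel: HaplotypePanel,
    locus_a: int,
    locus_b: int,
    population: str | None = None,
) -> HaplotypeFreqTable:
    """Two-locus haplotype class frequencies by plain counting of phased haplotypes.

    ``locus_a``/``locus_b`` are site indices into the panel. Haplotypes with a
    missing allele at either locus drop out of the denominator.
    """
    if population is not None:
        panel = panel.subset_population(population)
    a = panel.haplotypes[:, locus_a]
    b = panel.haplotypes[:, locus_b]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    n = len(a)
    if n == 0:
        raise ValueError("no haplotype has called alleles at both loci")
    return HaplotypeFreqTable(
        dd=float(np.sum((a == 1) & (b == 1)) / n),
        da=float(np.sum((a == 1) & (b == 0)) / n),
        ad=float(np.sum((a == 0) & (b == 1)) / n),
        aa=float(np.sum((a == 0) & (b == 0)) / n),
        n_haplotypes=n,
    )


def ld_from_haplotype_freqs(table: HaplotypeFreqTable) -> LDPair:
    """D, |D'| and r^2 from a two-locus haplotype frequency table.

    ``D = p11 - pA*pB`` (computed via the equivalent determinant
    ``dd*aa - da*ad`` for better floating-point behaviour);
    ``D' = |D| / Dmax`` with the usual frequency-dependent maximum;
    ``r^2 = D^2 / (pA(1-pA) pB(1-pB))``. Requires both loci polymorphic.
    """
    p = table.p_derived_a
    q = table.p_derived_b
    p_c = table.ad + table.aa  # 1 - p, taken from the table itself
    q_c = table.da + table.aa  # 1 - q
    if not (0.0 < p < 1.0) or not (0.0 < q < 1.0):
        raise ValueError("LD undefined: monomorphic locus")
    d = table.dd * table.aa - table.da * table.ad
    if d >= 0:
        d_max = min(p * q_c, p_c * q)
    else:
        d_max = min(p * q, p_c * q_c)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / ((p * q_c) * (p_c * q))
    return LDPair(d=float(d), d_prime=float(d_prime), r_squared=float(r2),
                  p_a=float(p), p_b=float(q))


def ld_between_sites(
    panel: HaplotypePanel,
    locus_a: int,
    locus_b: int,
    population: str | None = None,
) -> LDPair:
    """Convenience: haplotype counting followed by :func:`ld_from_haplotype_freqs`."""
    return ld_from_haplotype_freqs(
        haplotype_frequencies(panel, locus_a, locus_b, population)
    )


def fst_per_site(
    p1: float,
    n1: int,
    p2: float,
    n2: int,
    estimator: str = "hudson",
    position: int = 0,
) -> FstRecord:
    """Per-site Fst from two allele frequencies and haploid sample sizes.

    ``hudson``
        Sample-size-corrected Hudson estimator:
        ``[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] / [p1(1-p2)+p2(1-p1)]``.
        Can be (and is reported) negative at low differentiation.
    ``plugin``
        Uncorrected ``(p1-p2)^2 / [p1(1-p2)+p2(1-p1)]`` (always >= 0), useful
        for analytic checks.
    ``weir-cockerham``
        Two-population Weir & Cockerham theta from haploid allele counts.
    """
    denom = p1 * (1 - p2) + p2 * (1 - p1)
    if estimator in ("hudson", "plugin"):
        if denom == 0:
            raise ValueError("Fst undefined: both populations monomorphic for the same allele")
        if estimator == "hudson":
            if n1 < 2 or n2 < 2:
                raise ValueError("corrected estimator needs sample sizes >= 2")
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        else:
            num = (p1 - p2) ** 2
        fst = num / denom
    elif estimator == "weir-cockerham":
        fst = _weir_cockerham(p1, n1, p2, n2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return FstRecord(position=position, estimator=estimator, fst=float(fst),
                     n1=n1, n2=n2, p1=p1, p2=p2)


def _weir_cockerham(p1: float, n1: int, p2: float, n2: int) -> float:
    """Weir & Cockerham (1984) theta for two populations of haploid sequences."""
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = n_bar / n_c * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    if a + b == 0:
        raise ValueError("Fst undefined: no variation in either population")
    return a / (a + b)


def fst_scan(
    panel: HaplotypePanel,
    pop1: str,
    pop2: str,
    estimator: str = "hudson",
) -> list[FstRecord]:
    """Per-site Fst between two panel populations at every segregating site."""
    sub1 = panel.subset_population(pop1)
    sub2 = panel.subset_population(pop2)
    f1 = sub1.derived_frequencies()
    f2 = sub2.derived_frequencies()
    records = []
    for j, pos in enumerate(panel.positions):
        try:
            records.append(fst_per_site(
                float(f1[j]), sub1.n_haplotypes, float(f2[j]), sub2.n_haplotypes,
                estimator=estimator, position=int(pos),
            ))
        except ValueError:
            continue
    return records


# ---------------------------------------------------------------------------
# bundled worked-example tables
# ---------------------------------------------------------------------------

def _bundled(name: str):
    from importlib.resources import files

    return files("sweepfunc.data").joinpath(name)


def load_genotype_fractions_table(path=None) -> dict[str, GenotypeFractions]:
    """Genotype-fraction table (bundled Gumuz worked example by default).

    TSV columns: variant_id, position, ancestral, derived,
    frac_ancestral_hom, frac_het, frac_derived_hom.
    """
    import pandas as pd

    src = path if path is not None else _bundled("table_genotype_fractions.tsv")
    with open(src) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return {
        row["variant_id"]: GenotypeFractions(
            ancestral_hom=float(row["frac_ancestral_hom"]),
            heterozygous=float(row["frac_het"]),
            derived_hom=float(row["frac_derived_hom"]),
        )
        for _, row in df.iterrows()
    }


def load_haplotype_frequency_table(path=None) -> dict[str, HaplotypeFreqTable]:
    """Two-locus haplotype frequencies per population (bundled table by default).

    Published tables print rounded frequencies whose rows may not sum to
    exactly 1 (the bundled table has one such row); rows are renormalized by
    their sum so the strict table invariant holds.
    """
    import pandas as pd

    src = path if path is not None else _bundled("table_haplotype_frequencies.tsv")
    with open(src) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    out = {}
    for _, row in df.iterrows():
        vals = np.asarray([row["dd"], row["da"], row["ad"], row["aa"]], dtype=float)
        vals = vals / vals.sum()
        out[row["population"]] = HaplotypeFreqTable(*vals)
    return out
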