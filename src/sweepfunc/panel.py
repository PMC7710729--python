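"""Phased haplotype panels with ancestral/derived polarization.

The central container for the population-genetic stages: a matrix of phased
haplotypes (rows) by segregating sites (columns), alleles coded 0 for the
ancestral and 1 for the derived state (-1 for missing), together with 1-based
physical positions and a population label per sample.

On disk a panel is a VCF whose INFO field carries the ancestral allele
(``AA=<base>``) plus a two-column popmap TSV (``sample_id<TAB>population``).
Reading goes through :mod:`cyvcf2`; writing emits plain VCF text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = -1

_COMPLEMENT_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class HaplotypePanel:
    """Phased diploid panel: ``haplotypes[2*i]`` and ``[2*i+1]`` belong to sample ``i``.

    Parameters
    ----------
    chrom:
        Chromosome identifier.
    positions:
        1-based physical positions in bp, strictly increasing.
    haplotypes:
        ``(2*n_samples, n_sites)`` int8 matrix; 0 ancestral, 1 derived,
        -1 missing.
    samples:
        Sample identifiers, one per diploid individual.
    populations:
        Population label per sample.
    """

    chrom: str
    positions: np.ndarray
    haplotypes: np.ndarray
    samples: list[str]
    populations: list[str]
    metadata: dict = field(default_factory=dict)

    ploidy: int = 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        n_hap, n_sites = self.haplotypes.shape
        if n_hap != self.ploidy * len(self.samples):
            raise ValueError(
                f"haplotype rows ({n_hap}) != ploidy x samples "
                f"({self.ploidy} x {len(self.samples)})"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label required per sample")
        if len(self.positions) != n_sites:
            raise ValueError("positions length must match site count")
        if n_sites and (np.any(np.diff(self.positions) <= 0) or self.positions[0] < 1):
            raise ValueError("positions must be 1-based, strictly increasing")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0 (ancestral), 1 (derived) or -1 (missing)")

    # -- basic queries -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def derived_frequencies(self) -> np.ndarray:
        """Per-site derived allele frequency over non-missing alleles."""
        called = self.haplotypes != MISSING
        n_called = called.sum(axis=0)
        derived = (self.haplotypes == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, derived / np.maximum(n_called, 1), np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.derived_frequencies()
        return np.minimum(p, 1.0 - p)

    def subset_population(self, population: str) -> "HaplotypePanel":
        """Panel restricted to one population's samples (all sites kept)."""
        idx = [i for i, p in enumerate(self.populations) if p == population]
        if not idx:
            raise KeyError(f"population {population!r} not in panel")
        rows = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions.copy(),
            haplotypes=self.haplotypes[rows],
            samples=[self.samples[i] for i in idx],
            populations=[population] * len(idx),
            metadata=dict(self.metadata),
        )

    def subset_sites(self, site_mask: np.ndarray) -> "HaplotypePanel":
        site_mask = np.asarray(site_mask, dtype=bool)
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions[site_mask],
            haplotypes=self.haplotypes[:, site_mask],
            samples=list(self.samples),
            populations=list(self.populations),
            metadata=dict(self.metadata),
        )

    # -- I/O ---------------------------------------------------------------
    def write_vcf(self, vcf_path: str | Path, popmap_path: str | Path | None = None) -> None:
        """Write the panel as a phased VCF with ``AA`` annotations.

        The ancestral allele is written as REF and the derived allele as ALT,
        with ``INFO AA=<REF>``; genotypes are phased (``0|1``).
        """
        vcf_path = Path(vcf_path)
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            f"##contig=<ID={self.chrom}>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples),
        ]
        bases = self.metadata.get("ancestral_bases")
        for j, pos in enumerate(self.positions):
            ref = bases[j] if bases is not None else "A"
            alt = _COMPLEMENT_BASE.get(ref, "G")
            gts = []
            for i in range(len(self.samples)):
                a, b = self.haplotypes[2 * i, j], self.haplotypes[2 * i + 1, j]
                gts.append(f"{'.' if a == MISSING else a}|{'.' if b == MISSING else b}")
            lines.append(
                f"{self.chrom}\t{pos}\tsnp{j}\t{ref}\t{alt}\t.\tPASS\tAA={ref}\tGT\t" + "\t".join(gts)
            )
        vcf_path.write_text("\n".join(lines) + "\n")
        if popmap_path is not None:
            self.write_popmap(popmap_path)

    def write_popmap(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{p}\n" for s, p in zip(self.samples, self.populations))
        )


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a ``sample<TAB>population`` map."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sample, pop = line.split("\t")[:2]
        mapping[sample] = pop
    return mapping


def read_vcf(
    vcf_path: str | Path,
    popmap_path: str | Path | None = None,
    chrom: str | None = None,
) -> HaplotypePanel:
    """Load a phased, AA-annotated VCF into a polarized panel.

    Sites are polarized against the ``AA`` INFO tag: when AA equals ALT the
    coding is flipped so 1 is always the derived allele. Sites whose AA
    matches neither allele, or non-biallelic sites, are skipped with a
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    chrom_seen: str | None = None
    skipped = 0
    for variant in vcf:
        if chrom is not None and variant.CHROM != chrom:
            continue
        if chrom_seen is None:
            chrom_seen = variant.CHROM
        elif variant.CHROM != chrom_seen:
            raise ValueError("multi-chromosome VCF: pass chrom= to select one")
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        aa = variant.INFO.get("AA")
        if aa is None:
            skipped += 1
            continue
        aa = str(aa).upper()
        if aa == variant.REF.upper():
            flip = False
        elif aa == variant.ALT[0].upper():
            flip = True
        else:
            skipped += 1
            continue
        gts = np.asarray(variant.genotype.array())[:, :2]
        col = gts.reshape(-1).astype(np.int8)
        if flip:
            swap = col >= 0
            col[swap] = 1 - col[swap]
        col[col < 0] = MISSING
        positions.append(variant.POS)
        columns.append(col)
    if skipped:
        warnings.warn(f"{skipped} site(s) skipped (non-biallelic or unusable AA tag)")
    if not columns:
        raise ValueError(f"no usable sites in {vcf_path}")
    hap = np.stack(columns, axis=1)
    if popmap_path is not None:
        popmap = read_popmap(popmap_path)
        missing = [s for s in samples if s not in popmap]
        if missing:
            raise ValueError(f"samples absent from popmap: {missing}")
        populations = [popmap[s] for s in samples]
    else:
        populations = ["pop0"] * len(samples)
    return HaplotypePanel(
        chrom=chrom_seen or "1",
        positions=np.asarray(positions),
        haplotypes=hap,
        samples=samples,
        populations=populations,
    )
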