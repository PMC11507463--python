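"""VCF and recombination-map file adapters.

Reading goes through cyvcf2; writing emits plain-text VCF v4.2 (unphased
``0/1`` or phased ``0|1`` genotypes).  Genotypes are exchanged as alt-allele
dosage matrices with -1 for missing, matching the rest of the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genmap import GeneticMap
from .panel import MarkerPanel

__all__ = ["write_vcf", "read_vcf", "read_map_file", "hwe_exact_test", "VcfData"]


def write_vcf(
    path,
    panel: MarkerPanel,
    sample_ids: list[str],
    genotypes: np.ndarray | None = None,
    haplotypes: np.ndarray | None = None,
) -> None:
    """Write a plain-text VCF.

    Pass ``haplotypes`` ((2n, m) 0/1 rows) for phased output (``|`` separator)
    or ``genotypes`` ((n, m) dosage) for unphased; dosage -1 becomes ``./.``.
    Positions are written 1-based as stored in the panel.
    """
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("pass exactly one of genotypes/haplotypes")
    t = panel.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, bp in {c: b for c, b, _ in _chrom_info(panel)}.items():
            fh.write(f"##contig=<ID={chrom},length={int(bp) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        n = len(sample_ids)
        for j in range(len(panel)):
            row = t.iloc[j]
            if haplotypes is not None:
                calls = [f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}" for i in range(n)]
            else:
                calls = [_dosage_to_gt(int(genotypes[i, j])) for i in range(n)]
            fh.write(
                f"{row.chrom}\t{int(row.pos_bp)}\tsnp{row.chrom}_{int(row.pos_bp)}\t"
                f"{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _chrom_info(panel: MarkerPanel):
    for chrom, sl in panel.chrom_slices():
        yield chrom, panel.pos_bp[sl][-1], sl


def _dosage_to_gt(d: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}.get(d, "./.")


class VcfData:
    """Container for a parsed VCF: marker table, samples, dosage, haplotypes."""

    def __init__(self, table: pd.DataFrame, samples: list[str],
                 genotypes: np.ndarray, haplotypes: np.ndarray | None):
        self.table = table  # chrom, pos_bp, ref, alt
        self.samples = samples
        self.genotypes = genotypes  # (n_samples, n_markers) dosage, -1 missing
        self.haplotypes = haplotypes  # (2n, m) or None if any site unphased

    def to_panel(self, gmap: GeneticMap) -> MarkerPanel:
        """Attach genetic positions (from the map) and sample allele frequencies."""
        t = self.table.copy()
        t["pos_cm"] = [
            float(gmap.bp_to_cm(c, p)) for c, p in zip(t["chrom"], t["pos_bp"])
        ]
        g = self.genotypes
        with np.errstate(invalid="ignore"):
            called = (g >= 0).sum(axis=0)
            t["alt_freq"] = np.where(called > 0, (g.clip(0).sum(axis=0)) / (2 * called), np.nan)
        return MarkerPanel(t[["chrom", "pos_bp", "pos_cm", "ref", "alt", "alt_freq"]])


def read_vcf(path) -> VcfData:
    """Read biallelic SNP sites from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, genos, haps = [], [], []
    phased_ok = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        rows.append((_chrom_to_int(v.CHROM), v.POS, v.REF, v.ALT[0]))
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int16)
        phased_ok = phased_ok and all(gt[2] for gt in v.genotypes)
        dos = np.where((g < 0).any(axis=1), -1, g.clip(0).sum(axis=1))
        genos.append(dos)
        haps.append(g.reshape(-1))
    table = pd.DataFrame(rows, columns=["chrom", "pos_bp", "ref", "alt"])
    genotypes = np.asarray(genos, dtype=np.int8).T if genos else np.empty((len(samples), 0), np.int8)
    haplotypes = None
    if phased_ok and haps:
        h = np.asarray(haps, dtype=np.int16).T
        if h.min() >= 0:
            haplotypes = h.astype(np.uint8)
    return VcfData(table, samples, genotypes, haplotypes)


def _chrom_to_int(name: str) -> int:
    s = name.removeprefix("chr")
    return int(s)


def read_map_file(path, bp_per_cm_fallback: float = 1e6) -> GeneticMap:
    """Read a 3-column (chrom, pos_bp, pos_cm) recombination map file."""
    t = pd.read_csv(path, sep=r"\s+", comment="#",
                    names=["chrom", "pos_bp", "pos_cm"], header=0)
    ids, bps, cms = [], [], []
    for chrom, g in t.groupby("chrom", sort=True):
        g = g.sort_values("pos_bp")
        bp = g["pos_bp"].to_numpy(dtype=float)
        cm = g["pos_cm"].to_numpy(dtype=float)
        if bp[0] > 0:
            bp = np.concatenate([[0.0], bp])
            cm = np.concatenate([[max(0.0, cm[0] - bp[1] / bp_per_cm_fallback)], cm])
        ids.append(int(chrom))
        bps.append(bp)
        cms.append(np.maximum.accumulate(cm))
    return GeneticMap(ids, bps, cms)


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities <= observed).

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts no more likely than the observed one.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(np.minimum(p[p <= obs + 1e-12].sum(), 1.0))
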