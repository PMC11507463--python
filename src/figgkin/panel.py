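"""Synthetic SNP panels and phased founder haplotypes.

The panel emulates a dense autosomal genotyping array after standard quality
filters: biallelic SNPs only, minor allele frequency above 0.05, physical and
genetic coordinates on every marker.  Founder haplotypes are drawn site-wise
independently (no linkage disequilibrium), which makes the null distribution of
chance identity-by-state runs analytically tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = ["MarkerPanel", "HaplotypeSet", "generate_founders", "subsample_panel"]

_BASES = np.array(list("ACGT"))


@dataclass
class MarkerPanel:
    """Ordered biallelic marker table.

    ``table`` columns: ``chrom, pos_bp, pos_cm, ref, alt, alt_freq``; rows are
    sorted by (chrom, pos_bp) with strictly increasing positions within a
    chromosome and minor allele frequency >= 0.05.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "pos_bp", "pos_cm", "ref", "alt", "alt_freq"}
        if missing := required - set(t.columns):
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        for _, g in t.groupby("chrom", sort=False):
            if np.any(np.diff(g["pos_bp"].to_numpy()) <= 0):
                raise ValueError("marker bp positions must be strictly increasing per chromosome")
        f = t["alt_freq"].to_numpy()
        if np.any(np.minimum(f, 1 - f) < 0.05 - 1e-12):
            raise ValueError("all markers must satisfy MAF >= 0.05")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def pos_cm(self) -> np.ndarray:
        return self.table["pos_cm"].to_numpy()

    @property
    def alt_freq(self) -> np.ndarray:
        return self.table["alt_freq"].to_numpy()

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """Contiguous row slice per chromosome, in panel order."""
        out = []
        chroms = self.table["chrom"].to_numpy()
        bounds = np.flatnonzero(np.diff(chroms) != 0) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(chroms)]])
        for s, e in zip(starts, ends):
            out.append((int(chroms[s]), slice(int(s), int(e))))
        return out

    def take(self, idx: np.ndarray) -> "MarkerPanel":
        return MarkerPanel(self.table.iloc[idx].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        """PLINK .bim-like TSV: chrom, id, pos_cm, pos_bp, alt, ref (+ alt_freq)."""
        t = self.table
        out = pd.DataFrame(
            {
                "chrom": t["chrom"],
                "id": [f"snp{c}_{p}" for c, p in zip(t["chrom"], t["pos_bp"])],
                "pos_cm": t["pos_cm"],
                "pos_bp": t["pos_bp"],
                "alt": t["alt"],
                "ref": t["ref"],
                "alt_freq": t["alt_freq"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeSet:
    """Phased haplotypes: two {0,1} rows per individual over the panel markers."""

    alleles: np.ndarray  # (2*n_individuals, n_markers) uint8 in {0,1}
    ids: list[str]
    founder: np.ndarray  # bool per individual

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.founder = np.asarray(self.founder, dtype=bool)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 2 * len(self.ids):
            raise ValueError("alleles must have two rows per individual")
        if len(self.founder) != len(self.ids):
            raise ValueError("founder flags must align with ids")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def haplotypes_of(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.alleles[2 * i], self.alleles[2 * i + 1]

    def genotypes(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_individuals, n_markers), values {0,1,2}."""
        return (self.alleles[0::2].astype(np.int8) + self.alleles[1::2]).astype(np.int8)


def _uniform_maf(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.05, 0.5, size)


def _allocate_by_length(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n markers proportional to weights."""
    quota = n * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    if rem:
        order = np.argsort(-(quota - base))
        base[order[:rem]] += 1
    return base


def generate_founders(
    n_individuals: int,
    panel_size: int,
    gmap: GeneticMap,
    maf_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | None = None,
) -> tuple[MarkerPanel, HaplotypeSet]:
    """Draw a marker panel and phased founder haplotypes.

    Markers are placed uniformly along the genetic map (counts per chromosome
    proportional to genetic length), alternate-allele frequencies come from
    ``maf_law`` (default uniform(0.05, 0.5)) restricted to [0.05, 0.95] by
    rejection, and alleles are sampled independently per haplotype per site.
    """
    if n_individuals < 1 or panel_size < 1:
        raise ValueError("n_individuals and panel_size must be >= 1")
    rng = np.random.default_rng(seed)
    law = maf_law or _uniform_maf

    freqs = np.empty(panel_size)
    filled = 0
    while filled < panel_size:
        draw = np.asarray(law(rng, panel_size - filled), dtype=float)
        if np.any((draw <= 0) | (draw >= 1)):
            raise ValueError("maf_law must yield frequencies strictly inside (0, 1)")
        keep = draw[np.minimum(draw, 1 - draw) >= 0.05]
        freqs[filled : filled + len(keep)] = keep
        filled += len(keep)

    counts = _allocate_by_length(panel_size, gmap.lengths_cm)
    rows = []
    for chrom, n_c in zip(gmap.chrom_ids, counts):
        if n_c == 0:
            continue
        cm = np.sort(rng.uniform(0.0, gmap.chrom_length_cm(chrom), n_c))
        bp = np.asarray(np.round(gmap.cm_to_bp(chrom, cm)), dtype=np.int64)
        # enforce strictly increasing integer bp, then re-derive consistent cM
        ar = np.arange(n_c)
        bp = np.maximum.accumulate(bp - ar) + ar
        bp = np.maximum(bp, 1)
        if bp[-1] > gmap.chrom_length_bp(chrom):
            raise ValueError("panel too dense for chromosome physical length")
        cm = np.asarray(gmap.bp_to_cm(chrom, bp), dtype=float)
        rows.append(pd.DataFrame({"chrom": chrom, "pos_bp": bp, "pos_cm": cm}))
    table = pd.concat(rows, ignore_index=True)

    ref_i = rng.integers(0, 4, panel_size)
    alt_i = (ref_i + rng.integers(1, 4, panel_size)) % 4
    table["ref"] = _BASES[ref_i]
    table["alt"] = _BASES[alt_i]
    table["alt_freq"] = freqs
    panel = MarkerPanel(table)

    alleles = (rng.random((2 * n_individuals, panel_size)) < freqs).astype(np.uint8)
    haps = HaplotypeSet(
        alleles=alleles,
        ids=[f"F{i:03d}" for i in range(n_individuals)],
        founder=np.ones(n_individuals, dtype=bool),
    )
    return panel, haps


def subsample_panel(
    panel: MarkerPanel,
    haplotypes: HaplotypeSet,
    n_keep: int,
    seed: int | None = None,
) -> tuple[MarkerPanel, HaplotypeSet]:
    """Uniform random marker subset without replacement, order preserved."""
    if not 1 <= n_keep <= len(panel):
        raise ValueError(f"n_keep must be in [1, {len(panel)}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(panel), size=n_keep, replace=False))
    sub_h = HaplotypeSet(
        alleles=haplotypes.alleles[:, idx],
        ids=list(haplotypes.ids),
        founder=haplotypes.founder.copy(),
    )
    return panel.take(idx), sub_h
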